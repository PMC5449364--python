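"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator draws from its own seeded stream and emits a truth manifest
recording exactly what was planted: tandem arrays of same-family genes,
two-cluster subpopulation allele frequencies, co-expression modules with
stress fold-change profiles, promoter motif instances planted at elevated
in-module frequency, and EUL-like proteins with the conserved landmark
residues. Identical seed and configuration give byte-identical outputs.

Promoter sequences are i.i.d. uniform over {A,C,G,T} so chance-hit rates
are analytically checkable, and planted motif instances are exact consensus
insertions, guaranteeing detectability at any sensible score threshold.
SNP genotypes are haploid calls, one allele per accession.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .census import DEFAULT_FAMILY_MAP
from .domains import AMINO_ACIDS, EUL_DOMAIN_LENGTH
from .models import ConfigurationError, DomainAnnotation, GeneModel
from .promoter import PWM

FAMILY_TO_PFAM = {fam: acc for acc, fam in DEFAULT_FAMILY_MAP.items()}

#: EUL-domain landmark residues forced in every simulated domain
#: (1-based domain-frame position -> residue); 118 is handled separately
#: as an F/L mixture and 35 is unconstrained ("x" of the QxW signature).
_FIXED_LANDMARKS = {34: "Q", 36: "W", 116: "D", 136: "W", 143: "N", 144: "Q"}
_LANDMARK_POSITIONS = frozenset(_FIXED_LANDMARKS) | {118}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for all five generators.

    Defaults emulate the published setting: a multi-chromosome genome with a
    three-gene EUL tandem array on chromosome 7, a japonica/indica-like
    subpopulation split at reference-allele fractions 0.95 vs 0.05 with 50
    accessions per subpopulation over 20 SNPs, one 150-gene co-expression
    module with drought/osmotic/ABA/JA fold changes, a promoter motif planted
    at frequency 0.6 in the module vs 0.1 in a 2000-promoter background, a
    quarter of gene ids missing from the id-mapping table (the ~200 to ~150
    regulon shrinkage), and 2 single-domain plus 3 double-domain EUL-like
    proteins.
    """

    seed: int = 0
    # genome / gene models
    n_chromosomes: int = 7
    genes_per_chromosome: int = 50
    family_labels: tuple[str, ...] = ("EUL", "GNA", "legume")
    tandem_array_spec: tuple[tuple[str, int, str], ...] = (("EUL", 3, "chr7"),)
    scattered_spec: tuple[tuple[str, int], ...] = (("EUL", 2), ("GNA", 4), ("legume", 3))
    exon_length: tuple[int, int] = (150, 400)
    intron_length: tuple[int, int] = (80, 300)
    intergenic_length: tuple[int, int] = (300, 900)
    max_exons: int = 4
    # SNPs / subpopulations
    n_snps: int = 20
    subpop_spec: tuple[tuple[str, int, float], ...] = (
        ("Trop", 50, 0.95), ("Subtrop", 50, 0.95), ("Temp", 50, 0.95),
        ("Ind1A", 50, 0.05), ("Ind1B", 50, 0.05), ("Ind2", 50, 0.05),
    )
    missing_rate: float = 0.02
    # expression / co-expression modules
    n_background_genes: int = 2000
    module_spec: tuple[tuple, ...] = (
        ("M1", 150, 8.0, (("drought", 4.0), ("osmotic", 3.0), ("ABA", 2.0), ("JA", 0.5)), 0.35),
    )
    tissues: tuple[str, ...] = ("shoot", "root")
    timepoints: tuple[str, ...] = ("3h", "12h", "24h")
    n_replicates: int = 3
    background_baseline: float = 8.0
    background_sd: float = 0.35
    unmapped_fraction: float = 0.25
    # promoters / motifs / regions
    promoter_length: int = 2000
    motif_plant_spec: tuple[str, float, float] = ("PLANTED", 0.6, 0.1)
    n_null_motifs: int = 9
    motif_width: int = 8
    motif_dominant_prob: float = 0.999
    region_coverage: float = 0.3
    cover_planted_fraction: float = 1.0
    # EUL-like proteins
    eul_spec: tuple[int, int, float] = (2, 3, 0.05)
    fl_mix: float = 0.63  # fraction of domains with F (vs L) at position 118

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(self.n_chromosomes))


# ================================================================ genome

@dataclass
class GenomeSim:
    genome: dict[str, str]
    gene_models: dict[str, GeneModel]
    annotations: list[DomainAnnotation]
    assignments: dict[str, set[str]]
    manifest: dict


def _plan_family_ranks(config: SimulationConfig, rng) -> tuple[dict, list[dict]]:
    """Choose chromosomal ranks for tandem arrays and scattered family genes.

    Same-family genes outside an array stay at least 12 ranks from any other
    gene of that family, so each planted array is recovered exactly.
    """
    G = config.genes_per_chromosome
    by_chrom_family: dict[tuple[str, str], list[int]] = {}
    occupied: dict[str, set[int]] = {c: set() for c in config.chromosomes}
    arrays: list[dict] = []

    def family_ranks(chrom, family):
        return by_chrom_family.get((chrom, family), [])

    def isolated(chrom, family, ranks, min_gap=12):
        existing = family_ranks(chrom, family)
        return all(abs(r - e) >= min_gap for r in ranks for e in existing)

    for family, size, chrom in config.tandem_array_spec:
        if chrom not in config.chromosomes:
            raise ConfigurationError(f"tandem array chromosome {chrom} does not exist")
        if size < 2:
            raise ConfigurationError(f"tandem array size must be >= 2, got {size}")
        placed = False
        for _ in range(200):
            gaps = rng.integers(0, 3, size=size - 1)
            start = int(rng.integers(0, G))
            ranks = [start]
            for g in gaps:
                ranks.append(ranks[-1] + 1 + int(g))
            if ranks[-1] >= G:
                continue
            if any(r in occupied[chrom] for r in ranks):
                continue
            if not isolated(chrom, family, ranks):
                continue
            occupied[chrom].update(ranks)
            by_chrom_family.setdefault((chrom, family), []).extend(ranks)
            arrays.append({"family": family, "chromosome": chrom, "ranks": sorted(ranks)})
            placed = True
            break
        if not placed:
            raise ConfigurationError(
                f"could not place tandem array ({family}, {size}, {chrom}); "
                f"increase genes_per_chromosome")

    scattered: dict[tuple[str, str], list[int]] = {}
    for family, count in config.scattered_spec:
        for _ in range(count):
            placed = False
            for _ in range(500):
                chrom = config.chromosomes[int(rng.integers(0, config.n_chromosomes))]
                rank = int(rng.integers(0, G))
                if rank in occupied[chrom]:
                    continue
                if not isolated(chrom, family, [rank]):
                    continue
                occupied[chrom].add(rank)
                by_chrom_family.setdefault((chrom, family), []).append(rank)
                scattered.setdefault((chrom, family), []).append(rank)
                placed = True
                break
            if not placed:
                raise ConfigurationError(
                    f"could not place scattered {family} gene; genome too crowded")
    return by_chrom_family, arrays


def simulate_genome(config: SimulationConfig) -> GenomeSim:
    """Random genome with non-overlapping, ordered gene models, planted
    tandem arrays and an InterProScan-style domain-annotation table."""
    if config.genes_per_chromosome <= 0:
        raise ConfigurationError("genes_per_chromosome must be positive")
    rng = config.rng(1)
    by_chrom_family, arrays = _plan_family_ranks(config, rng)
    family_of_rank: dict[tuple[str, int], str] = {}
    for (chrom, family), ranks in by_chrom_family.items():
        for r in ranks:
            family_of_rank[(chrom, r)] = family

    genome: dict[str, str] = {}
    models: dict[str, GeneModel] = {}
    annotations: list[DomainAnnotation] = []
    assignments: dict[str, set[str]] = {}
    bases = np.array(list("ACGT"))
    id_of_rank: dict[tuple[str, int], str] = {}

    for ci, chrom in enumerate(config.chromosomes):
        cursor = int(rng.integers(*config.intergenic_length))
        for rank in range(config.genes_per_chromosome):
            gene_id = f"LOC_Os{ci + 1:02d}g{(rank + 1) * 10:05d}"
            id_of_rank[(chrom, rank)] = gene_id
            n_exons = int(rng.integers(1, config.max_exons + 1))
            exons = []
            pos = cursor
            for k in range(n_exons):
                if k:
                    pos += int(rng.integers(*config.intron_length))
                length = int(rng.integers(*config.exon_length))
                exons.append((pos, pos + length))
                pos += length
            utr5 = int(rng.integers(20, 61))
            utr3 = int(rng.integers(20, 61))
            total = sum(e - s for s, e in exons)
            utr3 += (total - utr5 - utr3) % 3
            # trim UTRs off the transcript ends to get CDS intervals
            strand = "+" if rng.random() < 0.5 else "-"
            left, right = (utr5, utr3) if strand == "+" else (utr3, utr5)
            cds = [list(iv) for iv in exons]
            cds[0][0] += left
            cds[-1][1] -= right
            cds = [tuple(iv) for iv in cds if iv[0] < iv[1]]
            model = GeneModel(gene_id, chrom, strand, tuple(exons), tuple(cds))
            models[gene_id] = model
            cursor = pos + int(rng.integers(*config.intergenic_length))

            plen = model.cds_length // 3
            family = family_of_rank.get((chrom, rank))
            if family is not None:
                dstart = int(rng.integers(1, max(2, plen // 4)))
                dend = min(plen, dstart + int(rng.integers(60, 120)))
                annotations.append(DomainAnnotation(gene_id, FAMILY_TO_PFAM[family],
                                                    dstart, dend))
                assignments[gene_id] = {family}
            elif rng.random() < 0.05:
                # decoy non-lectin domain, must be ignored by classification
                annotations.append(DomainAnnotation(gene_id, "PF99999", 1,
                                                    max(1, plen // 2)))
        genome[chrom] = "".join(rng.choice(bases, size=cursor + 200))

    manifest = {
        "tandem_arrays": [
            {"family": a["family"], "chromosome": a["chromosome"],
             "members": [id_of_rank[(a["chromosome"], r)] for r in a["ranks"]]}
            for a in arrays
        ],
        "family_genes": {
            fam: sorted(g for g, fs in assignments.items() if fam in fs)
            for fam in sorted({f for fs in assignments.values() for f in fs})
        },
    }
    return GenomeSim(genome, models, annotations, assignments, manifest)


# ================================================================ SNPs

@dataclass
class SNPSim:
    snp_table: pd.DataFrame        # locus_id, chrom, position (0-based), ref, alt, gene_id
    genotypes: pd.DataFrame        # loci x accessions, 0/1/NaN haploid calls
    subpopulations: pd.Series      # accession -> subpopulation
    manifest: dict


def simulate_population_snps(
    config: SimulationConfig,
    gene_models: Mapping[str, GeneModel],
    genome: Mapping[str, str] | None = None,
) -> SNPSim:
    """SNP loci in gene bodies with genotypes drawn at per-subpopulation
    reference-allele fractions; haploid calls, one allele per accession."""
    if not config.subpop_spec:
        raise ConfigurationError("subpop_spec must be non-empty")
    for name, n_acc, frac in config.subpop_spec:
        fr = np.atleast_1d(np.asarray(frac, dtype=float))
        if np.any((fr < 0) | (fr > 1)):
            raise ConfigurationError(f"{name}: reference fraction outside [0, 1]")
    rng = config.rng(2)
    gene_ids = sorted(gene_models)
    loci = []
    used: set[tuple[str, int]] = set()
    while len(loci) < config.n_snps:
        gid = gene_ids[int(rng.integers(0, len(gene_ids)))]
        m = gene_models[gid]
        pos = int(rng.integers(m.start, m.end))
        if (m.chromosome, pos) in used:
            continue
        used.add((m.chromosome, pos))
        if genome is not None:
            ref = genome[m.chromosome][pos]
        else:
            ref = "ACGT"[int(rng.integers(0, 4))]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        loci.append({"locus_id": f"snp{len(loci):03d}", "chrom": m.chromosome,
                     "position": pos, "ref": ref, "alt": str(alt), "gene_id": gid})
    snp_table = pd.DataFrame(loci, columns=["locus_id", "chrom", "position",
                                            "ref", "alt", "gene_id"])

    accession_cols: list[str] = []
    subpop_of: dict[str, str] = {}
    blocks = []
    true_fractions: dict[str, list[float]] = {}
    for name, n_acc, frac in config.subpop_spec:
        fr = np.broadcast_to(np.atleast_1d(np.asarray(frac, dtype=float)),
                             (config.n_snps,)).astype(float)
        true_fractions[name] = [float(f) for f in fr]
        cols = [f"{name}_{k:03d}" for k in range(n_acc)]
        accession_cols.extend(cols)
        for c in cols:
            subpop_of[c] = name
        draws = (rng.random((config.n_snps, n_acc)) >= fr[:, None]).astype(float)
        if config.missing_rate > 0:
            miss = rng.random((config.n_snps, n_acc)) < config.missing_rate
            draws[miss] = np.nan
        blocks.append(draws)
    genotypes = pd.DataFrame(
        np.hstack(blocks) if blocks else np.empty((config.n_snps, 0)),
        index=snp_table["locus_id"], columns=accession_cols)

    mean_frac = {name: (float(np.mean(f)) if f else 1.0)
                 for name, f in true_fractions.items()}
    manifest = {
        "true_fractions": true_fractions,
        "clusters": {
            "reference_like": sorted(n for n, f in mean_frac.items() if f >= 0.5),
            "alternative_like": sorted(n for n, f in mean_frac.items() if f < 0.5),
        },
    }
    return SNPSim(snp_table, genotypes, pd.Series(subpop_of, name="subpopulation"),
                  manifest)


# ================================================================ expression

def gene_universe(config: SimulationConfig) -> list[str]:
    """Deterministic LOC-style id universe shared by the expression and
    promoter generators."""
    return [f"LOC_Os{(i % 12) + 1:02d}g{60000 + i * 10:05d}"
            for i in range(config.n_background_genes)]


def _resolve_modules(config: SimulationConfig, universe: Sequence[str], rng):
    modules = []
    taken: set[str] = set()
    for module_id, members, baseline, fold_changes, noise_sd in config.module_spec:
        if noise_sd < 0:
            raise ConfigurationError(f"{module_id}: noise sd must be >= 0")
        if isinstance(members, int):
            free = [g for g in universe if g not in taken]
            if members > len(free):
                raise ConfigurationError(f"{module_id}: module larger than universe")
            idx = rng.choice(len(free), size=members, replace=False)
            member_ids = [free[i] for i in sorted(idx)]
        else:
            member_ids = list(members)
            unknown = [g for g in member_ids if g not in set(universe)]
            if unknown:
                raise ConfigurationError(
                    f"{module_id}: unknown gene id(s) {', '.join(unknown[:5])}")
        taken.update(member_ids)
        modules.append({"module_id": module_id, "members": member_ids,
                        "focal": member_ids[0], "baseline": float(baseline),
                        "fold_changes": dict(fold_changes),
                        "noise_sd": float(noise_sd)})
    return modules


@dataclass
class ExpressionSim:
    matrix: pd.DataFrame          # genes x samples, linear scale
    samples: pd.DataFrame         # sample, condition, tissue, timepoint, replicate
    id_map: dict[str, str]
    manifest: dict

    def tidy(self) -> pd.DataFrame:
        """Long-format table (gene, transcript, tissue, condition, timepoint,
        replicate, value) for the expression-response module."""
        long = self.matrix.reset_index(names="gene").melt(
            id_vars="gene", var_name="sample", value_name="value")
        long = long.merge(self.samples, on="sample")
        long["transcript"] = long["gene"] + ".1"
        return long[["gene", "transcript", "tissue", "condition", "timepoint",
                     "replicate", "value"]]


def simulate_expression(config: SimulationConfig) -> ExpressionSim:
    """Expression matrix with planted co-expression modules.

    Values are linear-scale: baseline x condition fold change x lognormal
    noise (sd in log2 units), so at sd 0 the treated/control ratio equals
    the planted fold change exactly. Non-members are uncorrelated noise
    around a flat profile.
    """
    rng = config.rng(3)
    universe = gene_universe(config)
    modules = _resolve_modules(config, universe, rng)

    sample_rows = []
    conditions = sorted({c for m in modules for c in m["fold_changes"]}) or \
        ["ABA", "JA", "drought", "osmotic"]
    for condition in ["control"] + conditions:
        for tissue in config.tissues:
            for timepoint in config.timepoints:
                for rep in range(1, config.n_replicates + 1):
                    sample_rows.append({
                        "sample": f"{condition}_{tissue}_{timepoint}_r{rep}",
                        "condition": condition, "tissue": tissue,
                        "timepoint": timepoint, "replicate": rep})
    samples = pd.DataFrame(sample_rows)

    member_of: dict[str, dict] = {}
    for m in modules:
        for g in m["members"]:
            member_of[g] = m

    n_samples = len(samples)
    cond = samples["condition"].to_numpy()
    values = np.empty((len(universe), n_samples))
    for i, g in enumerate(universe):
        mod = member_of.get(g)
        if mod is None:
            base, sd = config.background_baseline, config.background_sd
            fold = np.ones(n_samples)
        else:
            base, sd = mod["baseline"], mod["noise_sd"]
            fold = np.array([mod["fold_changes"].get(c, 1.0) for c in cond])
        noise = rng.normal(0.0, sd, size=n_samples) if sd > 0 else 0.0
        values[i] = base * fold * np.exp2(noise)
    matrix = pd.DataFrame(values, index=universe, columns=samples["sample"])

    n_unmapped = int(round(config.unmapped_fraction * len(universe)))
    unmapped_idx = rng.choice(len(universe), size=n_unmapped, replace=False)
    unmapped = {universe[i] for i in unmapped_idx}
    id_map = {g: g.replace("LOC_", "MSU_") for g in universe if g not in unmapped}

    manifest = {
        "modules": [{k: m[k] for k in ("module_id", "members", "focal",
                                       "fold_changes", "noise_sd")} for m in modules],
        "n_unmapped": n_unmapped,
    }
    return ExpressionSim(matrix, samples, id_map, manifest)


# ================================================================ promoters

@dataclass
class PromoterSim:
    promoters: dict[str, str]
    pwms: list[PWM]
    regions: dict[str, list[tuple[int, int]]]
    manifest: dict


def _random_pwm(motif_id: str, width: int, dominant: float, rng) -> PWM:
    consensus = rng.integers(0, 4, size=width)
    matrix = np.full((width, 4), (1.0 - dominant) / 3.0)
    matrix[np.arange(width), consensus] = dominant
    return PWM(motif_id, matrix)


def _functional_regions(length: int, coverage: float, rng) -> list[tuple[int, int]]:
    """Non-overlapping intervals covering exactly round(coverage * length)
    bases of one promoter."""
    target = int(round(coverage * length))
    intervals: list[tuple[int, int]] = []
    cursor = 0
    while target > 0:
        max_len = min(300, target)
        seg = int(rng.integers(100, max_len + 1)) if max_len >= 100 else max_len
        slack = length - cursor - target
        gap = int(rng.integers(0, min(200, slack) + 1)) if slack > 0 else 0
        start = cursor + gap
        intervals.append((start, start + seg))
        cursor = start + seg
        target -= seg
    return intervals


def simulate_promoters_and_motifs(
    config: SimulationConfig,
    gene_models: Mapping[str, GeneModel] | None = None,
) -> PromoterSim:
    """Uniform-random promoters with consensus motif instances planted at
    elevated frequency in the co-expression module, plus a PWM library and
    functional-region intervals."""
    motif_id, p_module, p_background = config.motif_plant_spec
    if not (0 <= p_module <= 1 and 0 <= p_background <= 1):
        raise ConfigurationError("plant probabilities must lie in [0, 1]")
    if config.motif_width > config.promoter_length:
        raise ConfigurationError("motif longer than promoter")
    rng = config.rng(4)
    universe = list(gene_universe(config))
    if gene_models:
        universe += [g for g in sorted(gene_models) if g not in set(universe)]
    module_members: set[str] = set()
    if config.module_spec:
        mod_rng = config.rng(3)  # same stream as simulate_expression
        module_members = set(_resolve_modules(config, gene_universe(config),
                                              mod_rng)[0]["members"])

    planted_pwm = _random_pwm(motif_id, config.motif_width,
                              config.motif_dominant_prob, rng)
    pwms = [planted_pwm] + [
        _random_pwm(f"NULL{i:02d}", config.motif_width,
                    config.motif_dominant_prob, rng)
        for i in range(config.n_null_motifs)
    ]
    consensus = planted_pwm.consensus
    w = len(consensus)
    L = config.promoter_length
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
    all_codes = rng.integers(0, 4, size=(len(universe), L), dtype=np.uint8)

    promoters: dict[str, str] = {}
    regions: dict[str, list[tuple[int, int]]] = {}
    planted: list[dict] = []
    for gi, g in enumerate(universe):
        seq = base_bytes[all_codes[gi]].tobytes().decode()
        p = p_module if g in module_members else p_background
        instance = None
        if rng.random() < p:
            start = int(rng.integers(0, L - w + 1))
            seq = seq[:start] + consensus + seq[start + w:]
            instance = (start, start + w)
            planted.append({"gene_id": g, "motif_id": motif_id,
                            "start": start, "end": start + w, "strand": "+"})
        promoters[g] = seq
        ivs = _functional_regions(L, config.region_coverage, rng)
        if instance is not None and rng.random() < config.cover_planted_fraction:
            s, e = instance
            covered = any(min(e, re) - max(s, rs) >= (e - s) for rs, re in ivs)
            if not covered:
                ivs.append(instance)
        regions[g] = sorted(ivs)

    manifest = {
        "planted_motif": {"motif_id": motif_id, "consensus": consensus,
                          "module_probability": p_module,
                          "background_probability": p_background},
        "planted_instances": planted,
        "module_members": sorted(module_members),
    }
    return PromoterSim(promoters, pwms, regions, manifest)


# ================================================================ EUL proteins

@dataclass
class ProteinSim:
    proteins: dict[str, str]
    architecture: pd.DataFrame
    msa: dict[str, str]            # domain name -> 151-aa sequence
    manifest: dict


def _mutate_domain(consensus: str, sub_prob: float, fl_mix: float, rng) -> str:
    residues = list(consensus)
    residues[117] = "F" if rng.random() < fl_mix else "L"  # position 118, 1-based
    if sub_prob > 0:
        for i in range(len(residues)):
            if (i + 1) in _LANDMARK_POSITIONS:
                continue
            if rng.random() < sub_prob:
                choices = [a for a in AMINO_ACIDS if a != residues[i]]
                residues[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(residues)


def simulate_eul_proteins(config: SimulationConfig) -> ProteinSim:
    """EUL-like proteins: every domain is 151 aa with Q34-x-W36, the
    D116/N143/Q144 triad, W136 and an F/L mixture at 118; D-type proteins
    are two domains joined by a linker."""
    n_s, n_d, sub_prob = config.eul_spec
    if n_s < 0 or n_d < 0:
        raise ConfigurationError("EUL protein counts must be >= 0")
    if not (0 <= sub_prob < 1):
        raise ConfigurationError("substitution probability must lie in [0, 1)")
    rng = config.rng(5)
    aas = np.array(list(AMINO_ACIDS))
    consensus = list(rng.choice(aas, size=EUL_DOMAIN_LENGTH))
    for pos, res in _FIXED_LANDMARKS.items():
        consensus[pos - 1] = res
    consensus[117] = "F"
    consensus = "".join(consensus)

    proteins: dict[str, str] = {}
    msa: dict[str, str] = {}
    arch_rows = []
    fl_residues: dict[str, str] = {}

    def new_domain(name: str) -> str:
        dom = _mutate_domain(consensus, sub_prob, config.fl_mix, rng)
        msa[name] = dom
        fl_residues[name] = dom[117]
        return dom

    for i in range(1, n_s + 1):
        pid = f"EULS{i}"
        nterm = "".join(rng.choice(aas, size=int(rng.integers(19, 118))))
        dom = new_domain(f"{pid}_1")
        proteins[pid] = nterm + dom
        arch_rows.append({"protein_id": pid, "type": "S",
                          "domain1_start": len(nterm) + 1,
                          "domain1_end": len(nterm) + EUL_DOMAIN_LENGTH,
                          "domain2_start": np.nan, "domain2_end": np.nan,
                          "nterm_length": len(nterm), "linker_length": 0})
    for i in range(1, n_d + 1):
        pid = f"EULD{i}"
        nterm = "".join(rng.choice(aas, size=int(rng.integers(19, 118))))
        linker = "".join(rng.choice(aas, size=int(rng.integers(18, 77))))
        d1, d2 = new_domain(f"{pid}_1"), new_domain(f"{pid}_2")
        proteins[pid] = nterm + d1 + linker + d2
        s1 = len(nterm) + 1
        e1 = s1 + EUL_DOMAIN_LENGTH - 1
        s2 = e1 + len(linker) + 1
        arch_rows.append({"protein_id": pid, "type": "D",
                          "domain1_start": s1, "domain1_end": e1,
                          "domain2_start": s2,
                          "domain2_end": s2 + EUL_DOMAIN_LENGTH - 1,
                          "nterm_length": len(nterm), "linker_length": len(linker)})
    architecture = pd.DataFrame(arch_rows)
    manifest = {
        "consensus": consensus,
        "substitution_probability": float(sub_prob),
        "fl_mix": config.fl_mix,
        "position118": fl_residues,
        "n_s_type": n_s, "n_d_type": n_d,
    }
    return ProteinSim(proteins, architecture, msa, manifest)


# ================================================================ bundle I/O

def simulate_all(config: SimulationConfig, outdir) -> dict:
    """Run all five generators and write every artifact plus truth.json."""
    from . import io as lio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    gsim = simulate_genome(config)
    ssim = simulate_population_snps(config, gsim.gene_models, gsim.genome)
    esim = simulate_expression(config)
    psim = simulate_promoters_and_motifs(config)
    prot = simulate_eul_proteins(config)

    lio.write_fasta(gsim.genome, out / "genome.fa")
    lio.write_gff3(gsim.gene_models, out / "genes.gff3")
    lio.write_domain_annotations(gsim.annotations, out / "domains.tsv")

    snp_out = ssim.snp_table.copy()
    snp_out["POS"] = snp_out["position"] + 1  # 1-based at the file boundary
    snp_out = snp_out.rename(columns={"chrom": "CHROM", "ref": "REF", "alt": "ALT"})
    lio.write_tsv(snp_out[["locus_id", "CHROM", "POS", "REF", "ALT", "gene_id"]],
                  out / "snps.tsv")
    lio.write_tsv(ssim.genotypes.reset_index(), out / "genotypes.tsv")
    lio.write_tsv(ssim.subpopulations.rename_axis("accession").reset_index(),
                  out / "subpopulations.tsv")

    lio.write_tsv(esim.matrix.rename_axis("gene").reset_index(), out / "expression.tsv")
    lio.write_tsv(esim.samples, out / "samples.tsv")
    lio.write_tsv(pd.DataFrame(sorted(esim.id_map.items()),
                               columns=["gene_id", "mapped_id"]), out / "id_map.tsv")

    lio.write_fasta(psim.promoters, out / "promoters.fa")
    pwm_lines = []
    for pwm in psim.pwms:  # JASPAR-style counts (probabilities x 100)
        pwm_lines.append(f">{pwm.motif_id}")
        for bi, base in enumerate("ACGT"):
            vals = " ".join(f"{100 * v:.2f}" for v in pwm.matrix[:, bi])
            pwm_lines.append(f"{base}  [ {vals} ]")
    (out / "motifs.jaspar").write_text("\n".join(pwm_lines) + "\n")
    bed = pd.DataFrame(
        [(g, s, e, "region") for g, ivs in psim.regions.items() for s, e in ivs],
        columns=["chrom", "start", "end", "name"])
    lio.write_bed(bed, out / "regions.bed")

    lio.write_fasta(prot.proteins, out / "proteins.fa")
    lio.write_fasta(prot.msa, out / "eul_domains.fa")
    lio.write_tsv(prot.architecture, out / "architectures.tsv")

    manifest = {
        "config": dataclasses.asdict(config),
        "genome": gsim.manifest,
        "snps": ssim.manifest,
        "expression": esim.manifest,
        "promoters": psim.manifest,
        "proteins": prot.manifest,
    }
    (out / "truth.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
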