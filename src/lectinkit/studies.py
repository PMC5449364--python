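"""Recovery and calibration studies on synthetic data.

Each study runs one pipeline stage across many simulation seeds under the
default study conditions and measures how well the planted truth is
recovered. They back both the test suite and the reproduction script, and
are deterministic given a base seed (per-replicate seeds are derived as
``base_seed * 100000 + i`` and stay below 2**31).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .census import RICE_JAPONICA_COUNTS, census_from_counts, classify_lectin_genes
from .duplication import GeneOrderIndex, call_tandem_duplications
from .domains import similarity_matrix, conservation_profile
from .promoter import build_regulon, hypergeom_enrichment, motif_presence
from .simulate import (
    SimulationConfig,
    gene_universe,
    simulate_eul_proteins,
    simulate_expression,
    simulate_genome,
    simulate_population_snps,
    simulate_promoters_and_motifs,
)
from .variation import reference_allele_matrix, upgma_rmsd


def _seed(base_seed: int, i: int) -> int:
    return (base_seed * 100_000 + i) % (2 ** 31 - 1)


# ---------------------------------------------------------------- census

def census_reference_study() -> dict:
    """Census arithmetic on the published japonica per-family counts."""
    table = census_from_counts(RICE_JAPONICA_COUNTS)
    largest = table.largest
    smallest = table.smallest
    return {
        "total": table.total,
        "largest_family": largest[0],
        "largest_count": largest[1],
        "largest_pct": table.percentages[largest[0]],
        "smallest_family": smallest[0],
        "smallest_pct": table.percentages[smallest[0]],
        "gna_legume_pct": table.share(["GNA", "legume"]),
        "n_represented": table.n_represented,
    }


# ---------------------------------------------------------------- tandem arrays

def tandem_recovery_study(n_seeds: int = 20, base_seed: int = 1) -> dict:
    """Fraction of planted tandem arrays recovered exactly (members and
    order) by the tandem-calling rule."""
    planted = recovered = 0
    for i in range(n_seeds):
        config = SimulationConfig(seed=_seed(base_seed, i))
        sim = simulate_genome(config)
        order = GeneOrderIndex.from_models(sim.gene_models)
        assignments = classify_lectin_genes(sim.annotations)
        blocks = call_tandem_duplications(order, assignments)
        called = {(b.family, b.chromosome, b.members) for b in blocks}
        for array in sim.manifest["tandem_arrays"]:
            planted += 1
            key = (array["family"], array["chromosome"], tuple(array["members"]))
            if key in called:
                recovered += 1
    return {"recovery_fraction": recovered / planted, "n_planted": planted,
            "n_seeds": n_seeds}


# ---------------------------------------------------------------- regulons

def regulon_recovery_study(n_seeds: int = 100, base_seed: int = 1,
                           top_n: int = 200) -> dict:
    """Membership recovery of the planted co-expression module in the
    top-``top_n`` regulon of its focal gene."""
    recoveries = []
    for i in range(n_seeds):
        config = SimulationConfig(seed=_seed(base_seed, i))
        sim = simulate_expression(config)
        module = sim.manifest["modules"][0]
        members = set(module["members"]) - {module["focal"]}
        regulon = build_regulon(sim.matrix, module["focal"], top_n=top_n,
                                log_transform=True)
        top = {g for g, _ in regulon.selected}
        recoveries.append(len(top & members) / len(members))
    rec = np.asarray(recoveries)
    return {
        "mean_recovery": float(rec.mean()),
        "min_recovery": float(rec.min()),
        "fraction_seeds_ge_095": float((rec >= 0.95).mean()),
        "n_seeds": n_seeds,
    }


def regulon_size_after_mapping(base_seed: int = 1) -> dict:
    """Top-200 regulon shrinkage through the id-mapping table (~200 -> ~150
    with a quarter of ids unmapped)."""
    config = SimulationConfig(seed=_seed(base_seed, 0))
    sim = simulate_expression(config)
    module = sim.manifest["modules"][0]
    regulon = build_regulon(sim.matrix, module["focal"], top_n=200,
                            id_map=sim.id_map, log_transform=True)
    return {"selected": len(regulon.selected), "mapped_size": regulon.size}


# ---------------------------------------------------------------- motif enrichment

def motif_enrichment_study(n_seeds: int = 100, base_seed: int = 1,
                           q_threshold: float = 0.05,
                           threshold_bits: float = 6.0) -> dict:
    """Power of the regulon hypergeometric test on the planted motif.

    Per seed: promoters are scanned for the full PWM library, presence is
    tallied over the planted module (foreground) and the whole universe
    (background), and the planted motif counts as detected when its BH q
    falls below ``q_threshold``.
    """
    detected = 0
    for i in range(n_seeds):
        config = SimulationConfig(seed=_seed(base_seed, i))
        sim = simulate_promoters_and_motifs(config)
        members = sim.manifest["module_members"]
        presence = motif_presence(sim.promoters, sim.pwms, threshold_bits)
        result = hypergeom_enrichment(members, presence,
                                      background_genes=list(sim.promoters),
                                      focal_gene=members[0],
                                      q_threshold=q_threshold)
        planted_id = sim.manifest["planted_motif"]["motif_id"]
        row = result[result["motif_id"] == planted_id].iloc[0]
        if row["q"] < q_threshold:
            detected += 1
    return {"power": detected / n_seeds, "n_seeds": n_seeds}


def motif_null_fdr_study(n_seeds: int = 100, base_seed: int = 1,
                         q_threshold: float = 0.05,
                         threshold_bits: float = 6.0) -> dict:
    """Empirical false-discovery behaviour with nothing planted.

    All motifs are null (plant probabilities zero; only chance PWM matches
    occur, at equal rates in foreground and background). Reports the
    fraction of motif tests reaching q < threshold, which should stay
    within the nominal FDR plus binomial noise.
    """
    rejections = tests = 0
    for i in range(n_seeds):
        config = dataclasses.replace(
            SimulationConfig(seed=_seed(base_seed, 10_000 + i)),
            motif_plant_spec=("PLANTED", 0.0, 0.0))
        sim = simulate_promoters_and_motifs(config)
        members = sim.manifest["module_members"]
        presence = motif_presence(sim.promoters, sim.pwms, threshold_bits)
        result = hypergeom_enrichment(members, presence,
                                      background_genes=list(sim.promoters),
                                      focal_gene=members[0],
                                      q_threshold=q_threshold)
        rejections += int((result["q"] < q_threshold).sum())
        tests += len(result)
    fraction = rejections / tests if tests else 0.0
    se = float(np.sqrt(q_threshold * (1 - q_threshold) / max(tests, 1)))
    return {"fraction_q_lt_threshold": fraction, "n_tests": tests,
            "bound": q_threshold + 2 * se, "n_seeds": n_seeds}


# ---------------------------------------------------------------- subpopulations

def bipartition_recovery_study(n_seeds: int = 200, base_seed: int = 1) -> dict:
    """Fraction of two-cluster SNP panels whose UPGMA root bipartition
    matches the planted reference-like vs alternative-like split."""
    config0 = SimulationConfig(
        n_chromosomes=1, genes_per_chromosome=25,
        tandem_array_spec=(), scattered_spec=())
    hits = 0
    for i in range(n_seeds):
        config = dataclasses.replace(config0, seed=_seed(base_seed, i))
        gsim = simulate_genome(config)
        ssim = simulate_population_snps(config, gsim.gene_models)
        matrix = reference_allele_matrix(ssim.genotypes, ssim.subpopulations)
        tree = upgma_rmsd(matrix)
        split = {frozenset(side) for side in tree.root_bipartition()}
        truth = {frozenset(ssim.manifest["clusters"]["reference_like"]),
                 frozenset(ssim.manifest["clusters"]["alternative_like"])}
        if split == truth:
            hits += 1
    return {"recovery_fraction": hits / n_seeds, "n_seeds": n_seeds}


# ---------------------------------------------------------------- EUL conservation

def eul_zero_noise_study(base_seed: int = 1) -> dict:
    """Landmark conservation and pairwise identity on noise-free EUL sets."""
    config = dataclasses.replace(SimulationConfig(seed=_seed(base_seed, 0)),
                                 eul_spec=(2, 3, 0.0), fl_mix=1.0)
    sim = simulate_eul_proteins(config)
    profile = conservation_profile(sim.msa)
    landmark_fractions = {name: rep["fraction"]
                          for name, rep in profile.landmarks.items()}
    sm = similarity_matrix(sim.msa)
    return {
        "min_landmark_fraction": min(landmark_fractions.values()),
        "landmarks": landmark_fractions,
        "min_pairwise_identity": float(sm["identity"].min()),
        "n_domains": len(sim.msa),
    }
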