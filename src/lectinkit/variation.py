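"""SNP consequence classification and subpopulation allele-frequency clustering.

Consequences are called against a gene model and its spliced CDS: a variant
falling in coding sequence has its codon substituted (strand-aware) and
translated; an unchanged amino acid is silent, a changed one missense.
Subpopulations are compared by the percentage of accessions carrying the
reference allele at each locus, clustered by UPGMA on an RMSD distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .models import GeneModel, StructuralError

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def spliced_cds(model: GeneModel, genome: Mapping[str, str]) -> str:
    """Spliced CDS sequence in transcript orientation."""
    chrom = genome[model.chromosome]
    seq = "".join(chrom[s:e] for s, e in model.cds)
    if model.strand == "-":
        seq = "".join(COMPLEMENT.get(b, "N") for b in reversed(seq.upper()))
    return seq.upper()


@dataclass(frozen=True)
class SNPRecord:
    chromosome: str
    position: int          # 0-based genomic
    ref: str
    alt: str
    gene_id: str | None
    feature: str           # intergenic | UTR | intron | exon-CDS
    consequence: str       # none | silent | missense
    aa_change: tuple[str, int, str] | None = None  # (ref aa, 1-based codon, alt aa)


def _cds_offset(model: GeneModel, position: int) -> int | None:
    """Map a genomic position to its 0-based offset in the spliced CDS,
    transcript orientation."""
    segments = model.cds if model.strand == "+" else tuple(reversed(model.cds))
    offset = 0
    for s, e in segments:
        if s <= position < e:
            return offset + (position - s if model.strand == "+" else e - 1 - position)
        offset += e - s
    return None


def classify_snp(
    model: GeneModel | None,
    cds_sequence: str | None,
    chromosome: str,
    position: int,
    ref: str,
    alt: str,
) -> SNPRecord:
    """Classify a single-base substitution against a gene model.

    ``position`` is 0-based genomic; ``ref``/``alt`` are genomic-strand bases.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise ValueError(f"alt allele equals ref ({ref}) at {chromosome}:{position + 1}")
    if model is None or model.chromosome != chromosome or not (model.start <= position < model.end):
        return SNPRecord(chromosome, position, ref, alt, None, "intergenic", "none")

    in_exon = any(s <= position < e for s, e in model.exons)
    if not in_exon:
        return SNPRecord(chromosome, position, ref, alt, model.gene_id, "intron", "none")

    offset = _cds_offset(model, position)
    if offset is None:
        return SNPRecord(chromosome, position, ref, alt, model.gene_id, "UTR", "none")

    if cds_sequence is None:
        raise StructuralError(f"{model.gene_id}: CDS sequence required for coding SNP")
    cds_sequence = cds_sequence.upper()
    if len(cds_sequence) % 3 != 0:
        raise StructuralError(
            f"{model.gene_id}: CDS length {len(cds_sequence)} not divisible by 3")
    # transcript-strand alleles
    t_ref = ref if model.strand == "+" else COMPLEMENT[ref]
    t_alt = alt if model.strand == "+" else COMPLEMENT[alt]
    if cds_sequence[offset] != t_ref:
        raise StructuralError(
            f"{model.gene_id}: CDS base {cds_sequence[offset]} at offset {offset} "
            f"does not match reference allele {t_ref}")
    codon_idx = offset // 3
    within = offset % 3
    codon = cds_sequence[3 * codon_idx: 3 * codon_idx + 3]
    alt_codon = codon[:within] + t_alt + codon[within + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref == aa_alt:
        return SNPRecord(chromosome, position, ref, alt, model.gene_id,
                         "exon-CDS", "silent")
    return SNPRecord(chromosome, position, ref, alt, model.gene_id,
                     "exon-CDS", "missense", (aa_ref, codon_idx + 1, aa_alt))


# ---------------------------------------------------------------- allele matrix

@dataclass
class AlleleFrequencyMatrix:
    """Percent reference allele per locus x subpopulation, with denominators.

    Cells are computed over non-missing genotypes only; a cell with no calls
    is NA and its denominator zero.
    """

    values: pd.DataFrame       # percent in [0, 100], NaN where undefined
    denominators: pd.DataFrame

    @property
    def fractions(self) -> pd.DataFrame:
        return self.values / 100.0


def reference_allele_matrix(
    genotypes: pd.DataFrame,
    subpopulations: pd.Series | Mapping[str, str],
) -> AlleleFrequencyMatrix:
    """Percent reference allele per locus and subpopulation.

    ``genotypes``: loci x accessions, coded 0 (reference), 1 (alternative),
    NaN (missing) — haploid calls. ``subpopulations`` maps accession -> name.
    """
    subpops = pd.Series(subpopulations)
    unassigned = [a for a in genotypes.columns if a not in subpops.index]
    if unassigned:
        raise KeyError(f"accessions without subpopulation: {', '.join(map(str, unassigned))}")
    groups = subpops.loc[genotypes.columns]
    values, denoms = {}, {}
    for name, cols in groups.groupby(groups).groups.items():
        block = genotypes[list(cols)]
        n = block.notna().sum(axis=1)
        ref = (block == 0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            values[name] = 100.0 * ref / n.replace(0, np.nan)
        denoms[name] = n
    return AlleleFrequencyMatrix(values=pd.DataFrame(values), denominators=pd.DataFrame(denoms))


# ---------------------------------------------------------------- UPGMA / RMSD

@dataclass(frozen=True)
class TreeNode:
    """Node of an ultrametric dendrogram; ``height`` is the merge height."""

    name: str | None
    height: float
    children: tuple["TreeNode", ...] = ()

    @property
    def leaves(self) -> tuple[str, ...]:
        if not self.children:
            return (self.name,)
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves)
        return tuple(out)

    def newick(self) -> str:
        return self._newick_inner(parent_height=self.height) + ";"

    def _newick_inner(self, parent_height: float) -> str:
        bl = parent_height - self.height
        if not self.children:
            return f"{self.name}:{bl:.6g}"
        inner = ",".join(c._newick_inner(self.height) for c in self.children)
        return f"({inner}):{bl:.6g}"


@dataclass
class Dendrogram:
    root: TreeNode
    labels: tuple[str, ...]
    merges: list[tuple[frozenset, float]]   # (leaf set, merge height)

    def newick(self) -> str:
        return self.root.newick()

    def root_bipartition(self) -> tuple[frozenset, frozenset]:
        a, b = self.root.children
        return frozenset(a.leaves), frozenset(b.leaves)


def rmsd_distance_matrix(fractions: pd.DataFrame) -> pd.DataFrame:
    """Pairwise RMSD between subpopulation columns on the fractional scale.

    d(a, b) = sqrt(mean over loci of (x_a - x_b)^2), using pairwise-complete
    loci when cells are missing.
    """
    cols = list(fractions.columns)
    x = fractions.to_numpy(dtype=float)
    n = len(cols)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~(np.isnan(x[:, i]) | np.isnan(x[:, j]))
            if not both.any():
                raise ValueError(f"no shared loci between {cols[i]} and {cols[j]}")
            diff = x[both, i] - x[both, j]
            d[i, j] = d[j, i] = float(np.sqrt(np.mean(diff ** 2)))
    return pd.DataFrame(d, index=cols, columns=cols)


def upgma(distance: pd.DataFrame) -> Dendrogram:
    """Average-linkage agglomeration of a symmetric distance matrix.

    Ties are broken toward the lowest-index pair (row-major scan) for
    determinism. Merge height is half the merged distance, giving an
    ultrametric tree with non-decreasing heights toward the root.
    """
    labels = tuple(distance.columns)
    if len(labels) < 2:
        raise ValueError("UPGMA needs at least two subpopulations")
    d = distance.to_numpy(dtype=float).copy()
    nodes: list[TreeNode] = [TreeNode(name=l, height=0.0) for l in labels]
    sizes = [1] * len(labels)
    active = list(range(len(labels)))
    merges: list[tuple[frozenset, float]] = []
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                if best is None or d[i, j] < best[0]:
                    best = (d[i, j], ai, aj)
        dist, ai, aj = best
        i, j = active[ai], active[aj]
        height = dist / 2.0
        node = TreeNode(name=None, height=height, children=(nodes[i], nodes[j]))
        merges.append((frozenset(node.leaves), height))
        # average-linkage update, weighted by cluster sizes
        ni, nj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            d_new = (ni * d[i, k] + nj * d[j, k]) / (ni + nj)
            d[i, k] = d[k, i] = d_new
        nodes[i] = node
        sizes[i] = ni + nj
        active.pop(aj)
    return Dendrogram(root=nodes[active[0]], labels=labels, merges=merges)


def upgma_rmsd(matrix: AlleleFrequencyMatrix | pd.DataFrame,
               scale: str = "fraction") -> Dendrogram:
    """UPGMA dendrogram over subpopulations from an allele-frequency matrix.

    ``scale``: 'fraction' (default; distances on 0-1 allele fractions) or
    'percent' (0-100, as printed).
    """
    values = matrix.values if isinstance(matrix, AlleleFrequencyMatrix) else matrix
    all_na = [c for c in values.columns if values[c].isna().all()]
    if all_na:
        import logging
        logging.getLogger(__name__).warning(
            "excluding all-missing subpopulation column(s): %s", ", ".join(all_na))
        values = values.drop(columns=all_na)
    frac = values / 100.0 if scale == "fraction" else values
    return upgma(rmsd_distance_matrix(frac))
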