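"""Lectin gene-family census.

Plant lectins fall into 12 structurally defined families, each recognised by
a diagnostic Pfam domain. Genes are classified from their domain annotations,
counted per family, and summarised Table-style (count, percentage of total,
largest/smallest family, number of represented families), together with
chromosome maps and exon/intron structure summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import pandas as pd

from .models import DomainAnnotation, GeneModel, StructuralError

logger = logging.getLogger(__name__)

#: Diagnostic Pfam accession for each of the 12 plant lectin families.
DEFAULT_FAMILY_MAP: dict[str, str] = {
    "PF07367": "ABA",        # fungal fruit body lectin
    "PF07468": "amaranthin",
    "PF00704": "CRA",        # glyco-hydrolase 18, chitinase-related agglutinin
    "PF08881": "cyanovirin",
    "PF14200": "EUL",        # ricin-lectin 2
    "PF01453": "GNA",        # B-lectin
    "PF00187": "hevein",     # chitin-binding 1
    "PF01419": "JRL",        # jacalin
    "PF00139": "legume",     # lectin legB
    "PF01476": "LysM",
    "PF14299": "nictaba",    # PP2
    "PF00652": "ricin-B",
}

FAMILY_NAMES: tuple[str, ...] = tuple(sorted(set(DEFAULT_FAMILY_MAP.values())))

#: Published japonica rice per-family gene counts (families absent from the
#: genome carry zero). Used as reference input for census arithmetic checks.
RICE_JAPONICA_COUNTS: dict[str, int] = {
    "ABA": 0, "amaranthin": 0, "CRA": 2, "cyanovirin": 0, "EUL": 5,
    "GNA": 134, "hevein": 10, "JRL": 30, "legume": 104, "LysM": 20,
    "nictaba": 20, "ricin-B": 4,
}


def _round_half_up(value: Decimal, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int, decimals: int = 1) -> float:
    """100 * count / total rounded half-up, matching printed table style."""
    if total == 0:
        return 0.0
    return _round_half_up(Decimal(100 * count) / Decimal(total), decimals)


# ---------------------------------------------------------------- classification

def classify_lectin_genes(
    annotations: Iterable[DomainAnnotation],
    family_map: Mapping[str, str] | None = None,
) -> dict[str, set[str]]:
    """Assign each gene the set of lectin families its domains belong to.

    Genes with no mapped lectin domain are excluded. Unknown accessions are
    ignored with a warning (they are simply non-lectin domains). Genes with
    domains from more than one family carry all labels.
    """
    fmap = dict(family_map) if family_map is not None else DEFAULT_FAMILY_MAP
    assignments: dict[str, set[str]] = {}
    unknown: set[str] = set()
    for ann in annotations:
        fam = fmap.get(ann.domain_id)
        if fam is None:
            unknown.add(ann.domain_id)
            continue
        assignments.setdefault(ann.gene_id, set()).add(fam)
    if unknown:
        logger.warning("ignored %d non-lectin domain accession(s): %s",
                       len(unknown), ", ".join(sorted(unknown)[:10]))
    return assignments


def multi_family_genes(assignments: Mapping[str, set[str]]) -> list[str]:
    return sorted(g for g, fams in assignments.items() if len(fams) > 1)


# ---------------------------------------------------------------- census

@dataclass
class CensusTable:
    """Per-family counts and shares of a lectin gene census.

    ``total`` counts distinct genes; ``family_total`` counts one entry per
    family label, so a gene carrying two family labels contributes twice to
    ``family_total`` but once to ``total``.
    """

    counts: dict[str, int]
    total: int
    family_total: int = 0
    percentages: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.family_total:
            self.family_total = sum(self.counts.values())
        if not self.percentages:
            self.percentages = {
                fam: percentage(c, self.total) for fam, c in self.counts.items()
            }

    @property
    def represented(self) -> list[str]:
        """Families with at least one gene."""
        return [f for f, c in self.counts.items() if c >= 1]

    @property
    def n_represented(self) -> int:
        return len(self.represented)

    @property
    def largest(self) -> tuple[str, int] | None:
        items = [(f, c) for f, c in self.counts.items() if c >= 1]
        return max(items, key=lambda fc: (fc[1], fc[0])) if items else None

    @property
    def smallest(self) -> tuple[str, int] | None:
        items = [(f, c) for f, c in self.counts.items() if c >= 1]
        return min(items, key=lambda fc: (fc[1], fc[0])) if items else None

    def share(self, families: Iterable[str]) -> float:
        """Combined percentage of the given families (rounded half-up)."""
        return percentage(sum(self.counts.get(f, 0) for f in families), self.total)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"family": fam, "count": self.counts.get(fam, 0),
             "percentage": self.percentages.get(fam, 0.0)}
            for fam in sorted(self.counts)
        ]
        return pd.DataFrame(rows)


def family_census(assignments: Mapping[str, set[str]],
                  families: Iterable[str] = FAMILY_NAMES) -> CensusTable:
    """Census of classified genes: counts per family and distinct-gene total."""
    counts = {fam: 0 for fam in families}
    for fams in assignments.values():
        for fam in fams:
            counts.setdefault(fam, 0)
            counts[fam] += 1
    return CensusTable(counts=counts, total=len(assignments))


def census_from_counts(counts: Mapping[str, int],
                       families: Iterable[str] = FAMILY_NAMES) -> CensusTable:
    """Census directly from printed per-family counts (one family per gene)."""
    full = {fam: 0 for fam in families}
    for fam, c in counts.items():
        full.setdefault(fam, 0)
        if c < 0:
            raise ValueError(f"negative count for family {fam}")
        full[fam] = int(c)
    return CensusTable(counts=full, total=sum(full.values()))


# ---------------------------------------------------------------- chromosome map

def chromosome_map(
    gene_models: Mapping[str, GeneModel],
    assignments: Mapping[str, set[str]],
) -> tuple[dict[str, list[dict]], list[str]]:
    """Ordered per-chromosome tracks of assigned genes plus an unplaced list.

    Each track entry carries the gene id, start position and family labels,
    sorted by start so the track is drawable to scale.
    """
    tracks: dict[str, list[dict]] = {}
    unplaced: list[str] = []
    for gene_id in sorted(assignments):
        model = gene_models.get(gene_id)
        if model is None:
            unplaced.append(gene_id)
            continue
        tracks.setdefault(model.chromosome, []).append(
            {"gene_id": gene_id, "start": model.start, "end": model.end,
             "strand": model.strand, "families": sorted(assignments[gene_id])}
        )
    for entries in tracks.values():
        entries.sort(key=lambda e: (e["start"], e["gene_id"]))
    return tracks, unplaced


# ---------------------------------------------------------------- gene structure

def gene_structure_summary(model: GeneModel) -> dict:
    """Exon/intron counts and sizes in transcript orientation, plus UTR extents.

    Intron i spans the gap between exon i and exon i+1; UTRs are the exonic
    bases outside the CDS span, oriented 5'/3' by strand.
    """
    exons = list(model.exons)
    exon_sizes = [e - s for s, e in exons]
    intron_sizes = [s1 - e0 for (_, e0), (s1, _) in zip(exons, exons[1:])]
    if any(sz <= 0 for sz in intron_sizes):
        raise StructuralError(f"{model.gene_id}: touching or overlapping exons")
    utr_left = utr_right = 0
    if model.cds:
        cds_lo, cds_hi = model.cds[0][0], model.cds[-1][1]
        utr_left = sum(min(e, cds_lo) - s for s, e in exons if s < cds_lo)
        utr_right = sum(e - max(s, cds_hi) for s, e in exons if e > cds_hi)
    if model.strand == "-":
        exon_sizes.reverse()
        intron_sizes.reverse()
        utr_left, utr_right = utr_right, utr_left
    return {
        "gene_id": model.gene_id,
        "n_exons": len(exons),
        "n_introns": len(exons) - 1,
        "exon_sizes": exon_sizes,
        "intron_sizes": intron_sizes,
        "utr5_length": utr_left,
        "utr3_length": utr_right,
        "cds_length": model.cds_length,
    }
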