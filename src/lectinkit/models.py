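"""Shared domain types.

Coordinate conventions: genomic intervals are 0-based half-open internally;
GFF3 (1-based inclusive), VCF-like TSV (1-based POS) and BED (0-based
half-open) are converted at the file boundary. Protein residue coordinates
are 1-based inclusive throughout, matching InterProScan-style tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

Interval = tuple[int, int]


class StructuralError(ValueError):
    """Raised when an input violates a structural invariant (e.g. overlapping
    exons, CDS length not divisible by three)."""


class ConfigurationError(ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


def _check_sorted_disjoint(intervals: Iterable[Interval], what: str) -> tuple[Interval, ...]:
    ivs = tuple((int(s), int(e)) for s, e in intervals)
    for s, e in ivs:
        if s >= e:
            raise StructuralError(f"empty or inverted {what} interval [{s}, {e})")
    for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
        if s1 < e0:
            raise StructuralError(f"overlapping {what} intervals [{s0},{e0}) and [{s1},{e1})")
    return ivs


@dataclass(frozen=True)
class GeneModel:
    """A gene's placement and structure on the genome.

    ``exons`` and ``cds`` are sorted, non-overlapping genomic intervals
    (0-based half-open) regardless of strand; transcript orientation is
    applied where needed (intron numbering, codon mapping, promoters).
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...] = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise StructuralError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        object.__setattr__(self, "exons", _check_sorted_disjoint(self.exons, "exon"))
        object.__setattr__(self, "cds", _check_sorted_disjoint(self.cds, "CDS"))

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def atg_position(self) -> int:
        """Translation-start anchor as a half-open boundary: the promoter is
        the ``length`` bases strictly upstream of this coordinate.

        On the + strand this is the first CDS base; on the - strand it is the
        end boundary of the last CDS interval (the first transcribed CDS base
        sits just left of it).
        """
        if not self.cds:
            raise StructuralError(f"{self.gene_id}: no CDS; cannot anchor on ATG")
        return self.cds[0][0] if self.strand == "+" else self.cds[-1][1]


@dataclass(frozen=True)
class DomainAnnotation:
    """One protein-domain hit (InterProScan-style), residues 1-based inclusive."""

    gene_id: str
    domain_id: str
    aa_start: int
    aa_end: int

    def __post_init__(self):
        if self.aa_start < 1 or self.aa_start > self.aa_end:
            raise StructuralError(
                f"{self.gene_id}/{self.domain_id}: bad residue interval "
                f"[{self.aa_start}, {self.aa_end}]"
            )


COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]
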