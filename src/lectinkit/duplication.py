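"""Tandem and segmental duplication calling for lectin genes.

Tandem rule: two genes are tandem-linked iff (1) they belong to the same
lectin family, (2) no more than ``max_intervening`` genes lie between them
in chromosomal order (counting ALL annotated genes, not just lectins), and
(3) they reside on the same chromosome. Blocks are connected components of
this link relation. Segmental (collinear) blocks are consumed from an
external collinearity table and filtered on Ks and lectin membership.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .models import GeneModel


@dataclass(frozen=True)
class GeneOrderIndex:
    """Ordinal rank of every annotated gene within its chromosome."""

    ranks: dict[str, tuple[str, int]]  # gene_id -> (chromosome, rank)
    order: dict[str, list[str]]        # chromosome -> gene ids by rank

    @classmethod
    def from_models(cls, models: Mapping[str, GeneModel]) -> "GeneOrderIndex":
        by_chrom: dict[str, list[tuple[int, str]]] = {}
        for gid, m in models.items():
            by_chrom.setdefault(m.chromosome, []).append((m.start, gid))
        order, ranks = {}, {}
        for chrom, entries in by_chrom.items():
            entries.sort()
            ids = [gid for _, gid in entries]
            order[chrom] = ids
            for rank, gid in enumerate(ids):
                ranks[gid] = (chrom, rank)
        return cls(ranks=ranks, order=order)


@dataclass(frozen=True)
class TandemBlock:
    family: str
    chromosome: str
    members: tuple[str, ...]           # in chromosomal order
    intervening: tuple[int, ...]       # gene count between consecutive members


@dataclass(frozen=True)
class SegmentalBlock:
    block_id: str
    gene_a: str
    gene_b: str
    ks: float

    def __post_init__(self):
        if self.ks < 0:
            raise ValueError(f"block {self.block_id}: negative Ks {self.ks}")


def call_tandem_duplications(
    order: GeneOrderIndex,
    assignments: Mapping[str, set[str]],
    max_intervening: int = 10,
) -> list[TandemBlock]:
    """Call tandem blocks as connected components of the pairwise link rule.

    Transitivity is deliberate: A-B and B-C linked puts {A,B,C} in one block
    even when A and C alone exceed the gap.
    """
    missing = sorted(g for g in assignments if g not in order.ranks)
    if missing:
        raise KeyError(f"assigned gene(s) missing from gene order: {', '.join(missing)}")
    blocks: list[TandemBlock] = []
    families = sorted({f for fams in assignments.values() for f in fams})
    for family in families:
        per_chrom: dict[str, list[int]] = {}
        rank_to_gene: dict[tuple[str, int], str] = {}
        for gid, fams in assignments.items():
            if family not in fams:
                continue
            chrom, rank = order.ranks[gid]
            per_chrom.setdefault(chrom, []).append(rank)
            rank_to_gene[(chrom, rank)] = gid
        for chrom, ranks in per_chrom.items():
            ranks.sort()
            run: list[int] = [ranks[0]]
            for rank in ranks[1:]:
                # consecutive same-family genes link iff the intervening gene
                # count (rank gap - 1) does not exceed the threshold; a chain
                # of links is one block
                if rank - run[-1] - 1 <= max_intervening:
                    run.append(rank)
                else:
                    if len(run) > 1:
                        blocks.append(_make_block(family, chrom, run, rank_to_gene))
                    run = [rank]
            if len(run) > 1:
                blocks.append(_make_block(family, chrom, run, rank_to_gene))
    blocks.sort(key=lambda b: (b.family, b.chromosome, b.members))
    return blocks


def _make_block(family, chrom, ranks, rank_to_gene) -> TandemBlock:
    members = tuple(rank_to_gene[(chrom, r)] for r in ranks)
    gaps = tuple(r1 - r0 - 1 for r0, r1 in zip(ranks, ranks[1:]))
    return TandemBlock(family=family, chromosome=chrom, members=members, intervening=gaps)


def filter_segmental_blocks(
    blocks: Iterable[SegmentalBlock],
    assignments: Mapping[str, set[str]],
    ks_max: float = 1.0,
) -> pd.DataFrame:
    """Retain collinear blocks with Ks <= ks_max and at least one lectin anchor.

    The Ks boundary is inclusive: blocks are omitted only when Ks is strictly
    greater than ``ks_max``.
    """
    rows = []
    for b in blocks:
        if b.ks > ks_max:
            continue
        fams = sorted(set(assignments.get(b.gene_a, set())) | set(assignments.get(b.gene_b, set())))
        if not fams:
            continue
        rows.append({"block_id": b.block_id, "gene_a": b.gene_a, "gene_b": b.gene_b,
                     "ks": b.ks, "families": ",".join(fams)})
    return pd.DataFrame(rows, columns=["block_id", "gene_a", "gene_b", "ks", "families"])


def read_segmental_blocks(path) -> list[SegmentalBlock]:
    df = pd.read_csv(path, sep="\t")
    return [SegmentalBlock(str(r.block_id), r.gene_a, r.gene_b, float(r.ks))
            for r in df.itertuples()]


def tandem_blocks_to_frame(blocks: Iterable[TandemBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"family": b.family, "chromosome": b.chromosome,
          "members": ",".join(b.members),
          "intervening": ",".join(map(str, b.intervening))} for b in blocks],
        columns=["family", "chromosome", "members", "intervening"],
    )
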