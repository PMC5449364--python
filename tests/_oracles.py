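"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: tandem blocks via
networkx connected components over an explicit all-pairs link relation,
hypergeometric tails by enumerating every draw, PWM scores by per-offset
python loops, UPGMA via scipy's average-linkage, and codon consequences via
a hard-coded standard genetic code table.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

#: standard genetic code, hard-coded independently of Biopython
GENETIC_CODE = {}
_bases = "TCAG"
_aas = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
for _i, (_b1, _b2, _b3) in enumerate(itertools.product(_bases, _bases, _bases)):
    GENETIC_CODE[_b1 + _b2 + _b3] = _aas[_i]


def tandem_blocks_brute_force(gene_order, assignments, max_intervening=10):
    """All-pairs linking + connected components.

    gene_order: dict chromosome -> list of gene ids in order.
    Returns a set of (family, chromosome, member-tuple-in-order).
    """
    rank = {}
    for chrom, ids in gene_order.items():
        for i, g in enumerate(ids):
            rank[g] = (chrom, i)
    out = set()
    families = {f for fams in assignments.values() for f in fams}
    for family in families:
        genes = [g for g, fams in assignments.items() if family in fams]
        graph = nx.Graph()
        graph.add_nodes_from(genes)
        for a, b in itertools.combinations(genes, 2):
            ca, ra = rank[a]
            cb, rb = rank[b]
            if ca == cb and abs(ra - rb) - 1 <= max_intervening:
                graph.add_edge(a, b)
        for comp in nx.connected_components(graph):
            if len(comp) > 1:
                members = tuple(sorted(comp, key=lambda g: rank[g][1]))
                out.add((family, rank[members[0]][0], members))
    return out


def hypergeom_upper_tail_enumerated(k, K, n, N):
    """P(X >= k) by enumerating all C(N, n) draws from an urn with K marked."""
    marked = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def scan_scores_brute_force(seq, matrix, background=None):
    """Per-offset, per-strand log-odds scores by explicit python loops.

    Returns {(+|-, offset): score} with offsets in forward-promoter
    coordinates of the match start.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    bg = background or {b: 0.25 for b in "ACGT"}
    w = len(matrix)
    idx = {b: i for i, b in enumerate("ACGT")}
    out = {}
    for strand in "+-":
        s = seq if strand == "+" else "".join(comp.get(b, "N") for b in reversed(seq))
        for off in range(len(s) - w + 1):
            score = 0.0
            for j in range(w):
                base = s[off + j]
                if base not in idx:
                    score = -math.inf
                    break
                score += math.log2(matrix[j][idx[base]] / bg[base])
            start = off if strand == "+" else len(seq) - w - off
            out[(strand, start)] = score
    return out


def upgma_merges_scipy(distance_df):
    """UPGMA merge events via scipy average linkage on the condensed matrix.

    Returns a set of (frozenset of leaves, rounded merge height).
    """
    labels = list(distance_df.columns)
    z = linkage(squareform(distance_df.to_numpy(), checks=False), method="average")
    clusters = {i: frozenset([labels[i]]) for i in range(len(labels))}
    merges = set()
    for step, (a, b, dist, _) in enumerate(z):
        merged = clusters[int(a)] | clusters[int(b)]
        clusters[len(labels) + step] = merged
        merges.add((merged, round(dist / 2.0, 6)))
    return merges


def filter_matches_naive(match, regions, min_fraction):
    """Per-base check of the single-merged-region overlap rule."""
    s, e = match
    length = e - s
    covered = set()
    merged = []
    for rs, re_ in sorted(regions):
        if merged and rs <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], re_))
        else:
            merged.append((rs, re_))
    for rs, re_ in merged:
        overlap = len(set(range(s, e)) & set(range(rs, re_)))
        if overlap >= min_fraction * length and overlap > 0:
            return True
    return False
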