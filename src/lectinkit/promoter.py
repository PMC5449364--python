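"""Integrative promoter cis-regulatory pipeline.

Four composable stages: extract 2-kb promoters upstream of the translation
start, scan them with PWMs (per-motif log-odds, both strands), optionally
filter matches on overlap with functional regions (open chromatin or
conserved non-coding sequence), and test motif over-representation in a
co-expression regulon with an upper-tail hypergeometric test under
Benjamini-Hochberg FDR control. Running with the region filter or the
regulon enrichment alone reproduces the individual analysis tracks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .models import GeneModel, revcomp

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}


# ---------------------------------------------------------------- promoters

@dataclass(frozen=True)
class Promoter:
    gene_id: str
    sequence: str
    chromosome: str
    start: int      # genomic, 0-based half-open
    end: int
    strand: str
    clipped: bool   # True when the upstream window ran off the chromosome


def extract_promoters(
    gene_models: Mapping[str, GeneModel],
    genome: Mapping[str, str],
    length: int = 2000,
    anchor: str = "atg",
) -> dict[str, Promoter]:
    """Extract upstream promoter windows, anchored on the ATG (default) or TSS.

    Plus strand: genomic [anchor - length, anchor), clipped at 0; minus
    strand: reverse complement of [anchor, anchor + length), clipped at the
    chromosome end. Genes without a CDS are skipped (warning) under the ATG
    anchor.
    """
    import logging
    logger = logging.getLogger(__name__)
    out: dict[str, Promoter] = {}
    for gene_id, model in gene_models.items():
        if anchor == "atg":
            if not model.cds:
                logger.warning("%s: no CDS, promoter skipped", gene_id)
                continue
            pos = model.atg_position()
        elif anchor == "tss":
            pos = model.start if model.strand == "+" else model.end
        else:
            raise ValueError(f"unknown anchor {anchor!r}")
        chrom_seq = genome[model.chromosome]
        if model.strand == "+":
            start, end = max(0, pos - length), pos
            seq = chrom_seq[start:end]
        else:
            start, end = pos, min(len(chrom_seq), pos + length)
            seq = revcomp(chrom_seq[start:end])
        out[gene_id] = Promoter(gene_id, seq, model.chromosome, start, end,
                                model.strand, clipped=(end - start) < length)
    return out


# ---------------------------------------------------------------- PWMs

@dataclass(frozen=True)
class PWM:
    """Position weight matrix: per-position base probabilities over ACGT."""

    motif_id: str
    matrix: np.ndarray                       # (width, 4) probabilities
    background: np.ndarray = None            # (4,), default uniform
    pseudocount: float = 0.0

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] == 0:
            raise ValueError(f"{self.motif_id}: matrix must be non-empty (width, 4)")
        bg = (np.full(4, 0.25) if self.background is None
              else np.asarray(self.background, dtype=float))
        m = m + self.pseudocount
        m = m / m.sum(axis=1, keepdims=True)
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"{self.motif_id}: columns do not normalise")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "background", bg / bg.sum())

    @classmethod
    def from_counts(cls, motif_id: str, counts, background=None,
                    pseudocount: float = 0.5) -> "PWM":
        return cls(motif_id, np.asarray(counts, dtype=float),
                   background=background, pseudocount=pseudocount)

    @classmethod
    def from_biopython(cls, motif, pseudocount: float = 0.5) -> "PWM":
        counts = np.array([[motif.counts[b][i] for b in BASES]
                           for i in range(motif.length)])
        return cls(motif.name or motif.matrix_id, counts, pseudocount=pseudocount)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        """(width, 5) log2(p/bg); column 4 (ambiguous base N) is -inf."""
        with np.errstate(divide="ignore"):
            lo = np.log2(self.matrix / self.background)
        return np.hstack([lo, np.full((self.width, 1), -np.inf)])

    @property
    def max_score(self) -> float:
        return float(np.log2(self.matrix / self.background).max(axis=1).sum())


@dataclass(frozen=True)
class MotifMatch:
    motif_id: str
    gene_id: str
    start: int       # promoter coordinates, 0-based half-open
    end: int
    strand: str
    score: float     # log-odds, bits


def encode(seq: str) -> np.ndarray:
    codes = np.full(len(seq), 4, dtype=np.int8)  # 4 = N / other
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    for base, code in _CODE.items():
        codes[arr == ord(base)] = code
    return codes


def _scan_one_strand(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Log-odds score at every offset of one promoter strand."""
    w = lo.shape[0]
    if len(codes) < w:
        return np.empty(0)
    windows = sliding_window_view(codes, w)          # (L - w + 1, w)
    return lo[np.arange(w), windows].sum(axis=1)


def scan_motifs(
    promoters: Mapping[str, str] | Mapping[str, Promoter],
    pwms: Sequence[PWM],
    score_threshold_bits: float = 6.0,
) -> list[MotifMatch]:
    """Scan both strands of every promoter with every PWM.

    Score = sum of log2(p_col(base)/bg(base)); windows overlapping an
    ambiguous base score -inf and are never reported. All windows scoring at
    or above the threshold are reported, with minus-strand hits mapped back
    to forward-promoter coordinates.
    """
    if not np.isfinite(score_threshold_bits):
        raise ValueError("score threshold must be finite")
    matches: list[MotifMatch] = []
    seqs = {g: (p.sequence if isinstance(p, Promoter) else p)
            for g, p in promoters.items()}
    for gene_id, seq in seqs.items():
        fwd = encode(seq)
        rev = encode(revcomp(seq))
        L = len(seq)
        for pwm in pwms:
            lo = pwm.log_odds()
            w = pwm.width
            for strand, codes in (("+", fwd), ("-", rev)):
                scores = _scan_one_strand(codes, lo)
                for i in np.flatnonzero(scores >= score_threshold_bits):
                    if strand == "+":
                        s = int(i)
                    else:
                        s = L - w - int(i)
                    matches.append(MotifMatch(pwm.motif_id, gene_id, s, s + w,
                                              strand, float(scores[i])))
    return matches


def motif_presence(
    promoters: Mapping[str, str],
    pwms: Sequence[PWM],
    score_threshold_bits: float = 6.0,
) -> dict[str, set[str]]:
    """Promoters with at least one match per motif, scanned in batch.

    Equivalent to deriving presence from :func:`scan_motifs` but vectorised
    across equal-length promoters; used by the enrichment pipeline where
    only presence/absence matters.
    """
    genes = list(promoters)
    if not genes:
        return {p.motif_id: set() for p in pwms}
    lengths = {len(promoters[g]) for g in genes}
    if len(lengths) != 1:
        # unequal lengths: fall back to the per-promoter scanner
        matches = scan_motifs(promoters, pwms, score_threshold_bits)
        out = {p.motif_id: set() for p in pwms}
        for m in matches:
            out[m.motif_id].add(m.gene_id)
        return out
    codes = np.vstack([encode(promoters[g]) for g in genes])
    rc = np.where(codes < 4, 3 - codes, 4)[:, ::-1]
    has_n = bool((codes == 4).any())
    out: dict[str, set[str]] = {}
    for pwm in pwms:
        lo = pwm.log_odds().astype(np.float32)
        w = pwm.width
        n_win = codes.shape[1] - w + 1
        present = np.zeros(len(genes), dtype=bool)
        if n_win > 0:
            two_level = None if has_n else _two_level_columns(lo[:, :4])
            for strand_codes in (codes, rc):
                if two_level is not None:
                    cons, weights, base = two_level
                    scores = np.full((len(genes), n_win), base, dtype=np.float32)
                    for j in range(w):
                        scores += weights[j] * (strand_codes[:, j:j + n_win] == cons[j])
                else:
                    scores = np.zeros((len(genes), n_win), dtype=np.float32)
                    for j in range(w):
                        scores += lo[j][strand_codes[:, j:j + n_win]]
                present |= scores.max(axis=1) >= score_threshold_bits
        out[pwm.motif_id] = {genes[i] for i in np.flatnonzero(present)}
    return out


def _two_level_columns(core: np.ndarray):
    """Fast-scan decomposition for PWMs whose columns take only two log-odds
    values (a dominant base vs the rest): score = base + sum of per-column
    match bonuses. Returns None when the PWM is not of that shape."""
    cons = core.argmax(axis=1)
    w = core.shape[0]
    rest = core.copy()
    rest[np.arange(w), cons] = np.nan
    lo_min = np.nanmin(rest, axis=1)
    if not np.allclose(np.nanmax(rest, axis=1), lo_min, atol=1e-6):
        return None
    weights = (core[np.arange(w), cons] - lo_min).astype(np.float32)
    return cons, weights, np.float32(lo_min.sum())


def matches_to_frame(matches: Iterable[MotifMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        [(m.gene_id, m.start, m.end, m.motif_id, m.score, m.strand) for m in matches],
        columns=["gene_id", "start", "end", "motif_id", "score", "strand"],
    )


# ---------------------------------------------------------------- region filter

def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals; overlapping or book-ended intervals are merged."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def filter_by_functional_regions(
    matches: Iterable[MotifMatch],
    regions: Mapping[str, Sequence[tuple[int, int]]],
    min_fraction: float = 0.5,
) -> list[MotifMatch]:
    """Keep matches overlapping a functional region by >= min_fraction of
    their length (intersectBed -f semantics).

    Regions are merged per promoter before testing; the overlap must come
    from a single merged region.
    """
    merged = {g: merge_intervals(ivs) for g, ivs in regions.items()}
    kept = []
    for m in matches:
        need = min_fraction * (m.end - m.start)
        for s, e in merged.get(m.gene_id, ()):
            overlap = min(e, m.end) - max(s, m.start)
            if overlap >= need and overlap > 0:
                kept.append(m)
                break
    return kept


# ---------------------------------------------------------------- regulons

@dataclass
class Regulon:
    """Focal gene plus its top co-expressed partners.

    ``members`` are (gene_id, r) pairs after id mapping, sorted by
    descending r; ``selected`` is the pre-mapping top-``top_n`` list.
    """

    focal: str
    members: list[tuple[str, float]]
    selected: list[tuple[str, float]]

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.members]


def build_regulon(
    expression: pd.DataFrame,
    focal_gene: str,
    top_n: int = 200,
    id_map: Mapping[str, str] | None = None,
    log_transform: bool = False,
) -> Regulon:
    """Select the ``top_n`` genes most positively Pearson-correlated with the
    focal gene, then drop ids absent from ``id_map`` (when given).

    ``expression`` is genes x samples. Selection uses signed r (top positive
    co-expression), not |r|.
    """
    if focal_gene not in expression.index:
        raise KeyError(f"focal gene {focal_gene} absent from expression matrix")
    if expression.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    x = expression.to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x + 1e-6)
    focal_idx = expression.index.get_loc(focal_gene)
    f = x[focal_idx]
    if np.std(f) == 0:
        raise ValueError(f"focal gene {focal_gene} has zero expression variance")
    xc = x - x.mean(axis=1, keepdims=True)
    fc = f - f.mean()
    denom = np.sqrt((xc ** 2).sum(axis=1)) * np.sqrt((fc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ fc) / denom
    order = np.argsort(-r, kind="stable")
    selected: list[tuple[str, float]] = []
    for idx in order:
        if idx == focal_idx or not np.isfinite(r[idx]):
            continue
        selected.append((expression.index[idx], float(r[idx])))
        if len(selected) == top_n:
            break
    if id_map is None:
        members = list(selected)
    else:
        members = [(g, rv) for g, rv in selected if g in id_map]
    return Regulon(focal=focal_gene, members=members, selected=selected)


# ---------------------------------------------------------------- enrichment

def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"impossible hypergeometric configuration k={k}, K={K}, n={n}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrichment(
    regulon: Regulon | Sequence[str],
    matches: Iterable[MotifMatch],
    background_genes: Sequence[str],
    focal_gene: str | None = None,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-motif regulon over-representation on promoter presence/absence.

    k = regulon promoters with >= 1 retained match, n = regulon size, K =
    background promoters with >= 1 match, N = background size; p is the
    upper-tail hypergeometric probability and q its BH-adjusted value across
    the motif library. ``enriched`` requires q < q_threshold and presence in
    the focal promoter.
    """
    if isinstance(regulon, Regulon):
        genes = regulon.genes
        focal_gene = focal_gene or regulon.focal
    else:
        genes = list(regulon)
    background = set(background_genes)
    outside = sorted(set(genes) - background)
    if outside:
        raise ValueError(f"regulon gene(s) not in background: {', '.join(outside[:5])}")
    regulon_set = set(genes)
    if isinstance(matches, Mapping):
        presence = {motif: set(hit) for motif, hit in matches.items()}
    else:
        presence = {}
        for m in matches:
            presence.setdefault(m.motif_id, set()).add(m.gene_id)
    N, n = len(background), len(regulon_set)
    rows = []
    for motif_id in sorted(presence):
        hit_genes = presence[motif_id] & background
        K = len(hit_genes)
        k = len(hit_genes & regulon_set)
        p = hypergeom_pvalue(k, K, n, N)
        rows.append({"motif_id": motif_id, "k": k, "n": n, "K": K, "N": N, "p": p,
                     "present_in_focal": bool(focal_gene in hit_genes)})
    df = pd.DataFrame(rows, columns=["motif_id", "k", "n", "K", "N", "p",
                                     "present_in_focal"])
    if len(df):
        df["q"] = bh_fdr(df["p"].to_numpy())
        df["enriched"] = (df["q"] < q_threshold) & df["present_in_focal"]
    else:
        df["q"] = []
        df["enriched"] = []
    return df.sort_values("p", kind="stable").reset_index(drop=True)
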