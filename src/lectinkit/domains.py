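"""EUL-domain architecture detection and conservation profiling.

The EUL (Euonymus-related lectin) domain is a 151-residue beta-trefoil.
Proteins carry either one domain (S-type) or two tandem domains joined by a
linker (D-type). Landmarks in the 151-residue domain frame (1-based): the
QxW signature at 34-36, the carbohydrate-binding D116-N143-Q144 triad, and
the stacking aromatics F/L118 and W136.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

EUL_DOMAIN_LENGTH = 151
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: landmark -> (position(s), accepted residue(s)) in the 151-aa domain frame
LANDMARKS: dict[str, tuple[tuple[int, ...], tuple[str, ...]]] = {
    "Q34": ((34,), ("Q",)),
    "W36": ((36,), ("W",)),
    "D116": ((116,), ("D",)),
    "F/L118": ((118,), ("F", "L")),
    "W136": ((136,), ("W",)),
    "N143": ((143,), ("N",)),
    "Q144": ((144,), ("Q",)),
}

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class ArchitectureCall:
    protein_id: str
    arch_type: str                       # "S", "D" or "unsupported"
    domains: tuple[tuple[int, int], ...]  # 1-based inclusive residue intervals
    nterm_length: int
    linker: tuple[int, int] | None = None

    @property
    def linker_length(self) -> int:
        return 0 if self.linker is None else self.linker[1] - self.linker[0] + 1


def detect_architecture(protein_id: str, sequence: str,
                        domain_hits: Sequence[tuple[int, int]]) -> ArchitectureCall:
    """Call S-/D-type architecture from EUL-domain hits on a protein.

    One hit gives an S-type call; two ordered, non-overlapping hits a D-type
    call with the inter-domain residues as linker. Zero hits reject the
    protein; more than two are flagged unsupported and reported raw.
    """
    hits = tuple(sorted((int(s), int(e)) for s, e in domain_hits))
    if not hits:
        raise ValueError(f"{protein_id}: no EUL domain hit; not an EUL protein")
    for s, e in hits:
        if not (1 <= s <= e <= len(sequence)):
            raise ValueError(f"{protein_id}: domain [{s},{e}] outside protein")
    nterm = hits[0][0] - 1
    if len(hits) == 1:
        return ArchitectureCall(protein_id, "S", hits, nterm)
    if len(hits) == 2:
        (s1, e1), (s2, e2) = hits
        if s2 <= e1:
            raise ValueError(f"{protein_id}: overlapping domain hits")
        linker = (e1 + 1, s2 - 1) if s2 > e1 + 1 else None
        return ArchitectureCall(protein_id, "D", hits, nterm, linker)
    return ArchitectureCall(protein_id, "unsupported", hits, nterm)


# ---------------------------------------------------------------- identity/similarity

def is_similar(a: str, b: str, matrix=_BLOSUM62) -> bool:
    """Positive-scoring substitution pair under BLOSUM62 (or identity)."""
    if a == b:
        return True
    try:
        return matrix[a, b] > 0
    except (KeyError, IndexError):
        return False


def pairwise_identity_similarity(
    seq_a: str, seq_b: str, decimals: int = 1, matrix=_BLOSUM62,
) -> tuple[float, float]:
    """Percent identity and similarity between two aligned sequences.

    Columns gapped in both sequences are excluded from the denominator;
    single-gap columns count as mismatches. Similarity additionally counts
    positive-scoring substitutions.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences differ in length")
    n = ident = simil = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a == "-" and b == "-":
            continue
        n += 1
        if a == "-" or b == "-":
            continue
        if a == b:
            ident += 1
            simil += 1
        elif is_similar(a, b, matrix):
            simil += 1
    if n == 0:
        raise ValueError("alignment contains only gap columns")
    return (round(100.0 * ident / n, decimals), round(100.0 * simil / n, decimals))


def similarity_matrix(msa: Mapping[str, str], decimals: int = 1) -> pd.DataFrame:
    """All-pairs identity/similarity table with columns id_a, id_b,
    identity, similarity; symmetric with a 100/100 diagonal."""
    names = list(msa)
    rows = []
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j < i:
                continue
            ident, simil = (100.0, 100.0) if i == j else pairwise_identity_similarity(
                msa[a], msa[b], decimals=decimals)
            rows.append({"id_a": a, "id_b": b, "identity": ident, "similarity": simil})
            if i != j:
                rows.append({"id_a": b, "id_b": a, "identity": ident, "similarity": simil})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- conservation profile

@dataclass
class DomainProfile:
    """Per-column composition and information content of an EUL-domain MSA."""

    frequencies: pd.DataFrame      # columns x amino acids, non-gap frequencies
    information: np.ndarray        # bits per column
    landmarks: dict[str, dict]
    n_sequences: int


def column_information(freqs: np.ndarray, small_sample_correction: int = 0) -> float:
    """IC = log2(20) - H over non-gap residues, optionally minus the
    small-sample correction term (19 / (2 ln 2 n))."""
    p = freqs[freqs > 0]
    h = float(-(p * np.log2(p)).sum()) if p.size else math.log2(20)
    ic = math.log2(20) - h
    if small_sample_correction:
        ic -= 19.0 / (2.0 * math.log(2) * small_sample_correction)
    return max(ic, 0.0)


def conservation_profile(
    msa: Mapping[str, str] | Sequence[str],
    column_map: Mapping[int, int] | None = None,
    small_sample_correction: bool = False,
) -> DomainProfile:
    """Column frequencies, information content and landmark conservation.

    ``column_map`` maps 1-based domain-frame positions to 0-based MSA
    columns when the alignment contains insertions; identity is assumed for
    a gap-free 151-column alignment.
    """
    seqs = [s.upper() for s in (msa.values() if isinstance(msa, Mapping) else msa)]
    if not seqs:
        raise ValueError("empty MSA")
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValueError("MSA sequences differ in length")
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    counts = np.zeros((width, len(AMINO_ACIDS)))
    nongap = np.zeros(width)
    for s in seqs:
        for col, a in enumerate(s):
            if a == "-":
                continue
            nongap[col] += 1
            if a in aa_index:
                counts[col, aa_index[a]] += 1
    with np.errstate(invalid="ignore"):
        freqs = counts / np.where(nongap == 0, np.nan, nongap)[:, None]
    freqs = np.nan_to_num(freqs)
    n = len(seqs)
    corr = n if small_sample_correction else 0
    ic = np.array([column_information(freqs[c], corr) for c in range(width)])

    if column_map is None:
        column_map = {pos: pos - 1 for pos in range(1, width + 1)}
    landmarks: dict[str, dict] = {}
    for name, (positions, accepted) in LANDMARKS.items():
        cols = [column_map.get(p) for p in positions]
        if any(c is None or c >= width for c in cols):
            landmarks[name] = {"fraction": float("nan"), "by_residue": {}}
            continue
        hits = 0
        by_res: dict[str, int] = {}
        for s in seqs:
            residues = [s[c] for c in cols]
            if all(r in accepted for r in residues):
                hits += 1
            for r in residues:
                by_res[r] = by_res.get(r, 0) + 1
        landmarks[name] = {
            "fraction": hits / n,
            "by_residue": {r: by_res[r] / (n * len(cols)) for r in sorted(by_res)},
        }
    # combined QxW signature: Q at 34 and W at 36, any residue between
    q_cols = [column_map.get(34), column_map.get(36)]
    if all(c is not None and c < width for c in q_cols):
        qxw = sum(1 for s in seqs if s[q_cols[0]] == "Q" and s[q_cols[1]] == "W")
        landmarks["QxW34-36"] = {"fraction": qxw / n, "by_residue": {}}
    freq_df = pd.DataFrame(freqs, columns=list(AMINO_ACIDS))
    freq_df.index = freq_df.index + 1  # 1-based domain-frame positions
    return DomainProfile(frequencies=freq_df, information=ic,
                         landmarks=landmarks, n_sequences=n)
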