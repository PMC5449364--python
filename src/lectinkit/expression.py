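"""Stress and hormone expression-response profiling.

Per-transcript fold change against the matched control stratum (same tissue
and timepoint), averaged over a gene's representative transcripts, with
FDR-derived significance stars. A pseudocount keeps fold changes finite
when a control is unexpressed.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .promoter import bh_fdr

#: Two-tier default: *** below 0.001, ** in [0.001, 0.05), nothing above.
DEFAULT_TIERS: tuple[tuple[float, str], ...] = ((0.001, "***"), (0.05, "**"))


def significance_stars(q: float,
                       tiers: Sequence[tuple[float, str]] = DEFAULT_TIERS) -> str:
    """Map an FDR q-value to a star annotation.

    ``tiers`` is a sequence of (threshold, label) pairs; the label of the
    smallest threshold with q < threshold wins. The default two-tier scheme
    can be extended with a single-star tier, e.g. ((0.001, "***"),
    (0.01, "**"), (0.05, "*")).
    """
    if not (0 <= q <= 1) or not np.isfinite(q):
        raise ValueError(f"q-value must lie in [0, 1], got {q}")
    for threshold, label in sorted(tiers):
        if q < threshold:
            return label
    return ""


def fold_change_profile(
    table: pd.DataFrame,
    pseudocount: float = 1e-6,
    control_condition: str = "control",
    fdr_column: str | None = "fdr",
    tiers: Sequence[tuple[float, str]] = DEFAULT_TIERS,
) -> pd.DataFrame:
    """Per-gene fold-change profile across conditions, tissues and timepoints.

    ``table`` is tidy with columns gene, transcript, tissue, condition,
    timepoint, value (plus optional replicate and fdr columns). Replicates
    are averaged first; per transcript, fold change = (treated + pc) /
    (control + pc) against the control of the same tissue and timepoint; per
    gene, the arithmetic mean over its transcripts. Rows where the control
    was zero are flagged. When an fdr column is present, the per-gene q
    (mean over transcripts) is annotated with stars.
    """
    required = {"gene", "transcript", "tissue", "condition", "timepoint", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"expression table lacks column(s): {', '.join(sorted(missing))}")
    keys = ["gene", "transcript", "tissue", "condition", "timepoint"]
    agg = {"value": "mean"}
    has_fdr = fdr_column is not None and fdr_column in table.columns
    if has_fdr:
        agg[fdr_column] = "mean"
    flat = table.groupby(keys, as_index=False).agg(agg)

    controls = flat[flat["condition"] == control_condition].set_index(
        ["transcript", "tissue", "timepoint"])["value"]
    treated = flat[flat["condition"] != control_condition].copy()
    idx = pd.MultiIndex.from_frame(treated[["transcript", "tissue", "timepoint"]])
    missing_ctrl = idx[~idx.isin(controls.index)]
    if len(missing_ctrl):
        t, ti, tp = missing_ctrl[0]
        raise KeyError(
            f"missing control for stratum transcript={t}, tissue={ti}, timepoint={tp}")
    ctrl_values = controls.loc[idx].to_numpy()
    treated["fold_change"] = (treated["value"] + pseudocount) / (ctrl_values + pseudocount)
    treated["zero_control"] = ctrl_values == 0

    group_keys = ["gene", "tissue", "condition", "timepoint"]
    agg2 = {"fold_change": "mean", "zero_control": "any", "transcript": "nunique"}
    if has_fdr:
        agg2[fdr_column] = "mean"
    prof = treated.groupby(group_keys, as_index=False).agg(agg2)
    prof = prof.rename(columns={"transcript": "n_transcripts"})
    if has_fdr:
        prof["stars"] = [significance_stars(q, tiers) for q in prof[fdr_column]]
    return prof


def replicate_fdr(
    table: pd.DataFrame,
    control_condition: str = "control",
) -> pd.DataFrame:
    """Stand-in FDR computation for synthetic tables without published q-values.

    Welch t-test of treated vs control replicates per (gene, transcript,
    tissue, condition, timepoint), BH-corrected across all strata, returned
    as an ``fdr`` column merged onto the input rows.
    """
    keys = ["gene", "transcript", "tissue", "condition", "timepoint"]
    rows = []
    ctrl = table[table["condition"] == control_condition]
    treated = table[table["condition"] != control_condition]
    for key, grp in treated.groupby(keys):
        gene, transcript, tissue, condition, timepoint = key
        ref = ctrl[(ctrl["transcript"] == transcript) & (ctrl["tissue"] == tissue)
                   & (ctrl["timepoint"] == timepoint)]["value"]
        if len(ref) < 2 or len(grp) < 2:
            p = 1.0
        else:
            p = float(stats.ttest_ind(grp["value"], ref, equal_var=False).pvalue)
            if not np.isfinite(p) or p <= 0:
                p = 1.0
        rows.append(dict(zip(keys, key), p=p))
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].to_numpy()) if len(out) else []
    return out
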