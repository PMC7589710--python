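"""Probe-level differential expression between sample groups.

Two-group contrasts use the two-sided Student t-test with pooled variance
(Welch is available behind a flag); multi-group contrasts use one-way ANOVA.
p-values are adjusted with the Benjamini-Hochberg procedure across all tested
probes, and features are ranked by the absolute group-mean difference on the
log2 scale (the mean difference of log2 intensities is the log2 fold change).

The reference side of a two-group contrast may pool several groups (e.g.
fetal liver sinusoidal ECs against cardiac + pulmonary ECs treated as one
reference set).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_qvalues, oneway_f_rows, pooled_t_rows
from .io_model import BetaMatrix, DesignError, ExpressionMatrix, SampleSheet


def _group_arrays(
    values: pd.DataFrame, sheet: SampleSheet, group: str | Sequence[str]
) -> np.ndarray:
    samples = sheet.samples(group)
    present = [s for s in samples if s in values.columns]
    if len(present) < 2:
        raise DesignError(
            f"group {group!r} has {len(present)} samples with data; need >= 2"
        )
    return values[present].to_numpy(dtype=float)


def two_group_diff(
    expr: ExpressionMatrix | BetaMatrix,
    sheet: SampleSheet,
    group_a: str | Sequence[str],
    group_b: str | Sequence[str],
    welch: bool = False,
) -> pd.DataFrame:
    """Per-feature two-group differential table (DiffTable).

    Returns a DataFrame indexed by feature id with columns ``gene`` (when the
    input carries a gene mapping), ``stat`` (t), ``p``, ``q`` (BH), ``mean_diff``
    (mean(A) - mean(B) on the native scale) and ``direction`` (sign of
    mean_diff).  Either side may name a single group or a list of groups
    pooled into one set.
    """
    values = expr.values
    a = _group_arrays(values, sheet, group_a)
    b = _group_arrays(values, sheet, group_b)
    if welch:
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False, nan_policy="omit")
        mean_diff = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
    else:
        t, _, p, mean_diff = pooled_t_rows(a, b)
    out = pd.DataFrame(
        {
            "stat": t,
            "p": p,
            "q": bh_qvalues(p),
            "mean_diff": mean_diff,
            "direction": np.sign(mean_diff).astype(int),
        },
        index=values.index,
    )
    if isinstance(expr, ExpressionMatrix):
        out.insert(0, "gene", expr.genes)
    return out


def multi_group_diff(
    expr: ExpressionMatrix | BetaMatrix,
    sheet: SampleSheet,
    groups: Sequence[str],
) -> pd.DataFrame:
    """One-way ANOVA differential table across three or more groups.

    ``mean_diff`` holds the largest pairwise group-mean difference (a ranking
    aid, always non-negative), so ``direction`` is 1 for any non-flat feature.
    """
    if len(groups) < 2:
        raise DesignError("multi_group_diff needs at least two groups")
    values = expr.values
    arrays = [_group_arrays(values, sheet, g) for g in groups]
    F, _, _, p = oneway_f_rows(arrays)
    means = np.stack([np.nanmean(a, axis=1) for a in arrays])
    mean_diff = means.max(axis=0) - means.min(axis=0)
    out = pd.DataFrame(
        {
            "stat": F,
            "p": p,
            "q": bh_qvalues(p),
            "mean_diff": mean_diff,
            "direction": np.sign(mean_diff).astype(int),
        },
        index=values.index,
    )
    if isinstance(expr, ExpressionMatrix):
        out.insert(0, "gene", expr.genes)
    return out


def top_features(diff: pd.DataFrame, n: int = 50, alpha: float = 0.05) -> pd.DataFrame:
    """Features with p < ``alpha`` ranked by |mean_diff| descending.

    Ties in |mean_diff| are broken by smaller p, then by feature id
    lexically.  If fewer than ``n`` features pass, all passing features are
    returned.
    """
    passing = diff[diff["p"] < alpha].copy()
    passing["_absdiff"] = passing["mean_diff"].abs()
    passing["_id"] = passing.index.astype(str)
    ranked = passing.sort_values(
        by=["_absdiff", "p", "_id"], ascending=[False, True, True], kind="mergesort"
    )
    return ranked.drop(columns=["_absdiff", "_id"]).head(n)
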