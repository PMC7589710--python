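"""Vectorised, missing-data-aware test statistics used across the pipeline.

All helpers operate row-wise on feature x sample arrays so that ten thousand
probes or CpGs are tested in a single call.  NaN cells are excluded pairwise
(per feature, per group), matching the package-wide convention that a missing
TSV cell simply drops that sample from that feature's test.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def pooled_t_rows(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Two-sided Student (pooled-variance) t-test per row.

    Parameters are feature x sample arrays (may contain NaN).  Returns
    ``(t, df, p, mean_diff)`` with ``mean_diff = mean(a) - mean(b)``.

    Conventions for degenerate rows: zero pooled variance with equal means
    gives ``t = 0, p = 1``; zero pooled variance with unequal means gives an
    infinite t and ``p = 0``; fewer than two observations in either group
    gives NaN statistics (callers exclude or log such rows).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.sum(~np.isnan(a), axis=1)
    nb = np.sum(~np.isnan(b), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ma = np.nanmean(np.where(np.isnan(a), np.nan, a), axis=1)
        mb = np.nanmean(np.where(np.isnan(b), np.nan, b), axis=1)
        ssa = np.nansum((a - ma[:, None]) ** 2, axis=1)
        ssb = np.nansum((b - mb[:, None]) ** 2, axis=1)
    df = na + nb - 2
    mean_diff = ma - mb
    valid = (na >= 2) & (nb >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = (ssa + ssb) / np.where(df > 0, df, np.nan)
        se = np.sqrt(s2 * (1.0 / na + 1.0 / nb))
        t = mean_diff / se
    p = np.full(a.shape[0], np.nan)
    ok = valid & (se > 0)
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    degenerate = valid & (se == 0)
    # zero pooled variance: identical values -> p=1; separated constants -> p=0
    zero_diff = degenerate & (mean_diff == 0)
    t[zero_diff] = 0.0
    p[zero_diff] = 1.0
    sep = degenerate & (mean_diff != 0)
    t[sep] = np.sign(mean_diff[sep]) * np.inf
    p[sep] = 0.0
    t[~valid] = np.nan
    return t, df.astype(float), p, mean_diff


def oneway_f_rows(
    groups: Sequence[np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One-way ANOVA F-test per row over ``k`` feature x sample group arrays.

    Returns ``(F, df_between, df_within, p)``.  Rows where every observation
    is identical get ``F = 0, p = 1``; rows with fewer than two observations
    in any group get NaN.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("ANOVA needs at least two groups")
    ns = np.stack([np.sum(~np.isnan(g), axis=1) for g in groups])
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.stack([np.nanmean(g, axis=1) for g in groups])
        sums = means * ns
        n_tot = ns.sum(axis=0)
        grand = sums.sum(axis=0) / n_tot
        ss_between = np.sum(ns * (means - grand) ** 2, axis=0)
        ss_within = np.zeros_like(grand)
        for g, m in zip(groups, means):
            ss_within += np.nansum((g - m[:, None]) ** 2, axis=1)
    df_b = np.full_like(grand, k - 1.0)
    df_w = n_tot - k
    valid = (ns >= 2).all(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (ss_between / df_b) / (ss_within / df_w)
    p = np.full(grand.shape, np.nan)
    ok = valid & (ss_within > 0)
    p[ok] = stats.f.sf(F[ok], df_b[ok], df_w[ok])
    flat = valid & (ss_within == 0) & (ss_between == 0)
    F[flat] = 0.0
    p[flat] = 1.0
    sep = valid & (ss_within == 0) & (ss_between > 0)
    F[sep] = np.inf
    p[sep] = 0.0
    F[~valid] = np.nan
    return F, df_b, df_w, p


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaN entries stay NaN, excluded
    from the number of tests)."""
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def signed_z_from_p(p: np.ndarray, sign: np.ndarray) -> np.ndarray:
    """Map a two-sided p-value and a direction to a signed normal deviate.

    ``z = sign * Phi^{-1}(1 - p/2)``, so p = 0.05 with positive direction gives
    z = +1.95996.  p values of exactly 0 are clipped to the smallest positive
    double to keep z finite.
    """
    p = np.clip(np.asarray(p, dtype=float), np.finfo(float).tiny, 1.0)
    return np.asarray(sign, dtype=float) * stats.norm.isf(p / 2.0)


def stouffer_combine(z: np.ndarray) -> tuple[float, float]:
    """Equal-weight Stouffer combination: Z = sum(z)/sqrt(n), two-sided p."""
    z = np.asarray(z, dtype=float)
    combined = z.sum() / np.sqrt(z.size)
    p = 2.0 * stats.norm.sf(abs(combined))
    return float(combined), float(p)


def pearson_pairwise(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Pearson r between two vectors using pairwise-complete observations.

    Returns ``(r, n_pairs)``; r is NaN when fewer than 3 complete pairs exist
    or either vector is constant over the complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    n = int(mask.sum())
    if n < 3:
        return np.nan, n
    xm = x[mask] - x[mask].mean()
    ym = y[mask] - y[mask].mean()
    denom = np.sqrt((xm**2).sum() * (ym**2).sum())
    if denom == 0:
        return np.nan, n
    return float((xm * ym).sum() / denom), n
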