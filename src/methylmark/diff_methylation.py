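"""Per-CpG differential methylation and cross-platform concordance.

Array mode tests beta values (methylation fractions from methylation arrays)
with the same pooled-variance t statistic used for expression; WGBS mode first
converts per-CpG methylated/total read counts to per-sample fractions, applies
a minimum-coverage filter, and then tests the fractions so that donors remain
the unit of replication on both platforms.  Significant CpGs (BH q below the
threshold) are labelled hypermethylated in group A when the beta difference is
positive and hypomethylated when negative.

Tests are run on the beta scale by default (group differences are then directly
interpretable as delta-beta); an M-value transform is available behind a flag
for variance stabilisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._stats import bh_qvalues, pearson_pairwise, pooled_t_rows
from .diff_expression import two_group_diff
from .io_model import BetaMatrix, CountMethylome, DesignError, SampleSheet

logger = logging.getLogger("methylmark")


def _mvalues(beta: pd.DataFrame, eps: float = 1e-3) -> pd.DataFrame:
    clipped = beta.clip(lower=eps, upper=1 - eps)
    return np.log2(clipped / (1 - clipped))


def dmc_array(
    beta: BetaMatrix,
    sheet: SampleSheet,
    group_a: str | Sequence[str],
    group_b: str | Sequence[str],
    q_threshold: float = 0.05,
    mvalues: bool = False,
) -> pd.DataFrame:
    """Differentially methylated CpGs from a beta-value matrix.

    Returns a DiffTable indexed by cpg_id with ``significant`` (q below the
    threshold) and ``status`` ('hyper'/'hypo' in group A for significant CpGs,
    '' otherwise).  CpGs with no finite value in either group are excluded and
    logged.
    """
    values = beta.values
    usable = values.notna().any(axis=1)
    if (~usable).any():
        logger.warning("excluding %d all-missing CpG rows", int((~usable).sum()))
        values = values[usable]
    matrix = BetaMatrix(values=_mvalues(values) if mvalues else values)
    diff = two_group_diff(matrix, sheet, group_a, group_b)
    if mvalues:
        # report the group difference on the beta scale even when testing M-values
        a = values[[s for s in sheet.samples(group_a) if s in values.columns]]
        b = values[[s for s in sheet.samples(group_b) if s in values.columns]]
        diff["mean_diff"] = a.mean(axis=1) - b.mean(axis=1)
        diff["direction"] = np.sign(diff["mean_diff"]).astype(int)
    diff["significant"] = diff["q"] < q_threshold
    diff["status"] = ""
    diff.loc[diff["significant"] & (diff["mean_diff"] > 0), "status"] = "hyper"
    diff.loc[diff["significant"] & (diff["mean_diff"] < 0), "status"] = "hypo"
    return diff


def dmc_wgbs(
    counts: CountMethylome,
    sheet: SampleSheet,
    group_a: str | Sequence[str],
    group_b: str | Sequence[str],
    min_cov: int = 5,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Differentially methylated CpGs from WGBS-style count data.

    Per-sample fractions are computed where coverage >= ``min_cov``; CpGs with
    fewer than two covered samples in either group are skipped (their count is
    logged).  The retained fractions are tested exactly like array betas, and
    BH adjustment runs over the tested CpGs only.
    """
    frac = counts.fractions(min_cov=min_cov)
    sa = [s for s in sheet.samples(group_a) if s in frac.columns]
    sb = [s for s in sheet.samples(group_b) if s in frac.columns]
    if len(sa) < 2 or len(sb) < 2:
        raise DesignError("each group needs >= 2 samples with WGBS data")
    covered_a = frac[sa].notna().sum(axis=1)
    covered_b = frac[sb].notna().sum(axis=1)
    tested = (covered_a >= 2) & (covered_b >= 2)
    skipped = int((~tested).sum())
    if skipped:
        logger.info(
            "skipping %d CpGs with <2 samples covered at >=%dx per group",
            skipped,
            min_cov,
        )
    frac = frac[tested]
    t, _, p, mean_diff = pooled_t_rows(
        frac[sa].to_numpy(dtype=float), frac[sb].to_numpy(dtype=float)
    )
    out = pd.DataFrame(
        {
            "stat": t,
            "p": p,
            "q": bh_qvalues(p),
            "mean_diff": mean_diff,
            "direction": np.sign(mean_diff).astype(int),
        },
        index=frac.index,
    )
    out["significant"] = out["q"] < q_threshold
    out["status"] = ""
    out.loc[out["significant"] & (out["mean_diff"] > 0), "status"] = "hyper"
    out.loc[out["significant"] & (out["mean_diff"] < 0), "status"] = "hypo"
    return out


@dataclass(frozen=True)
class ConcordanceResult:
    """Per-sample and pooled Pearson correlation between two beta matrices."""

    per_sample: pd.Series  # sample_id -> r
    pooled: float
    n_cpgs: int


def platform_concordance(beta_a: BetaMatrix, beta_b: BetaMatrix) -> ConcordanceResult:
    """Pearson correlation between matched samples of two methylation platforms.

    Correlates each shared sample's beta values over the shared CpGs
    (pairwise-complete), plus a pooled correlation over all shared cells.
    Intended for array-vs-WGBS agreement checks; fewer than ~100 shared CpGs
    makes the estimate unstable and is logged.
    """
    shared_cpgs = beta_a.values.index.intersection(beta_b.values.index)
    shared_samples = [s for s in beta_a.sample_ids if s in set(beta_b.sample_ids)]
    if len(shared_cpgs) < 100:
        logger.warning(
            "only %d shared CpGs; concordance estimates may be unstable",
            len(shared_cpgs),
        )
    if not shared_samples:
        raise DesignError("no shared samples between the two matrices")
    a = beta_a.values.loc[shared_cpgs, shared_samples]
    b = beta_b.values.loc[shared_cpgs, shared_samples]
    per_sample = {}
    for s in shared_samples:
        r, n = pearson_pairwise(a[s].to_numpy(), b[s].to_numpy())
        if n < 2:
            raise DesignError(f"sample {s!r}: fewer than 2 shared finite pairs")
        per_sample[s] = r
    pooled, n_pooled = pearson_pairwise(a.to_numpy().ravel(), b.to_numpy().ravel())
    if n_pooled < 2:
        raise DesignError("fewer than 2 shared finite pairs overall")
    return ConcordanceResult(
        per_sample=pd.Series(per_sample, name="r"),
        pooled=pooled,
        n_cpgs=len(shared_cpgs),
    )
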