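"""Expression-methylation correlation and external reference concordance.

`expr_meth_correlate` pairs each differentially expressed gene with the CpGs
annotated to it and computes pairwise-complete Pearson correlations across the
samples shared by the expression and beta matrices.  Pairs with |r| above the
retention threshold (0.7 by default, both signs kept) are tabulated in a
2x2 summary of correlation sign by genomic context (promoter vs non-promoter),
the bookkeeping used to ask whether promoter methylation is predominantly
anti-correlated with expression.

`reference_concordance` correlates a group's mean expression profile with an
external per-gene reference vector (e.g. mean expression of a cell population
from a published single-cell study) and reports the Pearson r with its
correlation-test p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import pearson_pairwise
from .io_model import (
    BetaMatrix,
    CpGAnnotation,
    DesignError,
    ExpressionMatrix,
    SampleSheet,
)

logger = logging.getLogger("methylmark")


@dataclass(frozen=True)
class CorrelationResult:
    """Retained (gene, CpG) correlation pairs plus the sign-by-context summary.

    ``pairs`` has columns gene, cpg_id, r, n_pairs, sign, promoter;
    ``summary`` is a 2x2 count table indexed by sign ('positive'/'negative')
    with columns 'promoter' and 'nonpromoter'.  The four summary cells sum to
    the number of retained pairs.
    """

    pairs: pd.DataFrame
    summary: pd.DataFrame

    def counts(self) -> dict[str, int]:
        """Summary flattened to {'positive_promoter': n, ...}."""
        return {
            f"{sign}_{ctx}": int(self.summary.loc[sign, ctx])
            for sign in self.summary.index
            for ctx in self.summary.columns
        }


def expr_meth_correlate(
    deg_table: pd.DataFrame,
    expr: ExpressionMatrix,
    beta: BetaMatrix,
    annotation: CpGAnnotation,
    r_threshold: float = 0.7,
    alpha: float = 0.05,
) -> CorrelationResult:
    """Correlate differentially expressed genes with their annotated CpGs.

    ``deg_table`` is a DiffTable from the expression stage; features with
    p < ``alpha`` define the DEG set.  For a gene measured by several probes
    the probe with the smallest p represents it.  Correlations use the samples
    shared between ``expr`` and ``beta`` (pairwise-complete per pair); pairs
    need at least 3 complete observations.  Pairs with |r| > ``r_threshold``
    are retained (``r_threshold=0`` retains every computable pair).
    """
    if "gene" not in deg_table.columns:
        raise DesignError("deg_table must carry a 'gene' column")
    shared = [s for s in expr.sample_ids if s in set(beta.sample_ids)]
    if not shared:
        raise DesignError("no shared samples between expression and beta matrices")
    degs = deg_table[deg_table["p"] < alpha]
    ann = annotation.table
    rows = []
    for gene, sub in degs.groupby("gene", sort=False):
        if gene == "":
            continue
        probe = sub["p"].idxmin()
        cpgs = ann.index[ann["gene"] == gene]
        if len(cpgs) == 0:
            logger.info("DEG gene %s has no annotated CpGs; skipped", gene)
            continue
        x = expr.values.loc[probe, shared].to_numpy(dtype=float)
        for cpg in cpgs:
            if cpg not in beta.values.index:
                continue
            y = beta.values.loc[cpg, shared].to_numpy(dtype=float)
            r, n = pearson_pairwise(x, y)
            if np.isnan(r):
                continue
            if r_threshold > 0 and not abs(r) > r_threshold:
                continue
            rows.append(
                {
                    "gene": gene,
                    "cpg_id": cpg,
                    "r": r,
                    "n_pairs": n,
                    "sign": 1 if r >= 0 else -1,
                    "promoter": bool(ann.loc[cpg, "promoter"]),
                }
            )
    pairs = pd.DataFrame(
        rows, columns=["gene", "cpg_id", "r", "n_pairs", "sign", "promoter"]
    )
    summary = pd.DataFrame(
        0,
        index=pd.Index(["positive", "negative"], name="sign"),
        columns=pd.Index(["promoter", "nonpromoter"], name="context"),
    )
    for _, row in pairs.iterrows():
        sign = "positive" if row["sign"] > 0 else "negative"
        ctx = "promoter" if row["promoter"] else "nonpromoter"
        summary.loc[sign, ctx] += 1
    return CorrelationResult(pairs=pairs, summary=summary)


def reference_concordance(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    group: str,
    reference: Mapping[str, float] | pd.Series,
) -> tuple[float, float, int]:
    """Pearson correlation of a group's mean expression with a reference profile.

    ``reference`` maps gene symbols to mean expression values.  Probes are
    collapsed to genes by averaging; at least 10 shared genes are required.
    Returns ``(r, p_value, n_genes)``.
    """
    reference = pd.Series(dict(reference), dtype=float)
    samples = [s for s in sheet.samples(group) if s in expr.values.columns]
    if not samples:
        raise DesignError(f"group {group!r} has no samples in the expression matrix")
    gene_means = (
        expr.values[samples]
        .mean(axis=1)
        .groupby(expr.genes.to_numpy())
        .mean()
        .drop(labels=[""], errors="ignore")
    )
    shared = gene_means.index.intersection(reference.index)
    if len(shared) < 10:
        raise DesignError(f"only {len(shared)} shared genes; need >= 10")
    r, p = stats.pearsonr(gene_means.loc[shared], reference.loc[shared])
    return float(r), float(p), int(len(shared))
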