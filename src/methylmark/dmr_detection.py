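"""Region-level differential methylation (DMR) calling.

Two unit definitions are supported:

* **gene-region units** for array data: CpGs sharing a (gene, region class)
  annotation, e.g. all TSS200 CpGs of GSTO2, optionally restricted to
  promoter classes (TSS1500/TSS200/5'UTR/1stExon);
* **sliding windows** for WGBS data: fixed-width genomic windows stepped
  along each chromosome, with overlapping significant windows merged into
  maximal runs and the merged unit re-scored on the union of its CpGs.

Each unit combines its members' per-CpG evidence with an equal-weight
Stouffer statistic over direction-signed z-scores, so CpGs pulling in
opposite directions cancel.  A unit is reported as a DMR when three
conditions hold simultaneously: BH q over units below ``q_threshold``,
directional coherence (fraction of member CpGs sharing the majority sign) of
at least ``coherence_min``, and an absolute mean beta difference of at least
``delta_min``.  The coherence and effect-size gates keep isolated strong CpGs
or noise-dominated units from being promoted to regions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._stats import bh_qvalues, signed_z_from_p, stouffer_combine
from .diff_methylation import dmc_array, dmc_wgbs
from .io_model import (
    BetaMatrix,
    CountMethylome,
    CpGAnnotation,
    DesignError,
    PROMOTER_CLASSES,
    SampleSheet,
)


@dataclass(frozen=True)
class DMRParams:
    """Tunable rules of the DMR caller.

    min_cpgs: smallest number of tested CpGs a unit may contain (3 for
        gene-region units, window mode uses 5 unless overridden).
    q_threshold: BH-adjusted significance level over units.
    coherence_min: required fraction of member CpGs sharing the majority
        direction.
    delta_min: required |mean delta-beta| of the unit.
    window / step: window width and stride in bp (window mode only).
    promoter_only: restrict gene-region units to promoter classes.
    min_cov: per-sample coverage filter passed to the WGBS per-CpG test.
    variance_floor: in window mode, floor each CpG's pooled variance at the
        binomial sampling variance implied by its coverage.  With two or
        three replicates the empirical variance of read fractions can
        collapse far below the known sampling noise, producing huge t values
        from what is pure counting coincidence; the floor moderates exactly
        those artefacts (the read-level noise is a hard lower bound on the
        variance of a fraction) while leaving well-behaved CpGs untouched.
    """

    min_cpgs: int = 3
    q_threshold: float = 0.05
    coherence_min: float = 0.8
    delta_min: float = 0.10
    window: int = 1000
    step: int = 500
    promoter_only: bool = False
    min_cov: int = 5
    variance_floor: bool = True


DMR_COLUMNS = (
    "n_cpgs",
    "combined_z",
    "combined_p",
    "q",
    "mean_delta_beta",
    "direction",
    "coherence",
    "significant",
)


def _unit_stats(sub: pd.DataFrame) -> dict:
    """Combine one unit's per-CpG rows (columns p, mean_diff, direction)."""
    signs = np.where(sub["mean_diff"] >= 0, 1.0, -1.0)
    z = signed_z_from_p(sub["p"].to_numpy(), signs)
    combined_z, combined_p = stouffer_combine(z)
    pos = float((signs > 0).sum())
    coherence = max(pos, len(signs) - pos) / len(signs)
    mean_delta = float(sub["mean_diff"].mean())
    return {
        "member_cpgs": list(sub.index),
        "n_cpgs": len(sub),
        "combined_z": combined_z,
        "combined_p": combined_p,
        "mean_delta_beta": mean_delta,
        "direction": int(np.sign(mean_delta)) if mean_delta != 0 else 0,
        "coherence": coherence,
    }


def _finalize(table: pd.DataFrame, params: DMRParams) -> pd.DataFrame:
    table["q"] = bh_qvalues(table["combined_p"].to_numpy())
    table["significant"] = (
        (table["q"] < params.q_threshold)
        & (table["coherence"] >= params.coherence_min)
        & (table["mean_delta_beta"].abs() >= params.delta_min)
    )
    return table.sort_values(["combined_p", "unit_id"], kind="mergesort").set_index(
        "unit_id"
    )


def dmr_by_gene_region(
    beta: BetaMatrix,
    annotation: CpGAnnotation,
    sheet: SampleSheet,
    group_a: str | Sequence[str],
    group_b: str | Sequence[str],
    params: DMRParams | None = None,
) -> pd.DataFrame:
    """DMR table over (gene, region-class) units of an array beta matrix.

    Runs the per-CpG test, groups tested CpGs by their annotated gene and
    region class (intergenic CpGs are ignored), and scores every unit with at
    least ``params.min_cpgs`` members.  The returned table is indexed by
    ``unit_id`` (``GENE|REGIONCLASS``) and sorted by combined p; the
    ``significant`` column marks accepted DMRs.
    """
    params = params or DMRParams()
    per_cpg = dmc_array(beta, sheet, group_a, group_b)
    ann = annotation.table.loc[annotation.table.index.intersection(per_cpg.index)]
    ann = ann[(ann["gene"] != "") & (ann["region_class"] != "Intergenic")]
    if params.promoter_only:
        ann = ann[ann["region_class"].isin(PROMOTER_CLASSES)]
    records = []
    for (gene, region_class), idx in ann.groupby(
        ["gene", "region_class"], sort=False
    ).groups.items():
        sub = per_cpg.loc[idx].dropna(subset=["p"])
        if len(sub) < params.min_cpgs:
            continue
        rec = _unit_stats(sub)
        rec.update(
            unit_id=f"{gene}|{region_class}", gene=gene, region_class=region_class
        )
        records.append(rec)
    if not records:
        raise DesignError("no (gene, region_class) unit has enough tested CpGs")
    return _finalize(pd.DataFrame.from_records(records), params)


def _wgbs_per_cpg_moderated(
    counts: CountMethylome,
    sheet: SampleSheet,
    group_a: str | Sequence[str],
    group_b: str | Sequence[str],
    params: DMRParams,
) -> pd.DataFrame:
    """Per-CpG table for the window caller, with the binomial variance floor.

    Identical to :func:`methylmark.diff_methylation.dmc_wgbs` except that the
    pooled variance entering each t statistic is bounded below by the
    binomial sampling variance ``p(1-p) * mean(1/coverage)`` of the tested
    fractions (see :class:`DMRParams.variance_floor`).
    """
    from scipy import stats as _st

    frac = counts.fractions(min_cov=params.min_cov)
    sa = [s for s in sheet.samples(group_a) if s in frac.columns]
    sb = [s for s in sheet.samples(group_b) if s in frac.columns]
    if len(sa) < 2 or len(sb) < 2:
        raise DesignError("each group needs >= 2 samples with WGBS data")
    a = frac[sa].to_numpy(dtype=float)
    b = frac[sb].to_numpy(dtype=float)
    na = np.sum(~np.isnan(a), axis=1)
    nb = np.sum(~np.isnan(b), axis=1)
    tested = (na >= 2) & (nb >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        ma = np.nansum(a, axis=1) / np.where(na > 0, na, np.nan)
        mb = np.nansum(b, axis=1) / np.where(nb > 0, nb, np.nan)
        ss = np.nansum((a - ma[:, None]) ** 2, axis=1) + np.nansum(
            (b - mb[:, None]) ** 2, axis=1
        )
        df = na + nb - 2
        s2 = ss / df
        if params.variance_floor:
            cov = counts.total[sa + sb].to_numpy(dtype=float)
            covered = np.where(cov >= max(params.min_cov, 1), cov, np.nan)
            inv_cov = np.nanmean(1.0 / covered, axis=1)
            pooled = (ma * na + mb * nb) / (na + nb)
            floor = pooled * (1.0 - pooled) * inv_cov
            s2 = np.maximum(s2, floor)
        se = np.sqrt(s2 * (1.0 / na + 1.0 / nb))
        mean_diff = ma - mb
        t = mean_diff / se
    p = np.full(t.shape, np.nan)
    ok = tested & (se > 0)
    p[ok] = 2.0 * _st.t.sf(np.abs(t[ok]), df[ok])
    zero = tested & (se == 0)
    t[zero & (mean_diff == 0)] = 0.0
    p[zero & (mean_diff == 0)] = 1.0
    direction = np.where(np.isfinite(mean_diff), np.sign(mean_diff), 0).astype(int)
    out = pd.DataFrame(
        {"stat": t, "p": p, "mean_diff": mean_diff, "direction": direction},
        index=frac.index,
    )
    return out[tested]


def _window_starts(positions: np.ndarray, window: int, step: int) -> np.ndarray:
    lo = (int(positions.min()) // step) * step
    hi = int(positions.max())
    return np.arange(lo, hi + 1, step)


def merge_intervals(
    intervals: Sequence[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Merge overlapping or touching half-open [start, end) intervals.

    Idempotent: merging an already-merged list returns it unchanged.
    """
    if not intervals:
        return []
    ordered = sorted(intervals)
    merged = [list(ordered[0])]
    for start, end in ordered[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [tuple(iv) for iv in merged]


def dmr_windows_wgbs(
    counts: CountMethylome,
    sheet: SampleSheet,
    group_a: str | Sequence[str],
    group_b: str | Sequence[str],
    params: DMRParams | None = None,
) -> pd.DataFrame:
    """DMR table over sliding genomic windows of a WGBS count methylome.

    Windows of ``params.window`` bp stepped by ``params.step`` are scored when
    they contain at least ``params.min_cpgs`` tested CpGs (the per-CpG test
    and coverage rules are those of :func:`dmc_wgbs`).  BH runs across all
    scored windows; overlapping significant windows are merged into maximal
    runs whose statistics are recomputed on the union of member CpGs (the
    merged unit keeps the smallest member q).  Unit ids are
    ``chrom:start-end`` with half-open coordinates.
    """
    params = params or replace(DMRParams(), min_cpgs=5)
    if counts.loci is None:
        raise DesignError("window DMR detection needs CpG positions (loci)")
    per_cpg = _wgbs_per_cpg_moderated(counts, sheet, group_a, group_b, params).dropna(
        subset=["p"]
    )
    loci = counts.loci.loc[counts.loci.index.intersection(per_cpg.index)]
    records = []
    for chrom, sub_loci in loci.groupby("chrom", sort=False):
        pos = sub_loci["pos"].to_numpy()
        order = np.argsort(pos, kind="mergesort")
        pos = pos[order]
        ids = sub_loci.index.to_numpy()[order]
        for start in _window_starts(pos, params.window, params.step):
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, start + params.window, side="left")
            if hi - lo < params.min_cpgs:
                continue
            sub = per_cpg.loc[ids[lo:hi]]
            rec = _unit_stats(sub)
            rec.update(
                unit_id=f"{chrom}:{start}-{start + params.window}",
                chrom=chrom,
                start=int(start),
                end=int(start + params.window),
            )
            records.append(rec)
    if not records:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "member_cpgs", *DMR_COLUMNS]
        ).rename_axis("unit_id")
    table = _finalize(pd.DataFrame.from_records(records), params)
    return _merge_significant_windows(table, per_cpg, loci, params)


def _merge_significant_windows(
    table: pd.DataFrame,
    per_cpg: pd.DataFrame,
    loci: pd.DataFrame,
    params: DMRParams,
) -> pd.DataFrame:
    keep = table[~table["significant"]]
    sig = table[table["significant"]]
    merged_records = []
    for chrom, sub in sig.groupby("chrom", sort=False):
        for start, end in merge_intervals(
            list(zip(sub["start"].astype(int), sub["end"].astype(int)))
        ):
            members = sub[(sub["start"] >= start) & (sub["end"] <= end)]
            cpgs = sorted({c for row in members["member_cpgs"] for c in row})
            on_chrom = loci.loc[cpgs]
            stats_sub = per_cpg.loc[on_chrom.index]
            rec = _unit_stats(stats_sub)
            rec.update(
                unit_id=f"{chrom}:{start}-{end}",
                chrom=chrom,
                start=start,
                end=end,
                q=float(members["q"].min()),
                significant=True,
            )
            merged_records.append(rec)
    pieces = [keep.reset_index()]
    if merged_records:
        pieces.append(pd.DataFrame.from_records(merged_records))
    out = pd.concat(pieces, ignore_index=True)
    return out.sort_values(["combined_p", "unit_id"], kind="mergesort").set_index(
        "unit_id"
    )


def significant_dmrs(dmr_table: pd.DataFrame) -> pd.DataFrame:
    """The accepted DMRs of a table (rows with ``significant`` set)."""
    return dmr_table[dmr_table["significant"]]


def rank_dmrs(
    dmr_table: pd.DataFrame, n: int | None = None, significant_only: bool = True
) -> pd.DataFrame:
    """Top DMR units sorted by combined p ascending.

    Ties are broken by larger |mean delta-beta|, then by unit id lexically.
    An empty table yields an empty output.
    """
    table = significant_dmrs(dmr_table) if significant_only else dmr_table
    if table.empty:
        return table
    table = table.copy()
    table["_abs"] = table["mean_delta_beta"].abs()
    table["_id"] = table.index.astype(str)
    ranked = table.sort_values(
        by=["combined_p", "_abs", "_id"],
        ascending=[True, False, True],
        kind="mergesort",
    ).drop(columns=["_abs", "_id"])
    return ranked if n is None else ranked.head(n)
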