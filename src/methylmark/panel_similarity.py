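"""Targeted-panel methylation summaries and cell-identity similarity scoring.

The targeted bisulfite panel sequences single DNA molecules over a fixed set
of regions, giving binary methylation calls per CpG per read.  This module

* summarises reads into per-CpG and per-region mean methylation per sample,
* selects CpGs that discriminate reference cell groups (one-way ANOVA at
  p < 0.05, or BH-FDR < 0.05),
* embeds samples by PCA for visual inspection, and
* scores query samples (e.g. iPS-derived vascular endothelial cells) by
  their Euclidean distance to reference-group centroids, either in the
  standardised selected-CpG space (default) or in a PCA space fitted on the
  references.

Query samples never participate in CpG selection, standardisation or PCA
fitting, so the similarity score is free of information leakage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._stats import bh_qvalues, oneway_f_rows
from .io_model import DesignError, ReadPanel, SampleSheet

logger = logging.getLogger("methylmark")

#: Seven-region panel that distinguishes adult and fetal liver sinusoidal
#: endothelial cells from each other and from other endothelial cells.
SEVEN_REGION_PANEL: tuple[str, ...] = (
    "3:GSTO2",
    "5:RABGGTA",
    "6:ZC3H12D",
    "7:HOXD3",
    "12:PCOLCE",
    "13:MGMT",
    "18:NACC2",
)


@dataclass(frozen=True)
class RegionMethProfile:
    """Per-sample methylation summaries of a read panel.

    ``cpg_means`` is indexed by (region_id, cpg_index) with one column per
    sample: the fraction of methylated calls among non-missing calls.
    ``region_means`` averages a region's per-CpG means; ``reads_used`` counts
    the reads behind each (region, sample) cell (0 -> missing, logged).
    """

    cpg_means: pd.DataFrame
    region_means: pd.DataFrame
    reads_used: pd.DataFrame


def summarize_regions(panel: ReadPanel) -> RegionMethProfile:
    """Aggregate read-level calls to per-CpG and per-region means per sample."""
    samples = panel.sample_ids
    index = pd.MultiIndex.from_tuples(
        [
            (region, i)
            for region in panel.region_ids
            for i in range(panel.region_ncpgs[region])
        ],
        names=["region_id", "cpg_index"],
    )
    cpg_means = pd.DataFrame(np.nan, index=index, columns=samples)
    reads_used = pd.DataFrame(
        0, index=pd.Index(panel.region_ids, name="region_id"), columns=samples
    )
    for (region, sample), sub in panel.reads.groupby(
        ["region_id", "sample_id"], sort=False
    ):
        calls = np.vstack(sub["calls"].to_numpy())
        with np.errstate(invalid="ignore"):
            means = np.nanmean(calls, axis=0)
        cpg_means.loc[(region, slice(None)), sample] = means
        reads_used.loc[region, sample] = len(sub)
    missing = (reads_used == 0).to_numpy().sum()
    if missing:
        logger.warning("%d (region, sample) cells have zero reads", int(missing))
    region_means = cpg_means.groupby(level="region_id", sort=False).mean()
    return RegionMethProfile(
        cpg_means=cpg_means, region_means=region_means, reads_used=reads_used
    )


def restrict_regions(
    profile: RegionMethProfile, regions: Sequence[str]
) -> RegionMethProfile:
    """Profile restricted to a subset of regions (e.g. the seven-region panel)."""
    missing = set(regions) - set(profile.region_means.index)
    if missing:
        raise DesignError(f"unknown region(s): {sorted(missing)}")
    mask = profile.cpg_means.index.get_level_values("region_id").isin(set(regions))
    return RegionMethProfile(
        cpg_means=profile.cpg_means[mask],
        region_means=profile.region_means.loc[list(regions)],
        reads_used=profile.reads_used.loc[list(regions)],
    )


def select_discriminative_cpgs(
    profile: RegionMethProfile,
    sheet: SampleSheet,
    groups: Sequence[str],
    criterion: str = "p",
    alpha: float = 0.05,
) -> pd.MultiIndex:
    """CpGs whose per-sample means separate the given groups by one-way ANOVA.

    ``criterion`` is ``"p"`` (unadjusted p < alpha) or ``"fdr"`` (BH q < alpha).
    Raises if no CpG passes, advising a threshold change.
    """
    if criterion not in {"p", "fdr"}:
        raise DesignError("criterion must be 'p' or 'fdr'")
    arrays = []
    for g in groups:
        samples = [s for s in sheet.samples(g) if s in profile.cpg_means.columns]
        if len(samples) < 2:
            raise DesignError(f"group {g!r} has {len(samples)} profiled samples; need >= 2")
        arrays.append(profile.cpg_means[samples].to_numpy(dtype=float))
    _, _, _, p = oneway_f_rows(arrays)
    score = bh_qvalues(p) if criterion == "fdr" else p
    keep = score < alpha
    keep &= ~np.isnan(score)
    if not keep.any():
        raise DesignError(
            "no CpG passes the ANOVA selection; relax alpha or use criterion='p'"
        )
    return profile.cpg_means.index[keep]


@dataclass(frozen=True)
class PCAResult:
    """Sample coordinates and variance decomposition of a centred-SVD PCA."""

    coordinates: pd.DataFrame  # sample x component
    explained_variance: np.ndarray  # per-component variance
    explained_variance_ratio: np.ndarray
    components: pd.DataFrame  # component x feature loadings
    center: pd.Series


def embed_pca(profile_matrix: pd.DataFrame, k: int = 3) -> PCAResult:
    """PCA of a sample x feature matrix via singular value decomposition.

    Columns are mean-centred; component signs follow a deterministic
    convention (the largest-magnitude loading of each component is positive).
    Requires at least ``k + 1`` samples and non-degenerate input.
    """
    if profile_matrix.shape[0] < k + 1:
        raise DesignError(f"PCA with k={k} needs >= {k + 1} samples")
    x = profile_matrix.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise DesignError("PCA input must be complete (impute first)")
    center = x.mean(axis=0)
    xc = x - center
    if not (xc**2).sum() > 0:
        raise DesignError("PCA input has zero variance")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    k = min(k, len(s))
    for i in range(len(s)):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    var = s**2 / (x.shape[0] - 1)
    coords = pd.DataFrame(
        (u * s)[:, :k],
        index=profile_matrix.index,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    components = pd.DataFrame(
        vt[:k], index=coords.columns, columns=profile_matrix.columns
    )
    return PCAResult(
        coordinates=coords,
        explained_variance=var[:k],
        explained_variance_ratio=var[:k] / var.sum(),
        components=components,
        center=pd.Series(center, index=profile_matrix.columns),
    )


@dataclass(frozen=True)
class SimilarityReport:
    """Distances of query samples to reference-group centroids.

    ``distances`` is query x reference-group; ``nearest`` holds the
    closest group per query (ties broken by lexical group order, logged);
    ``margin`` is the gap between the second-best and best distance;
    ``rankings`` lists groups from nearest to farthest per query;
    ``n_imputed`` counts selected CpGs that were mean-imputed per query.
    """

    distances: pd.DataFrame
    nearest: pd.Series
    margin: pd.Series
    rankings: dict[str, list[str]]
    n_imputed: pd.Series
    space: str
    selected_cpgs: pd.MultiIndex


def classify_similarity(
    profile: RegionMethProfile,
    sheet: SampleSheet,
    reference_groups: Sequence[str],
    query_samples: Sequence[str],
    space: str = "cpg",
    k: int = 3,
    criterion: str = "p",
    alpha: float = 0.05,
    selected: pd.MultiIndex | None = None,
) -> SimilarityReport:
    """Score query samples against reference-group methylation fingerprints.

    CpGs are selected on reference samples only (unless a pre-selected set is
    passed), standardised by the reference mean and standard deviation, and
    distances are Euclidean either in that standardised CpG space
    (``space="cpg"``) or in the first-``k`` PCA space fitted on references
    (``space="pca"``).  Query cells missing more than half of the selected
    CpGs are an error; the rest are imputed from reference means.
    """
    if space not in {"cpg", "pca"}:
        raise DesignError("space must be 'cpg' or 'pca'")
    group_of = sheet.group_of()
    ref_samples: dict[str, list[str]] = {}
    for g in reference_groups:
        samples = [
            s
            for s in sheet.samples(g)
            if s in profile.cpg_means.columns and s not in set(query_samples)
        ]
        if not samples:
            raise DesignError(f"reference group {g!r} has no profiled samples")
        if len(samples) < 2:
            logger.warning(
                "reference group %r has only %d sample(s); centroid is that sample",
                g,
                len(samples),
            )
        ref_samples[g] = samples
    all_refs = [s for group in ref_samples.values() for s in group]
    if selected is None:
        selectable_groups = [g for g in reference_groups if len(ref_samples[g]) >= 2]
        if len(selectable_groups) < 2:
            raise DesignError("need >= 2 reference groups with >= 2 samples each")
        selected = select_discriminative_cpgs(
            profile, sheet, selectable_groups, criterion=criterion, alpha=alpha
        )
    ref_matrix = profile.cpg_means.loc[selected, all_refs].T  # sample x cpg
    ref_mean = ref_matrix.mean(axis=0)
    if ref_mean.isna().any():
        raise DesignError("selected CpGs must have reference coverage")
    ref_matrix = ref_matrix.fillna(ref_mean)
    ref_sd = ref_matrix.std(axis=0, ddof=0).replace(0.0, 1.0)

    def standardize(frame: pd.DataFrame) -> pd.DataFrame:
        return (frame - ref_mean) / ref_sd

    ref_z = standardize(ref_matrix)
    missing_queries = [s for s in query_samples if s not in profile.cpg_means.columns]
    if missing_queries:
        raise DesignError(f"query sample(s) without panel data: {missing_queries}")
    query_matrix = profile.cpg_means.loc[selected, list(query_samples)].T
    n_missing = query_matrix.isna().sum(axis=1)
    too_sparse = n_missing > 0.5 * len(selected)
    if too_sparse.any():
        raise DesignError(
            f"query sample(s) missing >50% of selected CpGs: "
            f"{list(n_missing.index[too_sparse])}"
        )
    query_z = standardize(query_matrix.fillna(ref_mean))

    if space == "pca":
        pca = embed_pca(ref_z, k=k)
        ref_coords = pca.coordinates
        query_coords = pd.DataFrame(
            (query_z - pca.center) @ pca.components.T,
            index=query_z.index,
            columns=pca.coordinates.columns,
        )
    else:
        ref_coords, query_coords = ref_z, query_z

    centroids = pd.DataFrame(
        {
            g: ref_coords.loc[samples].mean(axis=0)
            for g, samples in ref_samples.items()
        }
    ).T  # group x feature
    dist = pd.DataFrame(
        np.sqrt(
            (
                (query_coords.to_numpy()[:, None, :] - centroids.to_numpy()[None, :, :])
                ** 2
            ).sum(axis=2)
        ),
        index=query_coords.index,
        columns=centroids.index,
    )
    ordered_cols = sorted(dist.columns)  # lexical tie-break
    nearest, margins, rankings = {}, {}, {}
    for q in dist.index:
        row = dist.loc[q, ordered_cols]
        order = row.sort_values(kind="mergesort")
        nearest[q] = order.index[0]
        margins[q] = float(order.iloc[1] - order.iloc[0]) if len(order) > 1 else np.inf
        if len(order) > 1 and np.isclose(order.iloc[0], order.iloc[1]):
            logger.warning(
                "query %r equidistant from %r and %r; tie broken lexically",
                q,
                order.index[0],
                order.index[1],
            )
        rankings[q] = list(order.index)
    return SimilarityReport(
        distances=dist,
        nearest=pd.Series(nearest, name="nearest_group"),
        margin=pd.Series(margins, name="margin"),
        rankings=rankings,
        n_imputed=n_missing.rename("n_imputed"),
        space=space,
        selected_cpgs=selected,
    )
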