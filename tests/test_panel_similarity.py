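"""Targeted-panel summaries, CpG selection, PCA and similarity scoring."""

import numpy as np
import pandas as pd
import pytest

import methylmark as mm
from methylmark.io_model import DesignError


def _panel_from(reads):
    """reads: list of (region, sample, read_id, calls list)."""
    frame = pd.DataFrame(reads, columns=["region_id", "sample_id", "read_id", "calls"])
    frame["calls"] = [np.asarray(c, dtype=float) for c in frame["calls"]]
    ncpgs = {r: len(sub["calls"].iloc[0]) for r, sub in frame.groupby("region_id")}
    return mm.ReadPanel(region_ncpgs=ncpgs, reads=frame)


def test_summarize_regions_means():
    panel = _panel_from(
        [
            ("R1", "s1", "a", [1, 1, 1]),
            ("R1", "s1", "b", [1, 1, 1]),
            ("R2", "s1", "a", [1, 0]),
            ("R2", "s1", "b", [0, 1]),
        ]
    )
    profile = mm.summarize_regions(panel)
    assert profile.region_means.loc["R1", "s1"] == pytest.approx(1.0)
    assert list(profile.cpg_means.loc["R2", "s1"]) == [0.5, 0.5]
    assert profile.region_means.loc["R2", "s1"] == pytest.approx(0.5)
    assert profile.reads_used.loc["R1", "s1"] == 2


def test_missing_calls_excluded_from_means():
    panel = _panel_from(
        [("R1", "s1", "a", [1, np.nan]), ("R1", "s1", "b", [0, 1])]
    )
    profile = mm.summarize_regions(panel)
    assert list(profile.cpg_means.loc["R1", "s1"]) == [0.5, 1.0]


def test_region_mean_tracks_fingerprint(study):
    """Observed region means stay within binomial error of the generating
    fingerprint (200 reads per region, small donor jitter)."""
    profile = mm.summarize_regions(study.panel)
    fp = study.truth.fingerprints
    group_of = study.sheet.group_of()
    region_fp = fp.groupby(level="region_id", sort=False).mean()
    errs = []
    for s in profile.region_means.columns:
        errs.append((profile.region_means[s] - region_fp[group_of[s]]).abs().max())
    assert max(errs) < 0.08


def test_select_discriminative_cpgs_rules():
    sheet = mm.make_sample_sheet({"A": 3, "B": 3})
    rng = np.random.default_rng(0)
    sep = np.concatenate([0.1 + rng.normal(0, 0.02, 3), 0.9 + rng.normal(0, 0.02, 3)])
    flat = np.full(6, 0.5)
    cpg_means = pd.DataFrame(
        [sep, flat],
        index=pd.MultiIndex.from_tuples([("R1", 0), ("R1", 1)],
                                        names=["region_id", "cpg_index"]),
        columns=sheet.sample_ids,
    )
    profile = mm.RegionMethProfile(
        cpg_means=cpg_means,
        region_means=cpg_means.groupby(level="region_id").mean(),
        reads_used=pd.DataFrame(10, index=["R1"], columns=sheet.sample_ids),
    )
    selected = mm.select_discriminative_cpgs(profile, sheet, ["A", "B"])
    assert list(selected) == [("R1", 0)]
    with pytest.raises(DesignError, match="ANOVA selection"):
        mm.select_discriminative_cpgs(profile, sheet, ["A", "B"], alpha=1e-30)


def test_selection_calibrated_on_null_panel():
    """With no fingerprint differences the p<0.05 selection keeps ~alpha."""
    config = mm.SimulationConfig(seed=41, fingerprint_shift=0.0, epc_shift=0.0,
                                 donor_jitter=0.0)
    fp = mm.simulate_fingerprints(config, rng=1)
    sheet = mm.make_sample_sheet({"f-LSEC": 6, "a-LSEC": 6, "HCMEC": 6})
    panel = mm.simulate_panel_reads(config, fp, sheet, rng=2)
    profile = mm.summarize_regions(panel)
    from methylmark._stats import oneway_f_rows

    arrays = [profile.cpg_means[sheet.samples(g)].to_numpy()
              for g in ["f-LSEC", "a-LSEC", "HCMEC"]]
    _, _, _, p = oneway_f_rows(arrays)
    frac = float((p < 0.05).mean())
    assert 0.01 <= frac <= 0.10  # 258 CpGs -> wide binomial band around 0.05


def test_pca_properties():
    rng = np.random.default_rng(1)
    # rank-one data: points on a line -> PC1 explains everything
    direction = rng.normal(size=5)
    coeffs = rng.normal(size=8)
    line = pd.DataFrame(np.outer(coeffs, direction),
                        index=[f"s{i}" for i in range(8)])
    pca = mm.embed_pca(line, k=3)
    assert pca.explained_variance_ratio[0] == pytest.approx(1.0)
    # full-rank data: variance conserved, full reconstruction exact
    x = pd.DataFrame(rng.normal(size=(10, 4)), index=[f"s{i}" for i in range(10)])
    full = mm.embed_pca(x, k=4)
    assert full.explained_variance.sum() == pytest.approx(
        x.var(axis=0, ddof=1).sum()
    )
    recon = full.coordinates.to_numpy() @ full.components.to_numpy() + full.center.to_numpy()
    assert np.allclose(recon, x.to_numpy(), atol=1e-10)
    with pytest.raises(DesignError, match="zero variance"):
        mm.embed_pca(pd.DataFrame(np.ones((5, 3))), k=2)


def test_query_at_centroid_has_zero_distance():
    sheet = mm.make_sample_sheet({"A": 2, "B": 2, "Q": 1})
    idx = pd.MultiIndex.from_tuples([("R1", i) for i in range(4)],
                                    names=["region_id", "cpg_index"])
    a = np.array([0.1, 0.2, 0.8, 0.9])
    b = np.array([0.9, 0.8, 0.2, 0.1])
    cpg_means = pd.DataFrame(
        {"A_d1": a, "A_d2": a, "B_d1": b, "B_d2": b, "Q_d1": a}, index=idx
    )
    profile = mm.RegionMethProfile(
        cpg_means=cpg_means,
        region_means=cpg_means.groupby(level="region_id").mean(),
        reads_used=pd.DataFrame(10, index=["R1"], columns=cpg_means.columns),
    )
    report = mm.classify_similarity(profile, sheet, ["A", "B"], ["Q_d1"])
    assert report.distances.loc["Q_d1", "A"] == pytest.approx(0.0)
    assert report.nearest["Q_d1"] == "A"
    assert report.margin["Q_d1"] > 0


def test_equidistant_tie_broken_lexically():
    sheet = mm.make_sample_sheet({"A": 2, "B": 2, "Q": 1})
    idx = pd.MultiIndex.from_tuples([("R1", i) for i in range(2)],
                                    names=["region_id", "cpg_index"])
    cpg_means = pd.DataFrame(
        {"A_d1": [0.2, 0.2], "A_d2": [0.2, 0.2],
         "B_d1": [0.8, 0.8], "B_d2": [0.8, 0.8],
         "Q_d1": [0.5, 0.5]},
        index=idx,
    )
    profile = mm.RegionMethProfile(
        cpg_means=cpg_means,
        region_means=cpg_means.groupby(level="region_id").mean(),
        reads_used=pd.DataFrame(10, index=["R1"], columns=cpg_means.columns),
    )
    report = mm.classify_similarity(profile, sheet, ["A", "B"], ["Q_d1"])
    assert report.nearest["Q_d1"] == "A"
    assert report.margin["Q_d1"] == pytest.approx(0.0)


def test_region_and_read_order_invariance(study):
    profile = mm.summarize_regions(study.panel)
    shuffled_reads = study.panel.reads.sample(frac=1.0, random_state=0)
    shuffled = mm.ReadPanel(region_ncpgs=dict(study.panel.region_ncpgs),
                            reads=shuffled_reads)
    profile2 = mm.summarize_regions(shuffled)
    refs = ["a-LSEC", "f-LSEC", "HCMEC", "HPAEC", "HPMEC"]
    queries = study.sheet.samples("vEC")
    r1 = mm.classify_similarity(profile, study.sheet, refs, queries)
    r2 = mm.classify_similarity(
        profile2, study.sheet, refs, queries,
        selected=r1.selected_cpgs,
    )
    pd.testing.assert_frame_equal(
        r1.distances, r2.distances.loc[r1.distances.index, r1.distances.columns]
    )


def test_leave_one_out_assigns_references_correctly(study):
    """Held-out reference samples come back to their own group."""
    profile = mm.summarize_regions(study.panel)
    refs = ["a-LSEC", "f-LSEC", "HCMEC", "HPAEC", "HPMEC"]
    sheet = study.sheet
    correct = total = 0
    for group in refs:
        for held_out in sheet.samples(group):
            report = mm.classify_similarity(profile, sheet, refs, [held_out])
            correct += report.nearest[held_out] == group
            total += 1
    assert correct == total


def test_vec_trajectory_geometry(study):
    """Simulated vECs sit nearest mesoderm/iPS and closer to fetal than to
    adult LSEC references, in both cpg and pca spaces."""
    profile = mm.summarize_regions(study.panel)
    refs = ["PBMC", "EPC", "iPS", "mesoderm", "f-LSEC", "a-LSEC",
            "HCMEC", "HPAEC", "HPMEC"]
    queries = study.sheet.samples("vEC")
    for space in ("cpg", "pca"):
        report = mm.classify_similarity(profile, study.sheet, refs, queries, space=space)
        for q in queries:
            d = report.distances.loc[q]
            assert d["f-LSEC"] < d["a-LSEC"], (space, q)
            assert report.rankings[q][0] in {"iPS", "mesoderm"}, (space, q)


def test_seven_region_preset(study):
    profile = mm.summarize_regions(study.panel)
    restricted = mm.restrict_regions(profile, mm.SEVEN_REGION_PANEL)
    assert set(restricted.region_means.index) == set(mm.SEVEN_REGION_PANEL)
    assert len(restricted.cpg_means) == sum(
        study.panel.region_ncpgs[r] for r in mm.SEVEN_REGION_PANEL
    )
    with pytest.raises(DesignError, match="unknown region"):
        mm.restrict_regions(profile, ["nope"])
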