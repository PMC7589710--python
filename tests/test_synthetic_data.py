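"""Determinism, bookkeeping and statistical structure of the study simulator."""

import numpy as np
import pandas as pd
import pytest

import methylmark as mm


def test_determinism_same_seed_identical(tmp_path):
    config = mm.SimulationConfig(seed=3, n_cpgs=500, n_genes=200, n_deg=20,
                                 n_dmr=5, linked_pairs={"negative_promoter": 5},
                                 reads_per_region=20)
    a = mm.simulate_study(config)
    b = mm.simulate_study(config)
    pd.testing.assert_frame_equal(a.expression.values, b.expression.values)
    pd.testing.assert_frame_equal(a.beta.values, b.beta.values)
    pd.testing.assert_frame_equal(a.counts.meth, b.counts.meth)
    pd.testing.assert_frame_equal(a.truth.deg, b.truth.deg)
    for x, y in zip(a.panel.reads["calls"], b.panel.reads["calls"]):
        np.testing.assert_array_equal(x, y)
    # changing only the seed changes draws but not the truth bookkeeping shape
    c = mm.simulate_study(mm.SimulationConfig(**{**config.__dict__, "seed": 4}))
    assert not np.allclose(a.expression.values, c.expression.values)
    assert len(c.truth.deg) == len(a.truth.deg)
    assert len(c.truth.dmr) == len(a.truth.dmr)


def test_null_config_has_empty_truth():
    config = mm.SimulationConfig(seed=5, delta_expr=0.0, delta_beta=0.0,
                                 linked_pairs={}, n_cpgs=500, n_genes=200)
    study = mm.simulate_study(config)
    assert study.truth.deg.empty and study.truth.dmr.empty and study.truth.linked.empty


def test_manifest_and_unit_bookkeeping():
    config = mm.SimulationConfig(seed=6, n_cpgs=503, n_genes=200, n_deg=10,
                                 n_dmr=5, linked_pairs={})
    study = mm.simulate_study(config)
    assert len(study.annotation.table) == 503
    assert all(len(m) == config.cpgs_per_region
               for m in study.truth.dmr["member_cpgs"])
    # truth references only simulated features
    assert set(study.truth.deg["probe_id"]) <= set(study.expression.values.index)
    assert {c for m in study.truth.dmr["member_cpgs"] for c in m} <= set(
        study.annotation.table.index
    )


def test_infeasible_config_rejected():
    with pytest.raises(ValueError, match="exceeds n_cpgs"):
        mm.SimulationConfig(n_cpgs=100, n_dmr=50, cpgs_per_region=5).validate()
    with pytest.raises(ValueError, match="linked pairs"):
        mm.SimulationConfig(n_deg=10,
                            linked_pairs={"negative_promoter": 50}).validate()


def test_expression_noise_free_limit():
    config = mm.SimulationConfig(seed=8, n_genes=100, n_cpgs=400, n_deg=20,
                                 delta_expr=2.0, sigma_expr_range=(1e-9, 1e-8),
                                 linked_pairs={}, n_dmr=0)
    study = mm.simulate_study(config)
    f = study.sheet.samples("f-LSEC")
    others = study.sheet.samples(["HCMEC", "HPAEC", "HPMEC"])
    diffs = study.expression.values[f].mean(axis=1) - study.expression.values[others].mean(axis=1)
    for _, row in study.truth.deg.iterrows():
        assert diffs[row["probe_id"]] == pytest.approx(row["sign"] * 2.0, abs=1e-6)


def test_non_deg_mean_differences_center_at_zero():
    config = mm.SimulationConfig(seed=9, n_genes=2000, n_cpgs=400, n_deg=0,
                                 delta_expr=0.0, linked_pairs={}, n_dmr=0)
    study = mm.simulate_study(config)
    f = study.sheet.samples("f-LSEC")
    others = study.sheet.samples(["HCMEC", "HPAEC", "HPMEC"])
    diffs = (study.expression.values[f].mean(axis=1)
             - study.expression.values[others].mean(axis=1))
    se = diffs.std() / np.sqrt(len(diffs))
    assert abs(diffs.mean()) < 3 * se


def test_deg_sign_bookkeeping_at_large_effect():
    config = mm.SimulationConfig(seed=10, n_genes=200, n_cpgs=400, n_deg=40,
                                 delta_expr=5 * 0.6, linked_pairs={}, n_dmr=0)
    study = mm.simulate_study(config)
    f = study.sheet.samples("f-LSEC")
    others = study.sheet.samples(["HCMEC", "HPAEC", "HPMEC"])
    diffs = (study.expression.values[f].mean(axis=1)
             - study.expression.values[others].mean(axis=1))
    for _, row in study.truth.deg.iterrows():
        assert np.sign(diffs[row["probe_id"]]) == row["sign"]


def test_methylation_noise_free_limit():
    config = mm.SimulationConfig(seed=11, n_cpgs=400, n_genes=200, n_dmr=8,
                                 delta_beta=0.3, sigma_beta=0.0,
                                 n_deg=0, delta_expr=0.0, linked_pairs={})
    study = mm.simulate_study(config)
    f = study.sheet.samples("f-LSEC")
    others = study.sheet.samples(["HCMEC", "HPAEC", "HPMEC", "a-LSEC"])
    vals = study.beta.values
    for _, row in study.truth.dmr.iterrows():
        for cpg in row["member_cpgs"]:
            delta = vals.loc[cpg, f].mean() - vals.loc[cpg, others].mean()
            assert delta == pytest.approx(row["direction"] * 0.3, abs=1e-9)
        # within-unit direction coherence of planted DMRs is total
        signs = {np.sign(vals.loc[c, f].mean() - vals.loc[c, others].mean())
                 for c in row["member_cpgs"]}
        assert signs == {row["direction"]}
    assert ((vals.to_numpy() >= 0) & (vals.to_numpy() <= 1)).all()


def test_linked_pairs_achieve_target_correlation():
    """r_gen = 0.95 with 12 samples: |r| > 0.7 and the planted sign, for
    (nearly) every pair."""
    config = mm.SimulationConfig(
        seed=12, n_cpgs=800, cpgs_per_region=1, n_deg=200, n_dmr=0,
        group_sizes={"f-LSEC": 3, "HCMEC": 3, "HPAEC": 3, "HPMEC": 3},
    )
    study = mm.simulate_study(config)
    from methylmark._stats import pearson_pairwise

    samples = study.expression.sample_ids
    ok_mag = ok_sign = 0
    for _, row in study.truth.linked.iterrows():
        x = study.expression.values.loc[row["probe_id"], samples].to_numpy()
        y = study.beta.values.loc[row["cpg_id"], samples].to_numpy()
        r, _ = pearson_pairwise(x, y)
        ok_mag += abs(r) > 0.7
        ok_sign += np.sign(r) == row["sign"]
    n = len(study.truth.linked)
    assert n == sum(config.linked_pairs.values())
    assert ok_mag >= 0.99 * n
    assert ok_sign == n


def test_wgbs_counts_edge_cases_and_mean():
    rng = np.random.default_rng(13)
    idx = pd.Index(["cg0", "cg1", "cg2"], name="cpg_id")
    beta = pd.DataFrame({f"s{i}": [0.0, 1.0, 0.3] for i in range(4)}, index=idx)
    counts = mm.simulate_wgbs_counts(beta, coverage_mean=30, rng=rng)
    assert (counts.meth.loc["cg0"] == 0).all()
    assert (counts.meth.loc["cg1"] == counts.total.loc["cg1"]).all()
    # law of large numbers at beta = 0.3 over 10,000 draws
    wide = pd.DataFrame(np.full((1, 10000), 0.3),
                        index=pd.Index(["cg"], name="cpg_id"),
                        columns=[f"s{i}" for i in range(10000)])
    c = mm.simulate_wgbs_counts(wide, coverage_mean=30, rng=rng)
    frac = c.fractions(min_cov=1).to_numpy()
    assert abs(np.nanmean(frac) - 0.3) < 0.01


def test_panel_defaults_match_design():
    regions = mm.default_panel_regions()
    assert len(regions) == 16 and sum(regions.values()) == 258
    groups = {
        "A": ["1:CDH5", "3:GSTO2", "5:RABGGTA", "6:ZC3H12D"],
        "B": ["7:HOXD3", "9:MAB21L1", "10:MIR503", "12:PCOLCE"],
        "C": ["13:MGMT", "15:ASPSCR1", "16:CTSZ", "17:intergenic", "18:NACC2"],
    }
    assert sum(regions[r] for r in groups["A"]) == 26
    assert sum(regions[r] for r in groups["B"]) == 98
    assert sum(regions[r] for r in groups["C"]) == 53


def test_fingerprint_mixture_geometry():
    """The vEC fingerprint mixes iPS with a 2:1 fetal:adult endothelial
    pattern, so its region-mean vector is strictly closer to f-LSEC than to
    a-LSEC, and EPC stays within the configured shift of PBMC."""
    config = mm.SimulationConfig(seed=14)
    fp = mm.simulate_fingerprints(config, rng=14)
    region_means = fp.groupby(level="region_id", sort=False).mean()
    d_f = np.linalg.norm(region_means["vEC"] - region_means["f-LSEC"])
    d_a = np.linalg.norm(region_means["vEC"] - region_means["a-LSEC"])
    assert d_f < d_a
    assert (fp["EPC"] - fp["PBMC"]).abs().max() <= config.epc_shift + 1e-12


def test_panel_read_means_match_fingerprint():
    """1,000 reads per region, no donor jitter: per-region means within the
    binomial standard error of the fingerprint."""
    config = mm.SimulationConfig(seed=15, reads_per_region=1000, donor_jitter=0.0,
                                 missing_call_rate=0.0,
                                 group_sizes={"f-LSEC": 1, "vEC": 1})
    fp = mm.simulate_fingerprints(config, rng=15)
    sheet = mm.make_sample_sheet(config.group_sizes)
    panel = mm.simulate_panel_reads(config, fp, sheet, rng=16)
    profile = mm.summarize_regions(panel)
    region_fp = fp.groupby(level="region_id", sort=False).mean()
    for sample, group in sheet.group_of().items():
        diff = (profile.region_means[sample] - region_fp[group]).abs()
        assert diff.max() < 0.03
    # degenerate probabilities give degenerate calls
    config0 = mm.SimulationConfig(seed=15, reads_per_region=50, donor_jitter=0.0,
                                  missing_call_rate=0.0, group_sizes={"f-LSEC": 1})
    fp0 = fp.copy()
    fp0.loc[:, "f-LSEC"] = 0.0
    panel0 = mm.simulate_panel_reads(config0, fp0, mm.make_sample_sheet({"f-LSEC": 1}),
                                     rng=17)
    assert all((np.nan_to_num(c) == 0).all() for c in panel0.reads["calls"])
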