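"""Region-level DMR calling: Stouffer combination, gating rules, merging."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methylmark as mm
from methylmark._stats import signed_z_from_p, stouffer_combine

from conftest import beta_from


def test_stouffer_worked_example():
    """Three same-direction CpGs at p = 0.05: z_i = 1.95996 each,
    combined Z = 3.3948, two-sided p ~ 6.9e-4 (normal CDF oracle)."""
    z = signed_z_from_p(np.full(3, 0.05), np.ones(3))
    assert np.allclose(z, 1.959964, atol=1e-5)
    combined, p = stouffer_combine(z)
    assert combined == pytest.approx(1.959964 * np.sqrt(3), abs=1e-4)
    assert p == pytest.approx(2 * stats.norm.sf(1.959964 * np.sqrt(3)), rel=1e-6)
    assert p == pytest.approx(6.9e-4, abs=5e-5)


def _single_unit_setup(betas_a, betas_b, region_class="TSS200"):
    """Beta matrix plus manifest with all CpGs in one (gene, region) unit."""
    n = betas_a.shape[0]
    sheet = mm.make_sample_sheet({"A": betas_a.shape[1], "B": betas_b.shape[1]})
    beta = beta_from(np.hstack([betas_a, betas_b]), sheet.sample_ids)
    table = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(n) * 100,
            "gene": "GENE1",
            "region_class": region_class,
        },
        index=beta.values.index,
    )
    return beta, mm.CpGAnnotation(table=table), sheet


def test_opposing_directions_rejected():
    """A unit whose members disagree on direction fails the coherence gate."""
    rng = np.random.default_rng(0)
    a = np.vstack(
        [
            0.8 + rng.normal(0, 0.01, (2, 3)),
            0.2 + rng.normal(0, 0.01, (2, 3)),
        ]
    )
    b = np.full((4, 3), 0.5) + rng.normal(0, 0.01, (4, 3))
    beta, ann, sheet = _single_unit_setup(a, b)
    table = mm.dmr_by_gene_region(beta, ann, sheet, "A", "B", mm.DMRParams(min_cpgs=3))
    row = table.iloc[0]
    assert row["coherence"] == pytest.approx(0.5)
    assert not row["significant"]


def test_coherent_unit_accepted():
    rng = np.random.default_rng(1)
    a = 0.75 + rng.normal(0, 0.02, (5, 3))
    b = 0.45 + rng.normal(0, 0.02, (5, 3))
    beta, ann, sheet = _single_unit_setup(a, b)
    table = mm.dmr_by_gene_region(beta, ann, sheet, "A", "B")
    row = table.iloc[0]
    assert row["significant"] and row["direction"] == 1
    assert row["n_cpgs"] == 5 and row["coherence"] == 1.0


def test_combination_gains_power_over_single_cpgs():
    """Individually non-significant CpGs with consistent small shifts are
    detected at the unit level (delta-beta 0.1, sigma 0.08)."""
    config = mm.SimulationConfig(
        seed=21,
        n_cpgs=2000,
        n_dmr=10,
        delta_beta=0.1,
        sigma_beta=0.08,
        n_deg=0,
        delta_expr=0.0,
        linked_pairs={},
        group_sizes={"f-LSEC": 3, "HCMEC": 3, "HPAEC": 3, "HPMEC": 3},
    )
    study = mm.simulate_study(config)
    others = ["HCMEC", "HPAEC", "HPMEC"]
    per_cpg = mm.dmc_array(study.beta, study.sheet, "f-LSEC", others)
    params = mm.DMRParams(delta_min=0.05)
    table = mm.dmr_by_gene_region(study.beta, study.annotation, study.sheet,
                                  "f-LSEC", others, params)
    hits = mm.significant_dmrs(table)
    truth_units = set(study.truth.dmr["unit_id"])
    recovered = truth_units & set(hits.index)
    assert len(recovered) >= 5
    # at least one recovered unit has no individually significant CpG (by q)
    member_q_min = [
        per_cpg.loc[table.loc[u, "member_cpgs"], "q"].min() for u in recovered
    ]
    assert any(q > 0.05 for q in member_q_min)


def test_recovery_sensitivity_and_fdp():
    """40 planted promoter DMRs (delta-beta 0.25, 5 CpGs, sigma 0.05, 3 vs 9)
    among ~2,000 units: sensitivity >= 0.9 and FDP <= 0.1 at q < 0.05."""
    config = mm.SimulationConfig(
        seed=23,
        n_cpgs=10000,
        n_dmr=40,
        delta_beta=0.25,
        sigma_beta=0.05,
        n_deg=0,
        delta_expr=0.0,
        linked_pairs={},
        group_sizes={"f-LSEC": 3, "HCMEC": 3, "HPAEC": 3, "HPMEC": 3},
    )
    study = mm.simulate_study(config)
    table = mm.dmr_by_gene_region(
        study.beta, study.annotation, study.sheet, "f-LSEC", ["HCMEC", "HPAEC", "HPMEC"]
    )
    hits = set(mm.significant_dmrs(table).index)
    truth = set(study.truth.dmr["unit_id"])
    sensitivity = len(hits & truth) / len(truth)
    fdp = len(hits - truth) / max(len(hits), 1)
    assert sensitivity >= 0.9
    assert fdp <= 0.1


def test_merge_intervals_rules():
    assert mm.merge_intervals([(0, 10)]) == [(0, 10)]
    assert mm.merge_intervals([(0, 10), (5, 15), (20, 30)]) == [(0, 15), (20, 30)]
    merged = mm.merge_intervals([(0, 10), (8, 12), (11, 20)])
    assert mm.merge_intervals(merged) == merged  # idempotent


def test_window_merging_on_planted_region():
    """Two overlapping significant windows collapse into one merged unit."""
    sheet = mm.make_sample_sheet({"A": 3, "B": 3})
    n = 16
    positions = np.arange(n) * 100  # CpGs span 0..1500: several windows overlap
    rng = np.random.default_rng(3)
    frac_a = np.clip(0.8 + rng.normal(0, 0.02, (n, 3)), 0, 1)
    frac_b = np.clip(0.3 + rng.normal(0, 0.02, (n, 3)), 0, 1)
    cov = 200
    index = pd.Index([f"cg{i}" for i in range(n)], name="cpg_id")
    counts = mm.CountMethylome(
        meth=pd.DataFrame(
            np.hstack([(frac_a * cov), (frac_b * cov)]).astype(int),
            index=index, columns=sheet.sample_ids,
        ),
        total=pd.DataFrame(cov, index=index, columns=sheet.sample_ids),
        loci=pd.DataFrame({"chrom": "chr1", "pos": positions}, index=index),
    )
    table = mm.dmr_windows_wgbs(counts, sheet, "A", "B")
    sig = mm.significant_dmrs(table)
    assert len(sig) == 1  # all overlapping windows merged into a single run
    row = sig.iloc[0]
    assert len(row["member_cpgs"]) == n
    assert row["direction"] == 1 and row["coherence"] == 1.0


def test_window_null_genome_yields_no_dmrs():
    config = mm.SimulationConfig(
        seed=29,
        n_cpgs=10000,
        n_dmr=0,
        delta_beta=0.0,
        n_deg=0,
        delta_expr=0.0,
        linked_pairs={},
        group_sizes={"f-LSEC": 3, "a-LSEC": 2},
    )
    study = mm.simulate_study(config)
    table = mm.dmr_windows_wgbs(study.counts, study.sheet, "a-LSEC", "f-LSEC",
                                mm.DMRParams(min_cpgs=5))
    assert len(mm.significant_dmrs(table)) == 0


def test_rank_dmrs_ordering_and_empty():
    table = pd.DataFrame(
        {
            "member_cpgs": [["a"], ["b"], ["c"]],
            "n_cpgs": [3, 3, 3],
            "combined_z": [3.0, 3.0, 4.0],
            "combined_p": [0.01, 0.01, 0.001],
            "q": [0.02, 0.02, 0.004],
            "mean_delta_beta": [0.1, -0.3, 0.2],
            "direction": [1, -1, 1],
            "coherence": [1.0, 1.0, 1.0],
            "significant": [True, True, True],
        },
        index=pd.Index(["u1", "u2", "u3"], name="unit_id"),
    )
    ranked = mm.rank_dmrs(table)
    # smallest p first; tie at p=0.01 broken by larger |delta-beta|
    assert list(ranked.index) == ["u3", "u2", "u1"]
    empty = mm.rank_dmrs(table[table["combined_p"] > 1])
    assert empty.empty
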