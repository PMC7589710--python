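"""End-to-end orchestration: run every analysis stage on one study.

Convenience layer used by scripts and reproducibility checks: given a
simulated (or loaded) study, run differential expression, array and WGBS
differential methylation, gene-region and window DMR detection, the
expression-methylation correlation bookkeeping and the panel similarity
report, and write every result as deterministic text files.
"""

from __future__ import annotations

import json
from pathlib import Path

from .diff_expression import two_group_diff
from .diff_methylation import dmc_array, dmc_wgbs
from .dmr_detection import DMRParams, dmr_by_gene_region, dmr_windows_wgbs
from .integration import expr_meth_correlate
from .io_model import FLOAT_FMT
from .panel_similarity import classify_similarity, summarize_regions
from .synthetic_data import StudyData, write_study

FETAL_EC_GROUPS = ["HCMEC", "HPAEC", "HPMEC"]
REFERENCE_GROUPS = ["a-LSEC", "f-LSEC", "HCMEC", "HPAEC", "HPMEC"]


def run_study_pipeline(study: StudyData, outdir: str | Path) -> dict[str, Path]:
    """Run the full analysis on ``study`` and write inputs plus results.

    Contrasts mirror the study design: f-LSEC against the pooled other fetal
    ECs for expression/methylation/DMRs, a-LSEC against f-LSEC for WGBS, and
    the vEC samples scored against the primary EC reference groups.
    Returns the mapping of artefact names to written paths; a second run with
    the same study writes byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_study(study, outdir)
    sheet = study.sheet
    paths: dict[str, Path] = {}

    dex = two_group_diff(study.expression, sheet, "f-LSEC", FETAL_EC_GROUPS)
    paths["dex"] = outdir / "dex.tsv"
    dex.rename_axis("feature_id").to_csv(paths["dex"], sep="\t", float_format=FLOAT_FMT)

    dmc = dmc_array(study.beta, sheet, "f-LSEC", FETAL_EC_GROUPS)
    paths["dmc_array"] = outdir / "dmc_array.tsv"
    dmc.rename_axis("cpg_id").to_csv(paths["dmc_array"], sep="\t", float_format=FLOAT_FMT)

    wgbs_groups = {g for g in ("a-LSEC", "f-LSEC") if len(sheet.table[sheet.table["group"] == g]) >= 2}
    if {"a-LSEC", "f-LSEC"} <= wgbs_groups:
        dmcw = dmc_wgbs(study.counts, sheet, "a-LSEC", "f-LSEC")
        paths["dmc_wgbs"] = outdir / "dmc_wgbs.tsv"
        dmcw.rename_axis("cpg_id").to_csv(paths["dmc_wgbs"], sep="\t", float_format=FLOAT_FMT)
        windows = dmr_windows_wgbs(study.counts, sheet, "a-LSEC", "f-LSEC",
                                   DMRParams(min_cpgs=5))
        windows = windows.assign(member_cpgs=[",".join(m) for m in windows["member_cpgs"]])
        paths["dmr_windows"] = outdir / "dmr_windows.tsv"
        windows.rename_axis("unit_id").to_csv(paths["dmr_windows"], sep="\t",
                                              float_format=FLOAT_FMT)

    dmr = dmr_by_gene_region(study.beta, study.annotation, sheet, "f-LSEC", FETAL_EC_GROUPS)
    dmr = dmr.assign(member_cpgs=[",".join(m) for m in dmr["member_cpgs"]])
    paths["dmr_generegion"] = outdir / "dmr_generegion.tsv"
    dmr.rename_axis("unit_id").to_csv(paths["dmr_generegion"], sep="\t",
                                      float_format=FLOAT_FMT)

    corr = expr_meth_correlate(dex, study.expression, study.beta, study.annotation)
    paths["correlations"] = outdir / "correlations.tsv"
    corr.pairs.to_csv(paths["correlations"], sep="\t", index=False, float_format=FLOAT_FMT)
    paths["correlation_summary"] = outdir / "correlation_summary.json"
    paths["correlation_summary"].write_text(
        json.dumps(corr.counts(), indent=1, sort_keys=True)
    )

    queries = [s for s in sheet.sample_ids if sheet.group_of()[s] == "vEC"]
    if queries:
        profile = summarize_regions(study.panel)
        report = classify_similarity(profile, sheet, REFERENCE_GROUPS, queries)
        payload = {
            q: {
                "distances": {g: round(float(d), 8) for g, d in report.distances.loc[q].items()},
                "nearest_group": report.nearest[q],
                "margin": round(float(report.margin[q]), 8),
                "ranking": report.rankings[q],
            }
            for q in report.distances.index
        }
        paths["similarity"] = outdir / "similarity.json"
        paths["similarity"].write_text(json.dumps(payload, indent=1, sort_keys=True))
    return paths
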