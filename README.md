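# methylmark

Integrative transcriptome/methylome analysis for endothelial-cell identity,
built around the question of what makes liver sinusoidal endothelial cells
(LSECs) — the main Factor-VIII-secreting cell type — molecularly distinct
from other endothelial cells, and how close in-vitro-derived vascular
endothelial cells come to the primary cells.

The package is aimed at analysts working with bulk expression arrays,
methylation arrays (450K/EPIC-style beta values), whole-genome bisulfite
sequencing (WGBS) counts and targeted bisulfite re-sequencing panels. It
provides, as plain functions over pandas containers plus a thin `methylmark`
CLI:

* **Differential expression** — probe-level two-sided Student t
  (pooled variance) or one-way ANOVA across groups, Benjamini–Hochberg FDR,
  ranking by |mean difference| (the mean difference of log2 intensities is
  the log2 fold change).
* **Differential methylation** — the same statistics on beta values (array
  mode) or on per-sample fractions from methylated/total read counts with a
  coverage filter (WGBS mode); significant CpGs are classified hyper-/
  hypomethylated; cross-platform per-sample Pearson concordance.
* **DMR detection** — region-level calls over (gene, region-class) units
  such as `GSTO2|TSS200`, or over sliding genomic windows for WGBS. Each
  unit combines direction-signed per-CpG z-scores with an equal-weight
  Stouffer statistic `Z = Σ z_i / √n`; a unit is a DMR when BH `q < 0.05`,
  directional coherence ≥ 0.8 and |mean Δβ| ≥ 0.10 hold simultaneously.
* **Expression–methylation integration** — Pearson correlation of each
  differentially expressed gene with its annotated CpGs, retaining
  |r| > 0.7 and tallying a 2×2 sign-by-context (promoter vs non-promoter)
  summary; plus concordance of group mean expression with external
  reference profiles.
* **Panel similarity** — read-level summaries of a 16-region / 258-CpG
  targeted bisulfite panel, ANOVA-based marker CpG selection, PCA
  embedding, and nearest-centroid scoring of query samples (e.g.
  iPS-derived vascular ECs) against reference-group methylation
  fingerprints in a standardized marker space.
* **Synthetic data** — a generator that emulates the full study design
  (fetal LSECs and other fetal ECs with three donors each, two adult LSEC
  donors, a PBMC → EPC → iPS → mesoderm → vEC differentiation series with
  five donors) with planted, recoverable ground truth for every stage.

## Worked example

```python
import methylmark as mm

study = mm.simulate_study(mm.SimulationConfig(seed=1))

dex = mm.two_group_diff(study.expression, study.sheet,
                        "f-LSEC", ["HCMEC", "HPAEC", "HPMEC"])
dmc = mm.dmc_array(study.beta, study.sheet,
                   "f-LSEC", ["HCMEC", "HPAEC", "HPMEC"])
dmr = mm.dmr_by_gene_region(study.beta, study.annotation, study.sheet,
                            "f-LSEC", ["HCMEC", "HPAEC", "HPMEC"])
corr = mm.expr_meth_correlate(dex, study.expression, study.beta, study.annotation)

profile = mm.summarize_regions(study.panel)
report = mm.classify_similarity(
    profile, study.sheet,
    ["a-LSEC", "f-LSEC", "HCMEC", "HPAEC", "HPMEC", "PBMC", "EPC", "iPS", "mesoderm"],
    study.sheet.samples("vEC"))
```

prints, with the summaries shown in the repository's examples:

```
DE probes at p<0.05: 283
DMCs at q<0.05: 393 | hyper: 211 hypo: 182
DMR units: 40 | planted recovered: 40 / 40
sign x context counts: {'positive_promoter': 28, 'positive_nonpromoter': 45,
                        'negative_promoter': 62, 'negative_nonpromoter': 58}
vEC_d1 ranking: ['mesoderm', 'iPS', 'f-LSEC', 'HPMEC'] | d(f-LSEC)=17.7 < d(a-LSEC)=27.5
```

Reading the output: 283 of 2,000 probes pass p < 0.05 (200 effects were
planted on a 5% false-positive background); all 40 planted promoter DMRs are
recovered with no false units; the sign-by-context counts recover the
planted 25/44/58/56 linked-pair design plus a handful of chance
correlations; and every simulated iPS-derived vEC sits nearest its mesoderm
and iPS precursors while being clearly closer to fetal than to adult LSEC
references — the expected geometry for partially differentiated cells.

The same pipeline runs from the shell:

```bash
methylmark simulate --out data/ --seed 1
methylmark dex --expr data/expression.tsv --samples data/samples.tsv \
    --contrast "f-LSEC vs HCMEC,HPAEC,HPMEC" --out dex.tsv
methylmark panel --reads data/panel_reads.tsv --samples data/samples.tsv \
    --refs a-LSEC,f-LSEC,HCMEC,HPAEC,HPMEC --query vEC --out report.json
```

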