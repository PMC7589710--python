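# Methods

This note documents the statistical model behind each pipeline stage, the
synthetic-data generator, the numerical conventions, and the limitations a
user should keep in mind.

## Differential testing

Two-group contrasts use the two-sided Student t-test with pooled variance on
the native scale of the data: log2 intensities for expression (so the mean
difference is the log2 fold change) and beta values (methylation fractions)
for arrays. Either side of a contrast may pool several groups into one
reference set (e.g. fetal LSECs against all other fetal ECs). Welch's
unequal-variance t is available behind a flag; the pooled form is the
default because donor groups of two and three samples give no usable
information for per-feature variance ratios. Multi-group contrasts use
one-way ANOVA. Features with zero variance everywhere get p = 1 by
convention; rows with fewer than two observations in a group are excluded
and logged. p-values are adjusted per analysis with the Benjamini–Hochberg
step-up procedure; expression analyses conventionally filter at unadjusted
p < 0.05 while methylation analyses use q < 0.05, mirroring how the two
data types are usually reported.

WGBS counts are reduced to per-sample fractions where coverage is at least
`min_cov` (default 5×); a CpG needs two covered samples per group to be
tested. Testing fractions with the same t statistic as array betas keeps
donors as the unit of replication across platforms and makes array and WGBS
results directly comparable — a count-level test (e.g. pooled proportions)
would ignore biological donor-to-donor variance and overstate significance.
No beta→M-value transform is applied by default so that group differences
remain interpretable as Δβ; an M-value mode exists for users who prefer
variance stabilisation (the difference column is reported on the beta scale
either way).

## DMR detection

Units are either all CpGs sharing a (gene, region-class) annotation — with
the promoter classes TSS1500, TSS200, 5′UTR and 1stExon available as a
restricted mode — or sliding windows (default 1,000 bp, step 500 bp) for
WGBS, where no gene-region grouping is available genome-wide. A unit with
at least `min_cpgs` tested CpGs (3 for gene-region units, 5 for windows) is
scored by an equal-weight Stouffer combination of direction-signed per-CpG
z-scores, `z_i = sign_i · Φ⁻¹(1 − p_i/2)`, `Z = Σ z_i / √n`, so opposing
directions cancel rather than accumulate. BH adjustment runs across units
(not CpGs). A unit is reported as a DMR only when three gates hold
simultaneously:

* `q < 0.05` on the combined p,
* directional coherence ≥ 0.8 (fraction of member CpGs on the majority
  side), and
* |mean Δβ| ≥ 0.10.

The coherence and effect-size gates keep single outlier CpGs and
statistically-significant-but-tiny shifts from being promoted to regions;
both thresholds, the window geometry and the minimum unit size are
configurable (`DMRParams`). Overlapping significant windows are merged into
maximal runs whose statistics are recomputed on the union of member CpGs;
the merged unit keeps the smallest member q (recomputing q after selection
would bias it), and merging is idempotent. Ranking is by combined p, ties
by |mean Δβ|, then unit id.

**Variance moderation in the window caller.** With two or three WGBS
replicates, the empirical variance of read fractions occasionally collapses
to nearly zero by counting coincidence (two samples drawing identical
methylated counts), which produces enormous t values on 3 degrees of
freedom and, once several CpGs of a window are combined, spurious
region-level significance. The window caller therefore floors each CpG's
pooled variance at the binomial sampling variance implied by its coverage,
`p̄(1−p̄) · mean(1/cᵢ)` — a hard lower bound on the true sampling noise of a
fraction. The floor only binds where the empirical variance is implausibly
small; per-CpG WGBS results (`dmc_wgbs`) are reported unmoderated. In null
simulations (10,000 CpGs, 20 seeds) both callers report zero DMRs in every
seed with the floor, versus occasional single false windows without it.

## Expression–methylation integration

Differentially expressed genes (p < 0.05; a gene with several probes is
represented by its smallest-p probe) are paired with every CpG annotated to
them. Pearson correlations run across all samples of the contrast pooled —
the group difference is the biological signal linking the two layers — with
pairwise-complete handling of missing cells and a minimum of three complete
pairs. Pairs with |r| > 0.7 are retained, keeping both signs, and tallied
in a 2×2 sign-by-context table where the promoter context is defined by the
annotation's region class (TSS1500/TSS200/5′UTR/1stExon), not by TSS
distance. A within-group correlation mode exists behind a flag for users
worried about group-driven correlation. `reference_concordance` collapses
probes to genes by averaging and reports the Pearson r (with its
correlation-test p) between a group's mean expression and an external
per-gene reference vector; at least ten shared genes are required.

## Panel similarity

Read-level panel calls are summarised to per-CpG means (fraction of
methylated calls among non-missing calls per sample) and per-region means.
Marker CpGs are selected by one-way ANOVA across the *reference* groups
only — at p < 0.05 for exploratory separation or BH-q < 0.05 for the
stricter mode. Query samples never participate in selection, centering,
standardisation or PCA fitting; this leakage-free convention is a design
choice the assay description leaves open. Distances are Euclidean in the
standardized selected-CpG space by default; a PCA space (first k = 3
components fitted on references, deterministic sign convention: the
largest-magnitude loading of each component is positive) is provided for
fidelity to low-dimensional visualisations, but with 5–20 reference samples
PCA axes are unstable, hence the CpG space default. Query cells missing up
to half of the selected CpGs are mean-imputed from references (count
reported); more missingness is an error. Distance ties are broken by
lexical group order with a logged warning. The seven-region preset
(3:GSTO2, 5:RABGGTA, 6:ZC3H12D, 7:HOXD3, 12:PCOLCE, 13:MGMT, 18:NACC2) is
exposed as `SEVEN_REGION_PANEL` with `restrict_regions`.

## Synthetic data

The generator reproduces the study design the pipeline targets: expression
and beta matrices for f-LSEC/HCMEC/HPAEC/HPMEC (three donors each) and
a-LSEC (two donors); WGBS counts for the LSEC samples; and a 16-region,
258-CpG targeted panel additionally covering a PBMC → EPC → iPS → mesoderm
→ vEC series with five donors per stage. Defaults (all in
`SimulationConfig`):

* **Expression** — per-gene baseline `N(8, 2)` log2 units, per-gene noise
  SD `U(0.2, 0.6)`; 200 DEGs at ±2 log2 units in the target group (both
  directions). 2,000 genes, one probe per gene.
* **Methylation** — 5,000 CpGs in units of 5 (one promoter and one
  non-promoter unit per annotated gene, units 5 kb apart with 100 bp CpG
  spacing across 22 chromosomes); latent means `U(0.3, 0.7)`; logit-normal
  per-sample noise scaled for a marginal SD of σ_β = 0.05 (logit-normal
  noise keeps effects additive mid-range and can never leave (0, 1), so no
  boundary pile-up). 40 DMR units shift all member CpGs coherently by
  ±0.25 in the target group; member baselines are drawn inside
  `[0.05 + Δβ, 0.95 − Δβ]` so the planted shift is exact.
* **Linked pairs** — 58/25/44/56 pairs per (sign × context) cell share a
  per-sample latent factor scaled for an expected Pearson |r| of 0.95, with
  a coherent ±0.2 group shift on the CpG side so group structure and noise
  correlation reinforce each other.
* **WGBS** — negative-binomial coverage (mean 30, size 5), binomial
  methylated reads, zero-coverage cells missing.
* **Panel fingerprints** — endothelial groups share a background;
  f-LSEC shifts coherently (whole regions, ±0.3) at its four marker regions
  and a-LSEC at its nine, so the two LSEC stages are separated by more
  marker mass than f-LSEC is from the other fetal ECs; each other fetal EC
  type carries its own per-CpG signature; PBMC and iPS are independent
  non-endothelial methylomes; EPC = PBMC ± ≤0.05; mesoderm and vEC are
  convex mixtures of iPS with a 2:1 fetal:adult endothelial pattern
  (mixing weights 0.85 and λ = 0.7 on iPS). Region-coherent marker shifts
  make the intended geometry — vECs nearest mesoderm/iPS, then closer to
  fetal than to adult LSECs — hold at the region-mean level
  deterministically, not just in expectation per CpG. 200 reads per region
  per sample, 1% missing calls, small logit-space donor jitter (SD 0.02).

Donor random effects beyond the panel jitter are omitted by default
(donors are treated as exchangeable replicates). A single integer seed
drives spawned generators per stage, so a fixed configuration is fully
deterministic and changing one stage's settings does not perturb another's
draws.

**What passing tests do and do not show.** The simulator plants clean,
independent effects on independent features with homoscedastic noise. Real
arrays have correlated probes, batch and chip effects, cell-composition
drift and annotation errors; real WGBS has non-uniform coverage and
conversion artefacts; real panels have PCR and mapping biases. Recovery and
calibration results on this generator therefore demonstrate the
correctness and internal consistency of the statistics, not expected
performance on any particular real data set.

## Numerical conventions

Coordinates are 0-based half-open; manifests are BED-like and headerless.
Missing values are empty TSV cells / NaN and are excluded pairwise.
Writers use a fixed `%.10g` float format so that write → read → write is
byte-identical. BH leaves NaN p-values NaN and excludes them from the test
count. z-scores from p = 0 are clipped to the largest finite deviate. Group
labels are free strings validated against the sample sheet; the study's
group names are defaults, not hard-coded. Problem sizes in the acceptance
script (10,000 features for calibration, 20 null seeds, 5,000 CpGs for
concordance, reduced read counts where only determinism is at stake) are
chosen to make every quantity statistically stable at desk scale.

## Known limitations

* The per-CpG WGBS test requires two covered replicates per group and has
  low power at n = 2 vs 3; genome-wide per-CpG significance is rarely
  reached at that design, which is why the region level is the primary
  WGBS readout.
* Gene-region DMR units depend entirely on the supplied manifest; CpGs
  annotated to no gene are never part of a unit (use window mode).
* The correlation stage does not model probe–CpG distance or causality;
  retained pairs are descriptive.
* PCA-space similarity is provided for visual fidelity but is less stable
  than the default standardized-CpG-space distance at small reference
  sizes.
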