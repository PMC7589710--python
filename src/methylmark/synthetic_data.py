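"""Study-shaped synthetic data with known ground truth.

The generator emulates the design of the endothelial-cell methylome study the
pipeline targets: expression and 450K/EPIC-style beta matrices for fetal liver
sinusoidal endothelial cells (f-LSEC, three donors) against other fetal
endothelial cells (HCMEC/HPAEC/HPMEC, three donors each) and adult LSECs (two
donors); WGBS-style counts for the LSEC samples; and a 16-region / 258-CpG
targeted bisulfite panel covering, in addition, a differentiation series
PBMC -> EPC -> iPS -> mesoderm -> vEC (five donors per stage).

Planted signals and their bookkeeping:

* differentially expressed genes: a +/- ``delta_expr`` log2 shift in the
  target group on a per-gene baseline ``N(8, 2)`` with per-gene noise SD drawn
  from ``U(0.2, 0.6)``;
* differentially methylated regions: coherent +/- ``delta_beta`` shifts of all
  CpGs in selected promoter (gene, region-class) units; per-CpG betas are
  sampled logit-normally around the group mean with marginal SD ~ ``sigma_beta``
  (logit-normal noise keeps effects additive mid-range and cannot leave (0,1));
* linked expression-methylation pairs: a DEG and a CpG annotated to it share a
  per-sample latent factor scaled for an expected Pearson |r| of ``r_linked``,
  with configurable counts per (sign x promoter-context) cell;
* WGBS counts: negative-binomial coverage, binomial methylated reads,
  zero-coverage cells missing;
* panel fingerprints: per-group methylation probabilities per panel CpG.  The
  EPC fingerprint is a small perturbation of PBMC; mesoderm and vEC are convex
  mixtures of the iPS fingerprint and an endothelial pattern
  (2:1 fetal:adult LSEC), vEC with mixing weight ``lambda_vec`` on iPS, which
  reproduces the qualitative geometry in which vECs sit nearest mesoderm/iPS
  while remaining closer to fetal than to adult LSECs.

Everything is driven by a single integer seed through spawned NumPy
generators, so a fixed configuration is fully deterministic.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io_model import (
    BetaMatrix,
    CountMethylome,
    CpGAnnotation,
    ExpressionMatrix,
    ReadPanel,
    SampleSheet,
    write_beta_table,
    write_counts_table,
    write_cpg_manifest,
    write_expression_table,
    write_panel_reads,
    write_sample_sheet,
)

ARRAY_GROUPS: tuple[str, ...] = ("f-LSEC", "HCMEC", "HPAEC", "HPMEC", "a-LSEC")
WGBS_GROUPS: tuple[str, ...] = ("f-LSEC", "a-LSEC")
TRAJECTORY_GROUPS: tuple[str, ...] = ("PBMC", "EPC", "iPS", "mesoderm", "vEC")

_PROMOTER_CYCLE = ("TSS200", "TSS1500", "5UTR", "1stExon")
_NONPROMOTER_CYCLE = ("Body", "3UTR")

#: Default linked-pair counts per (sign, context) cell.
DEFAULT_LINKED_PAIRS: Mapping[str, int] = {
    "negative_promoter": 58,
    "positive_promoter": 25,
    "positive_nonpromoter": 44,
    "negative_nonpromoter": 56,
}


def default_group_sizes() -> dict[str, int]:
    sizes = {"f-LSEC": 3, "HCMEC": 3, "HPAEC": 3, "HPMEC": 3, "a-LSEC": 2}
    sizes.update({g: 5 for g in TRAJECTORY_GROUPS})
    return sizes


def default_panel_regions() -> dict[str, int]:
    """Panel regions with their CpG counts (16 regions, 258 CpGs in total).

    The three verification groups hold 26, 98 and 53 CpGs; the remaining CpGs
    are distributed evenly over the three regions outside those groups.
    """
    regions: dict[str, int] = {}
    regions.update(dict(zip(["1:CDH5", "3:GSTO2", "5:RABGGTA", "6:ZC3H12D"], [7, 7, 6, 6])))
    regions.update(
        dict(zip(["7:HOXD3", "9:MAB21L1", "10:MIR503", "12:PCOLCE"], [25, 25, 24, 24]))
    )
    regions.update(
        dict(
            zip(
                ["13:MGMT", "15:ASPSCR1", "16:CTSZ", "17:intergenic", "18:NACC2"],
                [11, 11, 11, 10, 10],
            )
        )
    )
    regions.update({"2:COL20A1": 27, "4:MIR21": 27, "8:region8": 27})

    def _order(rid: str) -> int:
        return int(rid.split(":")[0])

    ordered = dict(sorted(regions.items(), key=lambda kv: _order(kv[0])))
    assert sum(ordered.values()) == 258 and len(ordered) == 16
    return ordered


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the study simulator (defaults emulate the study design)."""

    seed: int = 0
    n_genes: int = 2000
    n_cpgs: int = 5000
    cpgs_per_region: int = 5
    group_sizes: Mapping[str, int] = field(default_factory=default_group_sizes)
    target_group: str = "f-LSEC"
    # expression
    n_deg: int = 200
    delta_expr: float = 2.0
    sigma_expr_range: tuple[float, float] = (0.2, 0.6)
    # methylation
    n_dmr: int = 40
    delta_beta: float = 0.25
    sigma_beta: float = 0.05
    # linked expression-methylation pairs
    linked_pairs: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_LINKED_PAIRS)
    )
    r_linked: float = 0.95
    delta_beta_linked: float = 0.2
    # WGBS counts
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0
    # targeted panel
    panel_regions: Mapping[str, int] = field(default_factory=default_panel_regions)
    reads_per_region: int = 200
    missing_call_rate: float = 0.01
    fingerprint_shift: float = 0.3
    fingerprint_frac: float = 0.2
    epc_shift: float = 0.05
    lambda_mesoderm: float = 0.85
    lambda_vec: float = 0.7
    donor_jitter: float = 0.02

    def n_units(self) -> int:
        return self.n_cpgs // self.cpgs_per_region

    def n_annotated_genes(self) -> int:
        return self.n_units() // 2

    def total_linked(self) -> int:
        return int(sum(self.linked_pairs.values()))

    def validate(self) -> None:
        if any(v < 0 for v in self.group_sizes.values()):
            raise ValueError("group sizes must be non-negative")
        if self.n_dmr * self.cpgs_per_region > self.n_cpgs:
            raise ValueError(
                f"n_dmr x cpgs_per_region = {self.n_dmr * self.cpgs_per_region} "
                f"exceeds n_cpgs = {self.n_cpgs}"
            )
        n_deg_eff = self.n_deg if self.delta_expr != 0 else 0
        if self.total_linked() > n_deg_eff:
            raise ValueError(
                f"{self.total_linked()} linked pairs requested but only "
                f"{n_deg_eff} DEGs available"
            )
        if n_deg_eff + (self.n_dmr if self.delta_beta != 0 else 0) > self.n_annotated_genes():
            raise ValueError("not enough annotated genes for DEGs plus DMR units")
        if self.n_genes < self.n_annotated_genes():
            raise ValueError("n_genes must cover the annotated genes")
        if not 0 <= self.r_linked <= 1:
            raise ValueError("r_linked must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted signals: the recoverable truth behind a simulated study."""

    deg: pd.DataFrame  # probe_id, gene, sign, delta
    dmr: pd.DataFrame  # unit_id, gene, region_class, member_cpgs, direction, delta
    dmc: pd.DataFrame  # cpg_id, direction, delta, source
    linked: pd.DataFrame  # probe_id, gene, cpg_id, sign, promoter
    fingerprints: pd.DataFrame  # (region_id, cpg_index) x group


@dataclass
class StudyData:
    """All artefacts of one simulated study."""

    config: SimulationConfig
    sheet: SampleSheet
    annotation: CpGAnnotation
    expression: ExpressionMatrix
    beta: BetaMatrix
    counts: CountMethylome
    panel: ReadPanel
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------


def _rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def make_sample_sheet(group_sizes: Mapping[str, int]) -> SampleSheet:
    """One sample per (group, donor); groups with size 0 are omitted."""
    rows = []
    for group, n in group_sizes.items():
        for d in range(1, n + 1):
            rows.append(
                {"sample_id": f"{group}_d{d}", "group": group, "donor_id": f"d{d}"}
            )
    return SampleSheet(table=pd.DataFrame(rows, columns=["sample_id", "group", "donor_id"]))


def make_annotation(config: SimulationConfig) -> tuple[CpGAnnotation, pd.DataFrame]:
    """CpG manifest plus the unit table that groups CpGs for DMR simulation.

    Each annotated gene owns one promoter and one non-promoter unit of
    ``cpgs_per_region`` CpGs; leftover CpGs are intergenic.  CpGs of a unit
    are 100 bp apart and units are separated by 5 kb so that sliding windows
    see one unit at a time; units are spread over 22 chromosomes.
    """
    n_units = config.n_units()
    n_genes = config.n_annotated_genes()
    per_chrom = max(1, -(-n_units // 22))
    records = []
    cpg = 0
    cursor: dict[str, int] = {}
    for u in range(n_units):
        gene_idx, which = divmod(u, 2)
        if gene_idx < n_genes:
            gene = f"G{gene_idx:04d}"
            cycle = _PROMOTER_CYCLE if which == 0 else _NONPROMOTER_CYCLE
            region_class = cycle[gene_idx % len(cycle)]
        else:
            gene, region_class = "", "Intergenic"
        chrom = f"chr{1 + u // per_chrom}"
        start = cursor.get(chrom, 1000)
        for i in range(config.cpgs_per_region):
            records.append(
                {
                    "chrom": chrom,
                    "pos": start + 100 * i,
                    "cpg_id": f"cg{cpg:07d}",
                    "gene": gene,
                    "region_class": region_class,
                }
            )
            cpg += 1
        cursor[chrom] = start + 100 * config.cpgs_per_region + 5000
    # leftover CpGs that do not fill a unit become intergenic singletons
    chrom = "chr22"
    start = cursor.get(chrom, 1000)
    while cpg < config.n_cpgs:
        records.append(
            {
                "chrom": chrom,
                "pos": start,
                "cpg_id": f"cg{cpg:07d}",
                "gene": "",
                "region_class": "Intergenic",
            }
        )
        start += 5000
        cpg += 1
    table = pd.DataFrame(records).set_index("cpg_id")
    annotation = CpGAnnotation(table=table[["chrom", "pos", "gene", "region_class"]])
    units = (
        table[table["gene"] != ""]
        .reset_index()
        .groupby(["gene", "region_class"], sort=False)["cpg_id"]
        .apply(list)
        .reset_index()
        .rename(columns={"cpg_id": "member_cpgs"})
    )
    units["promoter"] = units["region_class"].isin(set(_PROMOTER_CYCLE))
    units["unit_id"] = units["gene"] + "|" + units["region_class"]
    return annotation, units


def simulate_expression(
    config: SimulationConfig,
    sheet: SampleSheet,
    rng: np.random.Generator | int | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Expression matrix over the sheet's array samples plus DEG truth.

    Returns ``(matrix, deg_truth, probe_params)``; ``probe_params`` carries the
    per-probe baseline, noise SD and signed effect needed to re-draw linked
    probes coherently.
    """
    rng = _rng(rng)
    samples = [
        s for g in sheet.groups if g in ARRAY_GROUPS for s in sheet.samples(g)
    ]
    probes = pd.Index([f"p{i:05d}" for i in range(config.n_genes)], name="probe_id")
    genes = pd.Series([f"G{i:04d}" for i in range(config.n_genes)], index=probes, name="gene")
    mu = rng.normal(8.0, 2.0, size=config.n_genes)
    sigma = rng.uniform(*config.sigma_expr_range, size=config.n_genes)
    effect = np.zeros(config.n_genes)
    n_deg = config.n_deg if config.delta_expr != 0 else 0
    deg_idx = np.array([], dtype=int)
    if n_deg:
        deg_idx = np.sort(rng.choice(config.n_annotated_genes(), size=n_deg, replace=False))
        signs = rng.choice([-1.0, 1.0], size=n_deg)
        effect[deg_idx] = signs * config.delta_expr
    in_target = np.array([s in set(sheet.samples(config.target_group)) for s in samples]) \
        if config.target_group in sheet.groups else np.zeros(len(samples), bool)
    values = (
        mu[:, None]
        + effect[:, None] * in_target[None, :]
        + rng.normal(0.0, 1.0, size=(config.n_genes, len(samples))) * sigma[:, None]
    )
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=probes, columns=samples), genes=genes
    )
    deg_truth = pd.DataFrame(
        {
            "probe_id": probes[deg_idx],
            "gene": genes.iloc[deg_idx].to_numpy(),
            "sign": np.sign(effect[deg_idx]).astype(int),
            "delta": effect[deg_idx],
        }
    )
    probe_params = pd.DataFrame(
        {"gene": genes, "mu": mu, "sigma": sigma, "effect": effect}, index=probes
    )
    return matrix, deg_truth, probe_params


def _beta_noise_scale(m: np.ndarray, sigma_beta: float) -> np.ndarray:
    m = np.clip(m, 0.02, 0.98)
    return sigma_beta / (m * (1.0 - m))


def _sample_betas(
    group_means: np.ndarray, sigma_beta: float, rng: np.random.Generator
) -> np.ndarray:
    """Logit-normal draws around per-cell means with marginal SD ~ sigma_beta."""
    if sigma_beta == 0:
        return group_means.copy()
    scale = _beta_noise_scale(group_means, sigma_beta)
    noise = rng.normal(0.0, 1.0, size=group_means.shape) * scale
    return expit(logit(np.clip(group_means, 0.02, 0.98)) + noise)


def simulate_methylation(
    config: SimulationConfig,
    sheet: SampleSheet,
    annotation: CpGAnnotation,
    units: pd.DataFrame,
    deg_truth: pd.DataFrame | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[BetaMatrix, pd.DataFrame, pd.DataFrame]:
    """Beta matrix over array samples plus DMR truth and per-group CpG means.

    DMR units are promoter units of genes that are not DEGs (so planted
    expression and methylation signals stay disentangled unless explicitly
    linked); all member CpGs shift coherently by +/- ``delta_beta`` in the
    target group.  Returns ``(beta, dmr_truth, group_means)`` where
    ``group_means`` is the CpG x group matrix of latent means.
    """
    rng = _rng(rng)
    samples = [s for g in sheet.groups if g in ARRAY_GROUPS for s in sheet.samples(g)]
    cpgs = annotation.cpg_ids
    base = rng.uniform(0.3, 0.7, size=len(cpgs))
    groups = [g for g in sheet.groups if g in ARRAY_GROUPS]
    group_means = pd.DataFrame(
        np.tile(base[:, None], (1, len(groups))), index=cpgs, columns=groups
    )
    n_dmr = config.n_dmr if config.delta_beta != 0 else 0
    dmr_rows = []
    if n_dmr and config.target_group in groups:
        deg_genes = set() if deg_truth is None else set(deg_truth["gene"])
        pool = units[(units["promoter"]) & (~units["gene"].isin(deg_genes))]
        if len(pool) < n_dmr:
            raise ValueError(f"only {len(pool)} promoter units free for {n_dmr} DMRs")
        chosen = pool.iloc[
            np.sort(rng.choice(len(pool), size=n_dmr, replace=False))
        ]
        directions = rng.choice([-1.0, 1.0], size=n_dmr)
        # member baselines are re-drawn inside [0.05 + delta, 0.95 - delta] so
        # the planted shift is exact (no boundary clipping); for very large
        # deltas the shifted mean is clipped instead
        lo, hi = 0.05 + config.delta_beta, 0.95 - config.delta_beta
        for (_, unit), direction in zip(chosen.iterrows(), directions):
            members = unit["member_cpgs"]
            if lo < hi:
                fresh = rng.uniform(lo, hi, size=len(members))
                group_means.loc[members, :] = fresh[:, None]
            shifted = np.clip(
                group_means.loc[members, config.target_group] + direction * config.delta_beta,
                0.05,
                0.95,
            )
            group_means.loc[members, config.target_group] = shifted
            dmr_rows.append(
                {
                    "unit_id": unit["unit_id"],
                    "gene": unit["gene"],
                    "region_class": unit["region_class"],
                    "member_cpgs": list(members),
                    "direction": int(direction),
                    "delta": direction * config.delta_beta,
                }
            )
    mean_per_sample = group_means[
        [sheet.group_of()[s] for s in samples]
    ].to_numpy()
    betas = _sample_betas(mean_per_sample, config.sigma_beta, rng)
    beta = BetaMatrix(values=pd.DataFrame(betas, index=cpgs, columns=samples))
    dmr_truth = pd.DataFrame(
        dmr_rows,
        columns=["unit_id", "gene", "region_class", "member_cpgs", "direction", "delta"],
    )
    return beta, dmr_truth, group_means


def simulate_linked_pairs(
    config: SimulationConfig,
    sheet: SampleSheet,
    units: pd.DataFrame,
    expression: ExpressionMatrix,
    probe_params: pd.DataFrame,
    beta: BetaMatrix,
    group_means: pd.DataFrame,
    deg_truth: pd.DataFrame,
    rng: np.random.Generator | int | None = None,
) -> tuple[ExpressionMatrix, BetaMatrix, pd.DataFrame]:
    """Re-draw selected (DEG, CpG) pairs with a shared per-sample latent factor.

    For each requested pair the gene's probe and one CpG annotated to it (in
    the requested promoter/non-promoter context) receive correlated noise with
    expected Pearson r ``r_linked`` of the configured sign; the CpG's group
    mean additionally shifts by ``delta_beta_linked`` with the sign that makes
    the group structure reinforce, not fight, the noise correlation.  Raises
    when more pairs are requested than DEGs are available.
    """
    rng = _rng(rng)
    requested = {k: int(v) for k, v in config.linked_pairs.items()}
    total = sum(requested.values())
    if total == 0:
        return expression, beta, pd.DataFrame(
            columns=["probe_id", "gene", "cpg_id", "sign", "promoter"]
        )
    if total > len(deg_truth):
        raise ValueError(f"{total} linked pairs requested but only {len(deg_truth)} DEGs")
    samples = expression.sample_ids
    in_target = np.array(
        [s in set(sheet.samples(config.target_group)) for s in samples]
    )
    unit_of = {
        (row["gene"], row["promoter"]): row["member_cpgs"] for _, row in units.iterrows()
    }
    expr_values = expression.values.copy()
    beta_values = beta.values.copy()
    rho = config.r_linked
    deg_iter = deg_truth.sample(frac=1.0, random_state=int(rng.integers(2**31)))
    deg_rows = list(deg_iter.itertuples())
    rows = []
    i = 0
    for cell, count in requested.items():
        sign_label, ctx_label = cell.split("_")
        s_target = 1 if sign_label == "positive" else -1
        promoter = ctx_label == "promoter"
        for _ in range(count):
            deg = deg_rows[i]
            i += 1
            members = unit_of[(deg.gene, promoter)]
            cpg = members[0]
            e_sign = deg.sign
            # coherent group shift on the beta side
            dir_b = s_target * e_sign
            shifted = np.clip(
                group_means.loc[cpg] + dir_b * config.delta_beta_linked, 0.05, 0.95
            )
            m_target = shifted[config.target_group]
            m_per_sample = np.where(
                in_target,
                m_target,
                group_means.loc[cpg, [sheet.group_of()[s] for s in samples]],
            )
            z = rng.normal(size=len(samples))
            eps_e = rng.normal(size=len(samples))
            eps_b = rng.normal(size=len(samples))
            par = probe_params.loc[deg.probe_id]
            expr_noise = np.sqrt(rho) * z + np.sqrt(1 - rho) * eps_e
            expr_values.loc[deg.probe_id] = (
                par["mu"] + par["effect"] * in_target + par["sigma"] * expr_noise
            )
            scale = _beta_noise_scale(m_per_sample, config.sigma_beta)
            beta_noise = s_target * np.sqrt(rho) * z + np.sqrt(1 - rho) * eps_b
            beta_values.loc[cpg] = expit(
                logit(np.clip(m_per_sample, 0.02, 0.98)) + scale * beta_noise
            )
            group_means.loc[cpg, config.target_group] = m_target
            rows.append(
                {
                    "probe_id": deg.probe_id,
                    "gene": deg.gene,
                    "cpg_id": cpg,
                    "sign": s_target,
                    "promoter": promoter,
                }
            )
    linked = pd.DataFrame(rows, columns=["probe_id", "gene", "cpg_id", "sign", "promoter"])
    return (
        ExpressionMatrix(values=expr_values, genes=expression.genes),
        BetaMatrix(values=beta_values),
        linked,
    )


def simulate_wgbs_counts(
    beta: BetaMatrix | pd.DataFrame,
    coverage_mean: float = 30.0,
    coverage_dispersion: float = 5.0,
    rng: np.random.Generator | int | None = None,
    loci: pd.DataFrame | None = None,
) -> CountMethylome:
    """Count methylome from latent fractions.

    Coverage per cell is negative binomial with the given mean and dispersion
    (``dispersion`` is the NB size parameter; variance = mean + mean^2/size);
    methylated reads are binomial given coverage.  Zero-coverage cells are
    missing by construction (total = 0).
    """
    rng = _rng(rng)
    values = beta.values if isinstance(beta, BetaMatrix) else beta
    p_nb = coverage_dispersion / (coverage_dispersion + coverage_mean)
    coverage = rng.negative_binomial(coverage_dispersion, p_nb, size=values.shape)
    meth = rng.binomial(coverage, np.clip(values.to_numpy(dtype=float), 0, 1))
    return CountMethylome(
        meth=pd.DataFrame(meth, index=values.index, columns=values.columns),
        total=pd.DataFrame(coverage, index=values.index, columns=values.columns),
        loci=loci,
    )


def simulate_paired_platforms(
    n_cpgs: int = 5000,
    samples: Sequence[str] = ("f-LSEC_d1", "f-LSEC_d2", "f-LSEC_d3", "a-LSEC_d1", "a-LSEC_d2"),
    array_sigma: float = 0.03,
    coverage_mean: float = 30.0,
    coverage_dispersion: float = 5.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[BetaMatrix, CountMethylome]:
    """Array betas and WGBS counts drawn from one shared latent methylome.

    Used for platform-concordance checks: the array observes the latent
    fraction plus Gaussian noise of SD ``array_sigma`` (clipped to [0, 1]);
    WGBS observes binomial counts at negative-binomial coverage.
    """
    rng = _rng(rng)
    cpgs = pd.Index([f"cg{i:07d}" for i in range(n_cpgs)], name="cpg_id")
    latent = rng.uniform(0.05, 0.95, size=(n_cpgs, len(samples)))
    array = np.clip(latent + rng.normal(0.0, array_sigma, size=latent.shape), 0.0, 1.0)
    beta_array = BetaMatrix(values=pd.DataFrame(array, index=cpgs, columns=list(samples)))
    latent_frame = pd.DataFrame(latent, index=cpgs, columns=list(samples))
    counts = simulate_wgbs_counts(
        latent_frame, coverage_mean, coverage_dispersion, rng=rng
    )
    return beta_array, counts


#: Panel regions whose markers separate f-LSECs from other fetal ECs (group A)
#: and adult LSECs from everything else (groups B and C).
FLSEC_MARKER_REGIONS: tuple[str, ...] = ("1:CDH5", "3:GSTO2", "5:RABGGTA", "6:ZC3H12D")
ALSEC_MARKER_REGIONS: tuple[str, ...] = (
    "7:HOXD3", "9:MAB21L1", "10:MIR503", "12:PCOLCE",
    "13:MGMT", "15:ASPSCR1", "16:CTSZ", "17:intergenic", "18:NACC2",
)


def simulate_fingerprints(
    config: SimulationConfig, rng: np.random.Generator | int | None = None
) -> pd.DataFrame:
    """Per-group methylation probabilities for every panel CpG.

    Endothelial groups share a common background.  f-LSEC shifts coherently
    (all CpGs of a region, one random direction per region) by
    ``fingerprint_shift`` at the f-LSEC marker regions; a-LSEC does the same
    at the adult marker regions, so the two LSEC stages are separated by more
    regions than f-LSEC is from the other fetal ECs.  Each of HCMEC, HPAEC
    and HPMEC carries its own per-CpG signature on a random
    ``fingerprint_frac`` subset of CpGs.  PBMC and iPS are independent
    non-endothelial methylomes; EPC perturbs PBMC by at most ``epc_shift``
    per CpG; mesoderm and vEC are convex mixtures of iPS with the 2:1
    fetal:adult endothelial pattern.  Region-coherent marker shifts make the
    mixture geometry (vEC nearer fetal than adult LSEC) hold at the
    region-mean level, not only per CpG.
    """
    rng = _rng(rng)
    index = pd.MultiIndex.from_tuples(
        [(r, i) for r, n in config.panel_regions.items() for i in range(n)],
        names=["region_id", "cpg_index"],
    )
    n = len(index)
    region_ids = index.get_level_values("region_id")
    marker = region_ids.isin(FLSEC_MARKER_REGIONS + ALSEC_MARKER_REGIONS)
    base = np.where(
        marker, rng.uniform(0.35, 0.65, size=n), rng.uniform(0.25, 0.75, size=n)
    )

    def region_shift(regions: tuple[str, ...]) -> np.ndarray:
        shift = np.zeros(n)
        for r in regions:
            mask = region_ids == r
            shift[mask] = rng.choice([-1.0, 1.0]) * config.fingerprint_shift
        return shift

    fp = {}
    fp["f-LSEC"] = np.clip(base + region_shift(FLSEC_MARKER_REGIONS), 0.05, 0.95)
    fp["a-LSEC"] = np.clip(base + region_shift(ALSEC_MARKER_REGIONS), 0.05, 0.95)
    for group in ("HCMEC", "HPAEC", "HPMEC"):
        mask = rng.random(n) < config.fingerprint_frac
        signs = rng.choice([-1.0, 1.0], size=n)
        fp[group] = np.clip(base + mask * signs * config.fingerprint_shift, 0.05, 0.95)
    if config.fingerprint_shift > 0:
        fp["PBMC"] = rng.uniform(0.1, 0.9, size=n)
        fp["iPS"] = rng.uniform(0.1, 0.9, size=n)
    else:  # a flat panel stays flat everywhere (null configurations)
        fp["PBMC"] = base.copy()
        fp["iPS"] = base.copy()
    fp["EPC"] = np.clip(
        fp["PBMC"] + rng.uniform(-config.epc_shift, config.epc_shift, size=n), 0.05, 0.95
    )
    endo = 0.67 * fp["f-LSEC"] + 0.33 * fp["a-LSEC"]
    fp["mesoderm"] = config.lambda_mesoderm * fp["iPS"] + (1 - config.lambda_mesoderm) * endo
    fp["vEC"] = config.lambda_vec * fp["iPS"] + (1 - config.lambda_vec) * endo
    order = [g for g in (*ARRAY_GROUPS, *TRAJECTORY_GROUPS)]
    return pd.DataFrame({g: fp[g] for g in order}, index=index)


def simulate_panel_reads(
    config: SimulationConfig,
    fingerprints: pd.DataFrame,
    sheet: SampleSheet,
    rng: np.random.Generator | int | None = None,
) -> ReadPanel:
    """Read-level panel calls: independent Bernoulli draws per CpG per read.

    Each sample perturbs its group fingerprint by a small logit-space donor
    effect (SD ~ ``donor_jitter`` on the beta scale), then emits
    ``reads_per_region`` reads per region with ``missing_call_rate`` of calls
    dropped to NA.
    """
    rng = _rng(rng)
    group_of = sheet.group_of()
    rows = []
    region_slices = {
        r: fingerprints.index.get_locs([r]) for r in config.panel_regions
    }
    for sample in sheet.sample_ids:
        group = group_of[sample]
        if group not in fingerprints.columns:
            continue
        p = fingerprints[group].to_numpy(dtype=float)
        if config.donor_jitter > 0:
            scale = _beta_noise_scale(p, config.donor_jitter)
            p = expit(logit(np.clip(p, 0.02, 0.98)) + rng.normal(0, 1, p.shape) * scale)
        for region in config.panel_regions:
            pr = p[region_slices[region]]
            calls = (
                rng.random((config.reads_per_region, pr.size)) < pr[None, :]
            ).astype(float)
            if config.missing_call_rate > 0:
                drop = rng.random(calls.shape) < config.missing_call_rate
                calls[drop] = np.nan
            for j in range(config.reads_per_region):
                rows.append(
                    {
                        "region_id": region,
                        "sample_id": sample,
                        "read_id": f"r{j}",
                        "calls": calls[j],
                    }
                )
    reads = pd.DataFrame(rows, columns=["region_id", "sample_id", "read_id", "calls"])
    return ReadPanel(region_ncpgs=dict(config.panel_regions), reads=reads)


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------


def simulate_study(config: SimulationConfig | None = None) -> StudyData:
    """Generate a full study: sheet, matrices, counts, panel and ground truth.

    Deterministic for a fixed config (the seed drives spawned generators for
    each stage, so changing e.g. the panel settings does not perturb the
    expression draws).
    """
    config = config or SimulationConfig()
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(6)
    r_expr, r_meth, r_link, r_wgbs, r_fp, r_panel = map(np.random.default_rng, streams)

    sheet = make_sample_sheet(config.group_sizes)
    annotation, units = make_annotation(config)
    expression, deg_truth, probe_params = simulate_expression(config, sheet, r_expr)
    beta, dmr_truth, group_means = simulate_methylation(
        config, sheet, annotation, units, deg_truth, r_meth
    )
    expression, beta, linked_truth = simulate_linked_pairs(
        config, sheet, units, expression, probe_params, beta, group_means, deg_truth, r_link
    ) if config.total_linked() else (expression, beta, pd.DataFrame(
        columns=["probe_id", "gene", "cpg_id", "sign", "promoter"]
    ))

    wgbs_samples = [
        s for g in sheet.groups if g in WGBS_GROUPS for s in sheet.samples(g)
    ]
    counts = simulate_wgbs_counts(
        beta.values[wgbs_samples] if wgbs_samples else beta.values.iloc[:, :0],
        config.coverage_mean,
        config.coverage_dispersion,
        rng=r_wgbs,
        loci=annotation.table[["chrom", "pos"]],
    )
    fingerprints = simulate_fingerprints(config, r_fp)
    panel = simulate_panel_reads(config, fingerprints, sheet, r_panel)

    dmc_rows = [
        {"cpg_id": c, "direction": row["direction"], "delta": row["delta"], "source": "dmr"}
        for _, row in dmr_truth.iterrows()
        for c in row["member_cpgs"]
    ]
    for _, row in linked_truth.iterrows():
        dmc_rows.append(
            {
                "cpg_id": row["cpg_id"],
                "direction": 0,
                "delta": config.delta_beta_linked,
                "source": "linked",
            }
        )
    dmc_truth = pd.DataFrame(dmc_rows, columns=["cpg_id", "direction", "delta", "source"])
    truth = GroundTruth(
        deg=deg_truth, dmr=dmr_truth, dmc=dmc_truth, linked=linked_truth,
        fingerprints=fingerprints,
    )
    return StudyData(
        config=config,
        sheet=sheet,
        annotation=annotation,
        expression=expression,
        beta=beta,
        counts=counts,
        panel=panel,
        truth=truth,
    )


def write_study(study: StudyData, outdir: str | Path) -> None:
    """Write every artefact of a study as deterministic TSVs plus truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_sample_sheet(study.sheet, outdir / "samples.tsv")
    write_expression_table(study.expression, outdir / "expression.tsv")
    write_beta_table(study.beta, outdir / "beta.tsv")
    write_cpg_manifest(study.annotation, outdir / "manifest.bed.tsv")
    write_counts_table(study.counts, outdir / "counts.tsv")
    write_panel_reads(study.panel, outdir / "panel_reads.tsv")
    truth = {
        "deg": study.truth.deg.to_dict(orient="records"),
        "dmr": study.truth.dmr.to_dict(orient="records"),
        "dmc": study.truth.dmc.to_dict(orient="records"),
        "linked": study.truth.linked.to_dict(orient="records"),
        "fingerprints": {
            group: [round(float(v), 10) for v in study.truth.fingerprints[group]]
            for group in study.truth.fingerprints.columns
        },
        "config": {
            k: (dict(v) if isinstance(v, Mapping) else v)
            for k, v in dataclasses.asdict(study.config).items()
        },
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
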