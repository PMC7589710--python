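"""Domain types, TSV readers/writers and design validation shared by all stages.

The pipeline works on five kinds of input, all plain tab-separated text:

* an expression matrix (probe x sample, log2-scale intensities, with a
  probe -> gene symbol mapping),
* a beta-value matrix (CpG x sample methylation fractions in [0, 1]),
* a BED-like CpG manifest (chromosome, 0-based position, CpG id, gene,
  gene-region class such as ``TSS200`` or ``Body``),
* a per-CpG count methylome (methylated / total read counts per sample,
  as produced by whole-genome bisulfite sequencing),
* read-level calls from a targeted bisulfite panel (one row per sequenced
  molecule, with a comma-joined 0/1/NA call vector over the region's CpGs),

together with a sample sheet mapping samples to biological groups and donors.
All containers are thin dataclasses around :class:`pandas.DataFrame` objects
whose invariants are checked at construction time.

Coordinates are 0-based, half-open.  Missing values are empty cells in TSV
files and ``NaN`` in memory; they are excluded pairwise from downstream tests
and correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("methylmark")

#: Gene-region vocabulary used by Illumina-style CpG annotations.
REGION_CLASSES: tuple[str, ...] = (
    "TSS1500",
    "TSS200",
    "5UTR",
    "1stExon",
    "Body",
    "3UTR",
    "Intergenic",
)

#: Region classes counted as promoter context (TSS1500, TSS200, 5'UTR, first exon).
PROMOTER_CLASSES: frozenset[str] = frozenset({"TSS1500", "TSS200", "5UTR", "1stExon"})

#: Numeric format used by every writer; round-trips float64 exactly enough for
#: byte-identical re-writes at this precision.
FLOAT_FMT = "%.10g"

#: Column contract of differential tables (DiffTable): the feature id is the
#: index; ``stat`` is a t or F value, ``p`` the two-sided p-value, ``q`` the
#: Benjamini-Hochberg adjusted p, ``mean_diff`` the group-mean difference on
#: the native scale (log2 for expression, beta for methylation) and
#: ``direction`` its sign.
DIFF_COLUMNS = ("stat", "p", "q", "mean_diff", "direction")


class DesignError(ValueError):
    """Raised when inputs violate a documented invariant or design contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleSheet:
    """Sample -> (group, donor) mapping.

    ``table`` has columns ``sample_id``, ``group``, ``donor_id``; sample ids
    must be unique and every group must have at least one sample.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "donor_id"}
        missing = required - set(self.table.columns)
        if missing:
            raise DesignError(f"sample sheet missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            dups = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise DesignError(f"duplicate sample_id: {sorted(set(dups))}")
        if (self.table["group"].astype(str) == "").any():
            raise DesignError("empty group label in sample sheet")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def groups(self) -> list[str]:
        """Group labels in order of first appearance."""
        return list(dict.fromkeys(self.table["group"]))

    def samples(self, group: str | Iterable[str]) -> list[str]:
        """Samples belonging to ``group`` (a label or an iterable of labels)."""
        wanted = {group} if isinstance(group, str) else set(group)
        unknown = wanted - set(self.table["group"])
        if unknown:
            raise DesignError(f"unknown group(s): {sorted(unknown)}")
        mask = self.table["group"].isin(wanted)
        return list(self.table.loc[mask, "sample_id"])

    def group_of(self) -> pd.Series:
        """Series mapping sample_id -> group."""
        return self.table.set_index("sample_id")["group"]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Probe x sample matrix of log2-scale intensities with a gene mapping."""

    values: pd.DataFrame  # index probe_id, columns sample ids
    genes: pd.Series  # probe_id -> gene symbol

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()]
            raise DesignError(f"duplicate probe id(s): {sorted(set(dups))}")
        if not self.genes.index.equals(self.values.index):
            raise DesignError("gene mapping index does not match probe ids")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise DesignError("expression values must all be finite")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class CpGAnnotation:
    """CpG manifest keyed by cpg_id.

    ``table`` is indexed by ``cpg_id`` with columns ``chrom``, ``pos`` (0-based),
    ``gene`` (empty string for intergenic CpGs), ``region_class`` (from
    :data:`REGION_CLASSES`) and the derived boolean ``promoter``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise DesignError("duplicate cpg_id in manifest")
        bad = set(self.table["region_class"]) - set(REGION_CLASSES)
        if bad:
            raise DesignError(
                f"unknown region_class {sorted(bad)}; allowed: {list(REGION_CLASSES)}"
            )
        if "promoter" not in self.table.columns:
            object.__setattr__(
                self,
                "table",
                self.table.assign(
                    promoter=self.table["region_class"].isin(PROMOTER_CLASSES)
                ),
            )

    @property
    def cpg_ids(self) -> pd.Index:
        return self.table.index

    def cpgs_of_gene(self, gene: str) -> pd.Index:
        return self.table.index[self.table["gene"] == gene]


@dataclass(frozen=True)
class BetaMatrix:
    """CpG x sample matrix of methylation fractions in [0, 1] (NaN = missing)."""

    values: pd.DataFrame  # index cpg_id, columns sample ids

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise DesignError("duplicate cpg_id in beta matrix")
        arr = self.values.to_numpy(dtype=float)
        finite = arr[np.isfinite(arr)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise DesignError("beta values must lie in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class CountMethylome:
    """Per-CpG methylated / total read counts per sample (WGBS-style).

    ``meth`` and ``total`` are CpG x sample integer matrices; ``loci`` carries
    ``chrom`` and ``pos`` per CpG (needed for window-based DMR detection) and
    may be ``None`` when only per-CpG tests are required.
    """

    meth: pd.DataFrame
    total: pd.DataFrame
    loci: pd.DataFrame | None = None  # index cpg_id, columns chrom, pos

    def __post_init__(self) -> None:
        if not self.meth.index.equals(self.total.index) or not self.meth.columns.equals(
            self.total.columns
        ):
            raise DesignError("meth and total matrices must be aligned")
        m = self.meth.to_numpy(dtype=float)
        t = self.total.to_numpy(dtype=float)
        if np.nanmin(t.min(initial=0.0), initial=0.0) < 0 or (m < 0).any():
            raise DesignError("counts must be non-negative")
        if (m > t).any():
            raise DesignError("meth_reads exceeds total_reads")
        if self.loci is not None and not self.loci.index.equals(self.meth.index):
            raise DesignError("loci index does not match count matrices")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.meth.columns)

    def fractions(self, min_cov: int = 1) -> pd.DataFrame:
        """Methylated fraction per CpG/sample; cells with coverage < min_cov are NaN."""
        t = self.total.to_numpy(dtype=float)
        m = self.meth.to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(t >= max(min_cov, 1), m / t, np.nan)
        return pd.DataFrame(frac, index=self.meth.index, columns=self.meth.columns)


@dataclass(frozen=True)
class ReadPanel:
    """Read-level calls from a targeted bisulfite panel.

    ``region_ncpgs`` fixes the number of CpGs per region; ``reads`` has one row
    per sequenced molecule with columns ``region_id``, ``sample_id``,
    ``read_id`` and ``calls`` (a float array of 0/1/NaN of the region's length).
    """

    region_ncpgs: Mapping[str, int]
    reads: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"region_id", "sample_id", "read_id", "calls"}
        missing = required - set(self.reads.columns)
        if missing:
            raise DesignError(f"read table missing columns: {sorted(missing)}")
        for region, sub in self.reads.groupby("region_id", sort=False):
            if region not in self.region_ncpgs:
                raise DesignError(f"read for unknown region {region!r}")
            n = self.region_ncpgs[region]
            lengths = {len(c) for c in sub["calls"]}
            if lengths - {n}:
                raise DesignError(
                    f"region {region!r}: call vectors of length {sorted(lengths)}, "
                    f"expected {n}"
                )

    @property
    def region_ids(self) -> list[str]:
        return list(self.region_ncpgs)

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.reads["sample_id"]))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read ``samples.tsv`` (sample_id, group, donor_id)."""
    table = _read_tsv(path, dtype=str)
    return SampleSheet(table=table.reset_index(drop=True))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


def read_expression_table(
    path: str | Path, sheet: SampleSheet | None = None
) -> ExpressionMatrix:
    """Read ``expression.tsv``: probe_id, gene, then one numeric column per sample.

    Sample column order is preserved.  Duplicate probe rows and non-numeric
    cells are rejected; when ``sheet`` is given, sample columns not present in
    the sheet raise an error naming the offending column.
    """
    raw = _read_tsv(path, dtype={"probe_id": str, "gene": str})
    if raw.columns[0] != "probe_id" or raw.columns[1] != "gene":
        raise DesignError("expression table must start with probe_id and gene columns")
    if raw["probe_id"].duplicated().any():
        dups = raw.loc[raw["probe_id"].duplicated(), "probe_id"]
        raise DesignError(f"duplicate probe row(s): {sorted(set(dups))}")
    sample_cols = list(raw.columns[2:])
    if sheet is not None:
        unknown = [s for s in sample_cols if s not in set(sheet.sample_ids)]
        if unknown:
            raise DesignError(f"sample column(s) not in sample sheet: {unknown}")
    values = raw[sample_cols].apply(pd.to_numeric, errors="raise")
    values.index = pd.Index(raw["probe_id"], name="probe_id")
    genes = pd.Series(raw["gene"].fillna("").to_numpy(), index=values.index, name="gene")
    return ExpressionMatrix(values=values, genes=genes)


def write_expression_table(expr: ExpressionMatrix, path: str | Path) -> None:
    out = expr.values.copy()
    out.insert(0, "gene", expr.genes)
    out.insert(0, "probe_id", expr.values.index)
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_cpg_manifest(path: str | Path) -> CpGAnnotation:
    """Read a BED-like, headerless manifest: chrom, pos, cpg_id, gene, region_class.

    Positions are 0-based.  Unknown region classes raise an error listing the
    allowed vocabulary; the promoter flag is derived from the region class.
    """
    table = _read_tsv(
        path,
        header=None,
        names=["chrom", "pos", "cpg_id", "gene", "region_class"],
        dtype={"chrom": str, "cpg_id": str, "gene": str, "region_class": str},
    )
    table["gene"] = table["gene"].fillna("")
    table["pos"] = table["pos"].astype(int)
    table = table.set_index("cpg_id")
    return CpGAnnotation(table=table[["chrom", "pos", "gene", "region_class"]])


def write_cpg_manifest(annotation: CpGAnnotation, path: str | Path) -> None:
    out = annotation.table.reset_index()[
        ["chrom", "pos", "cpg_id", "gene", "region_class"]
    ]
    out.to_csv(path, sep="\t", index=False, header=False)


def read_beta_table(path: str | Path, sheet: SampleSheet | None = None) -> BetaMatrix:
    """Read ``beta.tsv``: cpg_id then one numeric column per sample; values in [0, 1]."""
    raw = _read_tsv(path, dtype={"cpg_id": str})
    if raw.columns[0] != "cpg_id":
        raise DesignError("beta table must start with a cpg_id column")
    sample_cols = list(raw.columns[1:])
    if sheet is not None:
        unknown = [s for s in sample_cols if s not in set(sheet.sample_ids)]
        if unknown:
            raise DesignError(f"sample column(s) not in sample sheet: {unknown}")
    values = raw[sample_cols].apply(pd.to_numeric, errors="raise")
    values.index = pd.Index(raw["cpg_id"], name="cpg_id")
    return BetaMatrix(values=values)


def write_beta_table(beta: BetaMatrix, path: str | Path) -> None:
    out = beta.values.copy()
    out.insert(0, "cpg_id", beta.values.index)
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_counts_table(
    path: str | Path, annotation: CpGAnnotation | None = None
) -> CountMethylome:
    """Read long-format ``counts.tsv``: cpg_id, sample, meth_reads, total_reads.

    Genomic positions are attached from ``annotation`` when provided (they are
    required for window-based DMR detection but not for per-CpG tests).
    """
    raw = _read_tsv(path, dtype={"cpg_id": str, "sample": str})
    meth = raw.pivot(index="cpg_id", columns="sample", values="meth_reads")
    total = raw.pivot(index="cpg_id", columns="sample", values="total_reads")
    order = pd.Index(dict.fromkeys(raw["cpg_id"]), name="cpg_id")
    sample_order = list(dict.fromkeys(raw["sample"]))
    meth = meth.reindex(index=order, columns=sample_order).fillna(0).astype(int)
    total = total.reindex(index=order, columns=sample_order).fillna(0).astype(int)
    meth.columns.name = None
    total.columns.name = None
    loci = None
    if annotation is not None:
        loci = annotation.table.loc[order, ["chrom", "pos"]]
    return CountMethylome(meth=meth, total=total, loci=loci)


def write_counts_table(counts: CountMethylome, path: str | Path) -> None:
    long = (
        counts.meth.stack()
        .rename("meth_reads")
        .to_frame()
        .join(counts.total.stack().rename("total_reads"))
        .reset_index()
    )
    long.columns = ["cpg_id", "sample", "meth_reads", "total_reads"]
    long.to_csv(path, sep="\t", index=False)


def _parse_calls(text: str) -> np.ndarray:
    out = []
    for token in str(text).split(","):
        token = token.strip()
        out.append(np.nan if token in {"NA", "", "nan"} else float(int(token)))
    return np.asarray(out, dtype=float)


def _format_calls(calls: np.ndarray) -> str:
    return ",".join("NA" if np.isnan(c) else str(int(c)) for c in calls)


def read_panel_reads(
    path: str | Path, region_ncpgs: Mapping[str, int] | None = None
) -> ReadPanel:
    """Read ``panel_reads.tsv``: region_id, sample, read_id, calls (comma 0/1/NA).

    When ``region_ncpgs`` is not given, each region's CpG count is inferred
    from its first read; all reads of a region must agree on length.
    """
    raw = _read_tsv(path, dtype={"region_id": str, "sample": str, "read_id": str})
    raw = raw.rename(columns={"sample": "sample_id"})
    raw["calls"] = [_parse_calls(c) for c in raw["calls"]]
    if region_ncpgs is None:
        region_ncpgs = {
            region: len(sub["calls"].iloc[0])
            for region, sub in raw.groupby("region_id", sort=False)
        }
    return ReadPanel(region_ncpgs=dict(region_ncpgs), reads=raw)


def write_panel_reads(panel: ReadPanel, path: str | Path) -> None:
    out = panel.reads.copy()
    out["calls"] = [_format_calls(c) for c in out["calls"]]
    out = out.rename(columns={"sample_id": "sample"})
    out[["region_id", "sample", "read_id", "calls"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Design validation
# ---------------------------------------------------------------------------


def validate_design(
    sheet: SampleSheet, matrix: ExpressionMatrix | BetaMatrix | pd.DataFrame
) -> list[str]:
    """Return the sample ordering shared by ``sheet`` and ``matrix``.

    The intersection keeps the matrix's column order and is what every
    downstream contrast iterates over; sheet samples without a matrix column
    are logged and dropped.  An empty intersection is an error.
    """
    columns = list(matrix.columns) if isinstance(matrix, pd.DataFrame) else matrix.sample_ids
    in_sheet = set(sheet.sample_ids)
    shared = [s for s in columns if s in in_sheet]
    if not shared:
        raise DesignError("no samples shared between sample sheet and matrix")
    dropped = sorted(in_sheet - set(shared))
    if dropped:
        logger.warning("samples in sheet without data columns: %s", dropped)
    return shared


def require_group_sizes(
    sheet: SampleSheet, groups: Sequence[str | Sequence[str]], minimum: int = 2
) -> None:
    """Raise unless every group (or pooled group list) has >= ``minimum`` samples."""
    for g in groups:
        n = len(sheet.samples(g))
        if n < minimum:
            raise DesignError(f"group {g!r} has {n} samples; need >= {minimum}")
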