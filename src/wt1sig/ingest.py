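"""Expression-matrix and clinical-table I/O, validation and sample alignment.

The pipeline consumes a normalized, log-scale expression matrix
(probes x samples, GCT 1.2 or plain TSV) and a delimited clinical table
with survival endpoints (OS/EFS/RFS time + event flag, times in months)
plus arbitrary binary/categorical covariates. Everything downstream works
on the validated containers defined here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("wt1sig")

#: survival endpoints recognised in clinical tables, as (time, event) column pairs
ENDPOINTS = {
    "os": ("os_time", "os_event"),
    "efs": ("efs_time", "efs_event"),
    "rfs": ("rfs_time", "rfs_event"),
}


class ValidationError(ValueError):
    """Input violates a documented contract (bad value, duplicate ID, ...)."""


class FormatError(ValueError):
    """File does not conform to the declared format."""


@dataclass
class ExpressionMatrix:
    """Log-scale expression values, probes x samples.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by probe ID, columns by sample ID.  Values are
        log2-scale intensities or log-transformed normalized counts.
    platform_tag : str
        Free-form platform annotation (e.g. ``"HG-U133_Plus_2"``).
    """

    values: pd.DataFrame
    platform_tag: str = ""

    def __post_init__(self) -> None:
        idx, cols = self.values.index, self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe IDs: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.isfinite(arr).all():
            n_bad = int((~np.isfinite(arr)).sum())
            raise ValidationError(
                f"{n_bad} non-finite expression cells; impute or clean before loading "
                "(load_expression(impute_median=True) imputes per-probe medians)"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def probe(self, probe_id: str) -> np.ndarray:
        if probe_id not in self.values.index:
            raise ValidationError(f"probe {probe_id!r} not in matrix")
        return self.values.loc[probe_id].to_numpy(float)

    def subset_probes(self, probe_ids) -> "ExpressionMatrix":
        present = [p for p in probe_ids if p in self.values.index]
        return ExpressionMatrix(self.values.loc[present], self.platform_tag)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)], self.platform_tag)


@dataclass
class ClinicalTable:
    """Per-sample survival endpoints and covariates.

    ``data`` is indexed by sample ID; endpoint columns follow the
    ``{os,efs,rfs}_{time,event}`` convention (months / 0-1 flags); every
    other column is treated as a covariate.
    """

    data: pd.DataFrame
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups[:5]}")
        found = False
        for name, (tcol, ecol) in ENDPOINTS.items():
            if tcol in df.columns and ecol in df.columns:
                found = True
                t = pd.to_numeric(df[tcol], errors="coerce")
                bad = df.index[(t < 0) | t.isna()]
                if len(bad):
                    raise ValidationError(
                        f"{tcol}: negative or non-numeric time for sample(s) {list(bad[:5])}"
                    )
                e = df[ecol]
                bad = df.index[~e.isin([0, 1])]
                if len(bad):
                    raise ValidationError(
                        f"{ecol}: event flag outside {{0,1}} for sample(s) {list(bad[:5])}"
                    )
            elif (tcol in df.columns) != (ecol in df.columns):
                raise ValidationError(f"endpoint {name}: need both {tcol} and {ecol}")
        if not found:
            raise ValidationError("no complete survival endpoint (time+event) found")
        if "ELN" in df.columns:
            levels = set(pd.unique(df["ELN"].dropna()))
            if not levels <= {1, 2, 3, 4}:
                raise ValidationError(f"ELN levels must be in {{1,2,3,4}}, got {levels}")
        endpoint_cols = {c for pair in ENDPOINTS.values() for c in pair}
        if not self.covariates:
            self.covariates = [c for c in df.columns if c not in endpoint_cols]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def endpoint(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (time, event) arrays for endpoint ``name`` in {os, efs, rfs}."""
        tcol, ecol = ENDPOINTS[name]
        if tcol not in self.data.columns:
            raise ValidationError(f"endpoint {name!r} not present")
        return (
            self.data[tcol].to_numpy(float),
            self.data[ecol].to_numpy(int),
        )

    def has_endpoint(self, name: str) -> bool:
        tcol, ecol = ENDPOINTS[name]
        return tcol in self.data.columns and ecol in self.data.columns


# ---------------------------------------------------------------------------
# readers / writers


def load_expression(
    path,
    format: str = "tsv",
    platform_tag: str = "",
    log2: bool = False,
    impute_median: bool = False,
) -> ExpressionMatrix:
    """Read an expression matrix from GCT 1.2 or plain TSV.

    TSV layout: first column = probe IDs, header row = sample IDs.
    GCT 1.2 layout: ``#1.2`` line, ``<n_rows>\\t<n_cols>`` line, then a table
    with ``Name`` and ``Description`` columns before the samples.

    ``log2`` applies log2(x+1) for raw RSEM-like input; inputs are otherwise
    assumed to be on a log scale already.  Missing cells are rejected unless
    ``impute_median`` is set, in which case per-probe medians are substituted.
    """
    if format == "gct":
        df = _read_gct(path)
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    else:
        raise ValueError(f"unknown format {format!r}")
    for j, col in enumerate(df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        fresh_na = coerced.isna() & df[col].notna()
        if fresh_na.any():
            i = int(np.argmax(fresh_na.to_numpy()))
            raise FormatError(
                f"non-numeric cell at probe {df.index[i]!r}, sample {col!r}"
            )
        df[col] = coerced
    if impute_median and df.isna().to_numpy().any():
        med = df.median(axis=1)
        df = df.apply(lambda row: row.fillna(med[row.name]), axis=1)
        logger.warning("imputed missing expression cells with per-probe medians")
    if log2:
        df = np.log2(df + 1.0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, platform_tag)


def _read_gct(path) -> pd.DataFrame:
    with open(path, newline="") as fh:
        version = fh.readline().strip()
        if version not in ("#1.2",):
            raise FormatError(f"not a GCT 1.2 file (first line {version!r})")
        dims = fh.readline().strip().split("\t")
        if len(dims) < 2:
            raise FormatError("GCT dimensions line malformed")
        try:
            n_rows, n_cols = int(dims[0]), int(dims[1])
        except ValueError as exc:
            raise FormatError("GCT dimensions line malformed") from exc
        df = pd.read_csv(fh, sep="\t", index_col=0)
    if "Description" not in df.columns:
        raise FormatError("GCT table missing Description column")
    df = df.drop(columns=["Description"])
    if df.shape != (n_rows, n_cols):
        raise FormatError(
            f"GCT declares {n_rows}x{n_cols} but table has "
            f"{df.shape[0]} rows x {df.shape[1]} samples"
        )
    return df


def write_expression(expr: ExpressionMatrix, path, format: str = "tsv") -> None:
    """Write a matrix back out in ``tsv`` or ``gct`` (1.2) layout."""
    if format == "tsv":
        expr.values.to_csv(path, sep="\t", index_label="probe_id")
    elif format == "gct":
        out = expr.values.copy()
        out.insert(0, "Description", "na")
        with open(path, "w", newline="") as fh:
            fh.write("#1.2\n")
            fh.write(f"{out.shape[0]}\t{out.shape[1] - 1}\n")
            out.to_csv(fh, sep="\t", index_label="Name", lineterminator="\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def load_clinical(path, sep: str | None = None) -> ClinicalTable:
    """Read a clinical CSV/TSV keyed by a ``sample_id`` column.

    Columns beyond the recognised endpoint pairs are preserved as covariates.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if "sample_id" not in df.columns:
        raise FormatError("clinical table needs a sample_id column")
    df["sample_id"] = df["sample_id"].astype(str)
    df = df.set_index("sample_id")
    return ClinicalTable(df)


def write_clinical(clin: ClinicalTable, path) -> None:
    clin.data.to_csv(path, index_label="sample_id")


def align(
    expr: ExpressionMatrix, clin: ClinicalTable
) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Restrict both inputs to the shared samples, ordered as in the clinical table.

    Survival code iterates clinically, so the clinical ordering wins. Raises
    on an empty intersection; logs how many samples each side dropped.
    """
    expr_ids = set(expr.sample_ids)
    common = [s for s in clin.sample_ids if s in expr_ids]
    if not common:
        raise ValidationError("expression and clinical tables share no samples")
    dropped_expr = len(expr.sample_ids) - len(common)
    dropped_clin = len(clin.sample_ids) - len(common)
    if dropped_expr or dropped_clin:
        logger.info(
            "align: dropped %d expression-only and %d clinical-only samples",
            dropped_expr,
            dropped_clin,
        )
    return (
        ExpressionMatrix(expr.values[common], expr.platform_tag),
        ClinicalTable(clin.data.loc[common], list(clin.covariates)),
    )
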