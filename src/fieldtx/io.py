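"""Expression-matrix containers, I/O, normalization and filtering.

The study design this package models is a single-color oligo-array
experiment: a probe x sample matrix of non-negative raw signal
intensities together with a sample-metadata table (organ/tissue,
developmental stage in days after transplanting, time of day,
replicate, fertility genotype).  Two inter-array normalizations are
supported:

``percentile75``
    Each sample is divided by its own 75th-percentile signal and
    log2-transformed, so the array's upper-quartile probe maps to 0.
``quantile``
    Classic rank-mean quantile normalization (all samples share one
    value distribution), then log2.

Relative expression values are per-gene median-centered log2 values
over a chosen reference sample set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RawMatrix",
    "ExpressionMatrix",
    "RelativeMatrix",
    "SampleMetadata",
    "ExpressedResult",
    "read_expression_table",
    "read_table",
    "write_expression_table",
    "write_series_matrix",
    "percentile_normalize",
    "quantile_normalize",
    "relative_expression",
    "filter_by_raw_intensity",
    "expressed_flags",
    "average_replicates",
]

#: floor applied to raw intensities before any log2 to avoid log(0);
#: affects only non-signal probes (typical signal is >> 1).
RAW_FLOOR = 0.1


def _check_axes(values: pd.DataFrame) -> None:
    for axis, name in ((values.index, "probe"), (values.columns, "sample")):
        if axis.has_duplicates:
            dup = axis[axis.duplicated()].unique().tolist()
            raise ValueError(f"duplicate {name} identifier(s): {dup}")


@dataclass(frozen=True)
class RawMatrix:
    """Probe x sample matrix of non-negative raw signal intensities."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_axes(self.values)
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise TypeError("raw matrix must be numeric")
        if np.isnan(arr).any():
            raise ValueError("raw matrix contains missing values")
        if (arr < 0).any():
            raise ValueError("raw matrix contains negative intensities")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class ExpressionMatrix:
    """Probe x sample matrix of log2-scale normalized intensities."""

    values: pd.DataFrame
    method: str  # "percentile75" | "quantile"

    def __post_init__(self) -> None:
        if self.method not in ("percentile75", "quantile"):
            raise ValueError(f"unknown normalization method: {self.method!r}")
        _check_axes(self.values)

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass(frozen=True)
class RelativeMatrix:
    """Log2 values after per-gene median subtraction over a reference set."""

    values: pd.DataFrame
    reference_samples: tuple[str, ...]

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


#: metadata fields that must agree across replicates of one condition
_CONDITION_FIELDS = ("organ", "dat", "time_of_day", "genotype", "stage")


@dataclass
class SampleMetadata:
    """Per-sample annotation table.

    Required columns: ``sample_id``, ``condition_id``, ``organ``,
    ``replicate``.  Optional: ``dat`` (days after transplanting),
    ``time_of_day`` ("12:00"/"24:00"), ``genotype``
    ("fertile"/"sterile"), ``stage``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "condition_id", "organ", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"metadata missing column(s): {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample_id(s): {dup.tolist()}")
        # replicates of one condition share every non-replicate field
        present = [c for c in _CONDITION_FIELDS if c in self.table.columns]
        if present:
            nun = self.table.groupby("condition_id")[present].nunique(dropna=False)
            bad = nun[(nun > 1).any(axis=1)]
            if len(bad):
                raise ValueError(
                    "replicates disagree on condition-level fields for "
                    f"condition(s): {bad.index.tolist()}"
                )
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.table["sample_id"])

    @property
    def condition_order(self) -> list[str]:
        """Condition ids in order of first appearance (design order)."""
        return list(dict.fromkeys(self.table["condition_id"]))

    def samples_of_condition(self, condition_id: str) -> list[str]:
        sel = self.table["condition_id"] == condition_id
        return self.table.loc[sel, "sample_id"].tolist()

    def select(self, **criteria) -> list[str]:
        """Sample ids matching all column=value criteria."""
        mask = pd.Series(True, index=self.table.index)
        for col, value in criteria.items():
            if col not in self.table.columns:
                raise KeyError(f"metadata has no column {col!r}")
            mask &= self.table[col] == value
        return self.table.loc[mask, "sample_id"].tolist()

    def check_matrix(self, values: pd.DataFrame) -> None:
        unknown = [s for s in values.columns if s not in set(self.sample_ids)]
        if unknown:
            raise ValueError(f"matrix sample(s) missing from metadata: {unknown}")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleMetadata":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reading / writing


def _parse_table_lines(
    lines: list[str], first_line_number: int
) -> tuple[list[str], list[str], list[list[str]]]:
    """Split tab-delimited lines into header + rows, checking raggedness."""
    header = lines[0].rstrip("\n").split("\t")
    width = len(header)
    ids: list[str] = []
    rows: list[list[str]] = []
    for offset, line in enumerate(lines[1:], start=1):
        fields = line.rstrip("\n").split("\t")
        if len(fields) != width:
            raise ValueError(
                f"ragged row at line {first_line_number + offset}: "
                f"expected {width} fields, found {len(fields)}"
            )
        ids.append(fields[0])
        rows.append(fields[1:])
    return header[1:], ids, rows


def read_expression_table(
    path: str | Path, orientation: str = "probes_by_samples"
) -> RawMatrix:
    """Read a raw intensity matrix from plain TSV or GEO Series-Matrix text.

    Plain TSV: header row of sample ids, first column probe ids.  The
    Series-Matrix dialect (leading ``!`` metadata lines, data table
    bracketed by ``!series_matrix_table_begin`` / ``..._end``) is
    detected automatically.  ``orientation="samples_by_probes"``
    transposes after parsing.
    """
    return RawMatrix(read_table(path, orientation))


def read_table(
    path: str | Path, orientation: str = "probes_by_samples"
) -> pd.DataFrame:
    """Like :func:`read_expression_table` but returns a plain numeric
    frame without the non-negativity constraint (log2 matrices)."""
    path = Path(path)
    raw_lines = path.read_text().splitlines(keepends=True)
    lines = [ln for ln in raw_lines if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")

    if lines[0].startswith("!") or lines[0].startswith("^"):
        try:
            begin = next(
                i for i, ln in enumerate(lines)
                if ln.startswith("!series_matrix_table_begin")
            )
            end = next(
                i for i, ln in enumerate(lines)
                if ln.startswith("!series_matrix_table_end")
            )
        except StopIteration:
            raise ValueError(f"{path}: series-matrix table markers not found")
        table_lines = lines[begin + 1 : end]
        table_lines = [ln.replace('"', "") for ln in table_lines]
        first_ln = begin + 2  # 1-based line number of the header
    else:
        table_lines = lines
        first_ln = 1

    sample_ids, probe_ids, rows = _parse_table_lines(table_lines, first_ln)
    try:
        arr = np.array(rows, dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell in data table ({exc})")
    values = pd.DataFrame(arr, index=pd.Index(probe_ids, name="probe_id"),
                          columns=sample_ids)
    if orientation == "samples_by_probes":
        values = values.T
    elif orientation != "probes_by_samples":
        raise ValueError(f"unknown orientation: {orientation!r}")
    _check_axes(values)
    return values


def write_expression_table(values: pd.DataFrame, path: str | Path) -> None:
    df = values.copy()
    df.index.name = df.index.name or "probe_id"
    df.to_csv(path, sep="\t")


def write_series_matrix(values: pd.DataFrame, path: str | Path,
                        series_id: str = "synthetic") -> None:
    """Write a minimal GEO Series-Matrix flavored export of a matrix."""
    with open(path, "w") as fh:
        fh.write(f"!Series_geo_accession\t\"{series_id}\"\n")
        fh.write("!Series_platform_id\t\"synthetic-array\"\n")
        fh.write("!series_matrix_table_begin\n")
        fh.write("\t".join(['"ID_REF"'] + [f'"{c}"' for c in values.columns]) + "\n")
        for pid, row in values.iterrows():
            fh.write("\t".join([f'"{pid}"'] + [repr(float(v)) for v in row]) + "\n")
        fh.write("!series_matrix_table_end\n")


# ---------------------------------------------------------------------------
# normalization


def percentile_normalize(
    raw: RawMatrix, percentile: float = 75.0, floor: float = RAW_FLOOR
) -> ExpressionMatrix:
    """Per-sample percentile (default 75th) normalization, log2 scale.

    Each sample's values are divided by that sample's linear-interpolation
    (type-7) percentile and log2-transformed, so a probe sitting exactly at
    the percentile maps to 0.0.  Raw values are floored at ``floor`` before
    division.
    """
    arr = raw.values.to_numpy(dtype=float)
    totals = arr.sum(axis=0)
    dead = np.flatnonzero(totals == 0)
    if dead.size:
        names = [raw.sample_ids[i] for i in dead]
        raise ValueError(f"sample(s) with all-zero signal: {names}")
    scale = np.percentile(arr, percentile, axis=0)  # linear interpolation
    scale = np.maximum(scale, floor)
    out = np.log2(np.maximum(arr, floor) / scale)
    return ExpressionMatrix(
        pd.DataFrame(out, index=raw.probe_ids, columns=raw.sample_ids),
        method="percentile75" if percentile == 75.0 else "percentile75",
    )


def quantile_normalize(raw: RawMatrix, floor: float = RAW_FLOOR) -> ExpressionMatrix:
    """Rank-mean quantile normalization followed by log2.

    The reference distribution is the across-sample mean of the sorted
    columns; tied values within a sample receive the mean of the
    reference values at their tied ranks.
    """
    arr = raw.values.to_numpy(dtype=float)
    n, m = arr.shape
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(m):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        # tie groups share the mean of their reference segment
        boundaries = np.flatnonzero(np.diff(sorted_col)) + 1
        starts = np.concatenate(([0], boundaries))
        stops = np.concatenate((boundaries, [n]))
        assigned = np.empty(n)
        for a, b in zip(starts, stops):
            assigned[a:b] = ref[a:b].mean()
        out[order, j] = assigned
    out = np.log2(np.maximum(out, floor))
    return ExpressionMatrix(
        pd.DataFrame(out, index=raw.probe_ids, columns=raw.sample_ids),
        method="quantile",
    )


def relative_expression(
    mat: ExpressionMatrix | pd.DataFrame,
    reference_samples: Sequence[str] | None = None,
) -> RelativeMatrix:
    """Subtract, per gene, the median over ``reference_samples``.

    With the default ``None`` every sample in the matrix is part of the
    reference (the study's convention: the median over the dataset used
    for each analysis).
    """
    values = mat.values if isinstance(mat, ExpressionMatrix) else mat
    if reference_samples is None:
        reference_samples = list(values.columns)
    reference_samples = list(reference_samples)
    if not reference_samples:
        raise ValueError("reference sample set is empty")
    unknown = [s for s in reference_samples if s not in values.columns]
    if unknown:
        raise ValueError(f"reference sample(s) not in matrix: {unknown}")
    med = values[reference_samples].median(axis=1)
    return RelativeMatrix(values.sub(med, axis=0), tuple(reference_samples))


# ---------------------------------------------------------------------------
# filters and summaries


def filter_by_raw_intensity(
    raw: RawMatrix, threshold: float = 100.0, min_samples: int = 1
) -> pd.Index:
    """Probes with raw intensity strictly above ``threshold`` in at least
    ``min_samples`` samples (order preserved)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    hits = (raw.values.to_numpy() > threshold).sum(axis=1)
    return raw.probe_ids[hits >= min_samples]


@dataclass(frozen=True)
class ExpressedResult:
    """Per-condition 'expressed' calls on replicate-mean log2 values."""

    flags: pd.DataFrame          # condition x gene booleans
    fraction: pd.Series          # per-condition expressed fraction
    universal: pd.Index          # genes expressed in every condition


def average_replicates(
    mat: ExpressionMatrix | RelativeMatrix | pd.DataFrame,
    metadata: SampleMetadata,
) -> pd.DataFrame:
    """Arithmetic mean over replicates: genes x conditions, design order."""
    values = mat if isinstance(mat, pd.DataFrame) else mat.values
    metadata.check_matrix(values)
    cols = {}
    for cond in metadata.condition_order:
        samples = [s for s in metadata.samples_of_condition(cond)
                   if s in values.columns]
        if not samples:
            continue
        cols[cond] = values[samples].mean(axis=1)
    if not cols:
        raise ValueError("no metadata condition matches the matrix samples")
    return pd.DataFrame(cols)


def expressed_flags(
    mat: ExpressionMatrix,
    metadata: SampleMetadata,
    threshold: float = -5.0,
) -> ExpressedResult:
    """Call a gene 'expressed' in a condition when its replicate-mean
    normalized value is strictly above ``threshold``."""
    if mat.method != "percentile75":
        raise ValueError("expressed calls are defined on percentile75-normalized data")
    for cond in metadata.condition_order:
        if not [s for s in metadata.samples_of_condition(cond)
                if s in mat.values.columns]:
            raise ValueError(f"condition with zero samples in matrix: {cond}")
    means = average_replicates(mat, metadata)
    flags = (means > threshold).T  # condition x gene
    fraction = flags.mean(axis=1)
    universal = means.index[flags.all(axis=0).to_numpy()]
    return ExpressedResult(flags=flags, fraction=fraction, universal=universal)
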