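"""Reading, writing and filtering of expression matrices and clinical tables.

Expression matrices follow the wide-matrix convention used by public
expression hubs: tab-separated, UTF-8, one gene per row, first column the
gene identifier, first row the sample identifiers, values on the
log2(normalized count + 1) scale (hence finite and non-negative; a stored
value of exactly 0 means a raw count of zero).

Clinical tables are tab-separated with a ``sample_id`` column and ``NA``
for missing fields.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = "NA"

#: Columns of a sample-annotation table, in canonical order.
ANNOTATION_COLUMNS = [
    "sample_id",
    "group",
    "subcohort",
    "stage",
    "age_years",
    "gender",
    "race",
    "bmi",
    "os_status",
    "os_time_days",
]


class ExpressionValidationError(ValueError):
    """Raised when a matrix violates the expression-matrix contract."""


def validate_expression(m: pd.DataFrame) -> pd.DataFrame:
    """Check the expression-matrix invariants and return the matrix.

    Genes are rows (index), samples are columns. Identifiers must be
    unique; values must be numeric, finite and >= 0.
    """
    if m.index.has_duplicates:
        dupes = m.index[m.index.duplicated()].unique().tolist()
        raise ExpressionValidationError(f"duplicate gene identifiers: {dupes[:5]}")
    if m.columns.has_duplicates:
        dupes = m.columns[m.columns.duplicated()].unique().tolist()
        raise ExpressionValidationError(f"duplicate sample identifiers: {dupes[:5]}")
    values = m.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ExpressionValidationError("expression values must be numeric")
    if not np.isfinite(values).all():
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ExpressionValidationError(
            f"non-finite value at gene {m.index[bad[0]]!r}, sample {m.columns[bad[1]]!r}"
        )
    if (values < 0).any():
        bad = np.argwhere(values < 0)[0]
        raise ExpressionValidationError(
            f"negative value at gene {m.index[bad[0]]!r}, sample {m.columns[bad[1]]!r} "
            "(log2(count+1) values are non-negative)"
        )
    return m


def read_expression(path: str | Path, orientation: str = "genes-in-rows") -> pd.DataFrame:
    """Read a wide TSV expression matrix.

    Parameters
    ----------
    path
        TSV file with one identifier column and a numeric body.
    orientation
        ``"genes-in-rows"`` (default) or ``"samples-in-rows"``; the result
        is always genes x samples.
    """
    if orientation not in ("genes-in-rows", "samples-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    body = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            row = raw.index[bad.to_numpy().argmax()]
            raise ExpressionValidationError(
                f"malformed numeric cell at row {row!r}, column {col!r}: "
                f"{raw.loc[row, col]!r}"
            )
        if converted.isna().any():
            row = raw.index[converted.isna().to_numpy().argmax()]
            raise ExpressionValidationError(f"missing value at row {row!r}, column {col!r}")
        body[col] = converted
    if orientation == "samples-in-rows":
        body = body.T
    body.index.name = "gene_id"
    return validate_expression(body)


def write_expression(m: pd.DataFrame, path: str | Path) -> None:
    """Write a genes x samples matrix as wide TSV (6 decimal places)."""
    validate_expression(m)
    out = m.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.6f")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a sample-annotation table (``NA`` = missing)."""
    ann = pd.read_csv(path, sep="\t", na_values=[MISSING], keep_default_na=False)
    if "sample_id" not in ann.columns:
        raise ValueError("annotation table must contain a 'sample_id' column")
    if ann["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in annotation table")
    if "os_time_days" in ann.columns:
        times = pd.to_numeric(ann["os_time_days"], errors="raise")
        if (times.dropna() < 0).any():
            raise ValueError("os_time_days must be non-negative")
    if "stage" in ann.columns:
        stages = pd.to_numeric(ann["stage"], errors="raise").dropna()
        if not stages.isin([1, 2, 3, 4]).all():
            raise ValueError("stage must be in {1,2,3,4} when present")
    return ann


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def select_samples(ann: pd.DataFrame, criteria: Mapping[str, object]) -> list[str]:
    """Sample ids matching the conjunction of ``field == value`` predicates.

    Input order is preserved; an empty criteria set selects every sample.
    Unknown fields raise ``KeyError``.
    """
    mask = pd.Series(True, index=ann.index)
    for field, value in criteria.items():
        if field not in ann.columns:
            raise KeyError(f"unknown annotation field {field!r}")
        mask &= ann[field] == value
    return ann.loc[mask, "sample_id"].tolist()


def filter_zero_genes(m: pd.DataFrame, threshold_fraction: float = 2.0 / 3.0) -> pd.DataFrame:
    """Drop genes whose fraction of exactly-zero entries exceeds the threshold.

    A gene is removed iff  (# zeros) / (# samples)  is *strictly* greater
    than ``threshold_fraction`` ("expression of 0 in more than two-thirds
    of samples"); gene order is preserved.
    """
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in (0, 1]")
    zero_frac = (m.to_numpy() == 0).mean(axis=1)
    return m.loc[zero_frac <= threshold_fraction]


def align_labels(m: pd.DataFrame, ann: pd.DataFrame) -> pd.Series:
    """Group labels (``tumor``/``normal``) aligned to the matrix columns."""
    groups = ann.set_index("sample_id")["group"]
    missing = [s for s in m.columns if s not in groups.index]
    if missing:
        raise ValueError(f"samples without annotation: {missing[:5]}")
    return groups.loc[list(m.columns)]
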