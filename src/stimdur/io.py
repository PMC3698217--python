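"""Expression-matrix and sample-sheet I/O with reference-design pairing.

The pipeline's universal currency is a probes x samples table of log2
intensities held as a :class:`pandas.DataFrame` (index = probe ids, columns
= sample ids).  Sample metadata live in a flat sample sheet with one row per
array: ``sample_id``, ``experiment_id``, ``condition``, ``time_h``,
``replicate``.  Every treated sample is analysed against a non-treated
reference harvested at the same time point in the same biological replicate
("time course reference design"); :func:`pair_references` establishes that
mapping and is used by every downstream stage.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

CONDITIONS = ("untreated", "sustained", "transient", "chx", "gastrin_chx")

#: decimals used when matching harvest times between sheet writers
TIME_DECIMALS = 3

SHEET_COLUMNS = ["sample_id", "experiment_id", "condition", "time_h", "replicate"]


class MatrixFormatError(ValueError):
    """Raised when an expression matrix violates its format contract."""


class PairingError(ValueError):
    """Raised when treated samples lack a time-matched untreated reference."""


def validate_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check an expression matrix (probes x samples) and return it.

    Requires unique probe and sample ids, finite float values and at least
    a 2 x 2 shape.
    """
    if matrix.index.duplicated().any():
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise MatrixFormatError(f"duplicate probe ids: {dups}")
    if matrix.columns.duplicated().any():
        dups = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise MatrixFormatError(f"duplicate sample ids: {dups}")
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise MatrixFormatError(
            f"matrix must be at least 2 probes x 2 samples, got {matrix.shape}"
        )
    values = matrix.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = matrix.columns[
            [not np.issubdtype(dt, np.number) for dt in matrix.dtypes]
        ].tolist()
        raise MatrixFormatError(f"non-numeric columns: {bad}")
    if not np.isfinite(values).all():
        rows, cols = np.nonzero(~np.isfinite(values))
        where = (matrix.index[rows[0]], matrix.columns[cols[0]])
        raise MatrixFormatError(f"non-finite value at probe/sample {where}")
    return matrix


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TSV expression matrix (first column probe id, header sample ids)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dup = sorted({s for s in samples if samples.count(s) > 1})
        raise MatrixFormatError(f"{path}: duplicated sample header(s): {dup}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise MatrixFormatError(f"{path}: malformed TSV: {exc}") from exc
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise MatrixFormatError(
                f"{path}: non-numeric cell in column {col!r}, "
                f"row {bad.index[0]!r}: {bad.iloc[0]!r}"
            )
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    return validate_matrix(df.astype(float))


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    validate_matrix(matrix)
    out = matrix.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def validate_sheet(sheet: pd.DataFrame, matrix: pd.DataFrame | None = None) -> pd.DataFrame:
    """Check a sample sheet; optionally check agreement with a matrix."""
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in sheet: {dups}")
    bad = sorted(set(sheet["condition"]) - set(CONDITIONS))
    if bad:
        raise ValueError(f"unknown conditions {bad}; allowed: {CONDITIONS}")
    key = sheet[["experiment_id", "condition", "replicate"]].astype(str).agg("|".join, axis=1)
    key = key + "|" + sheet["time_h"].round(TIME_DECIMALS).astype(str)
    if key.duplicated().any():
        raise ValueError(
            "duplicate (experiment, condition, time, replicate) rows: "
            f"{sheet.loc[key.duplicated(), 'sample_id'].tolist()}"
        )
    if matrix is not None:
        if set(sheet["sample_id"]) != set(matrix.columns):
            only_sheet = sorted(set(sheet["sample_id"]) - set(matrix.columns))
            only_mat = sorted(set(matrix.columns) - set(sheet["sample_id"]))
            raise ValueError(
                f"sheet/matrix sample mismatch; sheet-only={only_sheet}, matrix-only={only_mat}"
            )
    return sheet


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    sheet["time_h"] = sheet["time_h"].astype(float)
    sheet["replicate"] = sheet["replicate"].astype(int)
    sheet["sample_id"] = sheet["sample_id"].astype(str)
    return validate_sheet(sheet)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    validate_sheet(sheet)
    sheet.to_csv(path, sep="\t", index=False)


def read_probe_annotation(path: str | Path, probes=None, sentinel: str = "NA") -> dict:
    """Read a two-column (probe_id, symbol) TSV into a total map over `probes`."""
    ann = pd.read_csv(path, sep="\t")
    mapping = dict(zip(ann.iloc[:, 0].astype(str), ann.iloc[:, 1].astype(str)))
    if probes is not None:
        mapping = {str(p): mapping.get(str(p), sentinel) for p in probes}
    return mapping


def pair_conditions(
    sheet: pd.DataFrame,
    treated_condition: str | None,
    reference_condition: str = "untreated",
) -> pd.Series:
    """Map each treated sample id to its time/replicate-matched reference.

    ``treated_condition=None`` pairs every non-reference condition.  Times
    are matched after rounding to ``TIME_DECIMALS``.  Raises
    :class:`PairingError` listing any treated sample without exactly one
    matching reference in the same experiment.
    """
    validate_sheet(sheet)
    sheet = sheet.copy()
    sheet["time_key"] = sheet["time_h"].round(TIME_DECIMALS)
    refs = sheet[sheet["condition"] == reference_condition]
    ref_lookup: Mapping = {
        (r.experiment_id, r.time_key, r.replicate): r.sample_id for r in refs.itertuples()
    }
    if treated_condition is None:
        treated = sheet[sheet["condition"] != reference_condition]
    else:
        treated = sheet[sheet["condition"] == treated_condition]
    mapping, unmatched = {}, []
    for r in treated.itertuples():
        ref = ref_lookup.get((r.experiment_id, r.time_key, r.replicate))
        if ref is None:
            unmatched.append(r.sample_id)
        else:
            mapping[r.sample_id] = ref
    if unmatched:
        raise PairingError(
            f"no time-matched {reference_condition!r} reference for samples: {unmatched}"
        )
    return pd.Series(mapping, name="reference", dtype=object)


def pair_references(sheet: pd.DataFrame) -> pd.Series:
    """Pair every treated (non-untreated) sample with its untreated reference."""
    return pair_conditions(sheet, None, "untreated")
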