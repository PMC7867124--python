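"""Plain-text I/O for bracelet-style recordings and feature tables.

Recording dialect (what the device writes to its SD card, already converted
to physical units):

* comma-separated, decimal point;
* two header lines — column names ``t,ax,ay,az,gx,gy,gz`` then units
  ``s,G,G,G,dps,dps,dps``;
* one row per sample.

The dialect carries no metadata columns, so subject/class/task travel in the
filename as ``<subject>__<class_label>__<task>.csv``; readers fall back to
``"unknown"`` when the name does not match.

All readers reject malformed input (wrong columns, wrong units, non-numeric
cells, non-monotone timestamps) with a :class:`FormatError` naming the
offending line rather than silently repairing it.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import List, Union

import numpy as np
import pandas as pd

from .synth import CHANNELS, Recording

__all__ = [
    "FormatError",
    "RECORDING_COLUMNS",
    "RECORDING_UNITS",
    "recording_filename",
    "write_recording",
    "read_recording",
    "write_feature_table",
    "read_feature_table",
]

RECORDING_COLUMNS = ("t",) + CHANNELS
RECORDING_UNITS = ("s", "G", "G", "G", "dps", "dps", "dps")

_FNAME_RE = re.compile(r"^(?P<sid>[^_]+)__(?P<label>[^_]+)__(?P<task>.+)$")


class FormatError(ValueError):
    """Raised when a file does not conform to the documented dialect."""


def recording_filename(rec: Recording) -> str:
    """Canonical file name encoding the recording metadata."""
    return f"{rec.subject_id}__{rec.class_label}__{rec.task}.csv"


def write_recording(rec: Recording, path: Union[str, Path]) -> None:
    """Write a recording in the two-header-line CSV dialect.

    Floats are written with ``repr`` precision so a read-back is
    sample-exact.
    """
    rec.validate()
    path = Path(path)
    df = pd.DataFrame({name: getattr(rec, name) for name in RECORDING_COLUMNS})
    with open(path, "w") as fh:
        fh.write(",".join(RECORDING_COLUMNS) + "\n")
        fh.write(",".join(RECORDING_UNITS) + "\n")
        df.to_csv(fh, header=False, index=False)


def read_recording(path: Union[str, Path]) -> Recording:
    """Read a dialect-conforming recording CSV.

    The sampling rate is inferred from the median timestamp step; metadata
    is parsed from the ``<subject>__<class>__<task>.csv`` name convention.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        units = fh.readline().rstrip("\n")
    if tuple(header.split(",")) != RECORDING_COLUMNS:
        raise FormatError(
            f"{path}: line 1: expected columns {','.join(RECORDING_COLUMNS)}, "
            f"got {header!r}"
        )
    if tuple(units.split(",")) != RECORDING_UNITS:
        raise FormatError(
            f"{path}: line 2: expected units {','.join(RECORDING_UNITS)}, "
            f"got {units!r}"
        )
    df = pd.read_csv(path, skiprows=2, header=None, names=list(RECORDING_COLUMNS),
                     dtype=str)
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no data rows")
    values = {}
    for col in RECORDING_COLUMNS:
        raw = df[col].to_numpy(dtype=object)
        try:
            # numpy string->float is correctly rounded, so the repr-precision
            # write round-trips bit-exactly (pandas' fast parser does not)
            values[col] = raw.astype(np.float64)
        except (TypeError, ValueError):
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 3  # 2 headers, 1-based
            raise FormatError(
                f"{path}: line {line}: non-numeric value in column {col!r}"
            ) from None
    t = values["t"]
    if len(t) >= 2:
        dt = np.diff(t)
        if np.any(dt <= 0):
            line = int(np.flatnonzero(dt <= 0)[0]) + 4  # offending (later) sample row
            raise FormatError(f"{path}: line {line}: non-monotone timestamp")
        fs = 1.0 / float(np.median(dt))
    else:
        fs = float("nan")
    m = _FNAME_RE.match(path.stem)
    sid, label, task = (
        (m.group("sid"), m.group("label"), m.group("task"))
        if m
        else ("unknown", "unknown", "unknown")
    )
    return Recording(
        subject_id=sid,
        class_label=label,
        task=task,
        sampling_rate_hz=fs,
        t=t,
        **{c: values[c] for c in CHANNELS},
    )


# --------------------------------------------------------------------------
# feature tables
# --------------------------------------------------------------------------

_META_COLS = ("subject_id", "class_label")


def write_feature_table(table: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a feature table (subject_id, class_label, then feature columns)."""
    for col in _META_COLS:
        if col not in table.columns:
            raise FormatError(f"feature table missing required column {col!r}")
    feature_cols = [c for c in table.columns if c not in _META_COLS]
    if len(set(feature_cols)) != len(feature_cols):
        raise FormatError("duplicate feature names in table")
    ordered = table[list(_META_COLS) + feature_cols]
    ordered.to_csv(path, index=False)


def read_feature_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a feature table, validating the dialect."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    if header[:2] != list(_META_COLS):
        raise FormatError(
            f"{path}: line 1: first columns must be {','.join(_META_COLS)}"
        )
    features: List[str] = header[2:]
    if len(set(features)) != len(features):
        dupes = sorted({f for f in features if features.count(f) > 1})
        raise FormatError(f"{path}: line 1: duplicate feature names {dupes}")
    df = pd.read_csv(path)
    for col in features:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise FormatError(f"{path}: non-numeric values in feature column {col!r}")
    return df
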