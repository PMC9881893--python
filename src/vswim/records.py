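"""Raw pose-record files and session metadata.

One acquisition run produces a tab-delimited record file with one row per
tracked frame and no header, columns in fixed order::

    time  body_x  body_z  head_x  head_z  pitch  epoch_id  length

(time in s, coordinates in mm with z positive up, pitch in degrees,
epoch_id an integer per contiguous detected span, fish length in mm).
Floats are written with 6 decimals so canonical files round-trip
byte-stably.  Metadata lives in a sibling ``key=value`` text file; unknown
keys are preserved.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

__all__ = [
    "RECORD_COLUMNS",
    "make_records",
    "validate_records",
    "write_records",
    "read_records",
    "SessionMetadata",
    "read_metadata",
    "write_metadata",
]

RECORD_COLUMNS = ("time", "body_x", "body_z", "head_x", "head_z", "pitch", "epoch_id", "length")
_FLOAT_COLUMNS = tuple(c for c in RECORD_COLUMNS if c != "epoch_id")


def make_records(**columns) -> pd.DataFrame:
    """Assemble a raw-record DataFrame from per-column arrays."""
    missing = set(RECORD_COLUMNS) - set(columns)
    if missing:
        raise ValueError(f"missing record columns: {sorted(missing)}")
    df = pd.DataFrame({c: np.asarray(columns[c]) for c in RECORD_COLUMNS})
    df["epoch_id"] = df["epoch_id"].astype(np.int64)
    for c in _FLOAT_COLUMNS:
        df[c] = df[c].astype(float)
    return df


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    if tuple(df.columns) != RECORD_COLUMNS:
        raise ValueError(f"record columns must be {RECORD_COLUMNS}, got {tuple(df.columns)}")
    if len(df) and (np.diff(df["time"].to_numpy()) < 0).any():
        raise ValueError("time must be non-decreasing")
    return df


def write_records(series: pd.DataFrame, path) -> None:
    """Write records as tab-separated rows, 6-decimal floats, no header."""
    validate_records(series)
    with open(path, "w", newline="\n") as fh:
        for row in series.itertuples(index=False):
            fh.write(
                "\t".join(
                    str(int(v)) if c == "epoch_id" else f"{v:.6f}"
                    for c, v in zip(RECORD_COLUMNS, row)
                )
                + "\n"
            )


def read_records(path) -> pd.DataFrame:
    """Read a raw record file; exact inverse of :func:`write_records`."""
    rows = []
    if isinstance(path, io.TextIOBase):
        lines = path.readlines()
    else:
        with open(path) as fh:
            lines = fh.readlines()
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != len(RECORD_COLUMNS):
            raise ValueError(
                f"line {lineno}: expected {len(RECORD_COLUMNS)} columns, got {len(parts)}"
            )
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: malformed value ({exc})") from None
    if not rows:
        return make_records(**{c: [] for c in RECORD_COLUMNS})
    arr = np.asarray(rows)
    return make_records(**{c: arr[:, i] for i, c in enumerate(RECORD_COLUMNS)})


@dataclass
class SessionMetadata:
    """Experiment metadata stored alongside a record file."""

    frame_rate: float  # Hz
    mm_per_pixel: float = 1.0
    light_on: str = "08:00"  # zeitgeber light phase start (clock time)
    light_off: str = "22:00"
    session_start: str = "08:00"  # clock time of the first record
    chamber_type: str = "standard"  # standard | narrow
    repeat_id: str = "r0"
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        if self.chamber_type not in ("standard", "narrow"):
            raise ValueError("chamber_type must be 'standard' or 'narrow'")


_META_FIELDS = {f.name for f in dc_fields(SessionMetadata)} - {"extras"}
_META_FLOATS = {"frame_rate", "mm_per_pixel"}


def write_metadata(meta: SessionMetadata, path) -> None:
    with open(path, "w", newline="\n") as fh:
        for name in sorted(_META_FIELDS):
            fh.write(f"{name}={getattr(meta, name)}\n")
        for key in sorted(meta.extras):
            fh.write(f"{key}={meta.extras[key]}\n")


def read_metadata(path) -> SessionMetadata:
    pairs: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected key=value, got {line!r}")
            key, _, value = line.partition("=")
            pairs[key.strip()] = value.strip()
    if "frame_rate" not in pairs:
        raise ValueError("metadata is missing required key 'frame_rate'")
    kwargs: dict = {}
    extras: dict[str, str] = {}
    for key, value in pairs.items():
        if key in _META_FIELDS:
            kwargs[key] = float(value) if key in _META_FLOATS else value
        else:
            extras[key] = value
    return SessionMetadata(extras=extras, **kwargs)
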