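"""Reading and writing accelerometry recordings and biomarker tables.

The canonical in-memory representation is :class:`RawRecording`: tri-axial
acceleration in gravitational units (g) sampled uniformly, nominally at
100 Hz.  All downstream constants (filter cut-offs, 4-s windows, the 60-s
static block) are stated at 100 Hz, so arbitrary-rate input is resampled
once, here, and never again.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

G_TO_MS2 = 9.80665

#: column order of the per-day biomarker table (validity flags last)
BIOMARKER_COLUMNS = [
    "subject_id",
    "day_index",
    "steps_per_day",
    "longest_walk_s",
    "arm_swing_prop",
    "pocket_prop",
    "texting_prop",
    "phonecall_prop",
    "shoulderbag_prop",
    "briefcase_prop",
    "unspecified_arm_prop",
    "step_walk_gradient_x100",
    "walks_le_8s_pct",
    "walks_le_60s_pct",
    "running_min",
    "speed_median",
    "speed_p95",
    "speed_iqr",
    "cadence_median_spm",
    "cadence_iqr_spm",
    "step_time_var_mode_s",
    "hr8",
    "step_regularity_pct",
    "stride_regularity_pct",
    "wear_hours",
    "n_walking_bouts",
    "valid_day",
]


class FormatError(ValueError):
    """Input file does not have the expected layout."""


class DataError(ValueError):
    """Input file is well-formed but its contents violate a precondition."""


class UnsupportedRateError(ValueError):
    """Sampling rate outside the supported [20, 1000] Hz range."""


@dataclass
class RawRecording:
    """Uniformly sampled tri-axial wrist acceleration in g.

    Parameters
    ----------
    subject_id : opaque identifier.
    start_time : absolute start as a pandas Timestamp (may be tz-aware).
    fs : sampling rate in Hz.
    samples : (n, 3) float array, columns x, y, z, in g.
    height_m : optional participant stature in metres (used by the
        walking-speed regression).
    meta : free-form provenance.
    """

    subject_id: str
    start_time: pd.Timestamp
    fs: float
    samples: np.ndarray
    height_m: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise DataError("samples must be an (n, 3) array")
        if not np.all(np.isfinite(self.samples)):
            raise DataError("samples contain non-finite values")
        if np.abs(self.samples).max(initial=0.0) > 16.0:
            raise DataError("axis values exceed 16 g after unit normalization")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def t(self) -> np.ndarray:
        """Seconds from start for each sample."""
        return np.arange(self.n_samples) / self.fs


def _parse_time_column(time: pd.Series) -> np.ndarray:
    """Return seconds-from-start from float seconds or ISO-8601 strings."""
    if pd.api.types.is_numeric_dtype(time):
        t = time.to_numpy(dtype=float)
    else:
        parsed = pd.to_datetime(time, format="ISO8601")
        t = (parsed - parsed.iloc[0]).dt.total_seconds().to_numpy()
    return t


def read_recording(
    path: str | Path,
    unit_hint: str = "auto",
    subject_id: Optional[str] = None,
    height_m: Optional[float] = None,
) -> RawRecording:
    """Read a ``time,x,y,z`` CSV into a :class:`RawRecording` in g.

    ``unit_hint`` is one of ``g``, ``m_s2``, ``auto``.  Under ``auto`` the
    recording is assumed to be in m/s² when the median vector magnitude
    exceeds 4 (a resting wrist reads ~1 g or ~9.81 m/s²).  Non-uniform
    timestamps are rejected; resampling is a separate, explicit step.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"{path} is empty") from exc
    required = {"time", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path} must have columns time,x,y,z; found {list(df.columns)}"
        )
    if len(df) < 2:
        raise DataError(f"{path} has fewer than two samples")

    t = _parse_time_column(df["time"])
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise DataError("time column must be strictly increasing")
    if not np.allclose(dt, dt[0], rtol=1e-3, atol=1e-6):
        raise DataError(
            "non-uniform sample spacing; resample explicitly before use"
        )
    fs = 1.0 / float(np.median(dt))

    xyz = df[["x", "y", "z"]].to_numpy(dtype=float)
    if unit_hint not in ("g", "m_s2", "auto"):
        raise ValueError(f"unknown unit_hint {unit_hint!r}")
    if unit_hint == "auto":
        magnitude = float(np.median(np.linalg.norm(xyz, axis=1)))
        unit_hint = "m_s2" if magnitude > 4.0 else "g"
    if unit_hint == "m_s2":
        xyz = xyz / G_TO_MS2

    if pd.api.types.is_numeric_dtype(df["time"]):
        start = pd.Timestamp("1970-01-01") + pd.to_timedelta(t[0], unit="s")
    else:
        start = pd.to_datetime(df["time"].iloc[0], format="ISO8601")

    return RawRecording(
        subject_id=subject_id or path.stem,
        start_time=start,
        fs=fs,
        samples=xyz,
        height_m=height_m,
        meta={"source": str(path)},
    )


def resample_to_canonical(rec: RawRecording, target_fs: float = 100.0) -> RawRecording:
    """Linearly resample to the canonical rate (default 100 Hz).

    A no-op when the rate already matches.  Rates outside [20, 1000] Hz are
    refused: below ~20 Hz the 0.25–2.5 Hz gait band is no longer safely
    recoverable and above 1000 Hz the input is presumed mislabelled.
    """
    if not (20.0 <= rec.fs <= 1000.0):
        raise UnsupportedRateError(
            f"sampling rate {rec.fs:g} Hz outside supported range [20, 1000]"
        )
    if np.isclose(rec.fs, target_fs):
        return rec
    t_old = rec.t
    n_new = int(np.floor(t_old[-1] * target_fs)) + 1
    t_new = np.arange(n_new) / target_fs
    resampled = np.column_stack(
        [np.interp(t_new, t_old, rec.samples[:, k]) for k in range(3)]
    )
    return RawRecording(
        subject_id=rec.subject_id,
        start_time=rec.start_time,
        fs=target_fs,
        samples=resampled,
        height_m=rec.height_m,
        meta={**rec.meta, "resampled_from_hz": rec.fs},
    )


def new_biomarker_table(rows: Optional[list[dict]] = None) -> pd.DataFrame:
    """Create a biomarker table with the stable column order.

    One row per (subject_id, day_index); missing biomarkers are NA, never 0.
    """
    df = pd.DataFrame(rows or [], columns=BIOMARKER_COLUMNS)
    return df


def write_biomarkers(table: pd.DataFrame, path: str | Path) -> None:
    """Write a biomarker table as CSV with stable column order.

    Nulls become empty cells and survive a round-trip through
    :func:`read_biomarkers`.
    """
    missing = [c for c in BIOMARKER_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"biomarker table missing columns: {missing}")
    table[BIOMARKER_COLUMNS].to_csv(path, index=False)


def read_biomarkers(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in BIOMARKER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"biomarker CSV missing columns: {missing}")
    return df[BIOMARKER_COLUMNS]


def write_biomarkers_json(table: pd.DataFrame, path: str | Path) -> None:
    """JSON export of the same schema (records orientation, NaN → null)."""
    records = json.loads(table[BIOMARKER_COLUMNS].to_json(orient="records"))
    Path(path).write_text(json.dumps(records, indent=1))
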