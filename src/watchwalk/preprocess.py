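"""Filtered norm channels and wear/sleep masks.

From a canonical recording this stage derives four per-sample channels:

- ``en_crude``: Euclidean norm sqrt(x²+y²+z²) in g;
- ``en_static_removed``: the norm minus its 60-s centred moving mean, which
  removes the gravity component and slow postural drift;
- ``en_lowpass``: the static-removed norm through a zero-phase 5th-order
  Butterworth low-pass at 20 Hz (machine-noise removal);
- ``en_band``: a zero-phase band-pass of 0.25–2.5 Hz, the band containing
  stride and step frequencies, used for peak-based step detection.

It also flags non-wear (long constant stretches) and candidate sleep periods
so that neither enters windowing or biomarker computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import signal


class TooShortError(ValueError):
    """Recording too short for the requested operation."""


@dataclass
class ExclusionInterval:
    """A span to remove before biomarker computation.

    kind is ``nonwear`` or ``sleep``; bounds are seconds from recording start.
    """

    kind: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.kind not in ("nonwear", "sleep"):
            raise ValueError(f"unknown exclusion kind {self.kind!r}")
        if self.end_s <= self.start_s:
            raise ValueError("end_s must exceed start_s")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class ProcessedSignal:
    """Derived channels plus wear/sleep masks, all on the input clock."""

    fs: float
    en_crude: np.ndarray
    en_static_removed: np.ndarray
    en_lowpass: np.ndarray
    en_band: np.ndarray
    axes: np.ndarray  # retained (n, 3) raw x, y, z for correlation features
    wear_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    sleep_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    start_time: Optional[pd.Timestamp] = None

    def __post_init__(self) -> None:
        n = len(self.en_crude)
        if self.wear_mask is None:
            self.wear_mask = np.ones(n, dtype=bool)
        if self.sleep_mask is None:
            self.sleep_mask = np.zeros(n, dtype=bool)
        for ch in (self.en_static_removed, self.en_lowpass, self.en_band,
                   self.wear_mask, self.sleep_mask):
            if len(ch) != n:
                raise ValueError("all channels must share the input length")

    @property
    def n_samples(self) -> int:
        return len(self.en_crude)

    @property
    def usable_mask(self) -> np.ndarray:
        """Samples eligible for windowing: worn and awake."""
        return self.wear_mask & ~self.sleep_mask


def _moving_mean_centered(x: np.ndarray, win: int) -> np.ndarray:
    # centred window with shrinking edges: the first/last half-window uses
    # whatever samples exist
    s = pd.Series(x)
    return s.rolling(win, center=True, min_periods=1).mean().to_numpy()


def compute_channels(rec) -> ProcessedSignal:
    """Derive the four norm channels from a canonical 100 Hz recording.

    Filtering is zero-phase (forward-backward) so that step-event times are
    not phase-shifted.  Edge effects are confined to the first/last 60 s;
    recordings shorter than 120 s are refused because the 60-s moving mean
    is then undefined over any interior sample.
    """
    fs = rec.fs
    if rec.duration_s < 120.0:
        raise TooShortError(
            f"need at least 120 s of data, got {rec.duration_s:.1f} s"
        )
    xyz = rec.samples
    en_crude = np.linalg.norm(xyz, axis=1)
    static = _moving_mean_centered(en_crude, int(round(60 * fs)))
    en_static_removed = en_crude - static

    sos_lp = signal.butter(5, 20.0, btype="low", fs=fs, output="sos")
    en_lowpass = signal.sosfiltfilt(sos_lp, en_static_removed)

    sos_bp = signal.butter(4, [0.25, 2.5], btype="bandpass", fs=fs, output="sos")
    en_band = signal.sosfiltfilt(sos_bp, en_static_removed)

    return ProcessedSignal(
        fs=fs,
        en_crude=en_crude,
        en_static_removed=en_static_removed,
        en_lowpass=en_lowpass,
        en_band=en_band,
        axes=xyz,
        start_time=getattr(rec, "start_time", None),
    )


def _merge_runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index runs where flags is True."""
    if not flags.any():
        return []
    padded = np.concatenate([[False], flags, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def detect_nonwear(
    ps: ProcessedSignal,
    sd_threshold_mg: float = 13.0,
    min_duration_min: float = 50.0,
    window_min: float = 10.0,
    step_min: float = 1.0,
) -> list[ExclusionInterval]:
    """Flag non-wear: stationary stretches exceeding 50 min at ≤ 13 mg SD.

    The per-axis standard deviation is evaluated in 10-min windows stepped
    by 1 min; a window is stationary when every axis is at or below the
    threshold.  Runs of stationary windows are merged and kept only when
    the merged span (first window start to last window end) exceeds the
    minimum duration, so a 60-min constant block is recovered to within a
    step while a 49-min block is rejected.
    """
    fs = ps.fs
    n = ps.n_samples
    win = int(round(window_min * 60 * fs))
    step = int(round(step_min * 60 * fs))
    if n < win + step:
        return []
    starts = np.arange(0, n - win + 1, step)
    thresh_g = sd_threshold_mg * 1e-3

    stationary = np.empty(len(starts), dtype=bool)
    for i, s0 in enumerate(starts):
        block = ps.axes[s0: s0 + win]
        stationary[i] = bool(np.all(block.std(axis=0) <= thresh_g))

    intervals = []
    for i0, i1 in _merge_runs(stationary):
        start_s = starts[i0] / fs
        end_s = (starts[i1 - 1] + win) / fs
        if end_s - start_s > min_duration_min * 60:
            intervals.append(ExclusionInterval("nonwear", start_s, end_s))
    return intervals


def detect_sleep(
    ps: ProcessedSignal,
    angle_change_deg: float = 5.0,
    block_s: float = 5.0,
    min_duration_min: float = 30.0,
) -> list[ExclusionInterval]:
    """Candidate sleep-period windows from a wrist-angle heuristic.

    The arm elevation angle atan2(z, sqrt(x²+y²)) is summarised in 5-s
    medians; stretches where successive medians change by less than 5° for
    at least 30 min are sleep candidates, and the longest candidate within
    each 24-h stretch of the recording is returned as that night's sleep
    period.  This captures the core signal of posture-based sleep detection
    (a sustained invariant arm angle) while staying self-contained; callers
    needing a validated sleep algorithm can substitute an external mask via
    :func:`apply_exclusions`.
    """
    fs = ps.fs
    if ps.n_samples / fs < 3600.0:
        raise TooShortError("sleep detection needs at least 1 h of data")
    blk = int(round(block_s * fs))
    n_blocks = ps.n_samples // blk
    x, y, z = (ps.axes[: n_blocks * blk, k].reshape(n_blocks, blk) for k in range(3))
    xm = np.median(x, axis=1)
    ym = np.median(y, axis=1)
    zm = np.median(z, axis=1)
    angle = np.degrees(np.arctan2(zm, np.hypot(xm, ym)))

    still = np.abs(np.diff(angle)) < angle_change_deg
    min_blocks = int(min_duration_min * 60 / block_s)
    candidates = []
    for i0, i1 in _merge_runs(still):
        if i1 - i0 >= min_blocks:
            candidates.append((i0 * block_s, (i1 + 1) * block_s))
    if not candidates:
        return []

    # one sleep-period window per 24-h stretch: the longest candidate whose
    # midpoint falls in that stretch
    day_len = 86400.0
    out: list[ExclusionInterval] = []
    n_days = int(np.ceil(ps.n_samples / fs / day_len))
    for d in range(n_days):
        lo, hi = d * day_len, (d + 1) * day_len
        in_day = [c for c in candidates if lo <= 0.5 * (c[0] + c[1]) < hi]
        if in_day:
            best = max(in_day, key=lambda c: c[1] - c[0])
            out.append(ExclusionInterval("sleep", best[0], min(best[1], ps.n_samples / fs)))
    return out


def apply_exclusions(
    ps: ProcessedSignal, intervals: Iterable[ExclusionInterval]
) -> ProcessedSignal:
    """Return a copy with wear/sleep masks updated from the intervals.

    Non-wear clears ``wear_mask``; sleep sets ``sleep_mask``.  Excluded
    samples never enter windowing (see ``usable_mask``).
    """
    wear = ps.wear_mask.copy()
    sleep = ps.sleep_mask.copy()
    duration = ps.n_samples / ps.fs
    for iv in intervals:
        if iv.start_s < 0 or iv.end_s > duration + 1.0 / ps.fs:
            raise ValueError(
                f"interval [{iv.start_s}, {iv.end_s}] outside recording span"
            )
        i0 = int(round(iv.start_s * ps.fs))
        i1 = min(int(round(iv.end_s * ps.fs)), ps.n_samples)
        if iv.kind == "nonwear":
            wear[i0:i1] = False
        else:
            sleep[i0:i1] = True
    return replace(ps, wear_mask=wear, sleep_mask=sleep)
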