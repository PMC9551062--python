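"""Step detection inside walking bouts.

Walking bouts are maximal runs of consecutive walking-classified 4-s
windows.  Within a bout, step events are the local maxima of the 0.25–2.5 Hz
band-passed norm that (a) strictly alternate with local minima, (b) are
spaced consistently with the per-window autocorrelation step-time estimate
and (c) clear an adaptive amplitude threshold tied to the local signal RMS.
The wrist norm peaks once per step (at twice the arm-swing frequency), so
retained maxima are counted as steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sp_signal

from watchwalk.features import Window4s, normalized_autocorr
from watchwalk.preprocess import ProcessedSignal

#: coarse labels that count as walking when assembling bouts
WALKING_LABELS = frozenset({"walk_armswing", "walk_other", "arm_activity_walking"})


@dataclass
class StepDetectionParams:
    """Tunables of the extremum-pruning step detector.

    min_peak_separation_s — refractory period between candidate extrema;
    0.25 s corresponds to the physiological cadence ceiling (240 spm).
    adaptive_threshold_factor — θ = factor × rolling 4-s RMS of the band
    channel; maxima must exceed +θ and minima fall below −θ.
    step_time_tolerance — fractional deviation of successive maxima
    intervals from the autocorrelation step-time estimate before the weaker
    extremum is pruned.
    """

    min_peak_separation_s: float = 0.25
    adaptive_threshold_factor: float = 0.3
    step_time_tolerance: float = 0.3

    def __post_init__(self) -> None:
        if self.min_peak_separation_s <= 0 or self.adaptive_threshold_factor <= 0:
            raise ValueError("parameters must be positive")
        if not 0 < self.step_time_tolerance < 1:
            raise ValueError("step_time_tolerance must be in (0, 1)")


@dataclass
class WalkingBout:
    """A maximal run of consecutive walking windows with its step events."""

    start_s: float
    end_s: float
    window_indices: list[int]
    arm_mode: str
    step_times: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def steps(self) -> int:
        return len(self.step_times)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def assemble_bouts(
    labels: Sequence[str],
    windows: Sequence[Window4s],
    refined: Optional[Sequence[Optional[str]]] = None,
    gap_tolerance_windows: int = 0,
) -> list[WalkingBout]:
    """Group consecutively-timed walking windows into maximal bouts.

    A bout's arm mode is the majority constituent label (the refined label
    where the coarse one is ``walk_other``).  One non-walking window — or a
    gap in wear time — ends the bout; ``gap_tolerance_windows`` is exposed
    for sensitivity analyses but defaults to the strict reading of
    "consecutive".
    """
    if len(labels) != len(windows):
        raise ValueError("labels and windows must align")
    win_s = 4.0
    bouts: list[WalkingBout] = []
    run: list[int] = []

    def flush(run_idx: list[int]) -> None:
        if not run_idx:
            return
        modes = []
        for i in run_idx:
            lab = labels[i]
            if lab == "walk_other" and refined is not None and refined[i]:
                lab = refined[i]
            modes.append(lab)
        vals, counts = np.unique(modes, return_counts=True)
        arm_mode = str(vals[np.argmax(counts)])
        bouts.append(
            WalkingBout(
                start_s=windows[run_idx[0]].start_s,
                end_s=windows[run_idx[-1]].start_s + win_s,
                window_indices=list(run_idx),
                arm_mode=arm_mode,
            )
        )

    gap_budget = gap_tolerance_windows
    for i, w in enumerate(windows):
        is_walk = labels[i] in WALKING_LABELS
        contiguous = bool(run) and np.isclose(
            w.start_s, windows[run[-1]].start_s + win_s * (i - run[-1])
        ) and (i - run[-1] - 1) <= gap_budget
        if is_walk and (not run or contiguous):
            run.append(i)
        elif is_walk:
            flush(run)
            run = [i]
        else:
            flush(run)
            run = []
    flush(run)
    return bouts


def estimate_step_time(
    window_band: np.ndarray,
    fs: float = 100.0,
    lag_range_s: tuple[float, float] = (0.2, 2.0),
    min_value: float = 0.2,
) -> Optional[float]:
    """Autocorrelation step-time estimate of one 4-s band-channel slice.

    The lag of the first local autocorrelation maximum inside
    [0.2, 2.0] s whose normalized value reaches 0.2; None when no such peak
    exists (no periodicity — e.g. noise or a flat signal).
    """
    lo = int(np.ceil(lag_range_s[0] * fs))
    hi = int(np.floor(lag_range_s[1] * fs))
    if len(window_band) < lo + 2:
        return None
    r = normalized_autocorr(window_band, hi)
    hi = min(hi, len(r) - 1)
    peaks, _ = sp_signal.find_peaks(r[: hi + 1])
    peaks = peaks[(peaks >= lo) & (r[peaks] >= min_value)]
    if len(peaks) == 0:
        return None
    return float(peaks[0] / fs)


def _alternate(events: list[tuple[int, int, float]]) -> list[tuple[int, int, float]]:
    """Enforce strict max/min alternation, keeping the more extreme of any
    same-type neighbours (ties → the earlier event)."""
    out: list[tuple[int, int, float]] = []
    for ev in events:
        if out and out[-1][1] == ev[1]:
            if abs(ev[2]) > abs(out[-1][2]):
                out[-1] = ev
        else:
            out.append(ev)
    return out


def detect_steps(
    bout: WalkingBout,
    ps: ProcessedSignal,
    params: StepDetectionParams = StepDetectionParams(),
) -> WalkingBout:
    """Detect step events inside one walking bout.

    Candidate extrema of the band channel are pruned in three passes:
    amplitude (adaptive threshold ±θ from the rolling 4-s RMS), alternation
    (strictly alternating maxima/minima), and step-time consistency
    (successive maxima whose spacing is far shorter than the local
    autocorrelation step-time estimate lose the weaker member — this
    rejects isolated artifact spikes).  Returns a copy of the bout with
    ``step_times`` filled; fewer than two surviving steps leaves it empty.
    """
    fs = ps.fs
    i0 = int(round(bout.start_s * fs))
    i1 = min(int(round(bout.end_s * fs)), ps.n_samples)
    x = ps.en_band[i0:i1]
    if len(x) < fs:  # sub-second fragment
        return replace(bout, step_times=np.array([]))

    # rolling 4-s RMS → per-sample adaptive threshold
    win = int(4 * fs)
    sq = np.convolve(x ** 2, np.ones(min(win, len(x))) / min(win, len(x)), mode="same")
    theta = params.adaptive_threshold_factor * np.sqrt(np.maximum(sq, 0))

    dist = int(round(params.min_peak_separation_s * fs))
    maxima, _ = sp_signal.find_peaks(x, distance=dist)
    minima, _ = sp_signal.find_peaks(-x, distance=dist)
    maxima = maxima[x[maxima] > theta[maxima]]
    minima = minima[x[minima] < -theta[minima]]

    events = sorted(
        [(int(k), +1, float(x[k])) for k in maxima]
        + [(int(k), -1, float(x[k])) for k in minima]
    )
    events = _alternate(events)

    # per-window autocorrelation step-time estimates over the bout
    n_win = max(1, len(x) // win)
    est: list[Optional[float]] = [
        estimate_step_time(x[j * win:(j + 1) * win], fs) for j in range(n_win)
    ]

    def local_tau(k: int) -> Optional[float]:
        return est[min(k // win, n_win - 1)]

    # step-time consistency: drop the weaker of two maxima spaced far
    # tighter than the local estimate
    changed = True
    while changed:
        changed = False
        maxima_ev = [e for e in events if e[1] == +1]
        for a, b in zip(maxima_ev, maxima_ev[1:]):
            tau = local_tau(a[0])
            if tau is None:
                continue
            if (b[0] - a[0]) / fs < (1 - params.step_time_tolerance) * tau:
                victim = a if abs(a[2]) < abs(b[2]) else b
                events = [e for e in events if e != victim]
                events = _alternate(events)
                changed = True
                break

    step_idx = np.array([e[0] for e in events if e[1] == +1])
    if len(step_idx) < 2:
        return replace(bout, step_times=np.array([]))
    return replace(bout, step_times=bout.start_s + step_idx / fs)


def count_daily_steps(
    bouts: Sequence[WalkingBout], day_span: tuple[float, float]
) -> int:
    """Steps falling inside one [start, end) day span (seconds from
    recording start).  Bouts straddling the boundary contribute only the
    step events actually inside the span."""
    lo, hi = day_span
    total = 0
    for b in bouts:
        if b.end_s <= lo or b.start_s >= hi:
            continue
        st = np.asarray(b.step_times)
        total += int(np.count_nonzero((st >= lo) & (st < hi)))
    return total
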