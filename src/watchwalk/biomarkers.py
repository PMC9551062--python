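"""The digital gait biomarker panel.

Per 24-h day the panel covers three families:

- **gait quantity and its distribution** — steps per day, longest walk
  duration, arm-carriage mode proportions, the step-walk gradient (slope of
  log walk-count against log steps-per-walk, ×100), percentages of short
  walks, cumulative exposure of walking durations, running minutes;
- **gait speed** — median, 95th-percentile ("maximal") and IQR of
  per-window walking speed from a 7-feature Gaussian-kernel support-vector
  regression (height, IQR and median of the static-removed norm, mean crude
  norm, mean step time, x/y and x/z axis correlations);
- **gait quality** — cadence statistics, the mode of a log-normal model of
  per-episode step-time SD, the 8-step harmonic ratio, and step/stride
  regularity, all computed over 8-step episodes of arm-swing walking.

Week-level values are means over valid days; a subject's panel is valid
with at least five valid days, each with (near-)24-h wear and at least one
walking bout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from sklearn.compose import TransformedTargetRegressor
from sklearn.model_selection import GroupKFold, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from watchwalk.features import Window4s, normalized_autocorr
from watchwalk.io import BIOMARKER_COLUMNS, new_biomarker_table
from watchwalk.preprocess import ProcessedSignal
from watchwalk.steps import WalkingBout, estimate_step_time

SPEED_FEATURES = [
    "height_m",
    "en_sr_iqr",
    "en_sr_median",
    "en_crude_mean",
    "mean_step_time_s",
    "corr_xy",
    "corr_xz",
]

ARM_MODE_COLUMNS = {
    "walk_armswing": "arm_swing_prop",
    "pocket": "pocket_prop",
    "texting": "texting_prop",
    "phonecall": "phonecall_prop",
    "shoulderbag": "shoulderbag_prop",
    "briefcase": "briefcase_prop",
    "arm_activity_walking": "unspecified_arm_prop",
}


# ---------------------------------------------------------------- quantity


def cumulative_exposure(durations: Sequence[float], d_i: float) -> float:
    """Cumulative exposure X_i of walking durations (percent).

    X_i = (Σ d for d ≤ d_i) / (Σ d) × 100 — the share of total walking
    time contributed by bouts no longer than d_i.
    """
    d = np.asarray(durations, dtype=float)
    if d.size == 0:
        raise ValueError("cumulative exposure is undefined for no bouts")
    if np.any(d <= 0):
        raise ValueError("bout durations must be positive")
    return float(d[d <= d_i].sum() / d.sum() * 100.0)


def walk_duration_percentages(
    bouts: Sequence[WalkingBout],
    thresholds_s: tuple[float, float] = (8.0, 60.0),
) -> tuple[Optional[float], Optional[float]]:
    """Percentage of walks no longer than each threshold (default 8 s, 60 s;
    a 7-s first threshold is the documented alternative preset)."""
    if not bouts:
        return None, None
    durations = np.array([b.duration_s for b in bouts])
    return tuple(
        float(np.mean(durations <= thr) * 100.0) for thr in thresholds_s
    )  # type: ignore[return-value]


def step_walk_gradient(
    bouts: Sequence[WalkingBout], n_bins: int = 16
) -> Optional[float]:
    """Slope β1 of log(walk count) on log(steps per walk), ×100.

    The log–log line is fit through (steps-per-walk, number of walks)
    points: one point per distinct step count when there are at most
    ``n_bins`` of them, otherwise per occupied log-spaced bin (with the
    bin's mean log step count as abscissa, which keeps discrete step
    counts from aliasing against bin edges).  More negative values mean
    the day consisted of relatively more short walks.  Null with fewer
    than three occupied bins.
    """
    steps = np.array([b.steps for b in bouts if b.steps > 0], dtype=float)
    if steps.size == 0:
        return None
    uniq, counts = np.unique(steps, return_counts=True)
    if len(uniq) > n_bins:
        edges = np.geomspace(steps.min(), steps.max() * (1 + 1e-9), n_bins + 1)
        which = np.clip(np.digitize(steps, edges) - 1, 0, n_bins - 1)
        log_x, log_n = [], []
        for b in range(n_bins):
            sel = which == b
            if sel.any():
                log_x.append(np.mean(np.log(steps[sel])))
                log_n.append(np.log(sel.sum()))
    else:
        log_x, log_n = np.log(uniq), np.log(counts)
    if len(log_x) < 3:
        return None
    slope = np.polyfit(log_x, log_n, 1)[0]
    return float(slope * 100.0)


def arm_mode_proportions(bouts: Sequence[WalkingBout]) -> dict[str, Optional[float]]:
    """Per-arm-mode share of total walking duration (percent; sums to 100)."""
    out: dict[str, Optional[float]] = {c: None for c in ARM_MODE_COLUMNS.values()}
    total = sum(b.duration_s for b in bouts)
    if total <= 0:
        return out
    for col in ARM_MODE_COLUMNS.values():
        out[col] = 0.0
    for b in bouts:
        col = ARM_MODE_COLUMNS.get(b.arm_mode)
        if col is None:  # a refined mode name may arrive directly
            col = ARM_MODE_COLUMNS.get(b.arm_mode, "unspecified_arm_prop")
        out[col] += b.duration_s / total * 100.0  # type: ignore[operator]
    return out


# ------------------------------------------------------------------- speed


@dataclass
class SpeedModel:
    """Gaussian-kernel SVR mapping the 7 window features to speed (m/s)."""

    regressor: TransformedTargetRegressor
    cv_mape_pct: float
    feature_names: list[str] = field(default_factory=lambda: list(SPEED_FEATURES))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.regressor.predict(np.asarray(X, dtype=float))


def speed_feature_vector(
    w: Window4s, height_m: float, fs: float = 100.0
) -> Optional[np.ndarray]:
    """The 7 speed-regression features of one walking window, or None when
    the window carries no step-time estimate."""
    if height_m is None:
        raise ValueError("speed features require participant height")
    sr = w.en_static_removed
    tau = estimate_step_time(w.en_band, fs)
    if tau is None:
        return None
    ax = w.axes
    with np.errstate(invalid="ignore"):
        cxy = np.corrcoef(ax[:, 0], ax[:, 1])[0, 1]
        cxz = np.corrcoef(ax[:, 0], ax[:, 2])[0, 1]
    q25, q50, q75 = np.percentile(sr, [25, 50, 75])
    return np.array([
        height_m,
        q75 - q25,
        q50,
        float(np.mean(w.en_crude)),
        tau,
        0.0 if not np.isfinite(cxy) else cxy,
        0.0 if not np.isfinite(cxz) else cxz,
    ])


def train_speed_model(
    X: np.ndarray,
    truth_speed: Sequence[float],
    seed: int = 0,
    subject_ids: Optional[Sequence] = None,
    n_folds: int = 10,
) -> SpeedModel:
    """Fit the walking-speed regression and report its cross-validated MAPE.

    X holds exactly the 7 predictors of :data:`SPEED_FEATURES` per walking
    window.  Folds partition subjects when ids are given, windows otherwise.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(truth_speed, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(SPEED_FEATURES):
        raise ValueError(f"speed model expects {len(SPEED_FEATURES)} features")
    if not np.all(np.isfinite(X)):
        raise ValueError("speed features contain non-finite values (height missing?)")
    if X.shape[0] < 50:
        raise ValueError("speed model needs at least 50 walking windows")

    def make() -> TransformedTargetRegressor:
        pipe = Pipeline([
            ("scale", StandardScaler()),
            ("svr", SVR(kernel="rbf", gamma=1.0 / X.shape[1], C=10.0, epsilon=0.01)),
        ])
        return TransformedTargetRegressor(regressor=pipe, transformer=StandardScaler())

    errs = []
    if subject_ids is not None:
        groups = np.asarray(subject_ids)
        splits = GroupKFold(n_splits=min(n_folds, len(set(groups)))).split(X, y, groups)
    else:
        splits = KFold(n_splits=min(n_folds, len(y)), shuffle=True,
                       random_state=seed).split(X)
    for tr, va in splits:
        m = make()
        m.fit(X[tr], y[tr])
        pred = m.predict(X[va])
        errs.extend(np.abs(pred - y[va]) / np.abs(y[va]))
    final = make()
    final.fit(X, y)
    return SpeedModel(regressor=final, cv_mape_pct=float(np.mean(errs) * 100.0))


def daily_speed_summary(
    speeds: Sequence[float],
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """(median, 95th percentile, IQR) of per-window walking speed.

    The 95th percentile is the "maximal walking speed" biomarker — peak
    performance with outliers excluded.  Linear interpolation throughout.
    """
    s = np.asarray(speeds, dtype=float)
    if s.size == 0:
        return None, None, None
    med = float(np.median(s))
    p95 = float(np.percentile(s, 95))
    q25, q75 = np.percentile(s, [25, 75])
    return med, p95, float(q75 - q25)


# ----------------------------------------------------------------- quality


@dataclass
class EightStepEpisode:
    """Eight consecutive steps of one bout with their temporal summaries.

    The episode duration spans eight step periods (8 × the mean of the 7
    observed inter-step intervals) so that cadence = 480 / duration_s gives
    exactly the underlying cadence for evenly spaced steps.
    """

    step_times: np.ndarray
    duration_s: float
    cadence_spm: float
    step_time_sd_s: float
    hr: Optional[float] = None
    step_reg: Optional[float] = None
    stride_reg: Optional[float] = None

    @property
    def start_s(self) -> float:
        return float(self.step_times[0])


def make_episodes(bout: WalkingBout) -> list[EightStepEpisode]:
    """Regroup a bout's steps into 8-step episodes, truncating remainders.

    A walk of 18 steps yields two episodes (steps 1–8 and 9–16) with steps
    17–18 discarded.
    """
    st = np.asarray(bout.step_times, dtype=float)
    episodes = []
    for e in range(len(st) // 8):
        ts = st[8 * e: 8 * e + 8]
        intervals = np.diff(ts)
        if np.any(intervals <= 0):
            continue
        duration = float(8 * intervals.mean())
        episodes.append(EightStepEpisode(
            step_times=ts,
            duration_s=duration,
            cadence_spm=480.0 / duration,
            step_time_sd_s=float(np.std(intervals, ddof=1)),
        ))
    return episodes


def fit_lognormal_mode(values: Sequence[float]) -> tuple[float, float, float]:
    """Maximum-likelihood log-normal fit; returns (mu, sigma, mode).

    mu and sigma are the mean and SD of the log values; the mode of the
    fitted distribution is e^(mu − sigma²).
    """
    v = np.asarray(values, dtype=float)
    logs = np.log(v)
    mu = float(np.mean(logs))
    sigma = float(np.std(logs, ddof=0))
    return mu, sigma, float(np.exp(mu - sigma ** 2))


def step_time_variability_mode(
    episode_sds: Sequence[float], min_count: int = 10
) -> Optional[float]:
    """Mode of a log-normal model of the day's per-episode step-time SDs.

    The mode of a log-normal is its most probable value and is robust to
    the long right tail that occasional irregular walks produce.  Episodes
    with non-positive SD are dropped; fewer than ``min_count`` remaining
    gives null.
    """
    v = np.asarray(episode_sds, dtype=float)
    v = v[v > 0]
    if v.size < min_count:
        return None
    return fit_lognormal_mode(v)[2]


def harmonic_ratio_8step(
    episode: EightStepEpisode,
    ps: ProcessedSignal,
    max_hr: float = 10.0,
) -> float:
    """8-step harmonic ratio of the static-removed norm.

    Over a window of exactly eight step periods the spectral fundamental is
    1/duration; energy at integer multiples of the step frequency
    (harmonics 8, 16, …, 80) represents the repeating, stabilising pattern,
    while intermediate odd stride harmonics (4, 12, …, 76) represent
    incomplete, destabilising patterns.  hr = Σ stabilising / Σ
    destabilising amplitudes, capped at ``max_hr`` when the destabilising
    sum vanishes.
    """
    fs = ps.fs
    i0 = int(round(episode.start_s * fs))
    n = int(round(episode.duration_s * fs))
    i1 = min(i0 + n, ps.n_samples)
    x = ps.en_static_removed[i0:i1]
    if len(x) < 16:
        return math.nan
    amp = np.abs(np.fft.rfft(x - x.mean()))
    stab_bins = [k for k in range(8, 81, 8) if k < len(amp)]
    destab_bins = [k for k in range(4, 77, 8) if k < len(amp)]
    stab = sum(amp[k] for k in stab_bins)
    destab = sum(amp[k] for k in destab_bins)
    if destab <= 0:
        return max_hr
    return float(min(stab / destab, max_hr))


def regularity(
    episode: EightStepEpisode,
    ps: ProcessedSignal,
    band: tuple[float, float] = (0.6, 1.4),
) -> tuple[Optional[float], Optional[float]]:
    """(step, stride) regularity of one episode, each in [−1, 1].

    The autocorrelation of the static-removed norm over the episode,
    normalised by its zero-lag value, is evaluated at its first and second
    dominant peaks: the local maximum nearest one mean step time (step
    regularity — similarity of consecutive steps) and nearest two step
    times (stride regularity — similarity of consecutive strides).  Null
    when the corresponding peak does not exist.
    """
    fs = ps.fs
    i0 = int(round(episode.start_s * fs))
    n = int(round(episode.duration_s * fs))
    i1 = min(i0 + n, ps.n_samples)
    x = ps.en_static_removed[i0:i1]
    tau = episode.duration_s / 8.0
    max_lag = min(int(round(2 * band[1] * tau * fs)), len(x) - 2)
    if max_lag < int(band[0] * tau * fs):
        return None, None
    r = normalized_autocorr(x, max_lag)
    peaks, _ = sp_signal.find_peaks(r)

    def peak_in(lo_s: float, hi_s: float) -> Optional[float]:
        lo, hi = int(round(lo_s * fs)), int(round(hi_s * fs))
        cand = peaks[(peaks >= lo) & (peaks <= hi)]
        if len(cand) == 0:
            return None
        return float(r[cand[np.argmax(r[cand])]])

    step_reg = peak_in(band[0] * tau, band[1] * tau)
    stride_reg = peak_in((1 + band[0]) * tau, 2 * band[1] * tau)
    return step_reg, stride_reg


# -------------------------------------------------------------- aggregation


@dataclass
class BiomarkerPanel:
    """Per-day biomarker rows with validity flags and week aggregates."""

    subject_id: str
    days: pd.DataFrame  # BIOMARKER_COLUMNS schema, one row per day
    week: pd.Series  # mean over valid days
    valid: bool
    n_valid_days: int


def aggregate(
    day_rows: Sequence[dict],
    subject_id: str,
    wear_hours_required: float = 22.8,
    min_valid_days: int = 5,
) -> BiomarkerPanel:
    """Assemble daily rows into a subject panel.

    A day is valid with near-24-h wear (default ≥ 22.8 h, i.e. 95% of the
    day — exact 100% is unattainable once exclusions are applied) and at
    least one walking bout.  The week aggregate is the mean of each
    biomarker over valid days; the panel is valid with at least five valid
    days.
    """
    rows = []
    for i, r in enumerate(day_rows):
        row = {c: r.get(c) for c in BIOMARKER_COLUMNS}
        row["subject_id"] = subject_id
        row["day_index"] = r.get("day_index", i)
        wear_ok = (row.get("wear_hours") or 0.0) >= wear_hours_required
        bouts_ok = (row.get("n_walking_bouts") or 0) >= 1
        row["valid_day"] = bool(wear_ok and bouts_ok)
        rows.append(row)
    days = new_biomarker_table(rows)
    metric_cols = [
        c for c in BIOMARKER_COLUMNS
        if c not in ("subject_id", "day_index", "valid_day")
    ]
    valid_days = days[days["valid_day"].astype(bool)]
    week = valid_days[metric_cols].astype(float).mean(skipna=True) if len(valid_days) else pd.Series(dtype=float)
    return BiomarkerPanel(
        subject_id=subject_id,
        days=days,
        week=week,
        valid=len(valid_days) >= min_valid_days,
        n_valid_days=len(valid_days),
    )
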