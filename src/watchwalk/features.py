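"""Non-overlapping 4-s windows and the activity-classification feature vector.

Wear-time signal is tiled into 4-s frames (400 samples at 100 Hz).  Each
frame yields a named feature vector: distributional summaries of the crude
and static-removed Euclidean norms, inter-axis correlations, and
autocorrelation shape features of the gait band.  A window size of 4 s is
fixed — long enough to hold several steps at everyday cadences, short
enough to resolve the brief walking bouts that dominate daily life — and is
not configurable, to preserve comparability of the biomarkers.

The named 17-feature core set is always present; an extended set (axis
summaries, jerk, spectral features) brings the default dimensionality to 54.
Greedy backward elimination with permutation importance under
subject-partitioned cross-validation reduces a feature matrix to a target
dimensionality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import GroupKFold

from watchwalk.preprocess import ProcessedSignal

WINDOW_S = 4.0

CORE17 = [
    "en_sr_mean", "en_sr_sd", "en_sr_p25", "en_sr_p50", "en_sr_p75",
    "en_crude_mean", "en_crude_sd", "en_crude_p25", "en_crude_p50", "en_crude_p75",
    "corr_xy", "corr_xz", "corr_yz",
    "ac_peak", "ac_lag_s", "ac_ratio_12", "ac_ratio_13",
]

EXTENDED_EXTRA = [
    "ax_mean_x", "ax_mean_y", "ax_mean_z",
    "ax_sd_x", "ax_sd_y", "ax_sd_z",
    "ax_p25_x", "ax_p50_x", "ax_p75_x",
    "ax_p25_y", "ax_p50_y", "ax_p75_y",
    "ax_p25_z", "ax_p50_z", "ax_p75_z",
    "jerk_rms_x", "jerk_rms_y", "jerk_rms_z", "jerk_rms_en",
    "dom_freq_hz", "dom_freq_power_frac",
    "bandpower_0.25_0.5", "bandpower_0.5_1", "bandpower_1_2",
    "bandpower_2_3", "bandpower_3_5", "bandpower_5_10",
    "en_band_rms", "en_band_ptp",
    "zcr_band", "zcr_sr",
    "skew_sr", "kurt_sr", "skew_crude", "kurt_crude",
    "spec_entropy",
    "ac_lag2_s",
]

EXTENDED54 = CORE17 + EXTENDED_EXTRA

FEATURE_SETS = {"core17": CORE17, "extended54": EXTENDED54}


@dataclass
class Window4s:
    """One 4-s frame of all processed channels."""

    index: int
    start_s: float
    i0: int
    i1: int
    ps: ProcessedSignal
    valid: bool

    @property
    def en_crude(self) -> np.ndarray:
        return self.ps.en_crude[self.i0:self.i1]

    @property
    def en_static_removed(self) -> np.ndarray:
        return self.ps.en_static_removed[self.i0:self.i1]

    @property
    def en_lowpass(self) -> np.ndarray:
        return self.ps.en_lowpass[self.i0:self.i1]

    @property
    def en_band(self) -> np.ndarray:
        return self.ps.en_band[self.i0:self.i1]

    @property
    def axes(self) -> np.ndarray:
        return self.ps.axes[self.i0:self.i1]


def segment_windows(ps: ProcessedSignal, only_valid: bool = True) -> list[Window4s]:
    """Tile the recording into consecutive 4-s windows.

    Windows are laid out from the start of the recording in 4-s strides; a
    window is valid only when every one of its samples is inside wear time
    and outside sleep, so a tile straddling an exclusion boundary is marked
    invalid.  A partial tail shorter than 4 s is dropped.  With
    ``only_valid`` (default) invalid tiles are omitted from the result.
    """
    n_per = int(round(WINDOW_S * ps.fs))
    usable = ps.usable_mask
    out = []
    for idx, i0 in enumerate(range(0, ps.n_samples - n_per + 1, n_per)):
        i1 = i0 + n_per
        valid = bool(usable[i0:i1].all())
        if only_valid and not valid:
            continue
        out.append(Window4s(index=idx, start_s=i0 / ps.fs, i0=i0, i1=i1,
                            ps=ps, valid=valid))
    return out


def normalized_autocorr(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Unbiased autocorrelation normalized by the zero-lag value.

    r[k] = (Σ x_i x_{i+k} / (N−k)) / (Σ x_i² / N), so a strictly periodic
    signal attains r ≈ 1 at its period regardless of window length.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    max_lag = min(max_lag, n - 1)
    full = sp_signal.correlate(x, x, mode="full")[n - 1: n + max_lag]
    counts = n - np.arange(max_lag + 1)
    r = full / counts
    if r[0] <= 0:
        return np.zeros(max_lag + 1)
    return r / r[0]


def _autocorr_peaks(
    x: np.ndarray, fs: float, lag_range_s: tuple[float, float] = (0.2, 2.0)
) -> list[tuple[float, float]]:
    """(lag_s, value) of local autocorrelation maxima inside the lag range,
    ordered by lag (ties in value broken by the smaller lag by construction)."""
    lo = int(math.ceil(lag_range_s[0] * fs))
    hi = int(math.floor(lag_range_s[1] * fs))
    r = normalized_autocorr(x, hi)
    if hi <= lo + 1:
        return []
    peaks, _ = sp_signal.find_peaks(r[: hi + 1])
    peaks = peaks[peaks >= lo]
    return [(k / fs, float(r[k])) for k in peaks]


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return math.nan
    return float(np.corrcoef(a, b)[0, 1])


def _bandpower(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    sel = (freqs >= lo) & (freqs < hi)
    return float(np.trapezoid(psd[sel], freqs[sel])) if sel.any() else 0.0


def extract_features(
    w: Window4s, feature_set: str | Sequence[str] = "core17"
) -> dict[str, float]:
    """Compute the named feature vector of one window.

    Returns an ordered dict; features that are undefined for the window
    (correlations of a constant axis, autocorrelation peaks of a flat
    signal) are null (NaN), never silently zero.
    """
    names = FEATURE_SETS[feature_set] if isinstance(feature_set, str) else list(feature_set)
    fs = w.ps.fs
    sr = w.en_static_removed
    crude = w.en_crude
    band = w.en_band
    ax = w.axes

    f: dict[str, float] = {}
    for prefix, x in (("en_sr", sr), ("en_crude", crude)):
        f[f"{prefix}_mean"] = float(np.mean(x))
        f[f"{prefix}_sd"] = float(np.std(x, ddof=1))
        p25, p50, p75 = np.percentile(x, [25, 50, 75])
        f[f"{prefix}_p25"] = float(p25)
        f[f"{prefix}_p50"] = float(p50)
        f[f"{prefix}_p75"] = float(p75)

    f["corr_xy"] = _safe_corr(ax[:, 0], ax[:, 1])
    f["corr_xz"] = _safe_corr(ax[:, 0], ax[:, 2])
    f["corr_yz"] = _safe_corr(ax[:, 1], ax[:, 2])

    pk = _autocorr_peaks(band, fs)
    f["ac_peak"] = pk[0][1] if pk else math.nan
    f["ac_lag_s"] = pk[0][0] if pk else math.nan
    f["ac_ratio_12"] = pk[0][1] / pk[1][1] if len(pk) > 1 and pk[1][1] != 0 else math.nan
    f["ac_ratio_13"] = pk[0][1] / pk[2][1] if len(pk) > 2 and pk[2][1] != 0 else math.nan

    if any(n in EXTENDED_EXTRA for n in names):
        for k, axis in enumerate("xyz"):
            f[f"ax_mean_{axis}"] = float(np.mean(ax[:, k]))
            f[f"ax_sd_{axis}"] = float(np.std(ax[:, k], ddof=1))
            q = np.percentile(ax[:, k], [25, 50, 75])
            f[f"ax_p25_{axis}"], f[f"ax_p50_{axis}"], f[f"ax_p75_{axis}"] = map(float, q)
            f[f"jerk_rms_{axis}"] = float(np.sqrt(np.mean(np.diff(ax[:, k]) ** 2))) * fs
        f["jerk_rms_en"] = float(np.sqrt(np.mean(np.diff(w.en_lowpass) ** 2))) * fs

        freqs, psd = sp_signal.periodogram(band, fs=fs)
        total = psd[1:].sum()
        if total > 0:
            i_dom = 1 + int(np.argmax(psd[1:]))
            f["dom_freq_hz"] = float(freqs[i_dom])
            f["dom_freq_power_frac"] = float(psd[i_dom] / total)
        else:
            f["dom_freq_hz"] = math.nan
            f["dom_freq_power_frac"] = math.nan

        freqs_lp, psd_lp = sp_signal.periodogram(w.en_lowpass, fs=fs)
        for lo, hi in [(0.25, 0.5), (0.5, 1), (1, 2), (2, 3), (3, 5), (5, 10)]:
            key = f"bandpower_{lo:g}_{hi:g}"
            f[key] = _bandpower(freqs_lp, psd_lp, lo, hi)

        f["en_band_rms"] = float(np.sqrt(np.mean(band ** 2)))
        f["en_band_ptp"] = float(np.ptp(band))
        f["zcr_band"] = float(np.mean(np.diff(np.signbit(band)) != 0))
        f["zcr_sr"] = float(np.mean(np.diff(np.signbit(sr)) != 0))
        f["skew_sr"] = float(sp_stats.skew(sr)) if np.std(sr) > 0 else math.nan
        f["kurt_sr"] = float(sp_stats.kurtosis(sr)) if np.std(sr) > 0 else math.nan
        f["skew_crude"] = float(sp_stats.skew(crude)) if np.std(crude) > 0 else math.nan
        f["kurt_crude"] = float(sp_stats.kurtosis(crude)) if np.std(crude) > 0 else math.nan
        p_norm = psd[1:] / total if total > 0 else None
        if p_norm is not None:
            p_nz = p_norm[p_norm > 0]
            f["spec_entropy"] = float(-(p_nz * np.log(p_nz)).sum() / np.log(len(psd) - 1))
        else:
            f["spec_entropy"] = math.nan
        f["ac_lag2_s"] = pk[1][0] if len(pk) > 1 else math.nan

    return {n: f[n] for n in names}


def feature_matrix(
    windows: Sequence[Window4s], feature_set: str | Sequence[str] = "core17"
) -> tuple[np.ndarray, list[str]]:
    """Stack per-window feature vectors into an (n_windows, n_features)
    matrix; null features become 0.0 (the natural neutral value for
    correlations and autocorrelation peaks of silent windows)."""
    names = FEATURE_SETS[feature_set] if isinstance(feature_set, str) else list(feature_set)
    rows = [extract_features(w, names) for w in windows]
    X = np.array([[row[n] for n in names] for row in rows], dtype=float)
    X[~np.isfinite(X)] = 0.0
    return X, list(names)


def backward_select(
    X: np.ndarray,
    labels: Sequence,
    subject_ids: Sequence,
    feature_names: Sequence[str],
    target_dim: int,
    seed: int = 0,
    n_repeats: int = 5,
) -> list[str]:
    """Greedy backward elimination by permutation importance.

    At each round a classifier is fit on the training folds of a
    subject-partitioned split and permutation importance is measured on the
    validation folds; the least important feature is removed until
    ``target_dim`` remain.  Deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    groups = np.asarray(subject_ids)
    names = list(feature_names)
    if len(np.unique(labels)) < 2:
        raise ValueError("backward selection needs at least two classes")
    if len(np.unique(groups)) < 2:
        raise ValueError("backward selection needs at least two subjects")
    if target_dim >= X.shape[1]:
        raise ValueError(
            f"target_dim {target_dim} must be below feature count {X.shape[1]}"
        )
    if target_dim < 1:
        raise ValueError("target_dim must be positive")

    keep = list(range(X.shape[1]))
    n_splits = min(3, len(np.unique(groups)))
    rng = np.random.default_rng(seed)
    while len(keep) > target_dim:
        importance = np.zeros(len(keep))
        gkf = GroupKFold(n_splits=n_splits)
        for tr, va in gkf.split(X[:, keep], labels, groups):
            clf = RandomForestClassifier(
                n_estimators=100, random_state=int(rng.integers(2**31))
            )
            clf.fit(X[np.ix_(tr, keep)], labels[tr])
            pi = permutation_importance(
                clf, X[np.ix_(va, keep)], labels[va],
                n_repeats=n_repeats, random_state=int(rng.integers(2**31)),
            )
            importance += pi.importances_mean
        keep.pop(int(np.argmin(importance)))
    return [names[i] for i in keep]
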