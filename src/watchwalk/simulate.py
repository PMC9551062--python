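"""Synthetic wrist accelerometry with ground truth for every pipeline stage.

The generator emulates the signal classes the pipeline must handle:
periodic step accelerations at configurable cadence, six arm-carriage modes
(free arm-swing plus five carry modes that suppress the swing and change
the wrist orientation), running, stationary time, unstructured arm
activity, vehicle vibration, non-wear (near-constant signal) and sleep
(stable posture with physiological noise), assembled into multi-day
schedules.  Every realization is deterministic given its seed and carries
full ground truth: per-segment activity labels, step event times, walking
bouts and per-window true walking speed.

The wrist signal model: a 1 g gravity vector in a mode-specific orientation,
a half-sine impact transient per step along the vertical axis, an arm-swing
sinusoid at half the step frequency on the swing axis (each arm swings once
per stride, so the norm's autocorrelation peaks first at one step and again
at one stride), mode-specific axis coupling, and white noise.  True walking
speed follows a fixed smooth map of cadence, impact amplitude and stature,
so the speed regression has a recoverable target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from watchwalk.io import RawRecording

FS = 100.0

#: speed (m/s) = A*cadence(spm) + B*impact amplitude (g) + C*height (m) + D
SPEED_COEF = {"cadence": 0.006, "impact": 1.0, "height": 0.30, "intercept": -0.10}

#: wrist orientation (unit gravity vector) per activity
_ORIENT = {
    "walk_armswing": (0.25, 0.10, 0.96),
    "pocket": (0.85, 0.35, 0.40),
    "texting": (0.10, 0.90, 0.42),
    "phonecall": (0.60, 0.60, 0.53),
    "shoulderbag": (0.40, 0.15, 0.90),
    "briefcase": (0.80, 0.10, 0.59),
    "running": (0.20, 0.20, 0.96),
    "arm_activity_walking": (0.30, 0.30, 0.90),
    "stationary": (0.10, 0.25, 0.96),
    "arm_activity_static": (0.35, 0.45, 0.82),
    "vehicle": (0.15, 0.20, 0.97),
    "nonwear": (0.05, 0.05, 1.00),
    "sleep": (0.55, 0.25, 0.80),
}

WALK_MODES = ("walk_armswing", "pocket", "texting", "phonecall",
              "shoulderbag", "briefcase")

#: segment activity → coarse classification label
COARSE_OF = {
    "walk_armswing": "walk_armswing",
    "pocket": "walk_other",
    "texting": "walk_other",
    "phonecall": "walk_other",
    "shoulderbag": "walk_other",
    "briefcase": "walk_other",
    "running": "running",
    "stationary": "stationary",
    "vehicle": "stationary",
    "arm_activity_static": "arm_activity_static",
    "arm_activity_walking": "arm_activity_walking",
}


@dataclass
class Segment:
    """One scripted activity stretch."""

    activity: str
    duration_s: float
    cadence_spm: Optional[float] = None
    speed_ms: Optional[float] = None
    noise_sd_g: float = 0.02

    def __post_init__(self) -> None:
        if self.activity not in _ORIENT:
            raise ValueError(f"unknown activity {self.activity!r}")
        if self.duration_s <= 0:
            raise ValueError("segment duration must be positive")
        walkish = self.activity in WALK_MODES + ("running", "arm_activity_walking")
        if walkish:
            if self.cadence_spm is None:
                self.cadence_spm = 165.0 if self.activity == "running" else 110.0
            if not 60 <= self.cadence_spm <= 200:
                raise ValueError("cadence must be in [60, 200] spm")


@dataclass
class ActivityScript:
    """Ordered segments plus the master seed they are realized from."""

    segments: list[Segment]
    master_seed: int = 0
    height_m: float = 1.70
    subject_id: str = "sim"

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("script must contain at least one segment")
        total = sum(s.duration_s for s in self.segments)
        if total > 7 * 86400:
            raise ValueError("script exceeds 7 days")


@dataclass
class GroundTruth:
    """What the generator knows that the pipeline must recover."""

    segments: list[tuple[float, float, str]]  # (start_s, end_s, activity)
    step_times: np.ndarray
    bouts: list[tuple[float, float, str]]  # walking (start_s, end_s, activity)
    window_speed: dict[int, float] = field(default_factory=dict)  # 4-s window idx → m/s
    nonwear: list[tuple[float, float]] = field(default_factory=list)
    sleep: list[tuple[float, float]] = field(default_factory=list)
    true_speed: Optional[float] = None
    impact_amp_g: Optional[float] = None

    def label_at(self, t: float) -> str:
        for s0, s1, act in self.segments:
            if s0 <= t < s1:
                return act
        return self.segments[-1][2]


def speed_from_map(cadence_spm: float, impact_amp_g: float, height_m: float) -> float:
    """The generator's fixed smooth cadence/amplitude/stature → speed map."""
    c = SPEED_COEF
    return (c["cadence"] * cadence_spm + c["impact"] * impact_amp_g
            + c["height"] * height_m + c["intercept"])


def _impact_amp_for_speed(speed: float, cadence_spm: float, height_m: float) -> float:
    c = SPEED_COEF
    amp = (speed - c["cadence"] * cadence_spm - c["height"] * height_m
           - c["intercept"]) / c["impact"]
    return float(np.clip(amp, 0.05, 0.8))


def _orient(activity: str) -> np.ndarray:
    v = np.array(_ORIENT[activity], dtype=float)
    return v / np.linalg.norm(v)


def _swing_axis(g_vec: np.ndarray) -> np.ndarray:
    # a horizontal-ish axis orthogonal to gravity
    ref = np.array([1.0, 0.0, 0.0])
    if abs(g_vec @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    ax = np.cross(g_vec, ref)
    return ax / np.linalg.norm(ax)


def _step_train(
    cadence_spm: float, duration_s: float, jitter_frac: float, rng: np.random.Generator
) -> np.ndarray:
    """Jittered step event times within [0, duration).

    Exactly round(duration × cadence / 60) events: nominal times on the
    cadence grid, each perturbed independently by ``jitter_frac`` of a
    step period, so the realized count always matches the nominal cadence.
    """
    period = 60.0 / cadence_spm
    n = int(round(duration_s * cadence_spm / 60.0))
    k = np.arange(n)
    times = (k + 0.5) * period + period * jitter_frac * rng.standard_normal(n)
    return np.sort(times[(times > 0) & (times < duration_s - 0.1 * period)])


def _segment_signal(
    seg: Segment,
    height_m: float,
    rng: np.random.Generator,
    jitter_frac: float = 0.02,
    asymmetry: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, Optional[float], Optional[float]]:
    """(xyz array, step times, true speed, impact amplitude) of one segment."""
    n = int(round(seg.duration_s * FS))
    t = np.arange(n) / FS
    g_vec = _orient(seg.activity)
    xyz = np.tile(g_vec, (n, 1))
    act = seg.activity
    step_times = np.array([])
    speed = amp = None

    if act in WALK_MODES or act in ("running", "arm_activity_walking"):
        cadence = seg.cadence_spm
        if act == "running":
            amp = 0.55
            jitter = jitter_frac
        else:
            if seg.speed_ms is not None:
                amp = _impact_amp_for_speed(seg.speed_ms, cadence, height_m)
            else:
                amp = 0.25
            jitter = jitter_frac
        speed = None if act == "running" else speed_from_map(cadence, amp, height_m)
        step_times = _step_train(cadence, seg.duration_s, jitter, rng)

        impact = np.zeros(n)
        period = 60.0 / cadence
        half_w = max(3, int(round(0.25 * period * FS)))
        bump = np.sin(np.linspace(0, np.pi, 2 * half_w))
        for i, st in enumerate(step_times):
            k = int(round(st * FS))
            a = amp * (1.0 + asymmetry * (1 if i % 2 == 0 else -1))
            lo, hi = max(0, k - half_w), min(n, k + half_w)
            impact[lo:hi] += a * bump[(lo - (k - half_w)):(hi - (k - half_w))]
        xyz += np.outer(impact, g_vec)

        f_step = cadence / 60.0
        if act == "walk_armswing":
            swing = 0.30 * np.sin(np.pi * f_step * t)  # half step frequency
            xyz += np.outer(swing, _swing_axis(g_vec))
        elif act == "arm_activity_walking":
            # irregular arm use superimposed on walking
            arm = _smooth_noise(n, 0.25, rng, lo_hz=0.3, hi_hz=1.5)
            xyz += np.outer(arm, _swing_axis(g_vec))
        else:
            # carry modes: small body-rocking component at step frequency,
            # coupled into two axes to shape the correlations
            rock = 0.06 * np.sin(2 * np.pi * f_step * t)
            xyz[:, 0] += rock
            xyz[:, 1] += 0.5 * rock

    elif act == "arm_activity_static":
        for k, scale in ((0, 0.30), (1, 0.25), (2, 0.15)):
            xyz[:, k] += _smooth_noise(n, scale, rng, lo_hz=0.3, hi_hz=1.5)
    elif act == "vehicle":
        f1, f2 = rng.uniform(0.1, 0.3), rng.uniform(0.3, 0.45)
        vib = 0.04 * np.sin(2 * np.pi * f1 * t) + 0.03 * np.sin(2 * np.pi * f2 * t + 1.0)
        xyz[:, 2] += vib
    elif act == "sleep":
        # slow postural drift, far below the 5°/5 s sleep-angle criterion
        drift = 0.02 * np.sin(2 * np.pi * t / 3600.0)
        xyz[:, 0] += drift
    elif act == "nonwear":
        # off-body: microjitter only, per-axis SD well under 13 mg
        xyz += rng.normal(0.0, 0.003, size=(n, 3))
        return xyz, step_times, speed, amp

    xyz += rng.normal(0.0, seg.noise_sd_g, size=(n, 3))
    return xyz, step_times, speed, amp


def _smooth_noise(
    n: int, sd: float, rng: np.random.Generator, lo_hz: float, hi_hz: float
) -> np.ndarray:
    """Band-limited Gaussian noise, scaled to the requested SD."""
    from scipy import signal as sp_signal

    white = rng.standard_normal(n + 400)
    sos = sp_signal.butter(2, [lo_hz, hi_hz], btype="bandpass", fs=FS, output="sos")
    out = sp_signal.sosfilt(sos, white)[400:]
    s = out.std()
    return out * (sd / s) if s > 0 else out


def simulate_walk(
    cadence_spm: float = 110.0,
    speed_ms: Optional[float] = None,
    arm_mode: str = "walk_armswing",
    duration_s: float = 60.0,
    noise_sd_g: float = 0.02,
    seed: int = 0,
    height_m: float = 1.70,
    jitter_frac: float = 0.02,
    asymmetry: float = 0.0,
) -> tuple[RawRecording, GroundTruth]:
    """One continuous walk in a single arm-carriage mode.

    ``speed_ms`` fixes the true walking speed (the impact amplitude is
    derived through the inverse of the speed map); left unset, the default
    impact amplitude determines the speed.  ``asymmetry`` alternates
    left/right impact amplitudes to create stride-level structure.
    """
    if arm_mode not in WALK_MODES + ("running", "arm_activity_walking"):
        raise ValueError(f"{arm_mode!r} is not a walking/running mode")
    rng = np.random.default_rng(seed)
    seg = Segment(arm_mode, duration_s, cadence_spm=cadence_spm,
                  speed_ms=speed_ms, noise_sd_g=noise_sd_g)
    xyz, step_times, speed, amp = _segment_signal(
        seg, height_m, rng, jitter_frac=jitter_frac, asymmetry=asymmetry
    )
    rec = RawRecording(
        subject_id=f"sim-walk-{seed}",
        start_time=pd.Timestamp("2013-06-03 10:00:00"),
        fs=FS,
        samples=xyz,
        height_m=height_m,
        meta={"generator": "simulate_walk", "seed": seed},
    )
    window_speed = {}
    if speed is not None:
        for wi in range(int(duration_s // 4)):
            window_speed[wi] = speed
    gt = GroundTruth(
        segments=[(0.0, duration_s, arm_mode)],
        step_times=step_times,
        bouts=[(0.0, duration_s, arm_mode)],
        window_speed=window_speed,
        true_speed=speed,
        impact_amp_g=amp,
    )
    return rec, gt


def simulate_day(script: ActivityScript) -> tuple[RawRecording, GroundTruth]:
    """Realize a scripted schedule into one continuous recording.

    Segments are concatenated with a 1-s crossfade from the previous
    segment's final posture, so orientation changes are smooth rather than
    instantaneous steps.
    """
    rng = np.random.default_rng(script.master_seed)
    parts, seg_spans, all_steps, bouts = [], [], [], []
    nonwear, sleep = [], []
    window_speed: dict[int, float] = {}
    t0 = 0.0
    for seg in script.segments:
        seg_rng = np.random.default_rng(rng.integers(2**31))
        xyz, st, speed, _ = _segment_signal(seg, script.height_m, seg_rng)
        if parts:  # crossfade from the previous posture over 1 s
            prev_last = parts[-1][-1]
            L = min(int(FS), len(xyz))
            w = np.linspace(0.0, 1.0, L)[:, None]
            xyz[:L] = w * xyz[:L] + (1 - w) * prev_last
        parts.append(xyz)
        seg_spans.append((t0, t0 + seg.duration_s, seg.activity))
        if len(st):
            all_steps.append(st + t0)
        if seg.activity in WALK_MODES + ("arm_activity_walking",):
            bouts.append((t0, t0 + seg.duration_s, seg.activity))
            if speed is not None:
                first_w = int(np.ceil(t0 / 4.0))
                last_w = int((t0 + seg.duration_s) // 4)
                for wi in range(first_w, last_w):
                    window_speed[wi] = speed
        elif seg.activity == "nonwear":
            nonwear.append((t0, t0 + seg.duration_s))
        elif seg.activity == "sleep":
            sleep.append((t0, t0 + seg.duration_s))
        t0 += seg.duration_s

    rec = RawRecording(
        subject_id=script.subject_id,
        start_time=pd.Timestamp("2013-06-03 00:00:00"),
        fs=FS,
        samples=np.vstack(parts),
        height_m=script.height_m,
        meta={"generator": "simulate_day", "seed": script.master_seed},
    )
    gt = GroundTruth(
        segments=seg_spans,
        step_times=np.concatenate(all_steps) if all_steps else np.array([]),
        bouts=bouts,
        window_speed=window_speed,
        nonwear=nonwear,
        sleep=sleep,
    )
    return rec, gt


def truth_window_labels(
    gt: GroundTruth, windows: Sequence
) -> tuple[np.ndarray, np.ndarray]:
    """(coarse, refined) ground-truth labels of each 4-s window, by the
    activity at the window midpoint."""
    coarse = []
    refined = []
    for w in windows:
        act = gt.label_at(w.start_s + 2.0)
        c = COARSE_OF.get(act, "stationary")
        coarse.append(c)
        refined.append(act if c == "walk_other" else None)
    return np.array(coarse, dtype=object), np.array(refined, dtype=object)


def mixed_day_script(seed: int, subject_id: str = "sim") -> ActivityScript:
    """A compact daily-life schedule covering all six coarse classes.

    Per-subject latent traits (cadence, walking speed, stature, noise) are
    drawn from realistic population ranges so that windows within a subject
    are correlated — the regime subject-partitioned CV exists for.
    """
    rng = np.random.default_rng(seed)
    cad = float(rng.uniform(95, 125))
    speed = float(rng.uniform(1.1, 1.6))
    height = float(rng.uniform(1.55, 1.90))
    noise = float(rng.uniform(0.015, 0.035))
    segs = [
        Segment("stationary", 120, noise_sd_g=noise),
        Segment("walk_armswing", 64, cadence_spm=cad, speed_ms=speed, noise_sd_g=noise),
        Segment("arm_activity_static", 60, noise_sd_g=noise),
        Segment("pocket", 48, cadence_spm=cad, speed_ms=speed, noise_sd_g=noise),
        Segment("texting", 48, cadence_spm=cad * 0.95, speed_ms=speed * 0.9, noise_sd_g=noise),
        Segment("running", 48, cadence_spm=float(rng.uniform(150, 180)), noise_sd_g=noise),
        Segment("walk_armswing", 48, cadence_spm=cad, speed_ms=speed, noise_sd_g=noise),
        Segment("phonecall", 40, cadence_spm=cad, speed_ms=speed, noise_sd_g=noise),
        Segment("arm_activity_walking", 48, cadence_spm=cad, noise_sd_g=noise),
        Segment("stationary", 80, noise_sd_g=noise),
        Segment("shoulderbag", 40, cadence_spm=cad, speed_ms=speed, noise_sd_g=noise),
        Segment("briefcase", 40, cadence_spm=cad, speed_ms=speed, noise_sd_g=noise),
        Segment("vehicle", 60, noise_sd_g=noise),
    ]
    return ActivityScript(segments=segs, master_seed=seed, height_m=height,
                          subject_id=subject_id)


def simulate_speed_dataset(
    n_walks: int = 25,
    master_seed: int = 0,
    noise_frac: float = 0.02,
    walk_duration_s: float = 124.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Walking windows with the 7 speed-regression features and noisy truth.

    Each walk draws a cadence, stature and impact amplitude; its true speed
    follows :func:`speed_from_map`, and per-window observed speed adds
    ``noise_frac`` relative Gaussian noise (the measurement error of a
    reference walkway).  Returns (X, speed, walk_ids) ready for
    :func:`watchwalk.biomarkers.train_speed_model`.
    """
    from watchwalk import features, preprocess
    from watchwalk.biomarkers import speed_feature_vector

    rng = np.random.default_rng(master_seed)
    X, y, g = [], [], []
    for w in range(n_walks):
        cad = rng.uniform(85, 135)
        h = rng.uniform(1.55, 1.90)
        speed = speed_from_map(cad, rng.uniform(0.12, 0.40), h)
        rec, gt = simulate_walk(
            cadence_spm=cad, speed_ms=speed, duration_s=walk_duration_s,
            noise_sd_g=0.02, seed=int(rng.integers(2**31)), height_m=h,
        )
        ps = preprocess.compute_channels(rec)
        for win in features.segment_windows(ps):
            fv = speed_feature_vector(win, h, ps.fs)
            if fv is not None:
                X.append(fv)
                y.append(gt.true_speed * (1 + noise_frac * rng.standard_normal()))
                g.append(w)
    return np.vstack(X), np.asarray(y), np.asarray(g)


def simulate_cohort(
    n_per_group: int,
    group_effects: dict[str, dict[str, float]],
    n_days: int = 7,
    master_seed: int = 0,
    base_means: Optional[dict[str, float]] = None,
    between_sd: Optional[dict[str, float]] = None,
    within_sd: Optional[dict[str, float]] = None,
    day_sd: Optional[dict[str, float]] = None,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Panel-level cohort generator with known variance components.

    Each biomarker value is  base + group shift + subject effect (SD
    ``between_sd``) + day effect (SD ``day_sd``) + residual (SD
    ``within_sd``), which makes the analytic ICC(2,k) of the generating
    model available as ground truth:

        ICC = σ²_b / (σ²_b + (σ²_day + σ²_w) / k).

    Returns (long per-day dataframe, per-subject group labels, truth dict
    with the analytic ICC and the group shifts).
    """
    if n_per_group < 2:
        raise ValueError("need at least two subjects per group")
    base_means = base_means or {
        "speed_p95": 1.43, "steps_per_day": 8000.0, "cadence_median_spm": 105.0
    }
    biomarkers = list(base_means)
    between_sd = between_sd or {b: 0.05 * abs(base_means[b]) for b in biomarkers}
    within_sd = within_sd or {b: 0.02 * abs(base_means[b]) for b in biomarkers}
    day_sd = day_sd or {b: 0.0 for b in biomarkers}

    rng = np.random.default_rng(master_seed)
    rows = []
    groups = {}
    for g, shifts in group_effects.items():
        for i in range(n_per_group):
            sid = f"{g}-{i:03d}"
            groups[sid] = g
            subj_eff = {b: rng.normal(0.0, between_sd[b]) for b in biomarkers}
            day_eff = {b: rng.normal(0.0, day_sd[b], size=n_days) for b in biomarkers}
            for d in range(n_days):
                row = {"subject_id": sid, "group": g, "day_index": d}
                for b in biomarkers:
                    row[b] = (base_means[b] + shifts.get(b, 0.0) + subj_eff[b]
                              + day_eff[b][d] + rng.normal(0.0, within_sd[b]))
                rows.append(row)
    df = pd.DataFrame(rows)
    truth = {
        "icc": {
            b: between_sd[b] ** 2
            / (between_sd[b] ** 2 + (day_sd[b] ** 2 + within_sd[b] ** 2) / n_days)
            for b in biomarkers
        },
        "group_shifts": group_effects,
        "n_days": n_days,
    }
    return df, pd.Series(groups, name="group"), truth
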