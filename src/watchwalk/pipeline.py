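"""End-to-end orchestration: recording → per-day biomarker panel.

Wires the stages together: channel derivation, non-wear/sleep exclusion,
windowing, activity labels (from fitted classifiers or supplied ground
truth), bout assembly, step detection, and the per-day biomarker panel.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np

from watchwalk import biomarkers as bm
from watchwalk import classify, features, preprocess, steps
from watchwalk.io import RawRecording
from watchwalk.steps import StepDetectionParams, WALKING_LABELS


def day_spans(rec: RawRecording) -> list[tuple[float, float]]:
    """[start, end) spans in seconds-from-start, split at local midnight."""
    start = rec.start_time
    first_midnight = (start.normalize() + np.timedelta64(1, "D") - start).total_seconds()
    edges = [0.0]
    t = first_midnight if first_midnight > 0 else 86400.0
    while t < rec.duration_s:
        edges.append(t)
        t += 86400.0
    edges.append(rec.duration_s)
    return [(a, b) for a, b in zip(edges[:-1], edges[1:]) if b - a > 1.0]


def extract_panel(
    rec: RawRecording,
    coarse_labels: Optional[Sequence[str]] = None,
    refined_labels: Optional[Sequence[Optional[str]]] = None,
    labeler: Optional[Callable] = None,
    coarse_model: Optional[classify.ClassifierModel] = None,
    refined_model: Optional[classify.ClassifierModel] = None,
    speed_model: Optional[bm.SpeedModel] = None,
    feature_set: str = "core17",
    step_params: StepDetectionParams = StepDetectionParams(),
    detect_exclusions: bool = True,
    wear_hours_required: float = 22.8,
) -> bm.BiomarkerPanel:
    """Run the full pipeline on one recording.

    Activity labels come from ground truth (``coarse_labels`` aligned to
    the valid windows), from a ``labeler`` callback invoked on the windows
    this function derives (returning coarse and refined label arrays), or
    from fitted classifier models; one of the three must be supplied.  Gait-quality measures (cadence, step-time
    variability, harmonic ratio, regularity) and speed estimates are
    restricted to arm-swing walking, matching their definition; quantity
    measures use all walking.
    """
    ps = preprocess.compute_channels(rec)
    if detect_exclusions:
        intervals = preprocess.detect_nonwear(ps)
        if rec.duration_s >= 3600:
            intervals += preprocess.detect_sleep(ps)
        ps = preprocess.apply_exclusions(ps, intervals)
    windows = features.segment_windows(ps)

    if coarse_labels is None and labeler is not None:
        coarse_labels, refined_labels = labeler(windows)
    if coarse_labels is None:
        if coarse_model is None:
            raise ValueError("supply coarse_labels, a labeler or a coarse_model")
        X, _ = features.feature_matrix(windows, coarse_model.feature_names)
        coarse_arr, refined_arr = classify.predict_two_stage(
            coarse_model, refined_model, X
        )
    else:
        coarse_arr = np.asarray(coarse_labels, dtype=object)
        refined_arr = (np.asarray(refined_labels, dtype=object)
                       if refined_labels is not None
                       else np.full(len(coarse_arr), None, dtype=object))
    if len(coarse_arr) != len(windows):
        raise ValueError("labels must align with the valid windows")

    bouts = steps.assemble_bouts(coarse_arr, windows, refined=refined_arr)
    bouts = [steps.detect_steps(b, ps, step_params) for b in bouts]

    day_rows = []
    for di, span in enumerate(day_spans(rec)):
        lo, hi = span
        in_day = [b for b in bouts if b.start_s < hi and b.end_s > lo]
        row: dict = {"day_index": di}
        row["wear_hours"] = float(
            ps.usable_mask[int(lo * ps.fs): int(hi * ps.fs)].sum() / ps.fs / 3600.0
        )
        row["n_walking_bouts"] = len(in_day)
        row["steps_per_day"] = steps.count_daily_steps(bouts, span)
        if in_day:
            row["longest_walk_s"] = max(b.duration_s for b in in_day)
            row.update(bm.arm_mode_proportions(in_day))
            row["step_walk_gradient_x100"] = bm.step_walk_gradient(in_day)
            le8, le60 = bm.walk_duration_percentages(in_day)
            row["walks_le_8s_pct"] = le8
            row["walks_le_60s_pct"] = le60

        win_in_day = [
            (i, w) for i, w in enumerate(windows) if lo <= w.start_s < hi
        ]
        row["running_min"] = float(
            sum(1 for i, _ in win_in_day if coarse_arr[i] == "running") * 4.0 / 60.0
        )

        armswing = [b for b in in_day if b.arm_mode == "walk_armswing"]
        episodes = [ep for b in armswing for ep in bm.make_episodes(b)]
        if episodes:
            cadences = np.array([ep.cadence_spm for ep in episodes])
            row["cadence_median_spm"] = float(np.median(cadences))
            q25, q75 = np.percentile(cadences, [25, 75])
            row["cadence_iqr_spm"] = float(q75 - q25)
            row["step_time_var_mode_s"] = bm.step_time_variability_mode(
                [ep.step_time_sd_s for ep in episodes]
            )
            hrs = [bm.harmonic_ratio_8step(ep, ps) for ep in episodes]
            hrs = [h for h in hrs if np.isfinite(h)]
            row["hr8"] = float(np.mean(hrs)) if hrs else None
            regs = [bm.regularity(ep, ps) for ep in episodes]
            step_r = [r[0] for r in regs if r[0] is not None]
            stride_r = [r[1] for r in regs if r[1] is not None]
            row["step_regularity_pct"] = 100.0 * float(np.mean(step_r)) if step_r else None
            row["stride_regularity_pct"] = 100.0 * float(np.mean(stride_r)) if stride_r else None

        if speed_model is not None and rec.height_m is not None:
            armswing_windows = {
                i for b in in_day if b.arm_mode == "walk_armswing"
                for i in b.window_indices
            }
            feats = []
            for i in sorted(armswing_windows):
                fv = bm.speed_feature_vector(windows[i], rec.height_m, ps.fs)
                if fv is not None:
                    feats.append(fv)
            if feats:
                speeds = speed_model.predict(np.vstack(feats))
                med, p95, iqr = bm.daily_speed_summary(speeds)
                row["speed_median"], row["speed_p95"], row["speed_iqr"] = med, p95, iqr
        day_rows.append(row)

    return bm.aggregate(day_rows, rec.subject_id,
                        wear_hours_required=wear_hours_required)
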