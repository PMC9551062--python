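import numpy as np
import pytest
from scipy import signal as sp_signal

from watchwalk import preprocess
from watchwalk.preprocess import ExclusionInterval, TooShortError
from watchwalk.simulate import ActivityScript, Segment, simulate_day
from tests.conftest import make_recording

FS = 100.0


def _sine_recording(freq_hz, duration_s=300.0, amplitude=1.0, offset=1.0):
    t = np.arange(int(duration_s * FS)) / FS
    z = offset + amplitude * np.sin(2 * np.pi * freq_hz * t)
    xyz = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    return make_recording(xyz)


class TestComputeChannels:
    def test_static_gravity_removed(self):
        rec = make_recording(np.tile([0.0, 0.0, 1.0], (int(300 * FS), 1)))
        ps = preprocess.compute_channels(rec)
        assert np.allclose(ps.en_crude, 1.0)
        interior = slice(int(60 * FS), -int(60 * FS))
        assert np.max(np.abs(ps.en_static_removed[interior])) < 1e-9

    def test_band_channel_passes_step_frequency(self):
        # 1.8 Hz is inside the 0.25-2.5 Hz gait band
        rec = _sine_recording(1.8, amplitude=0.5)
        ps = preprocess.compute_channels(rec)
        interior = slice(int(60 * FS), -int(60 * FS))
        ratio = np.ptp(ps.en_band[interior]) / np.ptp(ps.en_static_removed[interior])
        assert ratio >= 0.9

    def test_lowpass_attenuates_machine_noise(self):
        rec = _sine_recording(30.0, amplitude=0.2)
        ps = preprocess.compute_channels(rec)
        interior = slice(int(60 * FS), -int(60 * FS))
        assert np.ptp(ps.en_lowpass[interior]) < 0.1 * np.ptp(ps.en_static_removed[interior])

    def test_lowpass_idempotent_in_passband(self):
        t = np.arange(int(300 * FS)) / FS
        x = np.sin(2 * np.pi * 1.0 * t)
        sos = sp_signal.butter(5, 20.0, btype="low", fs=FS, output="sos")
        once = sp_signal.sosfiltfilt(sos, x)
        twice = sp_signal.sosfiltfilt(sos, once)
        interior = slice(int(10 * FS), -int(10 * FS))
        assert np.ptp(twice[interior]) > 0.99 * np.ptp(once[interior])

    def test_short_recording_rejected(self):
        rec = make_recording(np.tile([0.0, 0.0, 1.0], (int(100 * FS), 1)))
        with pytest.raises(TooShortError):
            preprocess.compute_channels(rec)


def _day_with_block(block_minutes, block_activity="nonwear", noise=None):
    segs = [
        Segment("walk_armswing", 300),
        Segment(block_activity, block_minutes * 60,
                **({"noise_sd_g": noise} if noise else {})),
        Segment("walk_armswing", 300),
    ]
    rec, _ = simulate_day(ActivityScript(segments=segs, master_seed=11))
    return preprocess.compute_channels(rec)


class TestDetectNonwear:
    def test_60_min_constant_block_flagged_within_one_minute(self):
        ps = _day_with_block(60)
        ivs = preprocess.detect_nonwear(ps)
        assert len(ivs) == 1
        iv = ivs[0]
        assert abs(iv.start_s - 300) <= 60
        assert abs(iv.end_s - (300 + 3600)) <= 60

    def test_49_min_block_below_duration_threshold(self):
        ps = _day_with_block(49)
        assert preprocess.detect_nonwear(ps) == []

    def test_block_with_20_mg_sd_not_flagged(self):
        # worn but still: physiological noise above the 13 mg rule
        ps = _day_with_block(60, block_activity="stationary", noise=0.020)
        assert preprocess.detect_nonwear(ps) == []

    def test_invariant_small_noise_on_constant_block_still_flagged(self):
        # adding band-limited noise with per-axis SD <= 5 mg keeps SD <= 13 mg
        ps = _day_with_block(60)
        rng = np.random.default_rng(3)
        noisy_axes = ps.axes + rng.normal(0, 0.005, ps.axes.shape)
        ps2 = preprocess.ProcessedSignal(
            fs=ps.fs, en_crude=ps.en_crude, en_static_removed=ps.en_static_removed,
            en_lowpass=ps.en_lowpass, en_band=ps.en_band, axes=noisy_axes,
        )
        assert len(preprocess.detect_nonwear(ps2)) == 1


class TestDetectSleep:
    def test_long_still_posture_recovered(self):
        segs = [
            Segment("walk_armswing", 3600),
            Segment("arm_activity_static", 3600),
            Segment("sleep", 8 * 3600),
            Segment("walk_armswing", 3600),
            Segment("stationary", 1200),
        ]
        rec, gt = simulate_day(ActivityScript(segments=segs, master_seed=2))
        ps = preprocess.compute_channels(rec)
        ivs = preprocess.detect_sleep(ps)
        assert len(ivs) >= 1
        true_lo, true_hi = gt.sleep[0]
        best = max(ivs, key=lambda iv: min(iv.end_s, true_hi) - max(iv.start_s, true_lo))
        overlap = min(best.end_s, true_hi) - max(best.start_s, true_lo)
        assert overlap >= 0.9 * (true_hi - true_lo)

    def test_fully_active_day_yields_no_sleep(self):
        segs = [Segment("walk_armswing", 1200), Segment("arm_activity_static", 1200),
                Segment("walk_armswing", 1200), Segment("arm_activity_static", 1200)]
        rec, _ = simulate_day(ActivityScript(segments=segs, master_seed=4))
        ps = preprocess.compute_channels(rec)
        assert preprocess.detect_sleep(ps) == []

    def test_sub_hour_recording_rejected(self):
        rec = make_recording(np.tile([0.0, 0.0, 1.0], (int(1800 * FS), 1)))
        ps = preprocess.compute_channels(rec)
        with pytest.raises(TooShortError):
            preprocess.detect_sleep(ps)


@pytest.fixture(scope="module")
def ps():
    rec = make_recording(np.tile([0.0, 0.0, 1.0], (int(7200 * FS), 1)))
    return preprocess.compute_channels(rec)


class TestApplyExclusions:

    def test_empty_interval_list_leaves_masks(self, ps):
        out = preprocess.apply_exclusions(ps, [])
        assert out.wear_mask.all()
        assert not out.sleep_mask.any()

    def test_nonwear_interval_clears_exact_span(self, ps):
        out = preprocess.apply_exclusions(
            ps, [ExclusionInterval("nonwear", 1800.0, 5400.0)]
        )
        i0, i1 = int(1800 * FS), int(5400 * FS)
        assert not out.wear_mask[i0:i1].any()
        assert out.wear_mask[:i0].all() and out.wear_mask[i1:].all()

    def test_overlapping_kinds_exclude_the_union(self, ps):
        out = preprocess.apply_exclusions(ps, [
            ExclusionInterval("nonwear", 1000.0, 3000.0),
            ExclusionInterval("sleep", 2000.0, 4000.0),
        ])
        expected = np.ones(ps.n_samples, dtype=bool)
        expected[int(1000 * FS): int(4000 * FS)] = False
        assert np.array_equal(out.usable_mask, expected)

    def test_out_of_span_interval_rejected(self, ps):
        with pytest.raises(ValueError):
            preprocess.apply_exclusions(
                ps, [ExclusionInterval("sleep", 7000.0, 9000.0)]
            )
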