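import numpy as np
import pytest

from watchwalk import biomarkers as bm
from watchwalk.simulate import simulate_speed_dataset
from watchwalk.steps import WalkingBout
from tests.conftest import make_signal

FS = 100.0


def _bout(duration_s, steps=None, arm_mode="walk_armswing", start_s=0.0):
    st = (np.linspace(start_s + 0.5, start_s + duration_s - 0.5, steps)
          if steps else np.array([]))
    return WalkingBout(start_s, start_s + duration_s, [], arm_mode, step_times=st)


class TestCumulativeExposure:
    def test_hand_evaluated_example(self):
        assert bm.cumulative_exposure([10, 20, 70], 20) == pytest.approx(30.0)

    def test_threshold_at_max_reaches_100(self):
        assert bm.cumulative_exposure([10, 20, 70], 70) == pytest.approx(100.0)

    def test_threshold_below_min_is_zero(self):
        assert bm.cumulative_exposure([10, 20, 70], 5) == 0.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(4, 600, 50)
        xs = [bm.cumulative_exposure(d, di) for di in np.sort(d)]
        assert all(a <= b + 1e-12 for a, b in zip(xs, xs[1:]))
        assert xs[-1] == pytest.approx(100.0)

    def test_empty_durations_rejected(self):
        with pytest.raises(ValueError):
            bm.cumulative_exposure([], 10)


class TestWalkDurationPercentages:
    def test_counts_against_thresholds(self):
        bouts = [_bout(4), _bout(8), _bout(120)]
        le8, le60 = bm.walk_duration_percentages(bouts)
        assert le8 == pytest.approx(100 * 2 / 3, abs=0.05)
        assert le60 == pytest.approx(100 * 2 / 3, abs=0.05)

    def test_all_short_walks_hit_100_at_both(self):
        bouts = [_bout(4)] * 5
        assert bm.walk_duration_percentages(bouts) == (100.0, 100.0)

    def test_single_long_walk_is_zero_at_8s(self):
        le8, le60 = bm.walk_duration_percentages([_bout(300)])
        assert le8 == 0.0 and le60 == 0.0

    def test_empty_gives_nulls(self):
        assert bm.walk_duration_percentages([]) == (None, None)


class TestStepWalkGradient:
    @staticmethod
    def _bin_centre_sizes(n_bins=12):
        # one walk size per log-spaced bin of the fitted histogram, so the
        # exact power-law counts translate directly into bin counts
        edges = np.geomspace(8, 512, n_bins + 1)
        return np.sqrt(edges[:-1] * edges[1:])

    def test_recovers_power_law_exponent(self):
        # walk counts drawn exactly from count ∝ size^(-1.2), sizes 8..512
        bouts = []
        for s in self._bin_centre_sizes():
            count = max(1, int(round(20000 * s ** (-1.2))))
            bouts += [_bout(s / 2, steps=int(round(s)))] * count
        grad = bm.step_walk_gradient(bouts, n_bins=12)
        assert grad == pytest.approx(-120.0, abs=2.0)

    def test_uniform_counts_give_flat_gradient(self):
        bouts = [b for s in self._bin_centre_sizes()
                 for b in [_bout(s / 2, steps=int(round(s)))] * 10]
        assert bm.step_walk_gradient(bouts, n_bins=12) == pytest.approx(0.0, abs=2.0)

    def test_too_few_bins_gives_null(self):
        bouts = [_bout(10, steps=20)] * 5 + [_bout(20, steps=40)] * 5
        assert bm.step_walk_gradient(bouts) is None


class TestArmModeProportions:
    def test_single_mode_is_100(self):
        props = bm.arm_mode_proportions([_bout(60)])
        assert props["arm_swing_prop"] == pytest.approx(100.0)

    def test_durations_weight_the_split(self):
        props = bm.arm_mode_proportions([_bout(60), _bout(40, arm_mode="texting")])
        assert props["arm_swing_prop"] == pytest.approx(60.0)
        assert props["texting_prop"] == pytest.approx(40.0)

    def test_proportions_conserve_100(self):
        rng = np.random.default_rng(1)
        modes = list(bm.ARM_MODE_COLUMNS)
        bouts = [_bout(rng.uniform(4, 300), arm_mode=rng.choice(modes))
                 for _ in range(40)]
        props = bm.arm_mode_proportions(bouts)
        assert sum(props.values()) == pytest.approx(100.0, abs=1e-9)

    def test_no_walking_gives_nulls(self):
        assert all(v is None for v in bm.arm_mode_proportions([]).values())


class TestEpisodes:
    def test_18_step_walk_yields_two_episodes(self):
        assert len(bm.make_episodes(_bout(10, steps=18))) == 2

    def test_7_steps_yield_none(self):
        assert bm.make_episodes(_bout(4, steps=7)) == []

    def test_even_half_second_steps_give_cadence_120(self):
        st = 0.5 + 0.5 * np.arange(8)
        (ep,) = bm.make_episodes(WalkingBout(0, 5, [], "walk_armswing", step_times=st))
        assert ep.duration_s == pytest.approx(4.0)
        assert ep.cadence_spm == pytest.approx(120.0)
        assert ep.step_time_sd_s == pytest.approx(0.0)


class TestLogNormalMode:
    def test_sampled_mode_matches_closed_form(self):
        rng = np.random.default_rng(2)
        sds = rng.lognormal(-3.5, 0.5, 1000)
        mode = bm.step_time_variability_mode(sds)
        assert mode == pytest.approx(np.exp(-3.75), rel=0.05)

    def test_degenerate_equal_values(self):
        assert bm.step_time_variability_mode([0.03] * 20) == pytest.approx(0.03)

    def test_nonpositive_filtered_and_minimum_count_enforced(self):
        assert bm.step_time_variability_mode([0.0] * 50) is None
        assert bm.step_time_variability_mode([0.02] * 9) is None
        assert bm.step_time_variability_mode([0.02] * 9 + [0.0, 0.02]) is not None


def _episode_at_cadence(step_time_s=0.5, start=0.0):
    st = start + step_time_s * np.arange(8)
    return bm.EightStepEpisode(
        step_times=st,
        duration_s=8 * step_time_s,
        cadence_spm=480.0 / (8 * step_time_s),
        step_time_sd_s=0.0,
    )


class TestHarmonicRatio:
    def test_pure_step_frequency_energy_is_stabilising(self):
        t = np.arange(500) / FS
        ps = make_signal(np.sin(2 * np.pi * 2.0 * t))  # step freq for 0.5 s steps
        hr = bm.harmonic_ratio_8step(_episode_at_cadence(0.5), ps)
        assert hr >= 5.0

    def test_stride_odd_energy_is_destabilising(self):
        t = np.arange(500) / FS
        ps = make_signal(np.sin(2 * np.pi * 1.0 * t))  # half the step frequency
        hr = bm.harmonic_ratio_8step(_episode_at_cadence(0.5), ps)
        assert hr <= 0.2

    def test_hr_decreases_monotonically_with_stride_asymmetry(self):
        t = np.arange(500) / FS
        step = np.sin(2 * np.pi * 2.0 * t)
        stride = np.sin(2 * np.pi * 1.0 * t)
        hrs = [
            bm.harmonic_ratio_8step(_episode_at_cadence(0.5),
                                    make_signal(step + a * stride))
            for a in [0.0, 0.1, 0.2, 0.4, 0.8]
        ]
        assert all(a > b for a, b in zip(hrs, hrs[1:]))


class TestRegularity:
    def test_perfectly_periodic_signal_scores_near_one(self):
        t = np.arange(800) / FS
        ps = make_signal(np.sin(2 * np.pi * 2.0 * t))
        step_r, stride_r = bm.regularity(_episode_at_cadence(0.5), ps)
        assert step_r >= 0.99 and stride_r >= 0.99

    def test_asymmetric_steps_favour_stride_regularity(self):
        t = np.arange(800) / FS
        # period = one stride (1 s); consecutive steps differ
        ps = make_signal(np.sin(2 * np.pi * 2.0 * t) + 0.5 * np.sin(2 * np.pi * 1.0 * t))
        step_r, stride_r = bm.regularity(_episode_at_cadence(0.5), ps)
        assert stride_r > step_r

    def test_white_noise_scores_low(self):
        rng = np.random.default_rng(3)
        ps = make_signal(rng.standard_normal(800))
        step_r, stride_r = bm.regularity(_episode_at_cadence(0.5), ps)
        assert step_r is None or abs(step_r) < 0.3


class TestSpeedModel:
    def test_constant_truth_recovered(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 7))
        m = bm.train_speed_model(X, np.full(80, 1.4), seed=0)
        assert np.allclose(m.predict(X), 1.4, rtol=0.01)

    def test_too_few_windows_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError):
            bm.train_speed_model(rng.normal(size=(30, 7)), np.ones(30))

    def test_simulated_walks_held_out_mape_small(self):
        X, y, g = simulate_speed_dataset(n_walks=12, master_seed=6)
        m = bm.train_speed_model(X, y, seed=0, subject_ids=g)
        assert m.cv_mape_pct <= 5.0


class TestDailySpeedSummary:
    def test_order_statistics_with_interpolation(self):
        speeds = [1.0] * 19 + [2.0]
        med, p95, iqr = bm.daily_speed_summary(speeds)
        assert med == 1.0
        assert 1.0 < p95 <= 2.0
        assert iqr == 0.0

    def test_constant_speeds(self):
        assert bm.daily_speed_summary([1.4] * 6) == (1.4, 1.4, 0.0)

    def test_single_value_and_empty(self):
        assert bm.daily_speed_summary([1.2]) == (1.2, 1.2, 0.0)
        assert bm.daily_speed_summary([]) == (None, None, None)


class TestAggregate:
    def _day(self, wear=24.0, bouts=3, steps=8000):
        return {"wear_hours": wear, "n_walking_bouts": bouts,
                "steps_per_day": steps, "speed_median": 1.3}

    def test_seven_valid_days_give_valid_panel_with_day_means(self):
        rows = [self._day(steps=7000 + 100 * d) for d in range(7)]
        panel = bm.aggregate(rows, "subj")
        assert panel.valid and panel.n_valid_days == 7
        assert panel.week["steps_per_day"] == pytest.approx(7300.0)

    def test_four_valid_days_flag_panel_invalid(self):
        rows = [self._day() for _ in range(4)] + [self._day(wear=10.0)] * 3
        panel = bm.aggregate(rows, "subj")
        assert not panel.valid and panel.n_valid_days == 4

    def test_day_without_walking_bout_excluded_from_means(self):
        rows = [self._day(steps=8000) for _ in range(5)] + [
            {"wear_hours": 24.0, "n_walking_bouts": 0, "steps_per_day": 0}]
        panel = bm.aggregate(rows, "subj")
        assert panel.n_valid_days == 5
        assert panel.week["steps_per_day"] == pytest.approx(8000.0)
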