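"""Growth-curve analytics: normalization, threshold time, classification,
rebound detection, group summaries and the inoculum-size fit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from moca import growth
from moca.imaging import DropletTimeSeries


def _times(n, dt=0.5):
    return np.arange(n) * dt


class TestNormalize:
    def test_constant_series(self):
        assert np.array_equal(growth.normalize_curve([200, 200, 200]), [1, 1, 1])

    def test_arithmetic(self):
        assert np.allclose(growth.normalize_curve([200, 100, 50]), [1, 0.5, 0.25])

    def test_first_value_exactly_one(self, default_series):
        for s in default_series:
            assert growth.normalize_curve(s)[0] == 1.0

    def test_idempotent(self):
        v = np.array([200.0, 150.0, 90.0])
        once = growth.normalize_curve(v)
        assert np.array_equal(growth.normalize_curve(once), once)

    def test_baseline_errors(self):
        with pytest.raises(growth.NormalizationError):
            growth.normalize_curve([0.0, 1.0])
        with pytest.raises(ValueError):
            growth.normalize_curve([])
        with pytest.raises(ValueError):
            growth.normalize_curve([1.0, 2.0], baseline_frames=5)

    def test_accepts_timeseries(self):
        ts = DropletTimeSeries(0, [0.0, 0.5], [100.0, 50.0], 9)
        assert np.allclose(growth.normalize_curve(ts), [1.0, 0.5])


class TestThresholdGrowthTime:
    def test_flat_curve_never_crosses(self):
        v = np.ones(145)
        assert growth.threshold_growth_time(v, _times(145)) is None

    def test_linear_interpolation(self):
        # crossing 0.99 midway between 1.00 at t=0 and 0.98 at t=1
        t = growth.threshold_growth_time([1.0, 0.98], [0.0, 1.0])
        assert t == pytest.approx(0.5, abs=1e-12)

    def test_unnormalized_input_rejected(self):
        with pytest.raises(growth.ContractError):
            growth.threshold_growth_time([0.9, 0.5], [0.0, 1.0])

    def test_recovers_generator_truth_within_one_frame(
        self, default_results, default_render
    ):
        _, truth = default_render
        true_t = dict(zip(truth.droplet_id, truth.true_threshold_time_h))
        grown = [r for r in default_results if r.grew]
        assert len(grown) >= 15
        for r in grown:
            assert abs(r.threshold_time_h - true_t[r.droplet_id]) <= 0.5

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        drops=st.lists(st.floats(0.0, 0.05), min_size=2, max_size=40),
        thr_pair=st.tuples(st.floats(0.9, 0.999), st.floats(0.9, 0.999)),
    )
    def test_lower_threshold_never_earlier(self, drops, thr_pair):
        v = np.concatenate([[1.0], 1.0 - np.cumsum(drops)])
        t = _times(len(v))
        hi, lo = max(thr_pair), min(thr_pair)
        t_hi = growth.threshold_growth_time(v, t, hi)
        t_lo = growth.threshold_growth_time(v, t, lo)
        if t_lo is not None:
            assert t_hi is not None and t_hi <= t_lo


class TestClassifyGrowth:
    def test_flat_noisy_curve_is_no_growth(self):
        rng = np.random.default_rng(1)
        v = 1.0 + rng.normal(0, 0.002, 145)
        v[0] = 1.0
        assert growth.classify_growth(v, _times(145)) is False

    def test_single_frame_dip_rejected(self):
        v = np.ones(40)
        v[20] = 0.95  # one-frame artifact, returns to 1
        assert growth.classify_growth(v, _times(40)) is False

    def test_plateaued_growth_accepted(self, default_results):
        grown = [r for r in default_results if r.grew]
        assert len(grown) >= 15
        for r in grown:
            assert r.threshold_time_h is not None  # grew <=> crossing present
        for r in default_results:
            assert r.grew == (r.threshold_time_h is not None)


class TestDetectRebound:
    def test_monotone_curve_not_flagged(self):
        v = np.concatenate([np.linspace(1, 0.4, 60), np.full(40, 0.4)])
        v[0] = 1.0
        flag, onset = growth.detect_rebound(v, _times(100))
        assert flag is False and onset is None

    def test_rebound_flagged_with_onset_at_minimum(self):
        t = _times(100)
        v = np.concatenate(
            [np.linspace(1, 0.4, 50), np.linspace(0.4, 0.55, 50)]
        )
        flag, onset = growth.detect_rebound(v, t)
        assert flag is True
        assert onset == pytest.approx(t[49], abs=1.0)

    def test_small_rise_below_min_rise_not_flagged(self):
        v = np.concatenate([np.linspace(1, 0.4, 50), np.linspace(0.4, 0.43, 50)])
        flag, _ = growth.detect_rebound(v, _times(100))
        assert flag is False

    def test_short_lived_rise_not_flagged(self):
        v = np.concatenate([np.linspace(1, 0.4, 50), np.full(50, 0.4)])
        v[60:63] = 0.5  # three frames only
        flag, _ = growth.detect_rebound(v, _times(100))
        assert flag is False


class TestSummaries:
    def test_single_grown_droplet(self):
        r = growth.GrowthResult(0, 1.0, _times(3), np.ones(3), 9.5, True, False, None)
        (s,) = growth.summarize_groups([r])
        assert s.n_grew == 1
        assert s.median_h == 9.5
        assert s.q3_h - s.q1_h == 0.0

    def test_pseudoalteromonas_median(self):
        # six printed threshold times of the marine Pseudoalteromonas isolates
        times = [10.51, 11.02, 11.16, 9.43, 9.48, 15.37]
        results = [
            growth.GrowthResult(i, 0.25, _times(2), np.ones(2), t, True, False, None)
            for i, t in enumerate(times)
        ]
        (s,) = growth.summarize_groups(results)
        assert s.median_h == pytest.approx(10.765, abs=1e-9)
        assert s.q1_h <= s.median_h <= s.q3_h
        assert s.whisker_low_h == 9.43

    def test_group_with_no_growth_has_absent_stats(self):
        r = growth.GrowthResult(0, 1.0, _times(3), np.ones(3), None, False, False, None)
        (s,) = growth.summarize_groups([r])
        assert s.n_grew == 0 and s.median_h is None

    def test_median_decreases_with_concentration(self, default_results):
        summaries = growth.summarize_groups(default_results)
        medians = [s.median_h for s in summaries if s.n_grew > 0]
        # summaries sorted by ascending group; more cells -> earlier crossing
        assert all(a > b for a, b in zip(medians, medians[1:]))


class TestInoculumFit:
    def test_slope_matches_exponential_oracle(self, exponential_results):
        results, _ = exponential_results
        slope, intercept = growth.fit_threshold_vs_log_inoculum(results)
        predicted = -math.log(10) / 0.7
        assert abs(slope - predicted) <= 0.05 * abs(predicted)

    def test_identical_groups_give_zero_slope(self):
        results = [
            growth.GrowthResult(i, g, _times(2), np.ones(2), 8.0, True, False, None)
            for i, g in enumerate([1.0, 10.0])
        ]
        slope, intercept = growth.fit_threshold_vs_log_inoculum(results)
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert intercept == pytest.approx(8.0)

    def test_requires_two_distinct_concentrations(self):
        results = [
            growth.GrowthResult(0, 1.0, _times(2), np.ones(2), 8.0, True, False, None)
        ]
        with pytest.raises(ValueError):
            growth.fit_threshold_vs_log_inoculum(results)
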