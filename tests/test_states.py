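"""Per-second state classification: power, thresholds, minQS rule, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbsleep.containers import ABS, DI, DS, MID, QS, MotionSignal, PowerSeries
from pbsleep.errors import InvalidInputError, InvalidParameterError
from pbsleep.states import (
    SleepStateClassifier,
    calibrate_abs_threshold,
    classify_coarse,
    refine_qs_ds,
    runs_of,
    summarize_states,
    window_power,
)


def power_of(values):
    return PowerSeries(np.asarray(values, dtype=float))


class TestWindowPower:
    def test_constant_envelope_gives_squared_value(self):
        sig = MotionSignal(np.full(40, 0.5), fs=4.0, normalized=True)
        np.testing.assert_allclose(window_power(sig).values, 0.25)

    def test_all_zero(self):
        sig = MotionSignal(np.zeros(40), fs=4.0, normalized=True)
        assert np.all(window_power(sig).values == 0.0)

    def test_two_second_example(self):
        sig = MotionSignal(np.array([0, 0, 0, 0, 1, 1, 1, 1.0]), fs=4.0, normalized=True)
        np.testing.assert_array_equal(window_power(sig).values, [0.0, 1.0])

    def test_trailing_partial_window_dropped(self):
        sig = MotionSignal(np.ones(10), fs=4.0, normalized=True)
        assert len(window_power(sig)) == 2

    def test_requires_normalized_signal(self):
        with pytest.raises(InvalidInputError):
            window_power(MotionSignal(np.ones(8), fs=4.0, normalized=False))

    def test_shorter_than_one_window_rejected(self):
        with pytest.raises(InvalidInputError):
            window_power(MotionSignal(np.ones(3), fs=4.0, normalized=True))


class TestClassifyCoarse:
    def test_threshold_bands(self):
        labels = classify_coarse(power_of([0.0, 0.06, 0.02]), th_abs=0.001, th_di=0.05)
        np.testing.assert_array_equal(labels, [ABS, DI, MID])

    def test_boundaries_fall_in_middle_band(self):
        labels = classify_coarse(power_of([0.001, 0.05]), th_abs=0.001, th_di=0.05)
        np.testing.assert_array_equal(labels, [MID, MID])

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(InvalidParameterError):
            classify_coarse(power_of([0.1]), th_abs=0.05, th_di=0.05)


class TestRefineQsDs:
    def test_long_mid_run_becomes_qs(self):
        coarse = [DI] + [MID] * 1200 + [DI]
        labels = refine_qs_ds(np.array(coarse), min_qs_s=900)
        assert set(labels.labels[1:-1]) == {QS}

    def test_short_mid_run_becomes_ds(self):
        coarse = [DI] + [MID] * 300 + [DI]
        labels = refine_qs_ds(np.array(coarse), min_qs_s=900)
        assert set(labels.labels[1:-1]) == {DS}

    def test_run_of_exactly_min_qs_is_quiet(self):
        labels = refine_qs_ds(np.array([MID] * 900), min_qs_s=900)
        assert set(labels.labels) == {QS}

    def test_edge_runs_judged_by_observed_length(self):
        coarse = [MID] * 100 + [DI] + [MID] * 1000
        labels = refine_qs_ds(np.array(coarse), min_qs_s=900)
        assert set(labels.labels[:100]) == {DS}
        assert set(labels.labels[101:]) == {QS}

    def test_idempotent_on_refined_labels(self):
        coarse = np.array([DI] + [MID] * 50 + [ABS] * 3 + [MID] * 1000)
        once = refine_qs_ds(coarse, min_qs_s=900)
        again = refine_qs_ds(once.labels, min_qs_s=900)
        np.testing.assert_array_equal(once.labels, again.labels)


class TestSummarizeStates:
    def test_all_quiet(self):
        idx = summarize_states(refine_qs_ds(np.array([MID] * 1000), min_qs_s=900))
        assert (idx.qs_pct, idx.ds_pct, idx.di_pct, idx.abs_pct) == (100.0, 0, 0, 0)
        assert idx.dsdi_pct == 0.0

    def test_direct_counting(self):
        coarse = [MID] * 3000 + [DI] * 250 + [MID] * 500 + [DI] * 250
        idx = summarize_states(refine_qs_ds(np.array(coarse), min_qs_s=900))
        assert (idx.qs_pct, idx.ds_pct, idx.di_pct) == (75.0, 12.5, 12.5)
        assert idx.dsdi_pct == 25.0
        assert idx.n_di_events == 2
        np.testing.assert_array_equal(idx.di_durations_s, [250, 250])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.sampled_from([ABS, QS, DS, DI]), min_size=1, max_size=400))
    def test_percentages_sum_to_100(self, labels):
        idx = summarize_states(refine_qs_ds(np.array(labels), min_qs_s=900))
        assert idx.qs_pct + idx.ds_pct + idx.di_pct + idx.abs_pct == pytest.approx(100.0, abs=1e-9)

    def test_runs_tile_the_recording(self, rng):
        labels = rng.choice([ABS, QS, DS, DI], size=200)
        runs = runs_of(labels)
        assert sum(r.duration_s for r in runs) == 200
        assert runs[0].start_s == 0
        rebuilt = np.concatenate([[r.state] * r.duration_s for r in runs])
        np.testing.assert_array_equal(rebuilt, labels)


class TestMonotonicity:
    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_raising_th_di_never_decreases_mid_band(self, seed):
        power = power_of(np.random.default_rng(seed).uniform(0, 0.3, 300))
        lo = classify_coarse(power, 0.001, 0.05)
        hi = classify_coarse(power, 0.001, 0.1)
        assert np.sum(hi == MID) >= np.sum(lo == MID)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_raising_min_qs_never_increases_qs(self, seed):
        coarse = np.random.default_rng(seed).choice([MID, DI], size=2000, p=[0.95, 0.05])
        short = summarize_states(refine_qs_ds(coarse, min_qs_s=60))
        long_ = summarize_states(refine_qs_ds(coarse, min_qs_s=300))
        assert long_.qs_pct <= short.qs_pct


class TestCalibrateAbsThreshold:
    def test_perfect_separation_lands_in_gap(self, rng):
        empty = rng.uniform(0, 0.0005, 60)
        occupied = rng.uniform(0.002, 0.01, 60)
        th = calibrate_abs_threshold(empty, occupied)
        assert 0.0005 < th < 0.002
        assert np.all(empty <= th) and np.all(occupied > th)

    def test_matches_exhaustive_youden_maximization(self, rng):
        for _ in range(20):
            empty = rng.uniform(0, 1, 9)
            occupied = rng.uniform(0.3, 1.3, 11)
            th = calibrate_abs_threshold(empty, occupied)
            j_impl = np.mean(occupied > th) + np.mean(empty <= th) - 1
            # oracle: scan every cut between pooled order statistics
            pooled = np.sort(np.concatenate([empty, occupied]))
            j_best = max(
                np.mean(occupied > c) + np.mean(empty <= c) - 1
                for c in (pooled[:-1] + pooled[1:]) / 2
            )
            assert j_impl == pytest.approx(j_best, abs=1e-12)

    def test_identical_distributions_warn_and_return_median(self):
        vals = np.array([0.1, 0.2, 0.3, 0.4])
        with pytest.warns(UserWarning):
            th = calibrate_abs_threshold(vals, vals)
        assert th == pytest.approx(np.median(vals))


class TestSleepStateClassifier:
    def test_pipeline_prediction(self):
        power = power_of([0.0] * 5 + [0.003] * 1000 + [0.5] * 3 + [0.003] * 100)
        labels = SleepStateClassifier().fit().predict(power)
        assert list(labels[:5]) == [ABS] * 5
        assert set(labels[5:1005]) == {QS}
        assert set(labels[1005:1008]) == {DI}
        assert set(labels[1008:]) == {DS}

    def test_invalid_parameters_rejected_at_fit(self):
        with pytest.raises(InvalidParameterError):
            SleepStateClassifier(th_abs=0.1, th_di=0.05).fit()

    def test_calibrated_constructor(self, rng):
        clf = SleepStateClassifier.from_calibration(
            rng.uniform(0, 0.0004, 60), rng.uniform(0.002, 0.01, 60)
        ).fit()
        assert 0.0004 < clf.th_abs < 0.002
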