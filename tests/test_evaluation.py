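"""Metric tests: R^2 variants, frame selection, Fourier amplitudes,
paired-cone scoring, and the bootstrap comparison."""

import itertools
import warnings

import numpy as np
import pytest

from conesubunits.evaluation import (
    adjusted_r_squared,
    bootstrap_model_comparison,
    cancellation_index,
    cycle_average,
    f1_f2_amplitudes,
    improvement_slope,
    paired_prediction_score,
    paired_response_table,
    r_squared,
    select_max_diff_frames,
    windowed_rate,
)


class TestRSquared:
    def test_perfect_prediction(self, rng):
        obs = rng.poisson(2.0, 50)
        assert r_squared(obs.astype(float), obs) == pytest.approx(1.0)

    def test_mean_prediction_scores_zero(self, rng):
        obs = rng.poisson(2.0, 50).astype(float)
        pred = np.full(50, obs.mean())
        assert r_squared(pred, obs) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        pred = rng.uniform(0, 3, 30)
        obs = rng.poisson(1.5, 30).astype(float)
        expected = 1 - np.sum((pred - obs) ** 2) / np.sum((obs - obs.mean()) ** 2)
        assert r_squared(pred, obs) == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            r_squared(np.ones(5), np.ones(5))


class TestMaxDiffSelection:
    def test_top_two_of_ten(self):
        d = np.sqrt(np.arange(10.0))
        idx = select_max_diff_frames(d, np.zeros(10), fraction=0.2)
        assert list(idx) == [8, 9]

    def test_identical_predictions_tie_break_by_index(self):
        idx = select_max_diff_frames(np.ones(10), np.ones(10), fraction=0.3)
        assert list(idx) == [0, 1, 2]

    def test_matches_sort_oracle(self, rng):
        a, b = rng.normal(0, 1, 100), rng.normal(0, 1, 100)
        idx = select_max_diff_frames(a, b)
        d2 = (a - b) ** 2
        oracle = sorted(sorted(range(100), key=lambda i: (-d2[i], i))[:20])
        assert list(idx) == oracle

    def test_observation_blind(self, rng):
        # selection must depend only on the two predictions
        a, b = rng.normal(0, 1, 50), rng.normal(0, 1, 50)
        assert list(select_max_diff_frames(a, b)) == list(
            select_max_diff_frames(a, b)
        )


class TestImprovementSlope:
    def test_exact_proportionality(self, rng):
        a = rng.uniform(0.1, 0.6, 20)
        assert improvement_slope(1.2 * a, a) == pytest.approx(1.2, abs=1e-12)

    def test_single_cell(self):
        assert improvement_slope([0.6], [0.5]) == pytest.approx(1.2)

    def test_negative_reference_excluded(self):
        a = np.array([0.5, -0.2, 0.4])
        b = np.array([0.6, 0.9, 0.48])
        expected = (0.5 * 0.6 + 0.4 * 0.48) / (0.5**2 + 0.4**2)
        assert improvement_slope(b, a) == pytest.approx(expected, abs=1e-12)

    def test_matches_least_squares_oracle(self, rng):
        a = rng.uniform(0.05, 0.7, 40)
        b = 1.3 * a + rng.normal(0, 0.05, 40)
        oracle = np.linalg.lstsq(a[:, None], b, rcond=None)[0][0]
        assert improvement_slope(b, a) == pytest.approx(oracle, abs=1e-10)


class TestAdjustedRSquared:
    def test_noiseless_identical_trials(self, rng):
        trial = rng.uniform(0.5, 2.0, 40)
        trials = np.tile(trial, (4, 1))
        assert adjusted_r_squared(trials, trial) == pytest.approx(1.0)

    def test_gain_offset_invariance(self, rng):
        trial = rng.uniform(0.5, 2.0, 40)
        trials = np.tile(trial, (4, 1))
        assert adjusted_r_squared(trials, 3.7 * trial + 1.2) == pytest.approx(1.0)

    def test_matches_two_loop_reimplementation(self, rng):
        z = rng.uniform(0.5, 3.0, 60)
        trials = rng.poisson(z, size=(6, 60)).astype(float)

        def oracle(trials, pred):
            n = trials.shape[0]
            nums, dens = [], []
            for i in range(n):
                t = trials[i]
                others = (trials.sum(axis=0) - t) / (n - 1)
                c1 = np.corrcoef(pred, t)[0, 1]
                c2 = np.corrcoef(t, others)[0, 1]
                nums.append(c1**2)
                dens.append(c2**2)
            return np.mean(nums) / np.mean(dens)

        assert adjusted_r_squared(trials, z) == pytest.approx(
            oracle(trials, z), abs=1e-10
        )

    def test_converges_to_one_with_repeats(self, rng):
        z = rng.uniform(0.5, 3.0, 80)
        vals = []
        for n_rep in (4, 16, 64):
            trials = rng.poisson(z, size=(n_rep, 80)).astype(float)
            vals.append(adjusted_r_squared(trials, z))
        assert abs(vals[-1] - 1.0) < 0.1
        assert abs(vals[-1] - 1.0) < abs(vals[0] - 1.0) + 0.05

    def test_needs_three_repeats(self):
        with pytest.raises(ValueError, match="3 repeated"):
            adjusted_r_squared(np.ones((2, 10)), np.ones(10))


class TestCycleAverage:
    def test_constant_rate_flat(self):
        avg = cycle_average(np.full(60, 1.5), 12.0, 2.0)
        np.testing.assert_allclose(avg, 1.5)

    def test_sinusoidal_shape_recovered(self):
        t = np.arange(96) / 12.0
        rate = 1.0 + np.sin(2 * np.pi * 2.0 * t)
        avg = cycle_average(rate, 12.0, 2.0)
        np.testing.assert_allclose(avg, rate[:6], atol=1e-12)

    def test_spike_conservation(self, rng):
        counts = rng.poisson(1.0, size=(5, 48))
        avg = cycle_average(counts, 12.0, 2.0)
        assert avg.sum() * (48 // 6) * 5 == pytest.approx(counts.sum())

    def test_partial_cycle_rejected(self):
        with pytest.raises(ValueError, match="whole cycles"):
            cycle_average(np.ones(50), 12.0, 2.0)


class TestF1F2:
    def test_pure_modulation_has_no_second_harmonic(self):
        t = np.arange(12) / 12.0
        cyc = 2.0 + np.sin(2 * np.pi * t)
        f1, f2 = f1_f2_amplitudes(cyc)
        assert f1 == pytest.approx(1.0, abs=1e-9)
        assert f2 == pytest.approx(0.0, abs=1e-9)

    def test_full_wave_rectified_doubles(self):
        t = np.arange(12) / 12.0
        cyc = np.abs(np.sin(2 * np.pi * t))
        f1, f2 = f1_f2_amplitudes(cyc)
        assert f1 == pytest.approx(0.0, abs=1e-9)
        assert f2 > 0.1

    def test_matches_dft_oracle(self, rng):
        cyc = rng.uniform(0, 2, 12)
        f1, f2 = f1_f2_amplitudes(cyc)
        n = len(cyc)
        for k, val in ((1, f1), (2, f2)):
            direct = abs(sum(cyc[t] * np.exp(-2j * np.pi * k * t / n)
                             for t in range(n))) * 2 / n
            assert val == pytest.approx(direct, abs=1e-10)


class TestPairedScoring:
    def test_normalization_examples(self):
        np.testing.assert_allclose(
            paired_response_table([10.0, 5.0, 2.0, 8.0]), [1.0, 0.5, 0.2, 0.8]
        )
        np.testing.assert_allclose(
            paired_response_table([3.0, 3.0, 3.0, 3.0]), np.ones(4)
        )

    def test_perfect_prediction_scores_one(self, rng):
        m = rng.uniform(0.1, 1.0, (8, 4))
        assert paired_prediction_score(m, m.copy()) == pytest.approx(1.0)

    def test_uncorrelated_scores_near_zero(self, rng):
        m = rng.uniform(0, 1, 2000)
        p = rng.uniform(0, 1, 2000)
        assert paired_prediction_score(m, p) < 0.01

    def test_matches_direct_corr(self, rng):
        m = rng.uniform(0, 1, (5, 4))
        p = m + rng.normal(0, 0.1, (5, 4))
        expected = np.corrcoef(m.ravel(), p.ravel())[0, 1] ** 2
        assert paired_prediction_score(m, p) == pytest.approx(expected, abs=1e-12)


class TestBootstrap:
    def test_strictly_better_model_significant(self, rng):
        m = rng.uniform(0, 1, (30, 1))
        good = m + rng.normal(0, 0.01, m.shape)
        bad = rng.uniform(0, 1, m.shape)
        res = bootstrap_model_comparison(
            m, {"good": good, "bad": bad}, n_boot=500, seed=0
        )
        assert res.significant[("good", "bad")]

    def test_identical_models_not_significant(self, rng):
        m = rng.uniform(0, 1, (20, 1))
        p = m + rng.normal(0, 0.05, m.shape)
        res = bootstrap_model_comparison(
            m, {"a": p, "b": p.copy()}, n_boot=500, seed=1
        )
        assert not res.significant[("a", "b")]

    def test_deterministic_per_seed(self, rng):
        m = rng.uniform(0, 1, (15, 1))
        preds = {"a": m + rng.normal(0, 0.1, m.shape),
                 "b": m + rng.normal(0, 0.3, m.shape)}
        r1 = bootstrap_model_comparison(m, preds, n_boot=300, seed=7)
        r2 = bootstrap_model_comparison(m, preds, n_boot=300, seed=7)
        assert r1.fifth_percentiles == r2.fifth_percentiles

    def test_small_case_matches_exhaustive_enumeration(self, rng):
        # n_pairs = 4: enumerate all 4^4 equally likely resamples exactly
        n = 4
        m = rng.uniform(0, 1, (n, 1))
        preds = {"a": m + rng.normal(0, 0.05, m.shape),
                 "b": rng.uniform(0, 1, m.shape)}
        deltas = []
        for idx in itertools.product(range(n), repeat=n):
            idx = np.asarray(idx)
            try:
                d = paired_prediction_score(
                    m[idx], preds["a"][idx]
                ) - paired_prediction_score(m[idx], preds["b"][idx])
            except ValueError:
                d = np.nan
            deltas.append(d)
        exact_p5 = np.nanpercentile(deltas, 5.0)
        res = bootstrap_model_comparison(m, preds, n_boot=40_000, seed=3)
        assert res.fifth_percentiles[("a", "b")] == pytest.approx(
            exact_p5, abs=0.05
        )
        assert res.significant[("a", "b")] == bool(exact_p5 > 0)


class TestCancellation:
    @pytest.mark.parametrize(
        "single, paired, ratio, non_cancelling",
        [(10.0, 9.0, 0.9, True), (10.0, 1.0, 0.1, False), (4.0, 2.0, 0.5, True)],
    )
    def test_examples(self, single, paired, ratio, non_cancelling):
        r, flag = cancellation_index(single, paired)
        assert r == pytest.approx(ratio)
        assert flag is non_cancelling

    def test_requires_positive_single_response(self):
        with pytest.raises(ValueError):
            cancellation_index(0.0, 1.0)


class TestWindowedRate:
    def test_window_covers_four_bins_at_12hz(self):
        trials = np.zeros((2, 9))
        trials[:, :4] = 1.0
        trials[:, 4:] = 100.0  # outside the window; must not leak in
        assert windowed_rate(trials, 12.0, window_s=0.3) == pytest.approx(4.0)
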