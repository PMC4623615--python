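"""Estimation-procedure tests: splits, coordinate descent, greedy merging."""

import numpy as np
import pytest
from scipy.optimize import minimize

from conesubunits.fitting import (
    FitConfig,
    fit_continuous,
    fit_ln,
    fit_single_cone_subunit,
    greedy_fit,
    split_train_test,
)
from conesubunits.model_core import (
    ConeStimulus,
    ConeWeights,
    SpikeCounts,
    SubunitAssignment,
    SubunitModel,
    SubunitWeights,
    firing_rate,
    ln_predict,
)
from conesubunits.nonlinearity import init_f, init_g, make_spline
from conesubunits.synthetic import (
    aperture_noise_cone_stimulus,
    default_ground_truth,
    simulate_spikes,
)


class TestSplit:
    def test_exact_80_20_split(self):
        train, test = split_train_test(100, FitConfig(seed=0))
        assert len(train) == 80 and len(test) == 20

    def test_union_is_everything(self):
        cfg = FitConfig(seed=3)
        train, test = split_train_test(537, cfg)
        assert np.array_equal(np.sort(np.concatenate([train, test])), np.arange(537))
        assert np.intersect1d(train, test).size == 0

    def test_blocks_distributed_across_recording(self):
        # over many seeds, held-out blocks should land throughout the
        # recording, not pile up at one end
        T = 7200
        cfg = FitConfig()
        centers = []
        for seed in range(50):
            _, test = split_train_test(T, cfg, seed=seed)
            centers.append(test.mean() / T)
        assert 0.3 < np.mean(centers) < 0.7
        assert np.std(centers) > 0.05  # genuinely random placement

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(5, FitConfig())


def _single_subunit_truth(a=(0.7, 0.3)):
    f = init_f(node_range=(-1.2, 1.6))
    gx = np.linspace(-0.5, 3.0, 8)
    g = make_spline(gx, np.logaddexp(0, gx - 0.6))
    return SubunitModel(
        SubunitAssignment(np.ones((1, 2), dtype=np.int8)),
        ConeWeights(np.array([a])),
        SubunitWeights(np.array([-3.0])),
        f,
        g,
    )


class TestFitContinuous:
    def test_recovers_cone_weights(self):
        truth = _single_subunit_truth()
        stim = aperture_noise_cone_stimulus(2, 16.0, seed=11)
        counts = simulate_spikes(truth, stim, seed=12)
        model, trace, info = fit_continuous(
            truth.assignment, stim, counts, FitConfig(seed=13)
        )
        fitted = model.cone_weights.weights[0]
        np.testing.assert_allclose(fitted, [0.7, 0.3], atol=0.05)

    def test_w_step_matches_independent_lnp_optimizer(self, rng):
        # with f linear and g fixed, the w-step is a plain LNP weight fit;
        # an independent derivative-free optimizer must land on the same
        # training likelihood
        from conesubunits.fitting import _fit_pooling_weights

        C, T = 3, 400
        y = rng.uniform(-1, 1, (C, T))
        g = init_g(node_range=(-4, 4))
        w_true = np.array([1.2, -0.4, 0.7])
        z = np.maximum(np.asarray(g(w_true @ y)), 1e-6)
        r = rng.poisson(z).astype(float)

        w_fit, ll_fit = _fit_pooling_weights(y, np.ones(C), g, r, 1e-6, 200)

        def negll(w):
            rates = np.maximum(np.asarray(g(w @ y)), 1e-6)
            return -(np.dot(r, np.log(rates)) - rates.sum())

        oracle = minimize(negll, np.ones(C), method="Nelder-Mead",
                          options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
        assert ll_fit >= -oracle.fun - 1e-4
        np.testing.assert_allclose(w_fit, oracle.x, atol=1e-2)

    def test_zero_variance_stimulus_flagged(self):
        stim = ConeStimulus(np.zeros((3, 100)))
        counts = SpikeCounts(np.ones(100, dtype=int))
        model, trace, info = fit_continuous(
            SubunitAssignment.identity(3), stim, counts, FitConfig()
        )
        assert "degenerate_stimulus" in info["flags"]
        # initialization returned unchanged
        np.testing.assert_array_equal(model.subunit_weights.weights, np.ones(3))

    def test_trace_is_monotone(self):
        truth = default_ground_truth(4, (2,), seed=5)
        stim = aperture_noise_cone_stimulus(4, 2.0, seed=6)
        counts = simulate_spikes(truth, stim, seed=7)
        _, trace, _ = fit_continuous(
            truth.assignment, stim, counts, FitConfig(seed=8)
        )
        lls = [ll for _, ll in trace]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))


@pytest.fixture(scope="module")
def fitted():
    truth = default_ground_truth(5, (2,), seed=21)
    stim = aperture_noise_cone_stimulus(5, 6.0, seed=22)
    counts = simulate_spikes(truth, stim, seed=23)
    return truth, stim, counts, greedy_fit(stim, counts, FitConfig(seed=24))


class TestGreedyFit:

    def test_structural_invariants(self, fitted):
        truth, stim, counts, res = fitted
        accepted = [m for m in res.merge_history if m["accepted"]]
        assert len(accepted) <= stim.n_cones - 1
        assert np.all(res.model.assignment.indicator.sum(axis=0) == 1)

    def test_trace_monotone_within_phases_and_across_merges(self, fitted):
        truth, stim, counts, res = fitted
        segments, finals = [], []
        current = []
        for label, ll in res.ll_trace:
            if label.endswith("init") and current:
                segments.append(current)
                finals.append(current[-1])
                current = []
            current.append(ll)
        segments.append(current)
        finals.append(current[-1])
        for seg in segments:
            assert all(b >= a - 1e-9 for a, b in zip(seg, seg[1:]))
        assert all(b >= a - 1e-9 for a, b in zip(finals, finals[1:]))

    def test_deterministic_given_seed(self):
        truth = default_ground_truth(4, (2,), seed=31)
        stim = aperture_noise_cone_stimulus(4, 2.0, seed=32)
        counts = simulate_spikes(truth, stim, seed=33)
        res1 = greedy_fit(stim, counts, FitConfig(seed=34))
        res2 = greedy_fit(stim, counts, FitConfig(seed=34))
        assert res1.train_ll == res2.train_ll
        np.testing.assert_array_equal(
            res1.model.assignment.indicator, res2.model.assignment.indicator
        )
        np.testing.assert_array_equal(
            res1.model.cone_weights.weights, res2.model.cone_weights.weights
        )

    def test_ln_truth_finds_no_real_structure(self):
        # data from a model with no multi-cone subunits and linear f:
        # merges are likelihood-neutral in expectation, so any accepted
        # merge reflects only small overfit fluctuations, and the fitted
        # subunit model buys no predictive advantage over the LN model
        C = 5
        nodes = np.linspace(-1.5, 1.5, 8)
        truth = SubunitModel(
            SubunitAssignment.identity(C),
            ConeWeights(np.eye(C)),
            SubunitWeights(np.full(C, -1.5)),
            make_spline(nodes, nodes),
            make_spline(np.linspace(-4, 4, 8),
                        np.logaddexp(0, np.linspace(-4, 4, 8))),
        )
        stim = aperture_noise_cone_stimulus(C, 8.0, seed=41)
        counts = simulate_spikes(truth, stim, seed=42)
        cfg = FitConfig(seed=43)
        res = greedy_fit(stim, counts, cfg)
        accepted = [m for m in res.merge_history if m["accepted"]]
        assert len(accepted) <= C - 1
        # accepted deltas are noise-scale, far below those of real subunits
        # (tens of nats at comparable durations)
        assert all(m["delta_ll"] < 0.002 * abs(res.train_ll) for m in accepted)
        ln = fit_ln(stim, counts, cfg, train_idx=res.train_idx)
        z_sub = firing_rate(res.model, stim)[res.test_idx]
        z_ln = ln_predict(ln, stim)[res.test_idx]
        true_rate = firing_rate(truth, stim)[res.test_idx]
        err_sub = np.sqrt(np.mean((z_sub - true_rate) ** 2))
        err_ln = np.sqrt(np.mean((z_ln - true_rate) ** 2))
        assert err_sub < err_ln + 0.1 * true_rate.mean()


class TestReducedModels:
    def test_ln_fit_recovers_weights_up_to_scale(self):
        C = 4
        rng = np.random.default_rng(51)
        w_true = -np.array([1.0, 0.8, 1.2, 0.6])
        nodes = np.linspace(-4, 4, 8)
        g = make_spline(nodes, np.logaddexp(0, nodes))
        stim = aperture_noise_cone_stimulus(C, 30.0, seed=52)
        z = np.maximum(np.asarray(g(w_true @ stim.values)), 1e-6)
        counts = SpikeCounts(rng.poisson(z))
        ln = fit_ln(stim, counts, FitConfig(seed=53))
        w_fit = ln.cone_weights
        scale = np.dot(w_fit, w_true) / np.dot(w_fit, w_fit)
        rel_rms = np.sqrt(np.mean((scale * w_fit - w_true) ** 2)) / np.sqrt(
            np.mean(w_true**2)
        )
        assert rel_rms < 0.05

    def test_single_cone_subunit_matches_ln_on_linear_data(self):
        # when the truth is LN, the single-cone subunit model's extra f
        # cannot express anything the LN model cannot: predictions agree
        C = 3
        rng = np.random.default_rng(61)
        w_true = -np.array([1.2, 0.9, 1.1])
        nodes = np.linspace(-4, 4, 8)
        g = make_spline(nodes, np.logaddexp(0, nodes))
        stim = aperture_noise_cone_stimulus(C, 10.0, seed=62)
        z = np.maximum(np.asarray(g(w_true @ stim.values)), 1e-6)
        counts = SpikeCounts(rng.poisson(z))
        cfg = FitConfig(seed=63)
        train, test = split_train_test(stim.n_frames, cfg)
        ln = fit_ln(stim, counts, cfg, train_idx=train)
        sub = fit_single_cone_subunit(stim, counts, cfg, train_idx=train)
        z_ln = ln_predict(ln, stim)[test]
        z_sub = firing_rate(sub, stim)[test]
        assert np.sqrt(np.mean((z_ln - z_sub) ** 2)) < 0.05 * z.mean()

    def test_one_cone_ln_is_a_rate_curve_fit(self):
        rng = np.random.default_rng(71)
        stim = aperture_noise_cone_stimulus(1, 4.0, seed=72)
        z = np.maximum(1.0 - 1.5 * stim.values[0], 1e-6)
        counts = SpikeCounts(rng.poisson(z))
        ln = fit_ln(stim, counts, FitConfig(seed=73))
        pred = ln_predict(ln, stim)
        # the fitted 1-D rate curve tracks the true conditional rate
        corr = np.corrcoef(pred, z)[0, 1]
        assert corr > 0.98
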