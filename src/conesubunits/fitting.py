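"""Model estimation: coordinate descent nested in a greedy merge search.

The continuous parameters (subunit weights ``w``, within-subunit cone
weights ``A``, and the subunit nonlinearity ``f``) are optimized by
coordinate descent on the Poisson log likelihood, repeatedly cycling
``w -> A -> f`` until the likelihood stops improving; the output
nonlinearity ``g`` is refit only once, at the end.  The cone-to-subunit
assignment ``I`` is found by a greedy agglomerative search: starting from
the single-cone subunit model (identity ``I``), every possible merger of
two subunits is evaluated by re-estimating the continuous parameters, and
the best pair is merged whenever it improves the maximized training
likelihood; the search stops when no pairing improves it.

Each coordinate sub-step starts from the current parameters and keeps the
better of {incoming, optimized}, so the training log-likelihood trace is
non-decreasing by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .model_core import (
    ConeStimulus,
    ConeWeights,
    LNModel,
    SpikeCounts,
    SubunitAssignment,
    SubunitModel,
    SubunitWeights,
)
from .nonlinearity import (
    RATE_FLOOR,
    Spline,
    SplineBasis,
    fit_spline_ml,
    init_f,
    init_g,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "split_train_test",
    "fit_continuous",
    "greedy_fit",
    "fit_ln",
    "fit_single_cone_subunit",
]


@dataclass(frozen=True)
class FitConfig:
    """Tunable parameters of the estimation procedure."""

    train_fraction: float = 0.8
    max_rounds: int = 15            # outer (w, A, f) rounds at full budget
    candidate_rounds: int = 5       # reduced budget for candidate-merge refits
    rel_tol: float = 1e-6           # relative LL change declaring convergence
    weight_maxiter: int = 100       # L-BFGS iterations per w/A sub-step
    spline_maxiter: int = 50        # L-BFGS iterations per spline sub-step
    rate_floor: float = RATE_FLOOR  # spikes/frame clamp before log
    test_block_frames: int = 720    # ~1 min of held-out frames per block at 12 Hz
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly between 0 and 1")


@dataclass
class FitResult:
    """A fitted model plus the bookkeeping needed to audit the fit."""

    model: SubunitModel
    train_idx: np.ndarray
    test_idx: np.ndarray
    ll_trace: list            # [(step label, training LL per frame set), ...]
    merge_history: list       # [{round, n_candidates, pair, delta_ll, accepted}]
    train_ll: float
    test_ll: float
    info: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# train/test split
# ---------------------------------------------------------------------------

def split_train_test(T: int, config: FitConfig, seed: int | None = None):
    """Blocked random split of frame indices into train and test sets.

    Held-out frames come in contiguous blocks (roughly a minute each at
    default settings) placed at random positions, so the test set is
    distributed across the recording rather than i.i.d. frames.
    """
    if T < 10:
        raise ValueError("need at least 10 frames to split")
    if seed is None:
        seed = config.seed
    block = max(1, min(config.test_block_frames, T // 10))
    n_blocks = math.ceil(T / block)
    n_test = max(1, round((1.0 - config.train_fraction) * n_blocks))
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(n_blocks, size=n_test, replace=False))
    test_mask = np.zeros(T, dtype=bool)
    for b in chosen:
        test_mask[b * block : min((b + 1) * block, T)] = True
    all_idx = np.arange(T)
    return all_idx[~test_mask], all_idx[test_mask]


# ---------------------------------------------------------------------------
# likelihood plumbing
# ---------------------------------------------------------------------------

def _forward_ll(U, w, f: Spline, g: Spline, X, r, floor):
    v = U @ X
    y = f(v)
    h = w @ y
    z = g(h)
    rates = np.maximum(z, floor)
    return float(np.dot(r, np.log(rates)) - rates.sum())


def _model_ll(model: SubunitModel, X, r, floor) -> float:
    return _forward_ll(
        model.pooling_matrix(),
        model.subunit_weights.weights,
        model.f,
        model.g,
        X,
        r,
        floor,
    )


def _fit_pooling_weights(y, w0, g: Spline, r, floor, maxiter):
    """Maximize the Poisson LL over linear weights on fixed inputs ``y``.

    This is the classic LNP weight fit: rate_t = g(w . y_t).  Used for the
    w-step (y = subunit outputs) and for the LN model (y = cone inputs).
    """

    def negll(w):
        h = w @ y
        z = g(h)
        rates = np.maximum(z, floor)
        ll = np.dot(r, np.log(rates)) - rates.sum()
        q = np.where(z > floor, r / rates - 1.0, 0.0) * g.derivative(h)
        return -ll, -(y @ q)

    f0 = negll(w0)[0]
    res = minimize(negll, w0, jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "ftol": 1e-12})
    return (res.x, -res.fun) if res.fun < f0 else (np.asarray(w0, float), -f0)


def _softmax(z):
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def _fit_cone_weights(I, A0, w, f: Spline, g: Spline, X, r, floor, maxiter):
    """A-step: optimize within-subunit cone weights (positive, row sum 1).

    Each multi-cone row of A is parameterized by softmax logits, making the
    inner problem smooth and unconstrained while satisfying the
    constraints exactly.
    """
    multi = [s for s in range(I.shape[0]) if I[s].sum() > 1]
    if not multi:
        return A0, None
    supports = [np.flatnonzero(I[s]) for s in multi]
    sizes = [len(sup) for sup in supports]

    def unpack(theta):
        A = A0.copy()
        off = 0
        for s, sup, k in zip(multi, supports, sizes):
            A[s, sup] = _softmax(theta[off : off + k])
            off += k
        return A

    def negll(theta):
        A = unpack(theta)
        U = I * A
        v = U @ X
        y = f(v)
        h = w @ y
        z = g(h)
        rates = np.maximum(z, floor)
        ll = np.dot(r, np.log(rates)) - rates.sum()
        q = np.where(z > floor, r / rates - 1.0, 0.0) * g.derivative(h)
        fprime = f.derivative(v)
        grad = np.empty(sum(sizes))
        off = 0
        for s, sup, k in zip(multi, supports, sizes):
            # dLL/dA_sc, then chain through the softmax
            G = w[s] * ((q * fprime[s]) @ X[sup].T)
            a = A[s, sup]
            grad[off : off + k] = a * (G - np.dot(a, G))
            off += k
        return -ll, -grad

    theta0 = np.concatenate(
        [np.log(np.maximum(A0[s, sup], 1e-12)) for s, sup in zip(multi, supports)]
    )
    f0 = negll(theta0)[0]
    res = minimize(negll, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "ftol": 1e-12})
    theta = res.x if res.fun < f0 else theta0
    return unpack(theta), None


def _init_model(assignment: SubunitAssignment, X, floor) -> SubunitModel:
    """Paper-style initialization: w = A = 1 (A rows renormalized),
    f = negative half-wave rectification, g = softplus, with spline node
    ranges adapted to the initial drive distribution."""
    I = assignment.indicator.astype(float)
    A = I / I.sum(axis=1, keepdims=True)
    S = assignment.n_subunits
    w = np.ones(S)
    v = (I * A) @ X
    lo, hi = np.percentile(v, [1, 99])
    if not hi > lo:
        lo, hi = -1.0, 1.0
    f = init_f(node_range=(lo, hi))
    h = w @ f(v)
    m = max(1.0, float(np.abs(np.percentile(h, [1, 99])).max())) * 1.5
    g = init_g(node_range=(-m, m))
    return SubunitModel(
        assignment, ConeWeights(A), SubunitWeights(w), f, g
    )


def _refit_g(model: SubunitModel, X, r, floor, maxiter) -> SubunitModel:
    h = model.subunit_weights.weights @ model.f(model.pooling_matrix() @ X)
    try:
        basis = SplineBasis.from_percentiles(h)
    except ValueError:
        return model
    g_new, _ = fit_spline_ml(
        basis, h, r, init=model.g, rate_floor=floor, maxiter=maxiter
    )
    cand = SubunitModel(
        model.assignment, model.cone_weights, model.subunit_weights, model.f, g_new
    )
    if _model_ll(cand, X, r, floor) >= _model_ll(model, X, r, floor):
        return cand
    return model


# ---------------------------------------------------------------------------
# continuous-parameter fit (fixed assignment)
# ---------------------------------------------------------------------------

def fit_continuous(
    assignment: SubunitAssignment,
    stim: ConeStimulus,
    counts: SpikeCounts,
    config: FitConfig,
    *,
    init_model: SubunitModel | None = None,
    rounds: int | None = None,
    refit_g: bool = True,
    train_idx: np.ndarray | None = None,
):
    """Coordinate descent over (w, A, f) with ``I`` fixed; g once at the end.

    Returns ``(model, trace, info)`` where ``trace`` is a list of
    ``(step label, training LL)`` pairs, non-decreasing in LL.
    """
    if stim.n_frames != counts.n_frames:
        raise ValueError("stimulus and spike counts length mismatch")
    X = stim.values if train_idx is None else stim.values[:, train_idx]
    r = np.asarray(counts.counts, dtype=float)
    if train_idx is not None:
        r = r[train_idx]
    floor = config.rate_floor
    info: dict = {"flags": []}

    if np.all(X.std(axis=1) < 1e-12):
        model = init_model if init_model is not None else _init_model(assignment, X, floor)
        info["flags"].append("degenerate_stimulus")
        return model, [("init", _model_ll(model, X, r, floor))], info

    model = init_model if init_model is not None else _init_model(assignment, X, floor)
    I = model.assignment.indicator.astype(float)
    A = model.cone_weights.weights.copy()
    w = model.subunit_weights.weights.copy()
    f, g = model.f, model.g

    ll = _forward_ll(I * A, w, f, g, X, r, floor)
    trace = [("init", ll)]
    n_rounds = config.max_rounds if rounds is None else rounds

    for rnd in range(n_rounds):
        ll_round_start = ll

        # w-step (a standard LNP weight fit on fixed subunit outputs)
        y = f((I * A) @ X)
        w_new, ll_w = _fit_pooling_weights(y, w, g, r, floor, config.weight_maxiter)
        if ll_w >= ll:
            w, ll = w_new, ll_w
        trace.append(("w", ll))

        # A-step (within-subunit cone weights, positive and row-sum-1)
        A_new, _ = _fit_cone_weights(
            assignment.indicator, A, w, f, g, X, r, floor, config.weight_maxiter
        )
        ll_A = _forward_ll(I * A_new, w, f, g, X, r, floor)
        if ll_A >= ll:
            A, ll = A_new, ll_A
        trace.append(("A", ll))

        # f-step (subunit nonlinearity on adaptively placed nodes)
        v = (I * A) @ X
        try:
            basis = SplineBasis.from_percentiles(v)
        except ValueError:
            basis = None
            info["flags"].append("f_step_skipped_degenerate_drive")
        if basis is not None:
            f_new, sub = fit_spline_ml(
                basis, v, r,
                subunit_weights=w, output_nonlinearity=g, init=f,
                rate_floor=floor, maxiter=config.spline_maxiter,
            )
            if not sub["converged"]:
                info["flags"].append(f"f_step_iteration_budget_round_{rnd}")
            ll_f = _forward_ll(I * A, w, f_new, g, X, r, floor)
            if ll_f >= ll:
                f, ll = f_new, ll_f
        trace.append(("f", ll))

        if ll - ll_round_start < config.rel_tol * (abs(ll_round_start) + 1.0):
            break

    model = SubunitModel(assignment, ConeWeights(A), SubunitWeights(w), f, g)
    if refit_g:
        model = _refit_g(model, X, r, floor, config.spline_maxiter)
        ll = _model_ll(model, X, r, floor)
        trace.append(("g", ll))
    return model, trace, info


# ---------------------------------------------------------------------------
# greedy assignment search
# ---------------------------------------------------------------------------

def _merged_warm_start(model: SubunitModel, s1: int, s2: int) -> SubunitModel:
    """Warm start for a candidate merge of subunits s1 and s2.

    The merged row of A concatenates the two parents' cone weights scaled
    by |w|, renormalized to sum to 1; the merged w entry takes the value of
    the larger-|w| parent.
    """
    from .model_core import merge as merge_assignment

    lo, hi = sorted((s1, s2))
    new_assignment = merge_assignment(model.assignment, s1, s2)
    A = model.cone_weights.weights
    w = model.subunit_weights.weights
    row = np.abs(w[lo]) * A[lo] + np.abs(w[hi]) * A[hi]
    total = row.sum()
    row = row / total if total > 0 else (A[lo] + A[hi]) / (A[lo] + A[hi]).sum()
    A_new = np.delete(A.copy(), hi, axis=0)
    A_new[lo] = row
    w_new = np.delete(w.copy(), hi)
    w_new[lo] = w[lo] if abs(w[lo]) >= abs(w[hi]) else w[hi]
    return SubunitModel(
        new_assignment, ConeWeights(A_new), SubunitWeights(w_new), model.f, model.g
    )


def greedy_fit(stim: ConeStimulus, counts: SpikeCounts, config: FitConfig) -> FitResult:
    """Full estimation: greedy merging from the single-cone subunit model.

    At each round all S(S-1)/2 candidate pairs are refit (warm-started,
    reduced budget) and the best pair is merged iff its maximized training
    likelihood beats the current unmerged model's; the accepted merge is
    then refit to full tolerance.  ``g`` is refit once after the search
    terminates.  Deterministic given the config seed.
    """
    train_idx, test_idx = split_train_test(stim.n_frames, config)
    floor = config.rate_floor
    X_train = stim.values[:, train_idx]
    r_train = np.asarray(counts.counts, dtype=float)[train_idx]
    X_test = stim.values[:, test_idx]
    r_test = np.asarray(counts.counts, dtype=float)[test_idx]

    assignment = SubunitAssignment.identity(stim.n_cones)
    model, trace, info = fit_continuous(
        assignment, stim, counts, config, refit_g=False, train_idx=train_idx
    )
    ll_current = trace[-1][1]
    merge_history = []

    rnd = 0
    while model.n_subunits > 1:
        S = model.n_subunits
        # give the unmerged model the same extra optimization budget the
        # candidates are about to receive, so that refinement of shared
        # parameters cannot masquerade as a merge improvement
        model_r, r_trace, _ = fit_continuous(
            model.assignment, stim, counts, config,
            init_model=model, rounds=config.candidate_rounds,
            refit_g=False, train_idx=train_idx,
        )
        if r_trace[-1][1] >= ll_current:
            model, ll_current = model_r, r_trace[-1][1]
        best = None  # (ll, (i, j), candidate model)
        n_candidates = 0
        for i in range(S):
            for j in range(i + 1, S):
                warm = _merged_warm_start(model, i, j)
                cand, cand_trace, _ = fit_continuous(
                    warm.assignment, stim, counts, config,
                    init_model=warm, rounds=config.candidate_rounds,
                    refit_g=False, train_idx=train_idx,
                )
                n_candidates += 1
                ll_cand = cand_trace[-1][1]
                if best is None or ll_cand > best[0]:
                    best = (ll_cand, (i, j), cand)
        accepted = best is not None and best[0] > ll_current
        merge_history.append(
            {
                "round": rnd,
                "n_candidates": n_candidates,
                "pair": best[1] if best else None,
                "delta_ll": (best[0] - ll_current) if best else None,
                "accepted": bool(accepted),
            }
        )
        if not accepted:
            break
        # full-tolerance refit of the accepted merge
        model, m_trace, _ = fit_continuous(
            best[2].assignment, stim, counts, config,
            init_model=best[2], refit_g=False, train_idx=train_idx,
        )
        ll_current = m_trace[-1][1]
        trace.extend([(f"merge{rnd}:{lbl}", v) for lbl, v in m_trace])
        rnd += 1

    model = _refit_g(model, X_train, r_train, floor, config.spline_maxiter)
    ll_current = _model_ll(model, X_train, r_train, floor)
    trace.append(("g", ll_current))

    test_ll = _model_ll(model, X_test, r_test, floor) if len(r_test) else float("nan")
    return FitResult(
        model=model,
        train_idx=train_idx,
        test_idx=test_idx,
        ll_trace=trace,
        merge_history=merge_history,
        train_ll=ll_current,
        test_ll=test_ll,
        info=info,
    )


# ---------------------------------------------------------------------------
# reduced models
# ---------------------------------------------------------------------------

def fit_ln(
    stim: ConeStimulus,
    counts: SpikeCounts,
    config: FitConfig,
    *,
    train_idx: np.ndarray | None = None,
) -> LNModel:
    """Fit the LN reduction: one weight per cone plus an output spline."""
    X = stim.values if train_idx is None else stim.values[:, train_idx]
    r = np.asarray(counts.counts, dtype=float)
    if train_idx is not None:
        r = r[train_idx]
    floor = config.rate_floor
    w = np.ones(stim.n_cones)
    h0 = w @ X
    m = max(1.0, float(np.abs(np.percentile(h0, [1, 99])).max())) * 1.5
    g = init_g(node_range=(-m, m))
    z0 = np.maximum(g(h0), floor)
    ll = float(np.dot(r, np.log(z0)) - z0.sum())
    # w until converged, then g once (mirroring the cascade fit)
    for _ in range(config.max_rounds):
        w_new, ll_new = _fit_pooling_weights(X, w, g, r, floor, config.weight_maxiter)
        if ll_new >= ll:
            w = w_new
        if ll_new - ll < config.rel_tol * (abs(ll) + 1.0):
            ll = max(ll, ll_new)
            break
        ll = ll_new
    h = w @ X
    try:
        basis = SplineBasis.from_percentiles(h)
        g_new, _ = fit_spline_ml(basis, h, r, init=g, rate_floor=floor,
                                 maxiter=config.spline_maxiter)
        z = np.maximum(g_new(h), floor)
        if float(np.dot(r, np.log(z)) - z.sum()) >= ll:
            g = g_new
    except ValueError:
        pass
    return LNModel(w, g)


def fit_single_cone_subunit(
    stim: ConeStimulus,
    counts: SpikeCounts,
    config: FitConfig,
    *,
    train_idx: np.ndarray | None = None,
) -> SubunitModel:
    """Fit the single-cone subunit model (identity I, free f)."""
    model, _, _ = fit_continuous(
        SubunitAssignment.identity(stim.n_cones),
        stim, counts, config, refit_g=True, train_idx=train_idx,
    )
    return model
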