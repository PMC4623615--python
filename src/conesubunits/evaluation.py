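"""Accuracy metrics and model comparisons.

Covers cross-validated variance explained (R^2), reliability-adjusted R^2
from repeated trials, maximally-differentiating-frame selection,
improvement slopes across cells, grating cycle averages with F1/F2
Fourier amplitudes (frequency doubling), paired-cone response
normalization and scoring, the bootstrap model-comparison test, and the
cancellation index used to classify cone pairs as within- or
across-subunit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MetricReport",
    "r_squared",
    "select_max_diff_frames",
    "improvement_slope",
    "adjusted_r_squared",
    "cycle_average",
    "f1_f2_amplitudes",
    "windowed_rate",
    "paired_response_table",
    "paired_prediction_score",
    "bootstrap_model_comparison",
    "BootstrapComparison",
    "cancellation_index",
]


@dataclass
class MetricReport:
    """Per-cell metric bundle used by the CLI evaluation commands."""

    cell_id: object
    r2_by_model: dict = field(default_factory=dict)
    adjusted_r2_by_model: dict = field(default_factory=dict)
    excluded: bool = False
    notes: list = field(default_factory=list)


def r_squared(pred, obs) -> float:
    """Fraction of response variance explained:
    ``1 - sum (z_t - r_t)^2 / sum (r_t - mean r)^2``.

    At most 1; negative when the prediction does worse than the mean.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(getattr(obs, "counts", obs), dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("prediction and observation lengths differ")
    ss_res = np.sum((pred - obs) ** 2)
    ss_tot = np.sum((obs - obs.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("observed response has zero variance; R^2 undefined")
    return float(1.0 - ss_res / ss_tot)


def select_max_diff_frames(pred_a, pred_b, fraction: float = 0.2) -> np.ndarray:
    """Indices of the ``fraction`` of frames where (pred_a - pred_b)^2 is
    largest; floor(fraction * T) frames, ties broken by ascending index.

    Selection depends only on the two predictions, never on observed data,
    so it cannot bias the subsequent model comparison.
    """
    pred_a = np.asarray(pred_a, dtype=float)
    pred_b = np.asarray(pred_b, dtype=float)
    if pred_a.shape != pred_b.shape:
        raise ValueError("predictions must have equal length")
    T = pred_a.shape[0]
    k = int(np.floor(fraction * T))
    d2 = (pred_a - pred_b) ** 2
    # lexsort: primary key descending d2, secondary ascending frame index
    order = np.lexsort((np.arange(T), -d2))
    return np.sort(order[:k])


def improvement_slope(r2_model_b, r2_model_a, exclude_negative_reference=True) -> float:
    """Slope of the through-origin regression of model B's R^2 on model A's
    across cells: ``sum a_i b_i / sum a_i^2``.

    Cells where the reference model's R^2 is negative (as happens for the
    LN model on maximally differentiating stimuli) are excluded when
    ``exclude_negative_reference`` is set.
    """
    b = np.asarray(r2_model_b, dtype=float)
    a = np.asarray(r2_model_a, dtype=float)
    if a.shape != b.shape:
        raise ValueError("per-cell R^2 vectors must have equal length")
    if exclude_negative_reference:
        keep = a >= 0
        a, b = a[keep], b[keep]
    if a.size < 1 or np.sum(a**2) == 0:
        raise ValueError("no usable cells for the improvement slope")
    return float(np.sum(a * b) / np.sum(a**2))


def _corr(x, y) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt(np.sum(x**2) * np.sum(y**2))
    if denom == 0:
        return np.nan
    return float(np.sum(x * y) / denom)


def adjusted_r_squared(per_trial_counts, pred) -> float:
    """Prediction accuracy normalized by trial-to-trial reliability.

    Numerator: mean over trials of corr^2(prediction, trial).  Denominator:
    mean over trials of corr^2(trial, mean of the remaining trials).  Being
    correlation-based, the measure allows an arbitrary offset and gain
    between prediction and response.
    """
    trials = np.asarray(per_trial_counts, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if trials.ndim != 2 or trials.shape[0] < 3:
        raise ValueError("need at least 3 repeated trials")
    if trials.shape[1] != pred.shape[0]:
        raise ValueError("trial length and prediction length differ")
    num, den = [], []
    n = trials.shape[0]
    for i in range(n):
        c_pred = _corr(pred, trials[i])
        others = trials[np.arange(n) != i].mean(axis=0)
        c_rel = _corr(trials[i], others)
        if np.isnan(c_rel):
            warnings.warn(f"skipping zero-variance trial {i}", stacklevel=2)
            continue
        # a flat prediction explains nothing but the trial still counts
        num.append(0.0 if np.isnan(c_pred) else c_pred**2)
        den.append(c_rel**2)
    if not den or np.mean(den) == 0:
        raise ValueError("response reliability is zero; adjusted R^2 undefined")
    return float(np.mean(num) / np.mean(den))


def cycle_average(
    counts,
    frame_rate_hz: float,
    temporal_freq_hz: float = 2.0,
    n_cycles: int = None,
) -> np.ndarray:
    """Fold a response onto one temporal-modulation cycle and average.

    ``counts`` is either a length-T vector or a repeats x T matrix of
    frame-aligned counts covering an integer number of modulation cycles.
    Returns the mean count per cycle bin (bin width = one stimulus frame).
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    period = frame_rate_hz / temporal_freq_hz
    n_bins = round(period)
    if abs(period - n_bins) > 1e-9:
        raise ValueError("frame rate must be an integer multiple of the "
                         "temporal frequency for exact cycle folding")
    T = counts.shape[1]
    if n_cycles is None:
        n_cycles = T // n_bins
    if n_cycles * n_bins != T:
        raise ValueError(
            f"{T} frames is not {n_cycles} whole cycles of {n_bins} frames"
        )
    folded = counts.reshape(counts.shape[0], n_cycles, n_bins)
    return folded.mean(axis=(0, 1))


def f1_f2_amplitudes(cycle_avg, temporal_freq_hz: float = 2.0):
    """Fourier amplitudes at 1x and 2x the modulation frequency.

    The cycle average spans exactly one modulation period, so F1 and F2
    are the discrete Fourier amplitudes at harmonics 1 and 2 (amplitude
    convention: ``(2/n) |sum y exp(-2 pi i k t / n)|``).
    """
    y = np.asarray(cycle_avg, dtype=float)
    n = y.shape[0]
    if n < 5:
        raise ValueError("cycle average too short to resolve F2")
    spectrum = np.fft.rfft(y)
    f1 = 2.0 / n * np.abs(spectrum[1])
    f2 = 2.0 / n * np.abs(spectrum[2])
    return float(f1), float(f2)


def windowed_rate(
    trial_counts, frame_rate_hz: float, window_s: float = 0.3, onset_frame: int = 0
) -> float:
    """Mean spike count per trial within a window following stimulus onset.

    A frame-aligned bin is included when its start time falls inside the
    window, so a 300 ms window at 12 Hz (83 ms bins) covers four bins.
    """
    trials = np.atleast_2d(np.asarray(trial_counts, dtype=float))
    n_bins = int(np.ceil(window_s * frame_rate_hz - 1e-9))
    sel = trials[:, onset_frame : onset_frame + n_bins]
    return float(sel.sum(axis=1).mean())


def paired_response_table(rates) -> np.ndarray:
    """Normalize each tested cone's four condition rates by their maximum.

    ``rates`` has shape (..., 4): the response to the cone alone plus its
    three pairings.  The maximum of each normalized 4-vector is exactly 1;
    the same normalization is applied to measured and predicted rates.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.shape[-1] != 4:
        raise ValueError("expected 4 conditions per tested cone")
    m = rates.max(axis=-1, keepdims=True)
    if np.any(m <= 0):
        raise ValueError("non-positive maximum rate; cannot normalize")
    return rates / m


def paired_prediction_score(measured_tables, predicted_tables) -> float:
    """Squared correlation between predicted and measured normalized
    responses, pooled across all cone pairs."""
    m = np.asarray(measured_tables, dtype=float).ravel()
    p = np.asarray(predicted_tables, dtype=float).ravel()
    if m.shape != p.shape:
        raise ValueError("measured and predicted tables must align")
    c = _corr(m, p)
    if np.isnan(c):
        raise ValueError("zero variance in tables; score undefined")
    return float(c**2)


@dataclass
class BootstrapComparison:
    """Outcome of the bootstrap accuracy comparison between models."""

    model_names: list
    accuracies: dict                 # model -> r^2 on the full data
    delta_distributions: dict        # (model_a, model_b) -> bootstrap deltas
    fifth_percentiles: dict          # (model_a, model_b) -> 5th percentile
    significant: dict                # (model_a, model_b) -> bool


def bootstrap_model_comparison(
    measured_tables, predicted_by_model: dict, n_boot: int = 10_000, seed: int = 0
) -> BootstrapComparison:
    """Bootstrap test for differences in paired-prediction accuracy.

    ``measured_tables`` is an (n_pairs, k) array of normalized measured
    responses (one row per cone pair); ``predicted_by_model`` maps model
    name to an aligned array.  On each bootstrap iteration, cone pairs are
    resampled with replacement, accuracies are re-estimated, and pairwise
    differences recorded.  A difference is significant iff the 5th
    percentile of its bootstrap distribution exceeds 0.  Deterministic per
    seed.
    """
    measured = np.atleast_2d(np.asarray(measured_tables, dtype=float))
    n_pairs = measured.shape[0]
    if n_pairs < 2:
        raise ValueError("need at least 2 cone pairs")
    if len(predicted_by_model) < 2:
        raise ValueError("need at least 2 models to compare")
    preds = {
        name: np.atleast_2d(np.asarray(p, dtype=float))
        for name, p in predicted_by_model.items()
    }
    for name, p in preds.items():
        if p.shape != measured.shape:
            raise ValueError(f"prediction table for {name!r} misaligned")

    names = list(preds)
    accuracies = {
        name: paired_prediction_score(measured, preds[name]) for name in names
    }
    rng = np.random.default_rng(seed)
    deltas = {
        (a, b): np.empty(n_boot) for i, a in enumerate(names) for b in names[i + 1 :]
    }
    for it in range(n_boot):
        idx = rng.integers(0, n_pairs, size=n_pairs)
        m = measured[idx]
        accs = {}
        for name in names:
            try:
                accs[name] = paired_prediction_score(m, preds[name][idx])
            except ValueError:
                accs[name] = np.nan
        for (a, b) in deltas:
            deltas[(a, b)][it] = accs[a] - accs[b]

    fifth = {
        key: float(np.nanpercentile(d, 5.0)) for key, d in deltas.items()
    }
    significant = {key: bool(p > 0) for key, p in fifth.items()}
    return BootstrapComparison(
        model_names=names,
        accuracies=accuracies,
        delta_distributions=deltas,
        fifth_percentiles=fifth,
        significant=significant,
    )


def cancellation_index(single_decrement_rate: float, paired_rate: float):
    """Ratio of the paired response to the single-cone decrement response.

    Returns ``(ratio, non_cancelling)`` where ``non_cancelling`` is True
    when the paired response is at least 50% of the single response —
    evidence that the two cones sit in different subunits.  A ratio below
    0.5 (cancellation) indicates summation within one subunit.
    """
    if not single_decrement_rate > 0:
        raise ValueError("single-cone response must be positive")
    ratio = float(paired_rate / single_decrement_rate)
    return ratio, ratio >= 0.5
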