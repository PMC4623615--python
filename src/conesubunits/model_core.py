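"""Domain types and the forward cascade model.

The model describes the light response of a retinal ganglion cell (RGC) as
a linear–nonlinear–linear–nonlinear–Poisson cascade operating on the
signals of the ``C`` cone photoreceptors feeding its receptive field:

1. cones are partitioned into ``S`` non-overlapping *subunits* (the
   functional correlates of bipolar cells); the binary indicator matrix
   ``I`` (S x C) holds the partition and the non-negative matrix ``A``
   holds the within-subunit cone weights, each row summing to 1;
2. each subunit linearly pools its cone inputs and passes the result
   through a shared nonlinearity ``f``:  ``y_st = f(sum_c (I*A)_sc x_ct)``;
3. the cell linearly pools subunit outputs with sign-unconstrained weights
   ``w`` and passes the sum through an output nonlinearity ``g`` to give
   the firing rate ``z_t = g(sum_s w_s y_st)``;
4. spike counts per stimulus frame are Poisson with rate ``z_t``.

With ``I = A = identity`` and a linear ``f`` the cascade collapses to the
classic linear–nonlinear (LN) model, which is the baseline the subunit
model is compared against throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nonlinearity import RATE_FLOOR, Spline

__all__ = [
    "ConeStimulus",
    "SpikeCounts",
    "SubunitAssignment",
    "ConeWeights",
    "SubunitWeights",
    "SubunitModel",
    "LNModel",
    "subunit_drive",
    "firing_rate",
    "poisson_log_likelihood",
    "ln_predict",
    "merge",
    "subunit_size_distribution",
]

_ROW_SUM_TOL = 1e-9


@dataclass(frozen=True, eq=False)
class ConeStimulus:
    """C x T matrix of per-cone contrast inputs (the x_ct of the model)."""

    values: np.ndarray
    frame_rate_hz: float = 12.0
    cone_ids: tuple = None

    def __post_init__(self):
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 1:
            raise ValueError("stimulus must be a C x T matrix with C,T >= 1")
        if not np.all(np.isfinite(values)):
            raise ValueError("stimulus contains non-finite entries")
        if not self.frame_rate_hz > 0:
            raise ValueError("frame rate must be positive")
        ids = self.cone_ids
        if ids is None:
            ids = tuple(range(values.shape[0]))
        else:
            ids = tuple(ids)
            if len(ids) != values.shape[0]:
                raise ValueError("cone_ids length must match number of cones")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "cone_ids", ids)

    @property
    def n_cones(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz


@dataclass(frozen=True, eq=False)
class SpikeCounts:
    """Length-T vector of non-negative integer spike counts (r_t)."""

    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise ValueError("counts must be a 1-D vector")
        if not np.issubdtype(counts.dtype, np.integer):
            as_int = counts.astype(np.int64)
            if not np.array_equal(as_int, counts):
                raise ValueError("counts must be integers")
            counts = as_int
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def n_frames(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True, eq=False)
class SubunitAssignment:
    """Binary S x C indicator matrix I: each cone in exactly one subunit."""

    indicator: np.ndarray

    def __post_init__(self):
        ind = np.asarray(self.indicator)
        if ind.ndim != 2:
            raise ValueError("indicator must be an S x C matrix")
        if not np.all((ind == 0) | (ind == 1)):
            raise ValueError("indicator must be binary")
        ind = ind.astype(np.int8)
        if not np.all(ind.sum(axis=0) == 1):
            raise ValueError("each cone must belong to exactly one subunit")
        if not np.all(ind.sum(axis=1) >= 1):
            raise ValueError("each subunit must contain at least one cone")
        object.__setattr__(self, "indicator", ind)

    @classmethod
    def identity(cls, n_cones: int) -> "SubunitAssignment":
        return cls(np.eye(n_cones, dtype=np.int8))

    @property
    def n_subunits(self) -> int:
        return self.indicator.shape[0]

    @property
    def n_cones(self) -> int:
        return self.indicator.shape[1]

    def cone_sets(self) -> list[frozenset]:
        return [frozenset(np.flatnonzero(row)) for row in self.indicator]

    def partition(self) -> frozenset:
        """Order-free view of the partition, for comparing assignments."""
        return frozenset(self.cone_sets())


@dataclass(frozen=True, eq=False)
class ConeWeights:
    """Non-negative S x C matrix A; each row sums to 1 over its support."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2:
            raise ValueError("weights must be an S x C matrix")
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValueError("cone weights must be finite and non-negative")
        if np.any(np.abs(w.sum(axis=1) - 1.0) > _ROW_SUM_TOL):
            raise ValueError("each subunit's cone weights must sum to 1")
        object.__setattr__(self, "weights", w)

    def check_support(self, assignment: SubunitAssignment) -> None:
        if self.weights.shape != assignment.indicator.shape:
            raise ValueError("cone-weight and assignment shapes differ")
        if np.any((self.weights > 0) & (assignment.indicator == 0)):
            raise ValueError("cone weights outside the assignment support")


@dataclass(frozen=True, eq=False)
class SubunitWeights:
    """Length-S subunit-to-cell weights w (unconstrained sign/magnitude)."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or not np.all(np.isfinite(w)):
            raise ValueError("subunit weights must be a finite 1-D vector")
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True, eq=False)
class SubunitModel:
    """Full parameter set (I, A, w, f, g) of the subunit cascade."""

    assignment: SubunitAssignment
    cone_weights: ConeWeights
    subunit_weights: SubunitWeights
    f: Spline
    g: Spline

    def __post_init__(self):
        S, C = self.assignment.indicator.shape
        self.cone_weights.check_support(self.assignment)
        if self.subunit_weights.weights.shape != (S,):
            raise ValueError("subunit weights length must equal subunit count")

    @property
    def n_subunits(self) -> int:
        return self.assignment.n_subunits

    @property
    def n_cones(self) -> int:
        return self.assignment.n_cones

    def pooling_matrix(self) -> np.ndarray:
        """U = I * A (elementwise), the cone-to-subunit weight matrix."""
        return self.assignment.indicator * self.cone_weights.weights


@dataclass(frozen=True, eq=False)
class LNModel:
    """Linear–nonlinear reduction: one weight per cone plus output spline."""

    cone_weights: np.ndarray
    g: Spline

    def __post_init__(self):
        w = np.asarray(self.cone_weights, dtype=float)
        if w.ndim != 1 or not np.all(np.isfinite(w)):
            raise ValueError("LN cone weights must be a finite 1-D vector")
        object.__setattr__(self, "cone_weights", w)

    @property
    def n_cones(self) -> int:
        return self.cone_weights.shape[0]


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def subunit_drive(model: SubunitModel, stim: ConeStimulus) -> np.ndarray:
    """Subunit outputs y_st = f(sum_c (I*A)_sc x_ct); shape (S, T)."""
    if stim.n_cones != model.n_cones:
        raise ValueError(
            f"stimulus has {stim.n_cones} cones, model expects {model.n_cones}"
        )
    return model.f(model.pooling_matrix() @ stim.values)


def firing_rate(
    model: SubunitModel, stim: ConeStimulus, rate_floor: float = 0.0
) -> np.ndarray:
    """Firing rate z_t = g(sum_s w_s y_st), floored at ``rate_floor``."""
    y = subunit_drive(model, stim)
    z = model.g(model.subunit_weights.weights @ y)
    if not np.all(np.isfinite(z)):
        raise FloatingPointError(
            "non-finite firing rate; check spline ranges and weight scales"
        )
    return np.maximum(z, rate_floor)


def ln_predict(model: LNModel, stim: ConeStimulus, rate_floor: float = 0.0) -> np.ndarray:
    """LN-model rate g(w . x_t), floored at ``rate_floor``."""
    if stim.n_cones != model.n_cones:
        raise ValueError(
            f"stimulus has {stim.n_cones} cones, model expects {model.n_cones}"
        )
    z = model.g(model.cone_weights @ stim.values)
    if not np.all(np.isfinite(z)):
        raise FloatingPointError("non-finite LN firing rate")
    return np.maximum(z, rate_floor)


def poisson_log_likelihood(rates, counts) -> float:
    """Poisson log likelihood sum_t r_t log z_t - sum_t z_t.

    The log-factorial constant is omitted; it does not depend on the model
    and cancels in every comparison.
    """
    rates = np.asarray(rates, dtype=float)
    r = np.asarray(getattr(counts, "counts", counts), dtype=float)
    if rates.shape != r.shape:
        raise ValueError("rates and counts must have the same length")
    if np.any(rates <= 0):
        raise FloatingPointError(
            "non-positive rate passed to the Poisson likelihood; "
            f"floor rates at {RATE_FLOOR} first"
        )
    return float(np.dot(r, np.log(rates)) - rates.sum())


# ---------------------------------------------------------------------------
# assignment operations
# ---------------------------------------------------------------------------

def merge(assignment: SubunitAssignment, s1: int, s2: int) -> SubunitAssignment:
    """Merge subunits ``s1`` and ``s2`` into one; S decreases by one.

    The merged subunit replaces the lower-index row; row order of the
    untouched subunits is preserved.
    """
    S = assignment.n_subunits
    if not (0 <= s1 < S and 0 <= s2 < S):
        raise IndexError(f"subunit indices ({s1}, {s2}) out of range for S={S}")
    if s1 == s2:
        raise ValueError("cannot merge a subunit with itself")
    lo, hi = sorted((s1, s2))
    ind = assignment.indicator.copy()
    ind[lo] = ind[lo] | ind[hi]
    ind = np.delete(ind, hi, axis=0)
    return SubunitAssignment(ind)


def subunit_size_distribution(model) -> dict[int, int]:
    """Histogram {cones-per-subunit: count}; counts sum to S.

    Accepts a :class:`SubunitModel` or a bare :class:`SubunitAssignment`.
    """
    assignment = getattr(model, "assignment", model)
    sizes = assignment.indicator.sum(axis=1)
    values, counts = np.unique(sizes, return_counts=True)
    return {int(v): int(c) for v, c in zip(values, counts)}
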