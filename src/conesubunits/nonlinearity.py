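"""Cubic-spline nonlinearities with eight nodes.

The subunit nonlinearity ``f`` and the output nonlinearity ``g`` of the
cascade model are smooth scalar functions parameterized as cubic splines
with eight node points.  A spline is represented by its nodal values and
interpolated with a *natural* cubic spline (zero second derivative at the
end nodes), which guarantees continuity of the value and of the first and
second derivatives at every interior node for any coefficient vector.
Beyond the end nodes the spline is continued linearly along the end
tangents; because the natural boundary condition zeroes the curvature at
the ends, the extension is itself twice continuously differentiable at the
junction.

Because natural-spline interpolation is linear in the nodal values, the
spline value at any query point is an inner product between a fixed basis
row and the 8-vector of nodal parameters.  :class:`SplineBasis` exposes
that design matrix, which turns likelihood fits of ``f`` and ``g`` into
smooth low-dimensional optimizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize

__all__ = [
    "N_NODES",
    "Spline",
    "SplineBasis",
    "make_spline",
    "eval_spline",
    "init_f",
    "init_g",
    "fit_spline_ml",
]

N_NODES = 8

# Floor applied to firing rates before taking logs in the Poisson
# likelihood (spikes/frame).
RATE_FLOOR = 1e-6


def _check_nodes(node_x: np.ndarray) -> np.ndarray:
    node_x = np.asarray(node_x, dtype=float)
    if node_x.shape != (N_NODES,):
        raise ValueError(f"expected {N_NODES} nodes, got shape {node_x.shape}")
    if not np.all(np.isfinite(node_x)):
        raise ValueError("spline nodes must be finite")
    if not np.all(np.diff(node_x) > 0):
        raise ValueError("spline nodes must be strictly increasing")
    return node_x


@dataclass(frozen=True, eq=False)
class Spline:
    """Natural cubic spline through 8 nodes with linear extrapolation."""

    node_x: np.ndarray
    node_y: np.ndarray
    _cs: CubicSpline = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        node_x = _check_nodes(self.node_x)
        node_y = np.asarray(self.node_y, dtype=float)
        if node_y.shape != (N_NODES,):
            raise ValueError("node_y must have one value per node")
        if not np.all(np.isfinite(node_y)):
            raise ValueError("spline nodal values must be finite")
        object.__setattr__(self, "node_x", node_x)
        object.__setattr__(self, "node_y", node_y)
        if self._cs is None:
            object.__setattr__(
                self, "_cs", CubicSpline(node_x, node_y, bc_type="natural")
            )

    # -- evaluation -----------------------------------------------------
    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        out = self._cs(np.clip(v, self.node_x[0], self.node_x[-1]))
        lo, hi = self.node_x[0], self.node_x[-1]
        below = v < lo
        above = v > hi
        if np.any(below):
            out = np.where(below, self.node_y[0] + self.slope_low * (v - lo), out)
        if np.any(above):
            out = np.where(above, self.node_y[-1] + self.slope_high * (v - hi), out)
        return out

    def derivative(self, v):
        v = np.asarray(v, dtype=float)
        d = self._cs(np.clip(v, self.node_x[0], self.node_x[-1]), 1)
        d = np.where(v < self.node_x[0], self.slope_low, d)
        d = np.where(v > self.node_x[-1], self.slope_high, d)
        return d

    @property
    def slope_low(self) -> float:
        return float(self._cs(self.node_x[0], 1))

    @property
    def slope_high(self) -> float:
        return float(self._cs(self.node_x[-1], 1))

    @property
    def coefficients(self) -> np.ndarray:
        """Piecewise polynomial coefficients, shape (4, 7) (highest first)."""
        return np.array(self._cs.c)

    def with_values(self, node_y) -> "Spline":
        return Spline(self.node_x, node_y)


class SplineBasis:
    """Linear map from nodal values to spline values at query points.

    ``design_matrix(v) @ theta`` equals ``Spline(node_x, theta)(v)`` for any
    8-vector ``theta``; the smoothness constraints hold for every ``theta``
    because they are built into the natural-spline interpolant.
    """

    def __init__(self, node_x):
        self.node_x = _check_nodes(np.asarray(node_x, dtype=float))
        # Vector-valued interpolation of the identity gives all 8 cardinal
        # basis splines in one object.
        self._cs = CubicSpline(self.node_x, np.eye(N_NODES), bc_type="natural")
        self._slope_low = self._cs(self.node_x[0], 1)
        self._slope_high = self._cs(self.node_x[-1], 1)

    @classmethod
    def from_percentiles(cls, v, lo: float = 1.0, hi: float = 99.0) -> "SplineBasis":
        """Nodes equally spaced between empirical percentiles of ``v``."""
        v = np.asarray(v, dtype=float).ravel()
        a, b = np.percentile(v, [lo, hi])
        if not b > a:
            raise ValueError("degenerate drive distribution: percentile range empty")
        return cls(np.linspace(a, b, N_NODES))

    def design_matrix(self, v) -> np.ndarray:
        """Basis values at ``v``; shape ``v.shape + (8,)``."""
        v = np.asarray(v, dtype=float)
        lo, hi = self.node_x[0], self.node_x[-1]
        out = self._cs(np.clip(v, lo, hi))
        below = v < lo
        above = v > hi
        if np.any(below):
            ext = np.eye(N_NODES)[0] + np.multiply.outer(v - lo, self._slope_low)
            out = np.where(below[..., None], ext, out)
        if np.any(above):
            ext = np.eye(N_NODES)[-1] + np.multiply.outer(v - hi, self._slope_high)
            out = np.where(above[..., None], ext, out)
        return out

    def spline(self, theta) -> Spline:
        return Spline(self.node_x, theta)


def make_spline(node_x, nodal_values) -> Spline:
    """Build the smooth spline through ``(node_x, nodal_values)``."""
    return Spline(node_x, nodal_values)


def eval_spline(spline: Spline, v):
    return spline(v)


def init_f(node_range=(-2.0, 2.0)) -> Spline:
    """Negative half-wave rectification min(v, 0), sampled at the nodes.

    The sign flip required for OFF-type responses is carried by the
    (sign-unconstrained) subunit weights, not by ``f``.
    """
    x = np.linspace(node_range[0], node_range[1], N_NODES)
    return Spline(x, np.minimum(x, 0.0))


def init_g(node_range=(-3.0, 3.0)) -> Spline:
    """Softplus log(1 + exp(v)), sampled at the nodes."""
    x = np.linspace(node_range[0], node_range[1], N_NODES)
    return Spline(x, np.logaddexp(0.0, x))


def _poisson_ll(rates, counts):
    return float(np.dot(counts, np.log(rates)) - rates.sum())


def fit_spline_ml(
    basis: SplineBasis,
    drive,
    counts,
    *,
    subunit_weights=None,
    output_nonlinearity: Spline | None = None,
    init: Spline | None = None,
    rate_floor: float = RATE_FLOOR,
    maxiter: int = 50,
    tol: float = 1e-6,
):
    """Maximum-likelihood refit of one spline with the rest of the model fixed.

    Two configurations are supported, matching the two nonlinearities of the
    cascade:

    * output spline ``g`` — ``drive`` is the length-T generator signal
      ``h_t``; the rate is ``clip(g(h_t), rate_floor)``.
    * subunit spline ``f`` — ``drive`` is the S x T matrix of subunit
      pre-nonlinearity drives, and ``subunit_weights`` (length S) and
      ``output_nonlinearity`` (a fixed ``g``) describe the downstream model:
      ``rate_t = clip(g(sum_s w_s f(v_st)), rate_floor)``.

    Returns ``(spline, info)``.  The returned spline never has lower
    training likelihood than ``init`` (the better of the two is kept), so
    coordinate-descent traces stay monotone.  ``info['converged']`` is False
    when the inner optimizer hit its iteration budget.
    """
    drive = np.asarray(drive, dtype=float)
    counts = np.asarray(getattr(counts, "counts", counts), dtype=float)
    fitting_f = subunit_weights is not None
    if fitting_f and output_nonlinearity is None:
        raise ValueError("fitting f requires the fixed output nonlinearity g")

    Phi = basis.design_matrix(drive)  # (..., 8)
    if init is not None:
        theta0 = np.asarray(init(basis.node_x), dtype=float)
    elif fitting_f:
        theta0 = np.minimum(basis.node_x, 0.0)
    else:
        theta0 = np.logaddexp(0.0, basis.node_x)

    if fitting_f:
        w = np.asarray(subunit_weights, dtype=float)
        g = output_nonlinearity

        def negll(theta):
            y = Phi @ theta                      # (S, T)
            h = w @ y                            # (T,)
            z = g(h)
            rates = np.maximum(z, rate_floor)
            ll = _poisson_ll(rates, counts)
            live = z > rate_floor
            resid = np.where(live, counts / rates - 1.0, 0.0) * g.derivative(h)
            grad = np.einsum("t,s,stk->k", resid, w, Phi)
            return -ll, -grad

    else:

        def negll(theta):
            z = Phi @ theta
            rates = np.maximum(z, rate_floor)
            ll = _poisson_ll(rates, counts)
            live = z > rate_floor
            resid = np.where(live, counts / rates - 1.0, 0.0)
            grad = resid @ Phi
            return -ll, -grad

    f0 = negll(theta0)[0]
    res = minimize(
        negll,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": tol * 1e-3},
    )
    improved = res.fun < f0 - 0.0
    theta = res.x if improved else theta0
    info = {
        "converged": bool(res.success),
        "ll_before": -f0,
        "ll_after": -min(res.fun, f0),
        "n_iter": int(res.nit),
    }
    return basis.spline(theta), info
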