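import numpy as np
import pytest

from conesubunits.model_core import (
    ConeStimulus,
    ConeWeights,
    SubunitAssignment,
    SubunitModel,
    SubunitWeights,
)
from conesubunits.nonlinearity import Spline, init_f, init_g, make_spline


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_partition(rng, n_cones, n_subunits):
    """Random assignment with every subunit non-empty."""
    labels = np.concatenate(
        [np.arange(n_subunits), rng.integers(0, n_subunits, n_cones - n_subunits)]
    )
    rng.shuffle(labels)
    I = np.zeros((n_subunits, n_cones), dtype=np.int8)
    I[labels, np.arange(n_cones)] = 1
    return SubunitAssignment(I)


def random_model(rng, n_cones=5, n_subunits=3, linear_f=False):
    assignment = random_partition(rng, n_cones, n_subunits)
    A = assignment.indicator * rng.uniform(0.2, 1.0, (n_subunits, n_cones))
    A = A / A.sum(axis=1, keepdims=True)
    w = rng.normal(0, 1.5, n_subunits)
    if linear_f:
        nodes = np.linspace(-2.0, 2.0, 8)
        f = make_spline(nodes, nodes)
    else:
        f = init_f()
    g = init_g()
    return SubunitModel(assignment, ConeWeights(A), SubunitWeights(w), f, g)


def identity_model(weights, g=None, f_nodes=(-2.0, 2.0)):
    """Subunit model with I = A = identity and a linear f spline."""
    w = np.asarray(weights, dtype=float)
    C = w.shape[0]
    nodes = np.linspace(f_nodes[0], f_nodes[1], 8)
    return SubunitModel(
        SubunitAssignment.identity(C),
        ConeWeights(np.eye(C)),
        SubunitWeights(w),
        make_spline(nodes, nodes),
        g if g is not None else init_g(),
    )


@pytest.fixture
def small_model(rng):
    return random_model(rng)


@pytest.fixture
def small_stim(rng):
    return ConeStimulus(rng.uniform(-1, 1, (5, 50)))
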