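import itertools
import math

import numpy as np
import pytest

from redpart import DiscretePMF, GaussianModel

H_SCALAR = 0.5 * math.log(2 * math.pi * math.e)  # nats
ALPHA_4_BITS = 4 * math.log(2)


def scalar_gaussian_model(P: np.ndarray, alpha: float = ALPHA_4_BITS) -> GaussianModel:
    """Gaussian model with one scalar variate per element."""
    n = P.shape[0]
    return GaussianModel(
        correlation=np.asarray(P, dtype=float),
        element_map=[[i] for i in range(n)],
        h=np.full(n, H_SCALAR),
        block_logdets=np.zeros(n),
        alpha=alpha,
    )


def random_pmf(rng: np.random.Generator, shape: tuple[int, ...]) -> DiscretePMF:
    table = rng.random(shape)
    table /= table.sum()
    # renormalize exactly enough for the 1e-12 gate
    table = table / table.sum()
    return DiscretePMF(table)


def random_r_fn(rng: np.random.Generator, n: int, scale: float = 0.5):
    """Arbitrary redundancy-like set function: 0 on empty/singletons."""
    values = {}
    for size in range(2, n + 1):
        for combo in itertools.combinations(range(n), size):
            values[combo] = float(rng.random() * scale)
    return lambda A: values.get(tuple(sorted(A)), 0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def xor_pmf():
    """X, Y independent fair coins, Z = XOR(X, Y)."""
    table = np.zeros((2, 2, 2))
    for x, y in itertools.product((0, 1), repeat=2):
        table[x, y, x ^ y] = 0.25
    return DiscretePMF(table)


@pytest.fixture
def two_pair_model():
    """Four scalar elements: two independent highly correlated pairs."""
    P = np.eye(4)
    P[0, 1] = P[1, 0] = 0.95
    P[2, 3] = P[3, 2] = 0.95
    return scalar_gaussian_model(P)
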