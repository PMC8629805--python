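"""Exact discrete total correlation and relative redundancy.

Total correlation of a set of discrete random variables
``{X_i}`` is the difference between the cost of describing each element
separately and the cost of one joint description,

    I({X_i}) = sum_i H(X_i) - H({X_i}),

and relative redundancy normalizes it by the marginal description cost,

    r = I({X_i}) / sum_i H(X_i) = 1 - s,

where ``s`` is the incompressible fraction.  ``r`` lies in [0, 1 - 1/n)
for n elements and is invariant to the total amount of individual
variability, which is what makes it comparable across systems.

All discrete quantities are reported in bits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import entropy as _entropy

__all__ = [
    "DiscretePMF",
    "discrete_total_correlation",
    "discrete_relative_redundancy",
    "discrete_incompressibility",
]

_NORMALIZATION_TOL = 1e-12


@dataclass(frozen=True)
class DiscretePMF:
    """Joint probability mass function over ``n`` discrete elements.

    The joint table has one axis per element; axis lengths are the
    alphabet sizes.  Probabilities must be nonnegative and sum to one
    within 1e-12.
    """

    table: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        table = np.asarray(self.table, dtype=float)
        if table.ndim < 1:
            raise ValueError("joint table must have at least one axis")
        if np.any(table < 0):
            raise ValueError("probabilities must be nonnegative")
        total = table.sum()
        if abs(total - 1.0) > _NORMALIZATION_TOL:
            raise ValueError(
                f"joint table sums to {total!r}, not 1 (tolerance 1e-12)"
            )
        object.__setattr__(self, "table", table)

    @property
    def n(self) -> int:
        """Number of elements (axes of the joint table)."""
        return self.table.ndim

    @property
    def alphabet_sizes(self) -> tuple[int, ...]:
        return self.table.shape

    def marginal(self, i: int) -> np.ndarray:
        """Marginal distribution of element ``i``."""
        axes = tuple(a for a in range(self.n) if a != i)
        return self.table.sum(axis=axes)

    def marginal_entropies(self) -> np.ndarray:
        """H(X_i) for every element, in bits."""
        return np.array(
            [_entropy(self.marginal(i), base=2) for i in range(self.n)]
        )

    def joint_entropy(self) -> float:
        """H({X_i}), in bits."""
        return float(_entropy(self.table.ravel(), base=2))

    # -- convenience constructors used throughout the tests and docs ----

    @classmethod
    def identical_copies(cls, p: np.ndarray, n: int) -> "DiscretePMF":
        """n perfectly dependent copies of a variable with pmf ``p``.

        All probability mass sits on the diagonal of the n-fold table,
        so knowing any one element determines all the others.
        """
        p = np.asarray(p, dtype=float)
        k = p.size
        table = np.zeros((k,) * n)
        for sym in range(k):
            table[(sym,) * n] = p[sym]
        return cls(table)

    @classmethod
    def independent(cls, marginals: list[np.ndarray]) -> "DiscretePMF":
        """Product distribution of the given marginals."""
        table = np.array(1.0)
        for p in marginals:
            table = np.multiply.outer(table, np.asarray(p, dtype=float))
        return cls(table)


def discrete_total_correlation(pmf: DiscretePMF) -> float:
    """Total correlation I({X_i}) = sum_i H(X_i) - H({X_i}), in bits.

    Nonnegative; zero exactly when the joint factorizes into its
    marginals.
    """
    value = float(pmf.marginal_entropies().sum() - pmf.joint_entropy())
    # entropy differences can undershoot zero by rounding only
    return max(value, 0.0)


def discrete_relative_redundancy(pmf: DiscretePMF) -> float:
    """Relative redundancy r = I({X_i}) / sum_i H(X_i), in [0, 1).

    A system of constants (every marginal entropy zero) carries no
    information to make redundant; we define r = 0 for it and warn.
    """
    marginal_sum = float(pmf.marginal_entropies().sum())
    if marginal_sum <= 0.0:
        warnings.warn(
            "all elements are constant (sum of marginal entropies is 0); "
            "relative redundancy defined as 0",
            stacklevel=2,
        )
        return 0.0
    r = discrete_total_correlation(pmf) / marginal_sum
    return min(max(r, 0.0), 1.0)


def discrete_incompressibility(pmf: DiscretePMF) -> float:
    """Incompressibility s = 1 - r: the non-redundant fraction."""
    return 1.0 - discrete_relative_redundancy(pmf)
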