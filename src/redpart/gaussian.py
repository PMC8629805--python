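"""Gaussian lower bound on total correlation and relative redundancy.

For variates that are marginally Gaussian (enforced in practice by
rank-Gaussianization) with system correlation matrix ``P_S``,

    I_G({X_i}) = -1/2 log det(P_S)            (nats)

is a lower bound on the total correlation of the underlying continuous
variables.  Each element i with k_i variates and covariance block K_i
has differential entropy

    h_G(X_i) = 1/2 log[(2 pi e)^{k_i} det(K_i)],

and an alpha-bit quantization turns differential entropies into
(approximate) discrete ones, h + alpha, giving the practical bound

    r >= I_G({X_i}) / sum_i (h_G(X_i) + k_i * alpha).

alpha is applied per variate and must be held fixed when comparing
systems: it cancels in the numerator but rescales the denominator.

For elements with several variates the numerator subtracts the
within-element block terms, -1/2 [log det(P_A) - sum_{i in A} log
det(P_i)], so that dependence *within* an element never counts as
coordination and every singleton subset scores exactly zero.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.linalg import cho_factor

from .observations import ObservationMatrix

__all__ = [
    "GaussianModel",
    "estimate_gaussian_model",
    "gaussian_total_correlation",
    "gaussian_relative_redundancy",
    "DEFAULT_ALPHA_NATS",
    "bits_to_nats",
    "nats_to_bits",
]

logger = logging.getLogger(__name__)

LN_2PI_E = math.log(2.0 * math.pi * math.e)

#: Default quantization offset: 4 bits per variate, in nats.
DEFAULT_ALPHA_NATS = 4.0 * math.log(2.0)


def bits_to_nats(x: float) -> float:
    return x * math.log(2.0)


def nats_to_bits(x: float) -> float:
    return x / math.log(2.0)


def _chol_logdet(mat: np.ndarray) -> float:
    """log det of a symmetric PD matrix via Cholesky; ValueError if not PD."""
    c, _ = cho_factor(mat, lower=True, check_finite=False)
    return 2.0 * float(np.sum(np.log(np.diag(c))))


def _regularized_logdet(mat: np.ndarray, context: str) -> float:
    """log det with escalating shrinkage toward identity on failure.

    Shrinkage P <- (1 - eps) P + eps I with eps = 1e-8 escalating by
    decades to 1e-4; +inf sentinel (with a warning) if still singular.
    """
    try:
        return _chol_logdet(mat)
    except np.linalg.LinAlgError:
        pass
    except ValueError:
        pass
    eye = np.eye(mat.shape[0])
    eps = 1e-8
    while eps <= 1e-4:
        try:
            out = _chol_logdet((1.0 - eps) * mat + eps * eye)
            logger.warning(
                "%s: singular matrix, applied shrinkage eps=%g", context, eps
            )
            return out
        except (np.linalg.LinAlgError, ValueError):
            eps *= 10.0
    warnings.warn(
        f"{context}: submatrix singular even after shrinkage 1e-4; "
        "returning +inf total correlation",
        stacklevel=2,
    )
    return -math.inf  # log det -> -inf  =>  -1/2 log det -> +inf


@dataclass
class GaussianModel:
    """Everything needed to score the redundancy of any element subset.

    Attributes
    ----------
    correlation : (D, D) correlation matrix of the (rank-Gaussianized)
        variates, regularized to be positive definite if necessary.
    element_map : columns owned by each element.
    h : per-element differential entropies, nats.
    block_logdets : log det of each within-element correlation block.
    alpha : quantization offset, nats per variate.
    shrinkage : shrinkage actually applied to the correlation matrix.
    """

    correlation: np.ndarray = field(repr=False)
    element_map: list[list[int]]
    h: np.ndarray
    block_logdets: np.ndarray
    alpha: float
    shrinkage: float = 0.0

    def __post_init__(self) -> None:
        P = np.asarray(self.correlation, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("correlation must be square")
        if not np.allclose(P, P.T, atol=1e-10):
            raise ValueError("correlation must be symmetric")
        if not np.allclose(np.diag(P), 1.0, atol=1e-8):
            raise ValueError("correlation must have unit diagonal")
        self.correlation = P
        self.h = np.asarray(self.h, dtype=float)
        self.block_logdets = np.asarray(self.block_logdets, dtype=float)
        if not np.all(np.isfinite(self.h)):
            raise ValueError("marginal entropies must be finite")
        if self.denominator(range(self.n_elements)) <= 0:
            raise ValueError(
                "sum_i (h_i + k_i * alpha) must be positive; increase alpha"
            )

    @property
    def n_elements(self) -> int:
        return len(self.element_map)

    def element_sizes(self) -> np.ndarray:
        return np.array([len(cols) for cols in self.element_map])

    def columns_of(self, subset: Iterable[int]) -> np.ndarray:
        return np.concatenate(
            [np.asarray(self.element_map[i], dtype=int) for i in subset]
        )

    def denominator(self, subset: Iterable[int]) -> float:
        """sum_{i in A} (h_i + k_i * alpha), nats."""
        idx = list(subset)
        sizes = self.element_sizes()
        return float(
            sum(self.h[i] + sizes[i] * self.alpha for i in idx)
        )

    # convenient bound methods mirroring the module-level functions
    def total_correlation(self, subset: Iterable[int], *,
                          include_within: bool = False) -> float:
        return gaussian_total_correlation(
            self, subset, include_within=include_within
        )

    def relative_redundancy(self, subset: Iterable[int]) -> float:
        return gaussian_relative_redundancy(self, subset)

    def subset_r_function(self, cached: bool = True) -> Callable:
        """A ``subset -> r(A)`` callable suitable for the partitioner."""
        if not cached:
            return lambda A: gaussian_relative_redundancy(self, A)
        cache: dict[tuple, float] = {}

        def r_fn(A: Iterable[int]) -> float:
            key = tuple(sorted(A))
            if key not in cache:
                cache[key] = gaussian_relative_redundancy(self, key)
            return cache[key]

        return r_fn

    # ------------------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "correlation": self.correlation.ravel().tolist(),
            "dim": int(self.correlation.shape[0]),
            "element_map": self.element_map,
            "h_nats": self.h.tolist(),
            "block_logdets": self.block_logdets.tolist(),
            "alpha_nats": self.alpha,
            "shrinkage": self.shrinkage,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GaussianModel":
        s = str(source)
        text = s if s.lstrip().startswith("{") else Path(s).read_text()
        payload = json.loads(text)
        d = payload["dim"]
        return cls(
            correlation=np.array(payload["correlation"]).reshape(d, d),
            element_map=payload["element_map"],
            h=np.array(payload["h_nats"]),
            block_logdets=np.array(payload["block_logdets"]),
            alpha=payload["alpha_nats"],
            shrinkage=payload.get("shrinkage", 0.0),
        )


def estimate_gaussian_model(
    obs: ObservationMatrix,
    alpha: float = DEFAULT_ALPHA_NATS,
) -> GaussianModel:
    """Fit the Gaussian-bound model to (rank-Gaussianized) observations.

    ``P_S`` is the sample correlation of the columns; within-element
    blocks and their differential entropies follow from its principal
    blocks (unit variances after the rank transform).  The caller is
    expected to have rank-Gaussianized ``obs`` first; the estimate is
    still well defined otherwise, but the lower-bound guarantee is not.

    Parameters
    ----------
    alpha : quantization offset in **nats** per variate (default 4 bits).
        Must be held fixed across any systems being compared.
    """
    T, D = obs.values.shape
    if T < 3:
        raise ValueError(f"need at least 3 time-samples to estimate, got {T}")
    if T <= D:
        warnings.warn(
            f"T={T} <= D={D}: correlation estimate is rank-deficient",
            stacklevel=2,
        )
    with np.errstate(invalid="raise"):
        try:
            P = np.corrcoef(obs.values, rowvar=False)
        except FloatingPointError as exc:
            raise ValueError(
                "constant column encountered while estimating correlations"
            ) from exc
    P = np.atleast_2d(P)
    P = 0.5 * (P + P.T)
    np.fill_diagonal(P, 1.0)

    # regularize the full matrix once; principal submatrices of a PD
    # matrix are PD, so downstream subset evaluations stay safe.
    shrinkage = 0.0
    eps = 1e-8
    while True:
        try:
            c, _ = cho_factor(P, lower=True, check_finite=False)
            if float(np.min(np.diag(c))) > 1e-6:
                break
            raise np.linalg.LinAlgError("numerically singular")
        except (np.linalg.LinAlgError, ValueError):
            if eps > 1e-4:
                raise ValueError(
                    "correlation matrix singular even after shrinkage 1e-4"
                )
            logger.warning(
                "estimate_gaussian_model: singular correlation matrix, "
                "shrinking with eps=%g",
                eps,
            )
            P = (1.0 - eps) * P + eps * np.eye(D)
            np.fill_diagonal(P, 1.0)
            shrinkage = eps
            eps *= 10.0

    sizes = [len(cols) for cols in obs.element_map]
    block_logdets = np.empty(len(sizes))
    h = np.empty(len(sizes))
    for i, cols in enumerate(obs.element_map):
        block = P[np.ix_(cols, cols)]
        block_logdets[i] = _regularized_logdet(block, f"element {i} block")
        h[i] = 0.5 * (sizes[i] * LN_2PI_E + block_logdets[i])

    logger.info(
        "estimate_gaussian_model: T=%d D=%d n=%d alpha=%.4f nats "
        "(%.2f bits), shrinkage=%g",
        T, D, len(sizes), alpha, nats_to_bits(alpha), shrinkage,
    )
    denom = float(np.sum(h + np.asarray(sizes) * alpha))
    if denom <= 0:
        raise ValueError(
            f"denominator sum_i (h_i + k_i*alpha) = {denom:.4f} <= 0; "
            "choose a larger alpha"
        )
    return GaussianModel(
        correlation=P,
        element_map=[list(c) for c in obs.element_map],
        h=h,
        block_logdets=block_logdets,
        alpha=alpha,
        shrinkage=shrinkage,
    )


def gaussian_total_correlation(
    model: GaussianModel,
    subset: Iterable[int],
    *,
    include_within: bool = False,
) -> float:
    """Gaussian bound on the total correlation of a subset, nats.

    Default behavior subtracts the within-element block terms so
    singleton subsets are exactly zero; ``include_within=True`` restores
    the literal variate-level -1/2 log det(P_A).
    """
    idx = sorted(set(int(i) for i in subset))
    if not idx:
        raise ValueError("subset must be nonempty")
    if len(idx) == 1 and not include_within:
        return 0.0
    cols = model.columns_of(idx)
    logdet = _regularized_logdet(
        model.correlation[np.ix_(cols, cols)], f"subset {idx}"
    )
    if include_within:
        return -0.5 * logdet
    within = float(model.block_logdets[idx].sum())
    # Fischer's inequality: det(P_A) <= prod_i det(P_i); clip rounding
    return max(-0.5 * (logdet - within), 0.0)


def gaussian_relative_redundancy(
    model: GaussianModel, subset: Iterable[int]
) -> float:
    """Lower-bound estimate of r(A); r({}) = 0 and r({i}) = 0."""
    idx = sorted(set(int(i) for i in subset))
    if len(idx) <= 1:
        return 0.0
    denom = model.denominator(idx)
    if denom <= 0:
        raise ValueError(
            f"denominator for subset {idx} is {denom:.4f} <= 0; "
            "increase alpha"
        )
    return gaussian_total_correlation(model, idx) / denom
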