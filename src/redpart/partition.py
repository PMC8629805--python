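"""Redundancy partitioning: decompose a system into coordinated components.

Elements i in S = {1..n} are assigned, probabilistically, to components
j in {1..m} via a row-stochastic matrix p(j|i).  A component j induces a
Bernoulli product measure over element subsets,

    p(A|j) = prod_{i in A} p(j|i) * prod_{i not in A} [1 - p(j|i)],

and is scored by its expected redundancy E[r(A)|j] = sum_A r(A) p(A|j).
The average over components, E[r(A)] = (1/m) sum_j E[r(A)|j], is the
objective.  Assignments that achieve a target average redundancy while
retaining as little as possible about element identity (minimal rate
I(S; S^)) satisfy a Blahut–Arimoto-style self-consistency condition,

    p(j|i) ∝ p(j) exp(beta * Δd(i, j)),

iterated together with the marginal refresh p(j) = sum_i p(j|i) p(i).
Δd(i, j) is the marginal value of element i to component j: the
expected redundancy with i included minus with i excluded, weighted by
1/p(i).  As beta -> infinity rows become one-hot and the scheme reduces
to greedy hard reassignment, which is what `solve_hard` implements
directly (and efficiently, for Gaussian-bound redundancy).

The exact expectations need 2^n subset evaluations (practical to around
n = 15); `delta_d_monte_carlo` provides the sampling estimator for
larger systems.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .gaussian import GaussianModel, _regularized_logdet

__all__ = [
    "Assignment",
    "PartitionResult",
    "DeltaCurve",
    "subset_probability",
    "expected_component_redundancy",
    "average_redundancy",
    "delta_d_exact",
    "delta_d_monte_carlo",
    "iterate_assignment",
    "solve_partition",
    "solve_hard",
    "component_scan",
    "achieved_rate",
]

logger = logging.getLogger(__name__)

EXACT_ENUMERATION_CAP = 15
_ROW_TOL = 1e-10


# ======================================================================
# Types
# ======================================================================


@dataclass
class Assignment:
    """Probabilistic assignment state p(j|i) with priors and marginals."""

    p_j_given_i: np.ndarray  # (n, m), rows sum to 1
    p_i: np.ndarray  # (n,) element prior
    beta: float = 1.0

    def __post_init__(self) -> None:
        Q = np.asarray(self.p_j_given_i, dtype=float)
        if Q.ndim != 2:
            raise ValueError("p_j_given_i must be an n x m matrix")
        if np.any(Q < -1e-12) or np.any(Q > 1 + 1e-12):
            raise ValueError("assignment probabilities must lie in [0, 1]")
        rows = Q.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > _ROW_TOL):
            raise ValueError("each row of p(j|i) must sum to 1")
        self.p_j_given_i = np.clip(Q, 0.0, 1.0)
        self.p_i = np.asarray(self.p_i, dtype=float)
        if self.p_i.shape != (Q.shape[0],):
            raise ValueError("p_i must have length n")
        if abs(self.p_i.sum() - 1.0) > _ROW_TOL or np.any(self.p_i < 0):
            raise ValueError("p_i must be a probability vector")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")

    @property
    def n(self) -> int:
        return self.p_j_given_i.shape[0]

    @property
    def m(self) -> int:
        return self.p_j_given_i.shape[1]

    @property
    def p_j(self) -> np.ndarray:
        """Component marginal p(j) = sum_i p(j|i) p(i)."""
        return self.p_i @ self.p_j_given_i

    def hard_labels(self) -> np.ndarray:
        """argmax_j p(j|i) per element (ties to the lowest index)."""
        return np.argmax(self.p_j_given_i, axis=1)

    @classmethod
    def random(
        cls, n: int, m: int, beta: float, rng: np.random.Generator
    ) -> "Assignment":
        """Rows drawn from a symmetric Dirichlet (concentration 1)."""
        Q = rng.dirichlet(np.ones(m), size=n)
        return cls(Q, np.full(n, 1.0 / n), beta)

    @classmethod
    def from_labels(
        cls, labels: Sequence[int], m: int, beta: float = math.inf
    ) -> "Assignment":
        labels = np.asarray(labels, dtype=int)
        n = labels.size
        Q = np.zeros((n, m))
        Q[np.arange(n), labels] = 1.0
        return cls(Q, np.full(n, 1.0 / n), beta)


@dataclass
class PartitionResult:
    """Converged partitioning solution."""

    assignment: Assignment
    component_redundancy: np.ndarray  # E[r(A)|j] per component
    average_redundancy: float
    rate: float  # I(S; S^), bits
    objective_trace: list[float]
    hard_labels: np.ndarray
    n_restarts_used: int
    seed: int | None
    converged: bool = True

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "p_j_given_i": self.assignment.p_j_given_i.tolist(),
            "p_i": self.assignment.p_i.tolist(),
            "beta": self.assignment.beta,
            "component_redundancy": self.component_redundancy.tolist(),
            "average_redundancy": self.average_redundancy,
            "rate_bits": self.rate,
            "objective_trace": list(self.objective_trace),
            "hard_labels": self.hard_labels.tolist(),
            "n_restarts_used": self.n_restarts_used,
            "seed": self.seed,
            "converged": self.converged,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    def labels_to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("element_id,component\n")
            for i, j in enumerate(self.hard_labels):
                fh.write(f"{i},{int(j)}\n")


@dataclass
class DeltaCurve:
    """Best average redundancy vs component count, and its Δ curve.

    Δ(m) = rbar(m-1) - rbar(m) for m >= 2: the cost of allowing one more
    component.  A small Δ followed by a large one marks the point where
    further subdivision starts to split strongly coordinated parts; the
    first local minimum of Δ is the structure-count heuristic.
    """

    m_values: list[int]
    best_average_redundancy: list[float]
    delta: list[float]  # Δ(m) for m = 2 .. m_max
    local_minima: list[int]
    first_local_minimum: int | None

    @classmethod
    def from_average_redundancy(
        cls, m_values: Sequence[int], rbar: Sequence[float],
        tie_tol: float = 1e-12,
    ) -> "DeltaCurve":
        m_values = list(m_values)
        rbar = [float(v) for v in rbar]
        if m_values != list(range(m_values[0], m_values[0] + len(m_values))):
            raise ValueError("m_values must be consecutive")
        if len(m_values) != len(rbar):
            raise ValueError("length mismatch")
        delta = [rbar[k - 1] - rbar[k] for k in range(1, len(rbar))]
        minima = _delta_local_minima(delta, m_values[1], tie_tol)
        return cls(
            m_values=m_values,
            best_average_redundancy=rbar,
            delta=delta,
            local_minima=minima,
            first_local_minimum=minima[0] if minima else None,
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "m_values": self.m_values,
            "best_average_redundancy": self.best_average_redundancy,
            "delta": self.delta,
            "local_minima": self.local_minima,
            "first_local_minimum": self.first_local_minimum,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text


def _delta_local_minima(
    delta: Sequence[float], m_first: int, tol: float
) -> list[int]:
    """Local minima of the Δ sequence (values at m = m_first, ...).

    Interior points need Δ(m) strictly below the left neighbor and no
    greater than the right one (ties broken toward smaller m).  The left
    end of the curve counts when it sits below its only neighbor; the
    right end never does (there is nothing beyond it to compare).
    """
    k = len(delta)
    minima = []
    for idx in range(k - 1):  # exclude the right endpoint
        if idx == 0:
            if delta[0] <= delta[1] + tol:
                minima.append(m_first)
        elif delta[idx] < delta[idx - 1] - tol and delta[idx] <= delta[idx + 1] + tol:
            minima.append(m_first + idx)
    return minima


# ======================================================================
# Expectations over the Bernoulli product measure p(A|j)
# ======================================================================


def _as_r_table(r_fn: Callable, n: int) -> np.ndarray:
    """Evaluate r on every subset of {0..n-1}; index = bitmask."""
    table = np.empty(1 << n)
    for mask in range(1 << n):
        members = tuple(i for i in range(n) if mask >> i & 1)
        table[mask] = r_fn(members)
    return table


def _membership_matrix(n: int) -> np.ndarray:
    """(2^n, n) boolean matrix: row `mask` marks the members of `mask`."""
    masks = np.arange(1 << n)[:, None]
    return (masks >> np.arange(n)[None, :] & 1).astype(bool)


def _check_cap(n: int) -> None:
    if n > EXACT_ENUMERATION_CAP:
        raise ValueError(
            f"exact power-set enumeration capped at n = "
            f"{EXACT_ENUMERATION_CAP} (got n = {n}); use the Monte-Carlo "
            "estimator instead"
        )


def subset_probability(
    assignment: Assignment, j: int, A: Iterable[int]
) -> float:
    """p(A|j): Bernoulli product probability of subset A for component j."""
    members = set(int(i) for i in A)
    q = assignment.p_j_given_i[:, j]
    prob = 1.0
    for i in range(assignment.n):
        prob *= q[i] if i in members else (1.0 - q[i])
    return prob


def _subset_probabilities(q: np.ndarray) -> np.ndarray:
    """Vector of p(A|j) over all 2^n masks for inclusion probs q."""
    n = q.size
    member = _membership_matrix(n)
    with np.errstate(divide="ignore"):
        logq = np.log(q, where=q > 0, out=np.full_like(q, -np.inf))
        log1mq = np.log1p(-q, where=q < 1, out=np.full_like(q, -np.inf))
    logp = member @ np.nan_to_num(logq, neginf=0.0) + (
        ~member
    ) @ np.nan_to_num(log1mq, neginf=0.0)
    # re-impose exact zeros where an impossible inclusion/exclusion occurs
    impossible = (member & (q == 0.0)[None, :]).any(axis=1) | (
        (~member) & (q == 1.0)[None, :]
    ).any(axis=1)
    p = np.exp(logp)
    p[impossible] = 0.0
    return p


def expected_component_redundancy(
    assignment: Assignment, j: int, r_fn: Callable
) -> float:
    """E[r(A)|j] = sum over the power set of r(A) p(A|j), exactly."""
    n = assignment.n
    _check_cap(n)
    r_table = _as_r_table(r_fn, n)
    p = _subset_probabilities(assignment.p_j_given_i[:, j])
    return float(r_table @ p)


def average_redundancy(assignment: Assignment, r_fn: Callable) -> float:
    """E[r(A)] = (1/m) sum_j E[r(A)|j]."""
    return float(
        np.mean(
            [
                expected_component_redundancy(assignment, j, r_fn)
                for j in range(assignment.m)
            ]
        )
    )


# ======================================================================
# Δd: the marginal value of an element to a component
# ======================================================================


def delta_d_exact(
    assignment: Assignment, i: int, j: int, r_fn: Callable
) -> float:
    """Δd(i,j) = d(i,j) - d_c(i,j) by exact enumeration.

    d(i,j) sums r(A) over subsets containing i, weighted by the product
    measure of the *other* elements' inclusions, f_i(A|j), divided by
    p(i); d_c is the same over subsets excluding i.  Equivalently,
    Δd(i,j) = E_B[r(B ∪ {i}) - r(B)] / p(i) with B drawn from the
    other elements' inclusion probabilities.
    """
    n = assignment.n
    _check_cap(n)
    p_i = float(assignment.p_i[i])
    if p_i == 0.0:
        raise ValueError(f"p(i) = 0 for element {i}")
    q = assignment.p_j_given_i[:, j].copy()
    # weight of each mask from the other elements' inclusions only
    q[i] = 0.0  # exclude i: masks without i's bit carry the full weight
    w = _subset_probabilities(q)
    r_table = _as_r_table(r_fn, n)
    bit = 1 << i
    masks = np.flatnonzero(w)
    total = float(
        w[masks] @ (r_table[masks | bit] - r_table[masks])
    )
    return total / p_i


def delta_d_monte_carlo(
    assignment: Assignment,
    i: int,
    j: int,
    r_fn: Callable,
    K: int,
    rng: np.random.Generator | int | None = None,
    return_se: bool = False,
):
    """Monte-Carlo estimate of Δd(i,j).

    Draws K subsets by independent inclusion of each element k != i with
    probability p(j|k) and averages r(A ∪ {i}) - r(A \\ {i}); shared
    samples for the two terms make the difference low-variance.
    Reproducible given a seed.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(rng)
    n = assignment.n
    p_i = float(assignment.p_i[i])
    if p_i == 0.0:
        raise ValueError(f"p(i) = 0 for element {i}")
    q = assignment.p_j_given_i[:, j]
    include = rng.random((K, n)) < q[None, :]
    include[:, i] = False
    # collapse to unique subsets: r is evaluated once per distinct draw
    uniq, counts = np.unique(include, axis=0, return_counts=True)
    diffs = np.empty(uniq.shape[0])
    for row, members in enumerate(uniq):
        base = tuple(np.flatnonzero(members))
        diffs[row] = r_fn(base + (i,)) - r_fn(base)
    est = float((counts @ diffs) / K / p_i)
    if not return_se:
        return est
    mean = (counts @ diffs) / K
    var = float(counts @ (diffs - mean) ** 2) / K
    se = math.sqrt(var / K) / p_i
    return est, se


# ======================================================================
# Alternating-minimization updates
# ======================================================================


def _delta_d_matrix(
    assignment: Assignment,
    r_fn: Callable,
    estimator: str,
    K: int,
    rng: np.random.Generator,
) -> np.ndarray:
    n, m = assignment.n, assignment.m
    dd = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            if estimator == "exact":
                dd[i, j] = delta_d_exact(assignment, i, j, r_fn)
            else:
                dd[i, j] = delta_d_monte_carlo(
                    assignment, i, j, r_fn, K, rng
                )
    return dd


def iterate_assignment(
    assignment: Assignment,
    r_fn: Callable,
    estimator: str = "exact",
    K: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> Assignment:
    """One synchronous update cycle of the self-consistent equations.

    All rows are recomputed from the current marginals p(j) and Δd, then
    p(j) is refreshed from the new rows (the subset measure p(A|j)
    follows implicitly).  Exponentials are stabilized by subtracting the
    per-row max of beta * Δd.
    """
    if estimator not in ("exact", "mc"):
        raise ValueError("estimator must be 'exact' or 'mc'")
    rng = np.random.default_rng(rng)
    beta = assignment.beta
    dd = _delta_d_matrix(assignment, r_fn, estimator, K, rng)
    scores = beta * dd
    scores -= scores.max(axis=1, keepdims=True)
    with np.errstate(over="raise"):
        weights = assignment.p_j[None, :] * np.exp(scores)
    norm = weights.sum(axis=1, keepdims=True)
    if np.any(norm <= 0) or not np.all(np.isfinite(norm)):
        raise FloatingPointError("assignment update overflow/underflow")
    Q = weights / norm
    return Assignment(Q, assignment.p_i.copy(), beta)


def achieved_rate(assignment: Assignment) -> float:
    """I(S; S^) = sum_{i,j} p(i) p(j|i) log2 [p(j|i) / p(j)], bits."""
    Q = assignment.p_j_given_i
    pj = assignment.p_j
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(Q > 0, Q / pj[None, :], 1.0)
        terms = np.where(Q > 0, Q * np.log2(ratio), 0.0)
    return max(float(assignment.p_i @ terms.sum(axis=1)), 0.0)


def _result_from_assignment(
    assignment: Assignment,
    r_fn: Callable,
    trace: list[float],
    restarts: int,
    seed: int | None,
    converged: bool,
) -> PartitionResult:
    comp = np.array(
        [
            expected_component_redundancy(assignment, j, r_fn)
            for j in range(assignment.m)
        ]
    )
    return PartitionResult(
        assignment=assignment,
        component_redundancy=comp,
        average_redundancy=float(comp.mean()),
        rate=achieved_rate(assignment),
        objective_trace=trace,
        hard_labels=assignment.hard_labels(),
        n_restarts_used=restarts,
        seed=seed,
        converged=converged,
    )


def solve_partition(
    model_or_r_fn,
    m: int,
    beta: float,
    n: int | None = None,
    restarts: int = 100,
    max_iter: int = 500,
    tol: float = 1e-9,
    estimator: str = "exact",
    K: int = 1000,
    seed: int | None = None,
) -> PartitionResult:
    """Best soft partition over seeded random restarts.

    Each restart initializes p(j|i) rows from a symmetric Dirichlet and
    iterates the update cycle until the average redundancy changes by
    less than ``tol`` (or the assignment matrix stabilizes), up to
    ``max_iter`` cycles.  The restart with the highest average expected
    redundancy wins.  Surplus components simply end up empty.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    r_fn, n = _resolve_r_fn(model_or_r_fn, n)
    _check_cap(n)
    master = np.random.default_rng(seed)
    best: PartitionResult | None = None
    for _ in range(restarts):
        rng = np.random.default_rng(master.integers(2**31))
        assignment = Assignment.random(n, m, beta, rng)
        trace = [average_redundancy(assignment, r_fn)]
        best_iterate, best_obj = assignment, trace[0]
        prev_prev: np.ndarray | None = None
        converged = False
        for _it in range(max_iter):
            new = iterate_assignment(assignment, r_fn, estimator, K, rng)
            obj = average_redundancy(new, r_fn)
            drift = float(
                np.max(np.abs(new.p_j_given_i - assignment.p_j_given_i))
            )
            # synchronous updates can enter a 2-cycle at large beta
            cycle = prev_prev is not None and float(
                np.max(np.abs(new.p_j_given_i - prev_prev))
            ) < 1e-10
            prev_prev = assignment.p_j_given_i
            assignment = new
            trace.append(obj)
            if obj > best_obj:
                best_obj, best_iterate = obj, new
            if abs(trace[-1] - trace[-2]) < tol or drift < 1e-8 or cycle:
                converged = not cycle
                break
        if not converged:
            logger.warning(
                "solve_partition: restart did not settle in %d iterations "
                "(best iterate kept)",
                _it + 1,
            )
        candidate = _result_from_assignment(
            best_iterate, r_fn, trace, restarts, seed, converged
        )
        if best is None or candidate.average_redundancy > best.average_redundancy:
            best = candidate
    assert best is not None
    return best


def _resolve_r_fn(model_or_r_fn, n: int | None):
    if isinstance(model_or_r_fn, GaussianModel):
        return model_or_r_fn.subset_r_function(), model_or_r_fn.n_elements
    if n is None:
        raise ValueError("n must be given when passing a bare r_fn")
    return model_or_r_fn, n


# ======================================================================
# Hard-partition (beta -> infinity) greedy solver
# ======================================================================


class _HardObjective:
    """Cached subset-redundancy evaluations keyed by element bitmask.

    For a Gaussian model the redundancy of a subset costs one Cholesky
    factorization of a principal correlation submatrix; the cache makes
    repeated visits (across greedy passes and restarts) nearly free.
    """

    def __init__(self, model_or_r_fn, n: int | None = None):
        if isinstance(model_or_r_fn, GaussianModel):
            model = model_or_r_fn
            self.n = model.n_elements
            cols = [np.asarray(c, dtype=int) for c in model.element_map]
            sizes = np.array([c.size for c in cols])
            den_i = model.h + sizes * model.alpha
            P = model.correlation
            blocks = model.block_logdets

            def compute(members: tuple[int, ...]) -> float:
                idx = np.concatenate([cols[i] for i in members])
                logdet = _regularized_logdet(
                    P[np.ix_(idx, idx)], f"subset {members}"
                )
                num = max(-0.5 * (logdet - blocks[list(members)].sum()), 0.0)
                return num / den_i[list(members)].sum()

            self._compute = compute
        else:
            if n is None:
                raise ValueError("n must be given when passing a bare r_fn")
            self.n = n
            r_fn = model_or_r_fn
            self._compute = lambda members: r_fn(members)
        self._cache: dict[int, float] = {}

    def r_mask(self, mask: int) -> float:
        if mask & (mask - 1) == 0:  # empty set or singleton
            return 0.0
        value = self._cache.get(mask)
        if value is None:
            members = tuple(
                i for i in range(self.n) if mask >> i & 1
            )
            value = float(self._compute(members))
            self._cache[mask] = value
        return value


def _greedy_hard_pass(
    obj: _HardObjective,
    labels: np.ndarray,
    masks: list[int],
    r_comp: list[float],
    order: np.ndarray,
) -> bool:
    """One sequential reassignment pass; returns True if any move taken."""
    m = len(masks)
    moved = False
    for i in order:
        i = int(i)
        bit = 1 << i
        c = int(labels[i])
        gain_out = obj.r_mask(masks[c] & ~bit) - r_comp[c]
        best_j, best_delta = c, 0.0
        for j in range(m):
            if j == c:
                continue
            delta = obj.r_mask(masks[j] | bit) - r_comp[j] + gain_out
            if delta > best_delta + 1e-12:
                best_delta, best_j = delta, j
        if best_j != c:
            masks[c] &= ~bit
            masks[best_j] |= bit
            r_comp[c] = obj.r_mask(masks[c])
            r_comp[best_j] = obj.r_mask(masks[best_j])
            labels[i] = best_j
            moved = True
    return moved


def solve_hard(
    model_or_r_fn,
    m: int,
    restarts: int = 100,
    seed: int | None = None,
    n: int | None = None,
    max_passes: int = 200,
) -> PartitionResult:
    """Hard-partition limit: greedy sequential reassignment.

    Elements are visited in a seeded random order; each is moved to the
    component that maximizes the average-redundancy objective (ties to
    the lowest component index), until a full pass makes no move.  Equals
    the beta -> infinity limit of `solve_partition` and accepts m > n
    (surplus components stay empty).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    obj = _HardObjective(model_or_r_fn, n)
    n_el = obj.n
    master = np.random.default_rng(seed)
    best_labels: np.ndarray | None = None
    best_trace: list[float] = []
    best_avg = -np.inf
    best_converged = True
    for _ in range(restarts):
        rng = np.random.default_rng(master.integers(2**31))
        labels = rng.integers(0, m, size=n_el)
        masks = [0] * m
        for i, lab in enumerate(labels):
            masks[int(lab)] |= 1 << i
        r_comp = [obj.r_mask(mask) for mask in masks]
        trace = [sum(r_comp) / m]
        converged = False
        for _p in range(max_passes):
            order = rng.permutation(n_el)
            if not _greedy_hard_pass(obj, labels, masks, r_comp, order):
                converged = True
                break
            trace.append(sum(r_comp) / m)
        if not converged:
            logger.warning(
                "solve_hard: no fixed point after %d passes", max_passes
            )
        avg = sum(r_comp) / m
        if avg > best_avg:
            best_avg = avg
            best_labels = labels.copy()
            best_trace = trace
            best_converged = converged
    assert best_labels is not None
    assignment = Assignment.from_labels(best_labels, m)
    comp = np.array(
        [
            obj.r_mask(sum(1 << i for i in np.flatnonzero(best_labels == j)))
            for j in range(m)
        ]
    )
    return PartitionResult(
        assignment=assignment,
        component_redundancy=comp,
        average_redundancy=float(comp.mean()),
        rate=achieved_rate(assignment),
        objective_trace=best_trace,
        hard_labels=best_labels,
        n_restarts_used=restarts,
        seed=seed,
        converged=best_converged,
    )


def component_scan(
    model_or_r_fn,
    m_max: int = 10,
    restarts: int = 100,
    seed: int | None = None,
    n: int | None = None,
    solver: str = "hard",
    beta: float = 200.0,
    **solver_kwargs,
) -> DeltaCurve:
    """Best average redundancy for m = 1..m_max and the Δ curve.

    The hard solver (default) shares its subset-redundancy cache across
    the whole scan.
    """
    if m_max < 2:
        raise ValueError("m_max must be >= 2")
    master = np.random.default_rng(seed)
    rbar = []
    if solver == "hard":
        obj = _HardObjective(model_or_r_fn, n)
        shared = obj  # one cache for the whole scan
        for m in range(1, m_max + 1):
            res = solve_hard(
                _SharedObjectiveProxy(shared),
                m,
                restarts=restarts if m > 1 else 1,
                seed=int(master.integers(2**31)),
                n=shared.n,
                **solver_kwargs,
            )
            rbar.append(res.average_redundancy)
    elif solver == "soft":
        for m in range(1, m_max + 1):
            res = solve_partition(
                model_or_r_fn,
                m,
                beta=beta,
                n=n,
                restarts=restarts if m > 1 else 1,
                seed=int(master.integers(2**31)),
                **solver_kwargs,
            )
            rbar.append(res.average_redundancy)
    else:
        raise ValueError("solver must be 'hard' or 'soft'")
    return DeltaCurve.from_average_redundancy(
        list(range(1, m_max + 1)), rbar
    )


class _SharedObjectiveProxy:
    """Adapter letting several `solve_hard` calls reuse one cache."""

    def __init__(self, obj: _HardObjective):
        self._obj = obj

    def __call__(self, members: tuple[int, ...]) -> float:
        mask = 0
        for i in members:
            mask |= 1 << int(i)
        return self._obj.r_mask(mask)
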