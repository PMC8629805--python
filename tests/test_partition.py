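"""Redundancy partitioning: expectations, updates, and solvers."""

import itertools
import math

import numpy as np
import pytest

from redpart import (
    Assignment,
    DeltaCurve,
    achieved_rate,
    average_redundancy,
    component_scan,
    delta_d_exact,
    delta_d_monte_carlo,
    expected_component_redundancy,
    iterate_assignment,
    solve_hard,
    solve_partition,
    subset_probability,
)

from .conftest import random_r_fn, scalar_gaussian_model


# ----------------------------------------------------------------------
# independent oracles
# ----------------------------------------------------------------------


def all_subsets(n):
    for size in range(n + 1):
        yield from itertools.combinations(range(n), size)


def brute_expected_redundancy(assignment, j, r_fn):
    return sum(
        r_fn(A) * subset_probability(assignment, j, A)
        for A in all_subsets(assignment.n)
    )


def set_partitions_up_to(n, m):
    """All set partitions of {0..n-1} into at most m blocks (as labels)."""
    def grow(labels, used):
        i = len(labels)
        if i == n:
            yield tuple(labels)
            return
        for j in range(min(used + 1, m)):
            yield from grow(labels + [j], max(used, j + 1) if j == used else used)
    yield from grow([], 0)


def exhaustive_best_partition(r_fn, n, m):
    best, best_labels = -np.inf, None
    for labels in set_partitions_up_to(n, m):
        comps = [
            tuple(i for i in range(n) if labels[i] == j) for j in range(m)
        ]
        avg = sum(r_fn(c) for c in comps) / m
        if avg > best:
            best, best_labels = avg, labels
    return best, best_labels


# ----------------------------------------------------------------------
# subset probabilities and expectations
# ----------------------------------------------------------------------


class TestSubsetProbability:
    def test_hard_assignment_concentrates_on_the_component_set(self):
        a = Assignment.from_labels([0, 0, 1], m=2)
        assert subset_probability(a, 0, [0, 1]) == 1.0
        assert subset_probability(a, 0, [0]) == 0.0
        assert subset_probability(a, 1, [2]) == 1.0

    def test_uniform_half_probabilities(self):
        a = Assignment(np.full((2, 2), 0.5), np.full(2, 0.5))
        for A in all_subsets(2):
            assert subset_probability(a, 0, A) == pytest.approx(0.25)

    def test_bernoulli_product_normalizes(self, rng):
        a = Assignment.random(5, 3, beta=1.0, rng=rng)
        for j in range(3):
            total = sum(subset_probability(a, j, A) for A in all_subsets(5))
            assert total == pytest.approx(1.0, abs=1e-12)


class TestExpectations:
    def test_hard_assignment_returns_component_redundancy(self, rng):
        r_fn = random_r_fn(rng, 4)
        a = Assignment.from_labels([0, 0, 1, 1], m=2)
        assert expected_component_redundancy(a, 0, r_fn) == pytest.approx(
            r_fn((0, 1))
        )

    def test_all_singletons_score_zero(self, rng):
        r_fn = random_r_fn(rng, 4)
        a = Assignment.from_labels([0, 1, 2, 3], m=4)
        for j in range(4):
            assert expected_component_redundancy(a, j, r_fn) == 0.0
        assert average_redundancy(a, r_fn) == 0.0

    def test_soft_assignments_match_power_set_oracle(self, rng):
        for _ in range(20):
            r_fn = random_r_fn(rng, 4)
            a = Assignment.random(4, 2, beta=2.0, rng=rng)
            for j in range(2):
                assert expected_component_redundancy(a, j, r_fn) == pytest.approx(
                    brute_expected_redundancy(a, j, r_fn), abs=1e-10
                )
            assert average_redundancy(a, r_fn) == pytest.approx(
                np.mean([brute_expected_redundancy(a, j, r_fn) for j in range(2)]),
                abs=1e-10,
            )

    def test_enumeration_cap_enforced(self, rng):
        a = Assignment.random(16, 2, beta=1.0, rng=rng)
        with pytest.raises(ValueError, match="Monte-Carlo"):
            expected_component_redundancy(a, 0, lambda A: 0.0)


# ----------------------------------------------------------------------
# Delta d
# ----------------------------------------------------------------------


class TestDeltaD:
    def test_zero_redundancy_gives_zero_everywhere(self, rng):
        a = Assignment.random(5, 3, beta=1.0, rng=rng)
        for i in range(5):
            for j in range(3):
                assert delta_d_exact(a, i, j, lambda A: 0.0) == 0.0

    def test_hard_assignment_closed_form(self, rng):
        # uniform p(i): Delta d = n * [r(A_j + i) - r(A_j - i)]
        r_fn = random_r_fn(rng, 5)
        a = Assignment.from_labels([0, 0, 0, 1, 1], m=2)
        n = 5
        for i in range(n):
            for j in range(2):
                A_j = tuple(k for k in range(n) if a.hard_labels()[k] == j)
                with_i = tuple(sorted(set(A_j) | {i}))
                without_i = tuple(k for k in A_j if k != i)
                expect = n * (r_fn(with_i) - r_fn(without_i))
                assert delta_d_exact(a, i, j, r_fn) == pytest.approx(expect)

    def test_matches_finite_difference_of_expected_redundancy(self, rng):
        # d E[r|j] / d p(j|i) = p(i) * Delta d(i, j)
        r_fn = random_r_fn(rng, 4)
        a = Assignment.random(4, 2, beta=1.0, rng=rng)
        h = 1e-6
        for i, j in itertools.product(range(4), range(2)):
            def E(eps):
                Q = a.p_j_given_i.copy()
                Q[i, j] += eps
                q = Q[:, j]
                total = 0.0
                for A in all_subsets(4):
                    prob = 1.0
                    for k in range(4):
                        prob *= q[k] if k in A else 1 - q[k]
                    total += r_fn(A) * prob
                return total
            fd = (E(h) - E(-h)) / (2 * h)
            assert delta_d_exact(a, i, j, r_fn) == pytest.approx(
                fd / a.p_i[i], abs=1e-5
            )

    def test_monte_carlo_is_exact_for_hard_assignments(self, rng):
        r_fn = random_r_fn(rng, 5)
        a = Assignment.from_labels([0, 1, 0, 1, 0], m=2)
        for i, j in [(0, 0), (2, 1), (4, 0)]:
            est = delta_d_monte_carlo(a, i, j, r_fn, K=7, rng=0)
            assert est == pytest.approx(delta_d_exact(a, i, j, r_fn), abs=1e-12)

    def test_monte_carlo_within_three_standard_errors(self, rng):
        r_fn = random_r_fn(rng, 6)
        a = Assignment.random(6, 2, beta=1.0, rng=rng)
        exact = delta_d_exact(a, 2, 1, r_fn)
        est, se = delta_d_monte_carlo(
            a, 2, 1, r_fn, K=20000, rng=1, return_se=True
        )
        assert abs(est - exact) < 3 * se + 1e-12

    def test_monte_carlo_deterministic_given_seed(self, rng):
        r_fn = random_r_fn(rng, 5)
        a = Assignment.random(5, 2, beta=1.0, rng=rng)
        first = delta_d_monte_carlo(a, 1, 0, r_fn, K=500, rng=42)
        second = delta_d_monte_carlo(a, 1, 0, r_fn, K=500, rng=42)
        assert first == second


# ----------------------------------------------------------------------
# update cycle, rate, solvers
# ----------------------------------------------------------------------


class TestIterateAssignment:
    def test_beta_zero_decouples_from_data(self, rng):
        r_fn = random_r_fn(rng, 4)
        a = Assignment.random(4, 3, beta=0.0, rng=rng)
        new = iterate_assignment(a, r_fn)
        assert np.allclose(new.p_j_given_i, np.tile(a.p_j, (4, 1)))

    def test_large_beta_hardens_to_argmax(self, rng):
        r_fn = random_r_fn(rng, 5)
        a = Assignment.random(5, 2, beta=2000.0, rng=rng)
        dd = np.array(
            [[delta_d_exact(a, i, j, r_fn) for j in range(2)] for i in range(5)]
        )
        new = iterate_assignment(a, r_fn)
        assert np.array_equal(new.hard_labels(), np.argmax(dd, axis=1))
        assert np.all(new.p_j_given_i.max(axis=1) > 0.99)

    def test_rows_stay_normalized(self, rng):
        r_fn = random_r_fn(rng, 5)
        a = Assignment.random(5, 3, beta=7.0, rng=rng)
        new = iterate_assignment(a, r_fn)
        assert np.allclose(new.p_j_given_i.sum(axis=1), 1.0, atol=1e-10)


class TestAchievedRate:
    def test_equal_hard_groups_give_log2_m_bits(self):
        a = Assignment.from_labels([0, 0, 1, 1, 2, 2], m=3)
        assert achieved_rate(a) == pytest.approx(math.log2(3))

    def test_decoupled_assignment_has_zero_rate(self):
        a = Assignment(np.tile([0.3, 0.7], (4, 1)), np.full(4, 0.25))
        assert achieved_rate(a) == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative_on_random_assignments(self, rng):
        for _ in range(20):
            a = Assignment.random(6, 3, beta=1.0, rng=rng)
            assert achieved_rate(a) >= 0.0


class TestSolvePartition:
    def test_single_component_returns_full_system_redundancy(self, rng):
        r_fn = random_r_fn(rng, 4)
        res = solve_partition(r_fn, m=1, beta=10.0, n=4, restarts=2, seed=0)
        assert res.average_redundancy == pytest.approx(r_fn(tuple(range(4))))

    def test_recovers_duplicate_pairs(self, two_pair_model):
        res = solve_partition(two_pair_model, m=2, beta=200.0, restarts=10, seed=3)
        groups = {frozenset(np.flatnonzero(res.hard_labels == j)) for j in range(2)}
        assert groups == {frozenset({0, 1}), frozenset({2, 3})}
        # exhaustive search confirms this is the global optimum
        best, _ = exhaustive_best_partition(
            two_pair_model.subset_r_function(), 4, 2
        )
        assert res.average_redundancy == pytest.approx(best, abs=1e-9)

    def test_independent_elements_score_zero_at_m_equals_n(self):
        model = scalar_gaussian_model(np.eye(4))
        res = solve_partition(model, m=4, beta=50.0, restarts=5, seed=1)
        assert res.average_redundancy == pytest.approx(0.0, abs=1e-12)


class TestSolveHard:
    def test_duplicates_share_a_component(self):
        P = np.eye(3)
        P[0, 1] = P[1, 0] = 0.999
        model = scalar_gaussian_model(P)
        res = solve_hard(model, m=2, restarts=10, seed=0)
        assert res.hard_labels[0] == res.hard_labels[1]
        assert res.hard_labels[2] != res.hard_labels[0]

    @pytest.mark.parametrize("n,m", [(5, 2), (6, 3), (8, 3)])
    def test_matches_exhaustive_search(self, rng, n, m):
        # random PSD correlation structure
        A = rng.standard_normal((n, n + 3))
        C = A @ A.T
        d = np.sqrt(np.diag(C))
        P = C / np.outer(d, d)
        model = scalar_gaussian_model(P)
        res = solve_hard(model, m=m, restarts=30, seed=5)
        best, _ = exhaustive_best_partition(model.subset_r_function(), n, m)
        assert res.average_redundancy == pytest.approx(best, abs=1e-9)

    def test_objective_trace_is_nondecreasing(self, two_pair_model):
        res = solve_hard(two_pair_model, m=2, restarts=3, seed=2)
        trace = np.array(res.objective_trace)
        assert np.all(np.diff(trace) >= -1e-12)

    def test_agrees_with_soft_solver_at_large_beta(self):
        # seeded n=8 fixture: two coordinated groups of four plus weak
        # cross-talk, so the hard optimum is nontrivial but well separated
        P = np.eye(8)
        for block in (range(4), range(4, 8)):
            for a, b in itertools.combinations(block, 2):
                P[a, b] = P[b, a] = 0.75
        P[0, 4] = P[4, 0] = 0.1
        model = scalar_gaussian_model(P)
        hard = solve_hard(model, m=2, restarts=15, seed=7)
        soft = solve_partition(model, m=2, beta=200.0, restarts=15, seed=7)
        assert soft.average_redundancy == pytest.approx(
            hard.average_redundancy, abs=1e-6
        )
        assert np.array_equal(
            np.sort(soft.hard_labels), np.sort(hard.hard_labels)
        )

    def test_surplus_components_end_empty(self, two_pair_model):
        res = solve_hard(two_pair_model, m=6, restarts=10, seed=0)
        occupied = set(res.hard_labels.tolist())
        assert len(occupied) <= 4

    def test_permutation_equivariance(self, rng, two_pair_model):
        perm = np.array([2, 3, 0, 1])
        P = two_pair_model.correlation[np.ix_(perm, perm)]
        permuted = scalar_gaussian_model(P)
        a = solve_hard(two_pair_model, m=2, restarts=10, seed=4)
        b = solve_hard(permuted, m=2, restarts=10, seed=4)
        assert a.average_redundancy == pytest.approx(b.average_redundancy, abs=1e-12)
        groups_a = {
            frozenset(int(i) for i in np.flatnonzero(a.hard_labels == j))
            for j in range(2)
        }
        groups_b_original = {
            frozenset(int(perm[i]) for i in np.flatnonzero(b.hard_labels == j))
            for j in range(2)
        }
        assert groups_a == groups_b_original


class TestBetaStabilization:
    def test_average_redundancy_constant_above_beta_ten(self):
        # n=10 fixture with two coordination blocks: solutions stabilize
        # (within 2%) once beta is past the soft regime
        P = np.eye(10)
        for blk in (range(5), range(5, 10)):
            for a, b in itertools.combinations(blk, 2):
                P[a, b] = P[b, a] = 0.9
        model = scalar_gaussian_model(P)
        values = [
            solve_partition(model, m=2, beta=beta, restarts=10, seed=2
                            ).average_redundancy
            for beta in (10, 50, 200, 1000)
        ]
        spread = (max(values) - min(values)) / np.mean(values)
        assert spread < 0.02


class TestComponentScan:
    def test_injected_delta_sequence_minima(self):
        # Delta = (3, 1, 4, 2, 5) over m = 2..6
        rbar = [10.0]
        for d in (3, 1, 4, 2, 5):
            rbar.append(rbar[-1] - d)
        curve = DeltaCurve.from_average_redundancy(range(1, 7), rbar)
        assert curve.delta == pytest.approx([3, 1, 4, 2, 5])
        assert curve.local_minima == [3, 5]
        assert curve.first_local_minimum == 3

    def test_convex_decreasing_curve_has_no_minimum(self):
        rbar = [1.0 / m for m in range(1, 8)]
        curve = DeltaCurve.from_average_redundancy(range(1, 8), rbar)
        assert curve.local_minima == []
        assert curve.first_local_minimum is None

    def test_left_endpoint_can_be_a_minimum(self):
        rbar = [0.5, 0.49, 0.40, 0.35]  # Delta = (0.01, 0.09, 0.05)
        curve = DeltaCurve.from_average_redundancy(range(1, 5), rbar)
        assert curve.first_local_minimum == 2

    def test_best_redundancy_nonincreasing_on_nested_structure(self, rng):
        # equicorrelated system: every split strictly costs redundancy
        n = 6
        P = np.full((n, n), 0.6)
        np.fill_diagonal(P, 1.0)
        model = scalar_gaussian_model(P)
        curve = component_scan(model, m_max=6, restarts=15, seed=0)
        diffs = np.diff(curve.best_average_redundancy)
        assert np.all(diffs <= 1e-10)

    def test_serialization_round_trip(self, two_pair_model, tmp_path):
        import json

        curve = component_scan(two_pair_model, m_max=4, restarts=5, seed=1)
        payload = json.loads(curve.to_json(tmp_path / "curve.json"))
        assert payload["m_values"] == [1, 2, 3, 4]
        assert payload["first_local_minimum"] == curve.first_local_minimum
        res = solve_hard(two_pair_model, m=2, restarts=5, seed=1)
        res.labels_to_csv(tmp_path / "labels.csv")
        lines = (tmp_path / "labels.csv").read_text().strip().splitlines()
        assert lines[0] == "element_id,component"
        assert len(lines) == 5
        round_trip = json.loads(res.to_json())
        assert round_trip["average_redundancy"] == res.average_redundancy
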