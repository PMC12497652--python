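"""Cycle geometry: normalization, strength, ordering, inference, matching."""

import itertools
import json

import networkx as nx
import numpy as np
import pytest

from tinda import (
    AsymmetryMatrix,
    CircleLayout,
    cycle_strength,
    export_circle_graph,
    match_states,
    normalization_beta,
    optimize_ordering,
    permutation_test_cycle_strength,
    phase_difference,
)
from tinda.cycle_analysis import circle_graph_document, load_circle_graph
from tinda.tinda_core import group_asymmetry_test


def perfect_clockwise_matrix(K):
    """+1 on every clockwise ordered pair, −1 counterclockwise (identity order)."""
    q = 2 * np.pi * np.arange(K) / K
    return np.sign(np.sin(q[None, :] - q[:, None]))


def direct_cycle_strength(A, ordering):
    """Literal double-sum evaluation, independent of the vectorized path."""
    K = len(ordering)
    pos = {s: i for i, s in enumerate(ordering)}
    q = {s: 2 * np.pi * pos[s] / K for s in ordering}
    raw_max = sum(
        abs(np.sin(2 * np.pi * (i - j) / K))
        for i in range(K) for j in range(K) if i != j
    )
    total = sum(
        A[m - 1, n - 1] * np.sin(q[m] - q[n])
        for m in ordering for n in ordering if m != n
    )
    return -total / raw_max


class TestBeta:
    def test_k3_direct_summation(self):
        # 6 ordered pairs, each |sin(±2π/3)| = √3/2
        assert normalization_beta(3) == pytest.approx(1 / (6 * np.sqrt(3) / 2))
        assert normalization_beta(3) == pytest.approx(0.19245, abs=1e-5)

    def test_k4_direct_summation(self):
        # 8 pairs with |sin| = 1, 4 opposite pairs with sin(π) = 0
        assert normalization_beta(4) == pytest.approx(1 / 8)

    def test_k2_degenerate(self):
        with pytest.raises(ValueError):
            normalization_beta(2)


class TestCycleStrength:
    @pytest.mark.parametrize("K", [3, 4, 5, 8, 12])
    def test_perfect_clockwise_matrix_scores_one(self, K):
        S = cycle_strength(perfect_clockwise_matrix(K), CircleLayout.identity(K))
        assert S == pytest.approx(1.0, abs=1e-12)

    def test_zero_matrix_scores_zero(self):
        assert cycle_strength(np.zeros((5, 5)), CircleLayout.identity(5)) == 0.0

    def test_reflection_negates(self, rng):
        A = rng.normal(0, 0.1, (6, 6))
        np.fill_diagonal(A, 0)
        lay = CircleLayout.identity(6)
        assert cycle_strength(A, lay.reflected()) == pytest.approx(
            -cycle_strength(A, lay)
        )

    def test_rotation_invariant(self, rng):
        A = rng.normal(0, 0.1, (6, 6))
        np.fill_diagonal(A, 0)
        base = cycle_strength(A, CircleLayout(np.arange(1, 7)))
        for r in range(1, 6):
            rolled = CircleLayout(np.roll(np.arange(1, 7), r))
            assert cycle_strength(A, rolled) == pytest.approx(base)

    def test_transpose_negates(self, rng):
        A = rng.normal(0, 0.1, (7, 7))
        np.fill_diagonal(A, 0)
        lay = CircleLayout.identity(7)
        assert cycle_strength(A.T, lay) == pytest.approx(-cycle_strength(A, lay))

    def test_matches_literal_double_sum(self, rng):
        A = rng.normal(0, 0.1, (5, 5))
        np.fill_diagonal(A, 0)
        ordering = [3, 1, 4, 5, 2]
        assert cycle_strength(A, CircleLayout(ordering)) == pytest.approx(
            direct_cycle_strength(A, ordering)
        )


class TestOptimizeOrdering:
    def test_exhaustive_matches_bruteforce(self, rng):
        A = rng.normal(0, 0.2, (5, 5))
        np.fill_diagonal(A, 0)
        _, S = optimize_ordering(A, method="exhaustive")
        best = max(
            direct_cycle_strength(A, (1,) + p)
            for p in itertools.permutations(range(2, 6))
        )
        assert S == pytest.approx(best)

    def test_local_search_matches_exhaustive_k6(self, rng):
        for _ in range(10):
            A = rng.normal(0, 0.2, (6, 6))
            np.fill_diagonal(A, 0)
            _, s_ex = optimize_ordering(A, method="exhaustive")
            _, s_ls = optimize_ordering(A, method="local_search", seed=1,
                                        n_restarts=20)
            assert s_ls == pytest.approx(s_ex, abs=1e-10)

    def test_recovers_generative_order(self):
        # rotational drift along a known order: asymmetry follows the
        # tangential (sinusoidal) pattern of that arrangement
        K = 7
        true_order = np.array([1, 4, 2, 7, 5, 3, 6])
        pos = np.empty(K, dtype=int)
        pos[true_order - 1] = np.arange(K)
        q = 2 * np.pi * pos / K
        A = 0.5 * np.sin(q[None, :] - q[:, None])
        layout, S = optimize_ordering(A)
        # recovered up to rotation (canonical form pins state 1 at phase 0)
        rolled = np.roll(true_order, -int(np.argmin(true_order)))
        assert layout.ordering.tolist() == rolled.tolist()
        assert S > 0

    def test_canonical_form(self, rng):
        A = rng.normal(0, 0.2, (6, 6))
        np.fill_diagonal(A, 0)
        layout, S = optimize_ordering(A)
        assert layout.ordering[0] == 1
        assert S >= cycle_strength(A, CircleLayout.identity(6))
        assert S >= 0

    def test_k3_all_orderings_equivalent(self, rng):
        A = rng.normal(0, 0.2, (3, 3))
        np.fill_diagonal(A, 0)
        vals = {
            round(abs(direct_cycle_strength(A, (1,) + p)), 12)
            for p in itertools.permutations((2, 3))
        }
        assert len(vals) == 1


class TestPermutationTest:
    @staticmethod
    def _cohort(rng, K=5, n=6, bias=0.0):
        mats = []
        q = 2 * np.pi * np.arange(K) / K
        drift = np.sin(q[None, :] - q[:, None]) * bias
        for _ in range(n):
            A = rng.normal(0, 0.05, (K, K)) + drift
            np.fill_diagonal(A, 0)
            mats.append(AsymmetryMatrix(A=A, n_intervals_used=np.ones(K, int)))
        return mats

    def test_p_never_below_add_one_bound(self, rng):
        mats = self._cohort(rng, bias=0.5)
        res = permutation_test_cycle_strength(mats, n_perm=49, seed=0)
        assert res.p >= 1 / 50
        assert res.p == pytest.approx(1 / 50)  # strong cycle: minimal p

    def test_null_cohort_p_not_extreme(self, rng):
        mats = self._cohort(rng, bias=0.0)
        res = permutation_test_cycle_strength(
            mats, n_perm=99, scheme="fixed_layout",
            layout=CircleLayout.identity(5), seed=1,
        )
        assert res.p > 0.05

    def test_fixed_layout_null_centered_at_zero(self, rng):
        mats = self._cohort(rng, bias=0.3)
        res = permutation_test_cycle_strength(
            mats, n_perm=500, scheme="fixed_layout",
            layout=CircleLayout.identity(5), seed=2,
        )
        assert abs(res.null_values.mean()) < 3 * res.null_values.std() / np.sqrt(500)

    def test_input_validation(self, rng):
        mats = self._cohort(rng)
        with pytest.raises(ValueError):
            permutation_test_cycle_strength(mats, n_perm=0)
        with pytest.raises(ValueError):
            permutation_test_cycle_strength(mats[:1], n_perm=10)
        with pytest.raises(ValueError):
            permutation_test_cycle_strength(mats, n_perm=10, scheme="fixed_layout")

    def test_seed_reproducibility(self, rng):
        mats = self._cohort(rng, bias=0.1)
        a = permutation_test_cycle_strength(mats, n_perm=20, seed=7)
        b = permutation_test_cycle_strength(mats, n_perm=20, seed=7)
        np.testing.assert_array_equal(a.null_values, b.null_values)


class TestPhaseDifference:
    def test_identical_layouts(self):
        lay = CircleLayout.identity(12)
        res = phase_difference(lay, lay, n_perm=200, seed=0)
        assert res.delta_theta == 0.0
        assert res.p == pytest.approx(1 / 201)

    def test_single_rotation_k12(self):
        a = CircleLayout.identity(12)
        b = CircleLayout(np.roll(np.arange(1, 13), 1))
        res = phase_difference(a, b, n_perm=100, seed=0)
        assert res.delta_theta == pytest.approx(2 * np.pi / 12)

    def test_random_layouts_average_near_half_pi(self, rng):
        vals = []
        for _ in range(200):
            a = CircleLayout(rng.permutation(12) + 1)
            b = CircleLayout(rng.permutation(12) + 1)
            d = np.abs(a.phases - b.phases) % (2 * np.pi)
            vals.append(np.minimum(d, 2 * np.pi - d).mean())
        assert np.mean(vals) == pytest.approx(np.pi / 2, abs=0.05)

    def test_k_mismatch_rejected(self):
        with pytest.raises(ValueError):
            phase_difference(CircleLayout.identity(4), CircleLayout.identity(5))


class TestMatchStates:
    def test_identity_cost(self):
        cost = 1.0 - np.eye(4)
        res = match_states(cost)
        assert res.assignment.tolist() == [0, 1, 2, 3]
        assert res.total_cost == 0.0

    def test_recovers_permutation(self, rng):
        perm = rng.permutation(5)
        cost = np.ones((5, 5))
        cost[np.arange(5), perm] = 0.0
        res = match_states(cost)
        assert res.assignment.tolist() == perm.tolist()

    def test_matches_bruteforce_over_all_bijections(self, rng):
        cost = rng.random((5, 5))
        res = match_states(cost)
        best = min(
            sum(cost[i, p[i]] for i in range(5))
            for p in itertools.permutations(range(5))
        )
        assert res.total_cost == pytest.approx(best)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            match_states(np.ones((3, 4)))
        with pytest.raises(ValueError):
            match_states(np.array([[0.0, np.inf], [1.0, 0.0]]))


class TestCircleGraph:
    @staticmethod
    def _group(rng, K=5):
        mats = []
        for _ in range(10):
            A = rng.normal(0, 0.01, (K, K))
            A[0, 1] += 0.4
            A[2, 0] -= 0.4
            np.fill_diagonal(A, 0)
            mats.append(AsymmetryMatrix(A=A, n_intervals_used=np.ones(K, int)))
        return group_asymmetry_test(mats)

    def test_empty_edge_matrix_gives_empty_graph(self):
        g = export_circle_graph(CircleLayout.identity(5), np.zeros((5, 5)))
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 5

    def test_edge_direction_follows_sign(self, rng):
        group = self._group(rng)
        g = export_circle_graph(CircleLayout.identity(5), group.E, group)
        assert g.has_edge(1, 2)  # A[0,1] > 0: state 2 follows state 1
        assert g.has_edge(1, 3)  # A[2,0] < 0: state 1 precedes state 3
        assert not g.has_edge(2, 1)

    def test_json_roundtrip(self, tmp_path, rng):
        group = self._group(rng)
        layout = CircleLayout(np.array([1, 4, 2, 5, 3]))
        doc = circle_graph_document(layout, group.E, group)
        path = tmp_path / "graph.json"
        path.write_text(json.dumps(doc))
        layout2, E2 = load_circle_graph(path)
        assert layout2.ordering.tolist() == layout.ordering.tolist()
        np.testing.assert_array_equal(E2, group.E)

    def test_graphml_serializable(self, tmp_path, rng):
        group = self._group(rng)
        g = export_circle_graph(CircleLayout.identity(5), group.E, group)
        nx.write_graphml(g, tmp_path / "g.graphml")
        g2 = nx.read_graphml(tmp_path / "g.graphml")
        assert g2.number_of_edges() == g.number_of_edges()
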