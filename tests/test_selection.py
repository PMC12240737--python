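"""Pareto machinery, the constraint dominance principle, both preference
rankings, the cosine decay, and the two environmental selections.

Oracles here are deliberately naive: an O(N^2 m) pairwise-dominance front
assignment and a from-first-principles reimplementation of front-wise
filling, kept independent of the package's production code paths.
"""

import numpy as np
import pytest

from cmomo.errors import BadParams
from cmomo.selection import (
    alpha,
    comprehensive_score,
    constrained_dominates,
    constraint_preference_ranking,
    crowding_distance,
    dominates,
    environmental_selection_stage1,
    environmental_selection_stage2,
    fast_nondominated_sort,
    property_preference_ranking,
)


def oracle_fronts(F):
    """Brute force: peel non-dominated layers by pairwise comparison."""
    F = np.asarray(F, dtype=float)
    n = F.shape[0]
    remaining = set(range(n))
    fronts = np.zeros(n, dtype=int)
    k = 0
    while remaining:
        k += 1
        layer = [
            i
            for i in remaining
            if not any(
                np.all(F[j] >= F[i]) and np.any(F[j] > F[i])
                for j in remaining
                if j != i
            )
        ]
        for i in layer:
            fronts[i] = k
        remaining -= set(layer)
    return fronts


class TestDominance:
    def test_strict_dominance(self):
        assert dominates([2, 2], [1, 1])

    def test_incomparable_pair(self):
        assert not dominates([1, 2], [2, 1])
        assert not dominates([2, 1], [1, 2])

    def test_equal_vectors_do_not_dominate(self):
        assert not dominates([1, 1], [1, 1])


class TestNondominatedSort:
    def test_single_point_front_one(self):
        assert fast_nondominated_sort([[1.0, 2.0]]).tolist() == [1]

    def test_two_ordered_points(self):
        assert fast_nondominated_sort([[2, 2], [1, 1]]).tolist() == [1, 2]

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_pairwise_oracle_random(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(2, 65))
        m = int(rng.integers(2, 5))
        F = rng.random((n, m))
        if trial % 3 == 0:  # exercise ties
            F = np.round(F, 1)
        assert np.array_equal(fast_nondominated_sort(F), oracle_fronts(F))


class TestCrowdingDistance:
    def test_two_points_both_boundary(self):
        assert np.all(np.isinf(crowding_distance([[0, 2], [1, 1]])))

    def test_middle_point_hand_case(self):
        d = crowding_distance([[0, 2], [1, 1], [2, 0]])
        assert np.isinf(d[0]) and np.isinf(d[2])
        assert d[1] == pytest.approx(2.0)  # (2-0)/2 + (2-0)/2

    def test_strictly_interior_duplicate_gets_zero(self):
        # of three identical interior points, the middle one in sort order
        # has zero-gap neighbours on both sides in every objective
        d = crowding_distance([[0, 0], [1, 1], [1, 1], [1, 1], [2, 2]])
        assert np.isinf(d[0]) and np.isinf(d[4])
        assert min(d[1:4]) == 0.0


class TestConstrainedDominance:
    def test_feasible_beats_infeasible_regardless_of_objectives(self):
        assert constrained_dominates([0, 0], 0.0, [9, 9], 0.3)

    def test_smaller_violation_beats_larger(self):
        assert constrained_dominates([0, 0], 0.2, [9, 9], 0.5)

    def test_feasible_incomparable_pair(self):
        assert not constrained_dominates([1, 2], 0.0, [2, 1], 0.0)
        assert not constrained_dominates([2, 1], 0.0, [1, 2], 0.0)

    def test_equal_violations_incomparable(self):
        assert not constrained_dominates([2, 2], 0.4, [1, 1], 0.4)


class TestPreferenceRankings:
    def test_hand_ordering_by_front_then_crowding(self):
        # A: front 1 boundary (inf), B: front 1 interior, C: front 2
        F = np.array([[0.0, 3.0], [1.0, 1.0], [0.5, 0.5], [3.0, 0.0]])
        s1 = property_preference_ranking(F)
        assert s1[2] == 4  # dominated point ranks last
        assert s1[0] in (1, 2, 3) and np.isfinite(s1).all()

    def test_single_front_ordered_by_crowding(self):
        F = np.array([[0, 4], [1, 3], [2, 2], [3, 1], [4, 0]], dtype=float)
        s1 = property_preference_ranking(F)
        assert s1[0] in (1, 2) and s1[4] in (1, 2)  # boundaries first

    @pytest.mark.parametrize("trial", range(10))
    def test_both_rankings_are_permutations(self, trial):
        rng = np.random.default_rng(500 + trial)
        n = int(rng.integers(3, 40))
        F = rng.random((n, 3))
        cv = np.where(rng.random(n) < 0.5, 0.0, rng.random(n))
        s1 = property_preference_ranking(F)
        s2 = constraint_preference_ranking(F, cv)
        assert sorted(s1) == list(range(1, n + 1))
        assert sorted(s2) == list(range(1, n + 1))

    @pytest.mark.parametrize("trial", range(10))
    def test_rankings_coincide_when_all_feasible(self, trial):
        rng = np.random.default_rng(700 + trial)
        F = rng.random((int(rng.integers(3, 30)), 2))
        s1 = property_preference_ranking(F)
        s2 = constraint_preference_ranking(F, np.zeros(F.shape[0]))
        assert np.array_equal(s1, s2)

    def test_sole_feasible_molecule_tops_constraint_ranking(self):
        rng = np.random.default_rng(4)
        F = rng.random((8, 2))
        cv = rng.random(8) + 0.1
        cv[5] = 0.0
        assert constraint_preference_ranking(F, cv)[5] == 1


class TestAlphaSchedule:
    @pytest.mark.parametrize("T", [1, 2, 10, 30])
    def test_anchors(self, T):
        assert alpha(0, T) == pytest.approx(1.0)
        assert alpha(T, T) == pytest.approx(0.0, abs=1e-15)

    def test_midpoint_half(self):
        assert alpha(15, 30) == pytest.approx(0.5)

    @pytest.mark.parametrize("T", [1, 3, 17])
    def test_non_increasing_on_grid(self, T):
        vals = [alpha(t, T) for t in range(T + 1)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(BadParams):
            alpha(-1, 10)
        with pytest.raises(BadParams):
            alpha(11, 10)


class TestComprehensiveScore:
    def test_extremes_select_single_ranking(self):
        s1 = np.array([3, 1]); s2 = np.array([7, 2])
        assert comprehensive_score(s1, s2, 1.0).tolist() == [3.0, 1.0]
        assert comprehensive_score(s1, s2, 0.0).tolist() == [7.0, 2.0]

    def test_hand_arithmetic(self):
        assert comprehensive_score(np.array([3]), np.array([7]), 0.5)[0] == 5.0


def oracle_stage1(F, P):
    """Independent front-wise filling built from the oracle primitives."""
    F = np.asarray(F, dtype=float)
    fronts = oracle_fronts(F)
    selected = []
    for k in sorted(set(fronts)):
        idx = [i for i in range(len(F)) if fronts[i] == k]
        if len(selected) + len(idx) <= P:
            selected += idx
        else:
            d = crowding_distance(F[idx])
            ranked = sorted(range(len(idx)), key=lambda p: (-d[p], idx[p]))
            selected += [idx[p] for p in ranked[: P - len(selected)]]
            break
    return sorted(selected)


class TestStage1Selection:
    def test_identity_when_union_equals_capacity(self):
        F = np.random.default_rng(0).random((6, 2))
        assert environmental_selection_stage1(F, 6).tolist() == list(range(6))

    def test_whole_front_fill(self):
        F = np.array([[2, 2], [3, 1], [1, 1], [0.5, 0.5]])
        assert environmental_selection_stage1(F, 2).tolist() == [0, 1]

    @pytest.mark.parametrize("trial", range(100))
    def test_matches_independent_reference_40_to_20(self, trial):
        rng = np.random.default_rng(2000 + trial)
        F = rng.random((40, int(rng.integers(2, 4))))
        got = environmental_selection_stage1(F, 20).tolist()
        assert got == oracle_stage1(F, 20)

    def test_undersized_union_rejected(self):
        with pytest.raises(BadParams):
            environmental_selection_stage1(np.zeros((3, 2)), 4)


class TestStage2Selection:
    def test_t_zero_reduces_to_property_ranks(self):
        rng = np.random.default_rng(31)
        F = rng.random((12, 2))
        cv = np.where(rng.random(12) < 0.5, 0.0, rng.random(12))
        s1 = property_preference_ranking(F)
        expected = sorted(np.argsort(s1)[:6].tolist())
        assert environmental_selection_stage2(F, cv, 6, 0, 10).tolist() == expected

    def test_t_final_reduces_to_constraint_ranks(self):
        rng = np.random.default_rng(32)
        F = rng.random((12, 2))
        cv = np.where(rng.random(12) < 0.5, 0.0, rng.random(12))
        s2 = constraint_preference_ranking(F, cv)
        expected = sorted(np.argsort(s2)[:6].tolist())
        assert environmental_selection_stage2(F, cv, 6, 10, 10).tolist() == expected

    def test_midpoint_matches_exhaustive_score_enumeration(self):
        F = np.array([[0.9, 0.1], [0.1, 0.9], [0.5, 0.5], [0.4, 0.4], [0.8, 0.8], [0.2, 0.2]])
        cv = np.array([0.0, 0.5, 0.0, 0.2, 0.7, 0.0])
        s1 = property_preference_ranking(F)
        s2 = constraint_preference_ranking(F, cv)
        score = 0.5 * s1 + 0.5 * s2
        order = sorted(range(6), key=lambda i: (score[i], s2[i], i))
        expected = sorted(order[:3])
        got = environmental_selection_stage2(F, cv, 3, 5, 10).tolist()
        assert got == expected

    def test_feasibility_monotone_at_final_generation(self):
        """At t=T no infeasible molecule survives while a feasible one is cut."""
        for trial in range(20):
            rng = np.random.default_rng(3000 + trial)
            F = rng.random((20, 2))
            cv = np.where(rng.random(20) < 0.4, 0.0, rng.random(20))
            keep = set(environmental_selection_stage2(F, cv, 10, 10, 10).tolist())
            dropped_feasible = [i for i in range(20) if i not in keep and cv[i] == 0]
            kept_infeasible = [i for i in keep if cv[i] > 0]
            assert not (dropped_feasible and kept_infeasible)

    def test_deterministic_given_union_order(self):
        rng = np.random.default_rng(8)
        F = rng.random((14, 3))
        cv = rng.random(14)
        a = environmental_selection_stage2(F, cv, 7, 3, 9)
        b = environmental_selection_stage2(F, cv, 7, 3, 9)
        assert np.array_equal(a, b)
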