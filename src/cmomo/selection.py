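"""Pareto machinery and the two environmental-selection procedures.

Stage 1 (unconstrained scenario) uses classic NSGA-II selection: fill front
by front, truncate the boundary front by crowding distance.

Stage 2 (constrained scenario) uses ranking aggregation. Every molecule in
the parent-offspring union receives two ranks: a property-preference rank
s1 (non-dominated sorting on objectives alone, crowding as tie-breaker) and
a constraint-preference rank s2 (the same procedure but with fronts from the
constraint dominance principle: feasible beats infeasible, smaller CV beats
larger among infeasible, Pareto dominance decides among feasible). The two
ranks are aggregated into a comprehensive score

    S = alpha * s1 + (1 - alpha) * s2,
    alpha(t) = (1 + cos(t pi / T)) / 2,

and the P smallest scores survive. The cosine decay keeps alpha near 1
early in the constrained stage (property priority), drops fastest mid-stage
and approaches 0 late (constraint priority), moving the search from the
unconstrained Pareto front onto the constrained one.

All objective matrices are maximization-oriented. All tie-breaks fall back
to stable input index so selection is deterministic given the union order.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

from .errors import BadParams, DimensionMismatch


def dominates(a: np.ndarray, b: np.ndarray) -> bool:
    """Standard Pareto dominance (maximization): a >= b everywhere, > somewhere."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DimensionMismatch(f"objective shapes differ: {a.shape} vs {b.shape}")
    return bool(np.all(a >= b) and np.any(a > b))


def _sort_by_comparator(n: int, dom: Callable[[int, int], bool]) -> np.ndarray:
    """Fast non-dominated sorting skeleton over an arbitrary dominance relation.

    Returns 1-based front numbers. The bookkeeping is the standard
    dominated-count / dominates-list scheme.
    """
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    dom_count = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if dom(i, j):
                dominated_by[i].append(j)
                dom_count[j] += 1
            elif dom(j, i):
                dominated_by[j].append(i)
                dom_count[i] += 1
    fronts = np.zeros(n, dtype=int)
    current = [i for i in range(n) if dom_count[i] == 0]
    k = 1
    while current:
        nxt = []
        for i in current:
            fronts[i] = k
            for j in dominated_by[i]:
                dom_count[j] -= 1
                if dom_count[j] == 0:
                    nxt.append(j)
        current = nxt
        k += 1
    return fronts


def fast_nondominated_sort(F: np.ndarray) -> np.ndarray:
    """1-based front numbers under Pareto dominance on objective matrix F (N x m)."""
    F = np.atleast_2d(np.asarray(F, dtype=float))
    n = F.shape[0]
    if n == 0:
        raise BadParams("empty objective matrix")
    return _sort_by_comparator(n, lambda i, j: dominates(F[i], F[j]))


def constrained_dominates(
    Fa: np.ndarray, cva: float, Fb: np.ndarray, cvb: float
) -> bool:
    """Constraint dominance principle; feasible means cv == 0.

    a dominates b iff (i) both feasible and a Pareto-dominates b, or
    (ii) a feasible, b infeasible, or (iii) both infeasible and cv_a < cv_b.
    Infeasible molecules with equal CV are incomparable.
    """
    if cva < 0 or cvb < 0:
        raise BadParams("constraint violations must be non-negative")
    fa, fb = cva == 0, cvb == 0
    if fa and fb:
        return dominates(Fa, Fb)
    if fa and not fb:
        return True
    if not fa and not fb:
        return cva < cvb
    return False


def cdp_nondominated_sort(F: np.ndarray, cv: np.ndarray) -> np.ndarray:
    """1-based front numbers under the constraint dominance principle."""
    F = np.atleast_2d(np.asarray(F, dtype=float))
    cv = np.asarray(cv, dtype=float)
    if F.shape[0] != cv.shape[0]:
        raise DimensionMismatch("F and cv lengths differ")
    return _sort_by_comparator(
        F.shape[0], lambda i, j: constrained_dominates(F[i], cv[i], F[j], cv[j])
    )


def crowding_distance(F_front: np.ndarray) -> np.ndarray:
    """NSGA-II crowding distance for the members of one front.

    Boundary solutions per objective get +inf; interior solutions sum the
    normalized gap between their sorted neighbours over all objectives.
    Zero-range objectives contribute nothing (duplicated points get 0).
    """
    F = np.atleast_2d(np.asarray(F_front, dtype=float))
    n, m = F.shape
    if n <= 2:
        return np.full(n, np.inf)
    dist = np.zeros(n)
    for k in range(m):
        order = np.argsort(F[:, k], kind="stable")
        lo, hi = F[order[0], k], F[order[-1], k]
        dist[order[0]] = dist[order[-1]] = np.inf
        if hi - lo == 0:
            continue
        gaps = (F[order[2:], k] - F[order[:-2], k]) / (hi - lo)
        for pos in range(1, n - 1):
            if not np.isinf(dist[order[pos]]):
                dist[order[pos]] += gaps[pos - 1]
    return dist


def crowding_by_front(F: np.ndarray, fronts: np.ndarray) -> np.ndarray:
    """Crowding distance computed within each front of a partitioned set."""
    F = np.atleast_2d(np.asarray(F, dtype=float))
    out = np.zeros(F.shape[0])
    for k in np.unique(fronts):
        idx = np.flatnonzero(fronts == k)
        out[idx] = crowding_distance(F[idx])
    return out


def _rank_from(fronts: np.ndarray, crowding: np.ndarray) -> np.ndarray:
    """Unique 1..N ranks: front ascending, crowding descending, index ascending."""
    n = len(fronts)
    order = sorted(range(n), key=lambda i: (fronts[i], -crowding[i], i))
    ranks = np.empty(n, dtype=int)
    for pos, i in enumerate(order):
        ranks[i] = pos + 1
    return ranks


def property_preference_ranking(F: np.ndarray) -> np.ndarray:
    """Ranks 1..N from objectives alone (Pareto fronts, then crowding)."""
    fronts = fast_nondominated_sort(F)
    return _rank_from(fronts, crowding_by_front(F, fronts))


def constraint_preference_ranking(F: np.ndarray, cv: np.ndarray) -> np.ndarray:
    """Ranks 1..N with fronts from the constraint dominance principle.

    Crowding is still computed on objective values, within CDP fronts.
    """
    fronts = cdp_nondominated_sort(F, cv)
    return _rank_from(fronts, crowding_by_front(F, fronts))


def alpha(t: float, T: int) -> float:
    """Cosine-decay aggregation weight: (1 + cos(t pi / T)) / 2 on t in [0, T]."""
    if T < 1:
        raise BadParams(f"T must be >= 1, got {T}")
    if not 0 <= t <= T:
        raise BadParams(f"t must lie in [0, {T}], got {t}")
    return 0.5 * (1.0 + math.cos(t * math.pi / T))


def comprehensive_score(
    s1: np.ndarray, s2: np.ndarray, a: float
) -> np.ndarray:
    """Aggregate the two rank vectors: a*s1 + (1-a)*s2. Lower is better."""
    if not 0.0 <= a <= 1.0:
        raise BadParams(f"alpha must be in [0,1], got {a}")
    return a * np.asarray(s1, dtype=float) + (1.0 - a) * np.asarray(s2, dtype=float)


def environmental_selection_stage1(F: np.ndarray, P: int) -> np.ndarray:
    """NSGA-II environmental selection: indices of the P survivors.

    Whole fronts are admitted while they fit; the boundary front is
    truncated by discarding its smallest-crowding members (ties discard the
    later input index first). Survivor indices are returned in input order.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    n = F.shape[0]
    if n < P:
        raise BadParams(f"union of {n} cannot fill population of {P}")
    fronts = fast_nondominated_sort(F)
    crowd = crowding_by_front(F, fronts)
    selected: list[int] = []
    for k in sorted(np.unique(fronts)):
        idx = list(np.flatnonzero(fronts == k))
        if len(selected) + len(idx) <= P:
            selected.extend(idx)
            if len(selected) == P:
                break
        else:
            # keep the largest-crowding members of the boundary front;
            # on crowding ties the earlier input index survives
            keep = P - len(selected)
            idx.sort(key=lambda i: (-crowd[i], i))
            selected.extend(idx[:keep])
            break
    return np.array(sorted(selected), dtype=int)


def environmental_selection_stage2(
    F: np.ndarray, cv: np.ndarray, P: int, t: float, T: int
) -> np.ndarray:
    """Ranking-aggregation selection: indices of the P smallest scores.

    Ties are broken by smaller constraint-preference rank, then input index.
    Survivor indices are returned in input order.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    n = F.shape[0]
    if n < P:
        raise BadParams(f"union of {n} cannot fill population of {P}")
    s1 = property_preference_ranking(F)
    s2 = constraint_preference_ranking(F, cv)
    score = comprehensive_score(s1, s2, alpha(t, T))
    order = sorted(range(n), key=lambda i: (score[i], s2[i], i))
    return np.array(sorted(order[:P]), dtype=int)


def rank_table(F: np.ndarray, cv: np.ndarray, t: float, T: int) -> dict:
    """Diagnostic bundle of all per-molecule ranking quantities."""
    fronts = fast_nondominated_sort(F)
    crowd = crowding_by_front(F, fronts)
    s1 = property_preference_ranking(F)
    s2 = constraint_preference_ranking(F, cv)
    a = alpha(t, T)
    return {
        "front": fronts,
        "crowding": crowd,
        "s1": s1,
        "s2": s2,
        "alpha": a,
        "score": comprehensive_score(s1, s2, a),
    }
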