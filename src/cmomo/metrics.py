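"""Evaluation metrics: optimization success rate and the hypervolume indicator.

Both metrics follow the conventions of constrained molecular optimization
benchmarks: objectives are maximization-oriented, the hypervolume reference
point is the zero vector, and a lead molecule counts as successfully
optimized when its result set contains at least one feasible molecule
beating every success threshold.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .errors import DimensionMismatch, EmptyInput


def _hv_recursive(pts: np.ndarray, ref: np.ndarray) -> float:
    """Exact hypervolume by sweeping the last objective (maximization).

    Sorts points by the last coordinate descending and accumulates slab
    thickness times the (m-1)-dimensional hypervolume of the points whose
    last coordinate reaches the slab. Exponential in m, fine for m <= 4.
    """
    m = len(ref)
    if pts.shape[0] == 0:
        return 0.0
    if m == 1:
        return float(pts[:, 0].max() - ref[0])
    order = np.argsort(-pts[:, -1], kind="stable")
    pts = pts[order]
    hv = 0.0
    levels = np.append(pts[:, -1], ref[-1])
    for k in range(pts.shape[0]):
        thickness = levels[k] - levels[k + 1]
        if thickness > 0:
            hv += thickness * _hv_recursive(pts[: k + 1, :-1], ref[:-1])
    return hv


def hypervolume(points: Sequence[Sequence[float]], ref: Sequence[float]) -> float:
    """Hypervolume dominated by ``points`` above the reference point.

    Maximization orientation: the measure of the union of boxes
    [ref, p]. Coordinates below the reference are clipped to it, so points
    with some negative objective still contribute their positive part and a
    fully dominated-by-ref point contributes nothing.
    """
    ref = np.asarray(ref, dtype=float)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        return 0.0
    if pts.shape[1] != ref.shape[0]:
        raise DimensionMismatch(
            f"points have {pts.shape[1]} objectives, reference has {ref.shape[0]}"
        )
    pts = np.maximum(pts, ref)
    pts = pts[np.any(pts > ref, axis=1)]
    if pts.shape[0] == 0:
        return 0.0
    return _hv_recursive(pts, ref)


def molecule_success(
    objectives: Mapping[str, float],
    feasible: bool,
    thresholds: Mapping[str, float],
) -> bool:
    """A molecule succeeds iff feasible and every thresholded objective is beaten."""
    if not feasible:
        return False
    return all(objectives.get(name, -np.inf) >= th for name, th in thresholds.items())


def success_rate(
    per_lead_results: Sequence[Sequence[tuple[Mapping[str, float], bool]]],
    thresholds: Mapping[str, float],
) -> tuple[float, list[int]]:
    """Success rate over lead molecules, plus per-lead success counts.

    ``per_lead_results`` holds, for each lead, the final feasible candidates
    as (objective dict, feasible flag) pairs. A lead counts as a success iff
    at least one of its candidates is feasible and beats every threshold
    (maximization orientation). Returns (SR, N_SR per lead).
    """
    if len(per_lead_results) == 0:
        raise EmptyInput("no result sets")
    n_sr = [
        sum(1 for obj, feas in results if molecule_success(obj, feas, thresholds))
        for results in per_lead_results
    ]
    sr = sum(1 for c in n_sr if c > 0) / len(per_lead_results)
    return float(sr), n_sr
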