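"""Heading by local motion-parallax differencing (Longuet-Higgins/Prazdny
style).

Two dots coincident in the image but at different depths share the same
rotational flow; subtracting their velocities leaves a purely translational
vector that points along a line through the focus of expansion.  In random
dot displays exactly coincident dots essentially never occur, so the model
pairs the *closest* dots instead, forms a difference line per pair, and
estimates the FoE as the least-squares intersection of those lines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ..core import (DegenerateGeometryError, HeadingEstimate,
                    InsufficientDataError, tan_to_deg)
from ..stimulus import FlowField

#: pairs whose velocity difference (tangent units/s) is below this are dropped
DIFFERENCE_TOL = 1e-9
#: smallest acceptable angle (rad) between two line directions for a solve
PARALLEL_TOL = 1e-8


@dataclass(frozen=True)
class ProximalPair:
    index_a: int
    index_b: int
    separation: float  # deg of visual angle


@dataclass(frozen=True)
class DifferenceLine:
    anchor: np.ndarray     # (2,) tangent coords, midpoint of the pair
    direction: np.ndarray  # (2,) unit vector


def select_proximal_pairs(field: FlowField, max_pairs: int | None = None
                          ) -> list[ProximalPair]:
    """Greedy non-overlapping matching by image separation.

    Repeatedly takes the globally closest pair of unused dots until
    ``max_pairs`` pairs are formed or fewer than two dots remain; the result
    is sorted by separation ascending (the greedy order).
    """
    n = len(field)
    if n < 2:
        raise InsufficientDataError("need at least 2 dots to form a pair")
    if max_pairs is None:
        max_pairs = n // 2
    pos_deg = field.positions_deg
    d = squareform(pdist(pos_deg))
    iu, ju = np.triu_indices(n, k=1)
    order = np.argsort(d[iu, ju], kind="stable")
    used = np.zeros(n, dtype=bool)
    pairs: list[ProximalPair] = []
    for k in order:
        if len(pairs) >= max_pairs:
            break
        i, j = int(iu[k]), int(ju[k])
        if used[i] or used[j]:
            continue
        used[i] = used[j] = True
        pairs.append(ProximalPair(i, j, float(d[i, j])))
    return pairs


def difference_lines(field: FlowField, pairs: list[ProximalPair]
                     ) -> list[DifferenceLine]:
    """One line per pair: direction is the normalized velocity difference
    (rotational flow cancels under subtraction), anchored at the pair's
    midpoint.  Pairs with a negligible difference vector are dropped."""
    lines: list[DifferenceLine] = []
    for p in pairs:
        dv = field.velocities[p.index_a] - field.velocities[p.index_b]
        norm = np.linalg.norm(dv)
        if norm < DIFFERENCE_TOL:
            continue
        anchor = 0.5 * (field.positions[p.index_a] + field.positions[p.index_b])
        lines.append(DifferenceLine(anchor=anchor, direction=dv / norm))
    if not lines:
        raise InsufficientDataError("all pairs have degenerate velocity "
                                    "differences")
    return lines


def estimate_foe_lhp80(lines: list[DifferenceLine]) -> HeadingEstimate:
    """Point minimizing summed squared perpendicular distance to the lines.

    Stacks the perpendicular-projection normal equations
    sum_i (I - d_i d_i^T) p = sum_i (I - d_i d_i^T) a_i and solves the 2x2
    system; near-parallel line sets are rejected as degenerate.
    """
    if len(lines) < 2:
        raise DegenerateGeometryError("need >= 2 difference lines")
    D = np.array([ln.direction for ln in lines])
    A = np.array([ln.anchor for ln in lines])
    # normal matrix sum (I - d d^T); rank 2 iff directions are not all parallel
    M = len(lines) * np.eye(2) - D.T @ D
    b = np.einsum("i,ij->j", np.ones(len(lines)), A) - D.T @ np.einsum(
        "ij,ij->i", D, A)
    # smallest eigenvalue of M measures non-parallelism (= sum sin^2 angles)
    evals = np.linalg.eigvalsh(M)
    if evals[0] < len(lines) * PARALLEL_TOL ** 2:
        raise DegenerateGeometryError("difference lines are (near-)parallel")
    foe = np.linalg.solve(M, b)
    xy = tan_to_deg(foe)
    return HeadingEstimate(x_deg=float(xy[0]), y_deg=float(xy[1]),
                           model="lhp80", info={"n_lines": len(lines)})


def estimate_heading_lhp80(field: FlowField, max_pairs: int | None = None
                           ) -> HeadingEstimate:
    """Full pipeline: pair selection, differencing, line intersection."""
    pairs = select_proximal_pairs(field, max_pairs)
    lines = difference_lines(field, pairs)
    est = estimate_foe_lhp80(lines)
    est.info["n_pairs_used"] = len(pairs)
    return est
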