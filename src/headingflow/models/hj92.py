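"""Subspace-method heading estimation (Heeger-Jepson style).

For a candidate translation direction T the set of flow fields consistent
with T -- over all per-dot inverse depths and all rotations -- is a linear
subspace of the stacked 2n-dimensional flow space, spanned by n per-dot
translational columns A(x_i) T and 3 depth-independent rotational columns
B(x_i).  The residual of a candidate is the squared norm of the observed
flow's component orthogonal to that subspace (normalized by the total flow
energy, so it lies in [0, 1] and is scale invariant); the candidate with the
smallest residual is the heading estimate.  Rotation and depths are never
solved for explicitly -- they are implicitly least-squares-eliminated by the
projection, which is the point of the subspace method.

The per-dot translational columns have disjoint support (two rows each), so
the projection is computed dot-by-dot: within dot i's two rows the
orthogonal complement of A(x_i) T is the 90-degree-rotated direction; the
observed flow and the three rotational columns are projected onto those
complements and the remaining 3-column least-squares problem is solved in
closed form.  This makes the full candidate-grid scan vectorizable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import HeadingEstimate, InsufficientDataError, deg_to_tan
from .p92 import _central_argbest

#: relative tolerance for rank decisions in orthogonalization
RANK_TOL = 1e-10
#: |A(x) T| below this marks the dot as sitting at the candidate heading
SINGULAR_TOL = 1e-12


@dataclass
class CandidateGrid:
    """Grid of candidate headings (deg) and their unit translation vectors."""

    headings_deg: np.ndarray   # (m, 2)
    resolution: float

    @property
    def unit_translations(self) -> np.ndarray:
        t = np.column_stack([deg_to_tan(self.headings_deg[:, 0]),
                             deg_to_tan(self.headings_deg[:, 1]),
                             np.ones(len(self.headings_deg))])
        return t / np.linalg.norm(t, axis=1, keepdims=True)

    def __len__(self):
        return len(self.headings_deg)


def build_candidate_grid(extent: float = 20.0, resolution: float = 1.0
                         ) -> CandidateGrid:
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    steps = 2 * extent / resolution
    if abs(steps - round(steps)) > 1e-9:
        raise ValueError("resolution must divide the grid extent")
    ax = np.linspace(-extent, extent, int(round(steps)) + 1)
    gx, gy = np.meshgrid(ax, ax, indexing="ij")
    return CandidateGrid(headings_deg=np.column_stack([gx.ravel(), gy.ravel()]),
                         resolution=resolution)


def _rotation_columns(positions: np.ndarray) -> np.ndarray:
    """B(x) stacked over dots: (n, 2, 3); rotational flow is B @ Omega."""
    x, y = positions[:, 0], positions[:, 1]
    B = np.empty((len(positions), 2, 3))
    B[:, 0, 0] = x * y
    B[:, 0, 1] = -(1 + x ** 2)
    B[:, 0, 2] = y
    B[:, 1, 0] = 1 + y ** 2
    B[:, 1, 1] = -x * y
    B[:, 1, 2] = -x
    return B


def _translation_directions(positions: np.ndarray, T: np.ndarray) -> np.ndarray:
    """A(x_i) T for every dot: (..., n, 2); translational flow direction
    (up to the unknown positive inverse depth).  ``T`` may be a single
    3-vector or a stack of candidates (..., 3)."""
    x, y = positions[:, 0], positions[:, 1]
    T = np.asarray(T, dtype=float)
    tx = T[..., 0, None]
    ty = T[..., 1, None]
    tz = T[..., 2, None]
    return np.stack([x * tz - tx, y * tz - ty], axis=-1)


def constraint_matrix(candidate: np.ndarray, positions: np.ndarray
                      ) -> np.ndarray:
    """Dense 2n x (n+3) matrix C(T) whose column space is the candidate
    subspace: per-dot translational columns then the rotational columns."""
    n = len(positions)
    a = _translation_directions(positions, np.asarray(candidate, float))
    C = np.zeros((2 * n, n + 3))
    rows = np.arange(n)
    C[2 * rows, rows] = a[:, 0]
    C[2 * rows + 1, rows] = a[:, 1]
    C[:, n:] = _rotation_columns(positions).reshape(2 * n, 3)
    return C


def constraint_basis(candidate, positions: np.ndarray) -> np.ndarray:
    """Orthonormal basis (2n x r) of the candidate subspace, computed by a
    rank-revealing SVD of C(T)."""
    if len(positions) < 1:
        raise InsufficientDataError("need at least one dot")
    C = constraint_matrix(candidate, positions)
    u, s, _ = np.linalg.svd(C, full_matrices=False)
    rank = int(np.sum(s > RANK_TOL * s[0])) if s.size and s[0] > 0 else 0
    return u[:, :rank]


def residual_hj92(field, candidate) -> float:
    """Normalized squared distance of the stacked flow to the candidate
    subspace, in [0, 1]; 0 iff the flow is exactly consistent with the
    candidate translation for some depths and rotation."""
    if len(field) == 0:
        raise InsufficientDataError("empty flow field")
    v = field.velocities.reshape(-1)
    total = v @ v
    if total == 0:
        raise ValueError("undefined residual for a zero-flow field")
    Q = constraint_basis(np.asarray(candidate, float), field.positions)
    r = v - Q @ (Q.T @ v)
    return float(max(r @ r, 0.0) / total)


def _residual_surface(field, grid: CandidateGrid) -> np.ndarray:
    """Residual for every candidate on the grid, vectorized over candidates
    via the blockwise projection described in the module docstring."""
    p = field.positions
    v = field.velocities                            # (n, 2)
    total = float(np.sum(v ** 2))
    if total == 0:
        raise ValueError("undefined residual for a zero-flow field")
    x, y = p[:, 0], p[:, 1]
    T = grid.unit_translations                      # (m, 3)
    tx, ty, tz = T[:, 0, None], T[:, 1, None], T[:, 2, None]
    ax = x * tz - tx                                # (m, n)
    ay = y * tz - ty
    n2 = ax * ax + ay * ay
    regular = n2 > SINGULAR_TOL ** 2
    inv = np.where(regular, 1.0 / np.sqrt(np.where(regular, n2, 1.0)), 0.0)
    px = -ay * inv                                  # unit perp to A(x_i) T
    py = ax * inv

    B = _rotation_columns(p)                        # (n, 2, 3)
    B0, B1 = B[:, 0, :], B[:, 1, :]                 # (n, 3)
    s1 = px * v[:, 0] + py * v[:, 1]                # (m, n)

    # Gram matrix G = sum_n b b^T with b = px*B0 + py*B1: expand into
    # (m, n) weights times per-dot constant products so everything is a
    # BLAS matmul instead of an (m, n, 3) tensor contraction
    ii, jj = np.triu_indices(3)
    P00 = B0[:, ii] * B0[:, jj]                     # (n, 6)
    P01 = B0[:, ii] * B1[:, jj] + B1[:, ii] * B0[:, jj]
    P11 = B1[:, ii] * B1[:, jj]
    G6 = (px * px) @ P00 + (px * py) @ P01 + (py * py) @ P11   # (m, 6)
    rhs = (s1 * px) @ B0 + (s1 * py) @ B1           # (m, 3)
    ss = np.sum(s1 * s1, axis=1)                    # (m,)

    if not np.all(regular):
        # a dot sitting exactly at the candidate heading has a vanishing
        # translational column, so both of its rows survive the first
        # projection: add its raw components (perp was zeroed there)
        sing = (~regular).astype(float)             # (m, n)
        G6 += sing @ (P00 + P11)
        rhs += sing @ (v[:, 0, None] * B0 + v[:, 1, None] * B1)
        ss += sing @ (v[:, 0] ** 2 + v[:, 1] ** 2)

    G = np.empty((len(T), 3, 3))
    G[:, ii, jj] = G6
    G[:, jj, ii] = G6
    coef = np.linalg.solve(_regularize(G), rhs[..., None])[..., 0]
    resid = ss - np.sum(coef * rhs, axis=1)
    return np.clip(resid, 0.0, None) / total


def _regularize(G: np.ndarray) -> np.ndarray:
    """Tikhonov guard so the batched 3x3 solves never go singular; the ridge
    is tiny relative to each Gram matrix's scale."""
    scale = np.trace(G, axis1=1, axis2=2)[:, None, None]
    eye = np.eye(3)[None]
    return G + (RANK_TOL * np.maximum(scale, 1.0) + 1e-300) * eye


def estimate_heading_hj92(field, grid: CandidateGrid | None = None
                          ) -> HeadingEstimate:
    """Candidate minimizing the residual surface; ties broken toward central
    headings.  With fewer than 5 dots the subspace generically spans the
    whole flow space and every residual is ~0, so the estimate is flagged
    low-confidence (the 2AFC observer still answers)."""
    if grid is None:
        grid = build_candidate_grid()
    if len(field) == 0:
        raise InsufficientDataError("empty flow field")
    res = _residual_surface(field, grid)
    i = _central_argbest(res, grid.headings_deg, maximize=False)
    hx, hy = grid.headings_deg[i]
    return HeadingEstimate(x_deg=float(hx), y_deg=float(hy), model="hj92",
                           degenerate=len(field) < 5,
                           info={"min_residual": float(res[i])})
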