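"""Probabilistic heading estimation from pairwise convergence (Wang-Cutting
style).

The driving theorem: in a rigid scene under observer translation, if the
horizontal separation between two dots is shrinking (the pair is
*converging*) the heading cannot lie horizontally between them.  The visual field is split
into 1-degree-wide heading columns; each classified pair updates a posterior
over columns by Bayes' rule, with a converging verdict down-weighting the
columns strictly inside the pair's horizontal span.  A diverging verdict is
weak *positive* evidence for the in-span columns: by the same theorem
P(diverging | heading between) = 1 in a clean field, while outside the span
a pair still diverges only with probability 1 - q, q being the chance that
a random pair converges.  Without this boost, columns at the grid edges --
which lie outside nearly every pair span and therefore collect almost no
converging penalties -- become spurious MAP winners as soon as noise
produces scattered false convergences.  The MAP column center is the
heading estimate (azimuth only; the vertical component is reported as 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from ..core import HeadingEstimate, InsufficientDataError, tan_to_deg
from ..stimulus import FlowField


@dataclass(frozen=True)
class ConvergenceParams:
    """Per-verdict likelihoods for in-span vs out-of-span columns.

    p_between_given_converging is small (the theorem says the heading is
    never between a converging pair in a clean field; a small nonzero value
    keeps the update robust to noise).  The diverging in/out ratio defaults
    to 0.55/0.5 = 1.1 ~= (1 - eps)/(1 - q) with eps ~= 0.01 the chance of a
    false convergence across the heading and q ~= 0.1 the chance of
    convergence elsewhere: diverging pairs mildly favor their in-span
    columns.  Setting p_between_given_diverging = outside_given_diverging
    makes diverging pairs uninformative.
    """

    p_between_given_converging: float = 0.1
    p_between_given_diverging: float = 0.55
    outside_given_converging: float = 1.0
    outside_given_diverging: float = 0.5

    def __post_init__(self):
        if not (0 < self.p_between_given_converging < 1
                and 0 < self.p_between_given_diverging < 1):
            raise ValueError("between-likelihoods must lie in (0, 1)")


@dataclass
class HeadingColumns:
    """Angular heading bins spanning +/-extent with log-space posterior."""

    edges: np.ndarray                  # (k+1,) deg
    log_posterior: np.ndarray = dfield(default=None)

    def __post_init__(self):
        k = len(self.edges) - 1
        if self.log_posterior is None:
            self.log_posterior = np.full(k, -np.log(k))

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def posterior(self) -> np.ndarray:
        p = np.exp(self.log_posterior - self.log_posterior.max())
        return p / p.sum()


def build_columns(extent: float = 20.0, width: float = 1.0) -> HeadingColumns:
    if width <= 0:
        raise ValueError("column width must be positive")
    k = int(round(2 * extent / width))
    if abs(2 * extent / width - k) > 1e-9:
        raise ValueError("width must divide the span")
    return HeadingColumns(edges=np.linspace(-extent, extent, k + 1))


def classify_pair(fld: FlowField, i: int, j: int) -> str:
    """'converging' iff the *horizontal* separation of dots i and j is
    shrinking: (x_i - x_j) * (u_i - u_j) < 0; ties count as diverging.

    Convergence is azimuthal because the heading columns are vertical
    strips: for a rigid scene under translation the horizontal tangent
    velocity is u_k = c_k (x_k - f) with c_k > 0, so a heading azimuth f
    between x_i and x_j forces (x_i - x_j)(u_i - u_j) > 0 -- a horizontally
    converging pair can never straddle the heading.  (Full 2D image-distance
    shrinkage does not support this exclusion: vertical motion components
    let 2D-converging pairs straddle the heading azimuth.)
    """
    if i == j:
        raise ValueError("need two distinct dots")
    if not np.any(fld.positions[i] - fld.positions[j]):
        raise ValueError("skip-pair: coincident positions")
    dx = float(fld.positions[i, 0] - fld.positions[j, 0])
    du = float(fld.velocities[i, 0] - fld.velocities[j, 0])
    return "converging" if dx * du < 0 else "diverging"


def update_posterior(columns: HeadingColumns, pair_span: tuple[float, float],
                     verdict: str, params: ConvergenceParams = ConvergenceParams()
                     ) -> HeadingColumns:
    """Bayes update: columns whose centers lie strictly inside the open
    horizontal span get the between-likelihood for the verdict, the rest the
    outside likelihood; accumulation is in log space and the posterior is
    renormalized on read-out."""
    lo, hi = sorted(pair_span)
    if verdict == "converging":
        p_in, p_out = params.p_between_given_converging, params.outside_given_converging
    elif verdict == "diverging":
        p_in, p_out = params.p_between_given_diverging, params.outside_given_diverging
    else:
        raise ValueError(f"unknown verdict {verdict!r}")
    c = columns.centers
    inside = (c > lo) & (c < hi)
    loglik = np.where(inside, np.log(p_in), np.log(p_out))
    return HeadingColumns(edges=columns.edges,
                          log_posterior=columns.log_posterior + loglik)


def _pair_indices(n: int, max_pairs: int, rng) -> tuple[np.ndarray, np.ndarray]:
    iu, ju = np.triu_indices(n, k=1)
    if len(iu) > max_pairs:
        keep = rng.choice(len(iu), size=max_pairs, replace=False)
        iu, ju = iu[keep], ju[keep]
    return iu, ju


def estimate_heading_wc99(fld: FlowField,
                          columns: HeadingColumns | None = None,
                          params: ConvergenceParams = ConvergenceParams(),
                          max_pairs: int = 50000,
                          rng=None) -> HeadingEstimate:
    """Accumulate all pairs (or a seeded uniform subsample above
    ``max_pairs``) and return the MAP column center; ties go to the most
    central column."""
    n = len(fld)
    if n < 2:
        raise InsufficientDataError("need at least 2 dots")
    if columns is None:
        columns = build_columns()
    rng = np.random.default_rng(rng)
    iu, ju = _pair_indices(n, max_pairs, rng)

    p = fld.positions
    v = fld.velocities
    dp = p[iu] - p[ju]
    ok = np.any(dp != 0, axis=1)
    dclose = dp[:, 0] * (v[iu, 0] - v[ju, 0])
    conv = (dclose < 0) & ok

    az = tan_to_deg(p[:, 0])
    lo = np.minimum(az[iu], az[ju])
    hi = np.maximum(az[iu], az[ju])
    c = columns.centers
    inside = (c[None, :] > lo[:, None]) & (c[None, :] < hi[:, None])
    div = ok & ~conv
    logp = columns.log_posterior.copy()
    logp += inside[conv].sum(axis=0) * np.log(params.p_between_given_converging)
    logp += (~inside[conv]).sum(axis=0) * np.log(params.outside_given_converging)
    logp += inside[div].sum(axis=0) * np.log(params.p_between_given_diverging)
    logp += (~inside[div]).sum(axis=0) * np.log(params.outside_given_diverging)

    out = HeadingColumns(edges=columns.edges, log_posterior=logp)
    post = out.posterior
    best = post.max()
    tied = np.flatnonzero(post == best)
    i = int(tied[np.argmin(np.abs(c[tied]))])
    return HeadingEstimate(x_deg=float(c[i]), y_deg=0.0, model="wc99",
                           info={"posterior": post,
                                 "n_converging": int(conv.sum()),
                                 "n_pairs": int(ok.sum())})
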