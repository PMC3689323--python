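"""Template-matching heading estimation (Perrone style).

A bank of global radial-flow templates covers a grid of candidate headings
(+/-20 deg at 1 deg or 0.5 deg resolution).  Each template predicts, at any
image point, motion directly away from its candidate heading; a local unit
responds with a Gaussian direction-tuning curve to the mismatch between the
observed and predicted motion direction.  Template activation sums local
responses over dots, and the most active template signals heading.

Local units here are direction-only (speed tuning flattened): this keeps the
template-peak logic, is invariant to the large speed range produced by the
0.5-4.5 m depth spread, and is the minimal faithful reading of the scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from ..core import HeadingEstimate, InsufficientDataError, deg_to_tan
from ..stimulus import FlowField

#: dots closer than this (tangent units) to a candidate heading contribute 0
SINGULAR_TOL = 1e-12


@dataclass
class TemplateBank:
    """Candidate headings (deg) with precomputed tangent coordinates."""

    headings_deg: np.ndarray        # (m, 2)
    resolution: float
    direction_tuning_sd: float      # deg
    headings_tan: np.ndarray = dfield(init=False)

    def __post_init__(self):
        self.headings_tan = deg_to_tan(self.headings_deg)

    def __len__(self):
        return len(self.headings_deg)


def build_template_bank(extent: float = 20.0, resolution: float = 1.0,
                        tuning_sd: float = 30.0) -> TemplateBank:
    """Grid of (2*extent/resolution + 1)^2 candidate headings covering
    [-extent, extent] on both axes."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    steps = 2 * extent / resolution
    if abs(steps - round(steps)) > 1e-9:
        raise ValueError("resolution must divide the grid extent")
    ax = np.linspace(-extent, extent, int(round(steps)) + 1)
    gx, gy = np.meshgrid(ax, ax, indexing="ij")
    headings = np.column_stack([gx.ravel(), gy.ravel()])
    return TemplateBank(headings_deg=headings, resolution=resolution,
                        direction_tuning_sd=tuning_sd)


def _activations(bank: TemplateBank, fld: FlowField) -> np.ndarray:
    """Activation of every template: sum over dots of exp(-dtheta^2/2 sd^2),
    dtheta the angle between observed and template-predicted direction."""
    if len(fld) == 0:
        raise InsufficientDataError("empty flow field")
    p = fld.positions                     # (n, 2)
    v = fld.velocities
    speed = np.hypot(v[:, 0], v[:, 1])
    ok_v = speed > 0
    vhat = np.where(ok_v[:, None], v / np.where(ok_v, speed, 1.0)[:, None], 0.0)

    dx = p[None, :, 0] - bank.headings_tan[:, None, 0]      # (m, n)
    dy = p[None, :, 1] - bank.headings_tan[:, None, 1]
    # angle between predicted (radial) and observed direction
    dot = dx * vhat[:, 0] + dy * vhat[:, 1]
    crs = dx * vhat[:, 1] - dy * vhat[:, 0]
    dtheta = np.rad2deg(np.abs(np.arctan2(crs, dot)))       # (m, n), deg
    g = np.exp(-0.5 * (dtheta / bank.direction_tuning_sd) ** 2)
    g[(dx * dx + dy * dy <= SINGULAR_TOL ** 2) | ~ok_v[None, :]] = 0.0
    return g.sum(axis=1)


def template_activation(bank: TemplateBank, fld: FlowField,
                        heading_index: int) -> float:
    """Activation of one template (nonnegative; n at a perfect match)."""
    return float(_activations(bank, fld)[heading_index])


def _central_argbest(values: np.ndarray, headings_deg: np.ndarray,
                     maximize: bool) -> int:
    """Index of the best value; exact ties broken by smallest heading
    eccentricity, then lexicographically on (x, y)."""
    best = values.max() if maximize else values.min()
    tied = np.flatnonzero(values == best)
    ecc = np.linalg.norm(headings_deg[tied], axis=1)
    order = np.lexsort((headings_deg[tied, 1], headings_deg[tied, 0], ecc))
    return int(tied[order[0]])


def estimate_heading_p92(bank: TemplateBank, fld: FlowField) -> HeadingEstimate:
    """Heading of the most active template."""
    act = _activations(bank, fld)
    i = _central_argbest(act, bank.headings_deg, maximize=True)
    hx, hy = bank.headings_deg[i]
    return HeadingEstimate(x_deg=float(hx), y_deg=float(hy), model="p92",
                           info={"peak_activation": float(act[i])})
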