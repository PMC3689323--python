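"""Shared geometry helpers and the heading-estimate container.

All internal computation uses tangent-plane (pinhole, focal length 1) image
coordinates; a point at horizontal/vertical visual angles (ax, ay) has
tangent coordinates (tan ax, tan ay).  Degrees are the reporting unit and
are obtained with atan per axis, so a focus of expansion placed at a given
angular offset converts exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def deg_to_tan(deg):
    """Visual angle in degrees -> tangent-plane coordinate (per axis)."""
    return np.tan(np.deg2rad(deg))


def tan_to_deg(t):
    """Tangent-plane coordinate -> visual angle in degrees (per axis)."""
    return np.rad2deg(np.arctan(t))


def unit_rows(v: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """Normalize rows of an (n, 2) array; rows with norm <= eps become 0."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    safe = np.where(n > eps, n, 1.0)
    out = v / safe
    out[np.squeeze(n <= eps, axis=-1)] = 0.0
    return out


class InsufficientDataError(ValueError):
    """Raised when a model cannot run on the given flow field."""


class DegenerateGeometryError(RuntimeError):
    """Raised when an estimator's geometry is singular (e.g. all lines
    parallel); the simulated observer converts this into a coin flip."""


@dataclass
class HeadingEstimate:
    """A model's focus-of-expansion estimate in degrees of visual angle.

    ``y_deg`` is 0 for models that only estimate azimuth.  ``degenerate``
    flags estimates produced from under-constrained geometry; ``info``
    carries model-specific diagnostics (pair counts, residuals, posteriors).
    """

    x_deg: float
    y_deg: float = 0.0
    model: str = ""
    degenerate: bool = False
    info: dict = field(default_factory=dict)

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x_deg, self.y_deg])

    def error_deg(self, foe_true_deg) -> float:
        """Euclidean angular distance to a true FoE given in degrees."""
        return float(np.hypot(*(self.xy - np.asarray(foe_true_deg, float))))
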