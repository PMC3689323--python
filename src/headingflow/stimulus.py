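"""Radial optic-flow stimulus generation.

Simulates the displays used in dot-cloud heading psychophysics: an observer
translating forward at ~1 m/s through a cloud of dots at depths 0.5-4.5 m,
viewed through a 40 deg x 32 deg window.  Dots are placed uniformly over the
*image* (angle first, then depth, then back-projection to 3D), which fixes
the on-screen dot density independently of depth.

Flow is the instantaneous pinhole flow field.  In tangent coordinates
(x, y) = (X/Z, Y/Z) a dot at depth Z under translation T = (Tx, Ty, Tz) and
rotation Omega = (Ox, Oy, Oz) moves at

    dx/dt = (x*Tz - Tx)/Z + x*y*Ox - (1 + x^2)*Oy + y*Oz
    dy/dt = (y*Tz - Ty)/Z + (1 + y^2)*Ox - x*y*Oy - x*Oz

For pure forward translation the field is exactly radial about the focus of
expansion (FoE) at (Tx/Tz, Ty/Tz).  Directional noise rotates each velocity
vector by an independent zero-mean Gaussian angle, leaving speed untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import deg_to_tan, tan_to_deg


@dataclass(frozen=True)
class SceneConfig:
    """Scene and display parameters.

    translation_speed : observer speed, m/s.
    depth_min, depth_max : dot cloud depth range, m.
    fov_h, fov_v : field of view, deg.
    dot_lifetime : dot lifetime, ms (with visual persistence this motivates
        the 40% dot-count augmentation for model inputs).
    estimate_interval : flow needed for one independent heading estimate, ms.
    persistence : visual persistence estimate, ms.
    trial_duration : stimulus duration of one trial, ms.
    """

    translation_speed: float = 1.0
    depth_min: float = 0.5
    depth_max: float = 4.5
    fov_h: float = 40.0
    fov_v: float = 32.0
    dot_lifetime: float = 250.0
    estimate_interval: float = 270.0
    persistence: float = 100.0
    trial_duration: float = 2000.0

    def __post_init__(self):
        # equality allowed: a degenerate range puts every dot at one depth
        if self.depth_min <= 0 or self.depth_max < self.depth_min:
            raise ValueError("need 0 < depth_min <= depth_max")
        if self.fov_h <= 0 or self.fov_v <= 0:
            raise ValueError("field of view must be positive")
        if min(self.dot_lifetime, self.estimate_interval,
               self.persistence, self.trial_duration) <= 0:
            raise ValueError("durations must be positive")

    @property
    def persistence_factor(self) -> float:
        """Extra-dot fraction seen due to persistence (default 100/250 = 0.4)."""
        return self.persistence / self.dot_lifetime

    def estimates_per_trial(self) -> int:
        """Independent heading estimates available in one trial
        (trial duration divided by the per-estimate flow interval)."""
        return int(self.trial_duration / self.estimate_interval)


@dataclass(frozen=True)
class StimulusCondition:
    """One cell of the factorial design."""

    dots_per_frame: int
    noise_sd: float = 0.0
    foe_offset: float = 0.0
    target_position: float = 0.0

    def __post_init__(self):
        if self.dots_per_frame < 2:
            raise ValueError("dots_per_frame must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class DotCloud:
    """3D dot positions in the camera frame (m); z is optical-axis distance."""

    points: np.ndarray  # (n, 3)

    def __len__(self):
        return len(self.points)

    @property
    def depths(self) -> np.ndarray:
        return self.points[:, 2]


@dataclass
class FlowField:
    """Per-dot image positions and velocities, tangent-plane units.

    ``positions``/``velocities`` are (n, 2) arrays in tangent coordinates
    (focal length 1; velocities in tangent units per second); ``foe`` is the
    tangent-plane FoE.  Degree views convert with atan per axis, velocities
    by the chain rule d(atan x)/dt = (dx/dt)/(1 + x^2).
    """

    positions: np.ndarray
    velocities: np.ndarray
    foe: np.ndarray
    condition: StimulusCondition | None = None

    def __len__(self):
        return len(self.positions)

    @property
    def positions_deg(self) -> np.ndarray:
        return tan_to_deg(self.positions)

    @property
    def velocities_deg(self) -> np.ndarray:
        return np.rad2deg(self.velocities / (1.0 + self.positions ** 2))

    @property
    def foe_deg(self) -> np.ndarray:
        return tan_to_deg(self.foe)

    def to_dataframe(self) -> pd.DataFrame:
        pos, vel = self.positions_deg, self.velocities_deg
        return pd.DataFrame(
            {"x_deg": pos[:, 0], "y_deg": pos[:, 1],
             "vx_degps": vel[:, 0], "vy_degps": vel[:, 1]})

    def write_csv(self, path, seed: int | None = None) -> None:
        """Write the field as CSV plus a JSON sidecar (<path>.json) carrying
        the true FoE, the generating condition and the seed."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        meta = {"foe_true_deg": [float(v) for v in self.foe_deg],
                "condition": asdict(self.condition) if self.condition else None,
                "seed": seed}
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def read_csv(cls, path) -> "FlowField":
        path = Path(path)
        df = pd.read_csv(path)
        pos = deg_to_tan(df[["x_deg", "y_deg"]].to_numpy())
        vel = np.deg2rad(df[["vx_degps", "vy_degps"]].to_numpy()) * (1.0 + pos ** 2)
        foe = np.zeros(2)
        cond = None
        sidecar = Path(str(path) + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            foe = deg_to_tan(np.asarray(meta["foe_true_deg"], float))
            if meta.get("condition"):
                cond = StimulusCondition(**meta["condition"])
        return cls(positions=pos, velocities=vel, foe=foe, condition=cond)


def sample_dot_cloud(n: int, config: SceneConfig = SceneConfig(),
                     rng=None) -> DotCloud:
    """Sample ``n`` dots: image angle uniform over the field of view, depth
    uniform on [depth_min, depth_max], then back-project to 3D."""
    if n < 1:
        raise ValueError("need at least one dot")
    rng = np.random.default_rng(rng)
    ax = rng.uniform(-config.fov_h / 2, config.fov_h / 2, n)
    ay = rng.uniform(-config.fov_v / 2, config.fov_v / 2, n)
    z = rng.uniform(config.depth_min, config.depth_max, n)
    pts = np.column_stack([z * deg_to_tan(ax), z * deg_to_tan(ay), z])
    return DotCloud(points=pts)


def _rotate_y(v: np.ndarray, angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    x, y, z = v
    return np.array([c * x + s * z, y, -s * x + c * z])


def project_flow(cloud: DotCloud,
                 translation=(0.0, 0.0, 1.0),
                 rotation=(0.0, 0.0, 0.0),
                 foe_offset: float = 0.0,
                 config: SceneConfig = SceneConfig(),
                 condition: StimulusCondition | None = None) -> FlowField:
    """Instantaneous flow of ``cloud`` under observer motion.

    ``foe_offset`` (deg) rotates the translation vector in the horizontal
    plane, so for pure forward translation the FoE lands exactly at
    (foe_offset, 0) deg with the target at the image origin.
    """
    t = np.asarray(translation, dtype=float)
    if not np.any(t):
        raise ValueError("translation must be nonzero")
    z = cloud.depths
    if np.any(z <= 0):
        raise ValueError("invalid scene: dot at non-positive depth")
    t = _rotate_y(t, np.deg2rad(foe_offset))
    ox, oy, oz = np.asarray(rotation, dtype=float)

    x = cloud.points[:, 0] / z
    y = cloud.points[:, 1] / z
    u = (x * t[2] - t[0]) / z + x * y * ox - (1 + x ** 2) * oy + y * oz
    v = (y * t[2] - t[1]) / z + (1 + y ** 2) * ox - x * y * oy - x * oz
    if t[2] == 0:
        raise ValueError("frontal translation has no finite FoE")
    foe = np.array([t[0] / t[2], t[1] / t[2]])
    return FlowField(positions=np.column_stack([x, y]),
                     velocities=np.column_stack([u, v]),
                     foe=foe, condition=condition)


def apply_direction_noise(fld: FlowField, sd: float, rng=None) -> FlowField:
    """Rotate each velocity vector by an independent N(0, sd deg) angle.

    Speeds and positions are untouched; sd=0 returns an identical copy.
    """
    if sd < 0:
        raise ValueError("noise sd must be >= 0")
    vel = fld.velocities.copy()
    if sd > 0:
        rng = np.random.default_rng(rng)
        th = np.deg2rad(rng.normal(0.0, sd, size=len(vel)))
        c, s = np.cos(th), np.sin(th)
        vel = np.column_stack([c * vel[:, 0] - s * vel[:, 1],
                               s * vel[:, 0] + c * vel[:, 1]])
    return FlowField(positions=fld.positions.copy(), velocities=vel,
                     foe=fld.foe.copy(), condition=fld.condition)


def augment_dot_count(n: int, persistence_factor: float = 0.4) -> int:
    """Dot count a model should receive given visual persistence: redrawn
    limited-lifetime dots leave ~40% extra dots visible at any moment."""
    if n < 1:
        raise ValueError("need at least one dot")
    return int(round(n * (1.0 + persistence_factor)))


def make_flow_field(condition: StimulusCondition,
                    config: SceneConfig = SceneConfig(),
                    rng=None, augment: bool = True) -> FlowField:
    """One model-ready flow field for a design cell: sample a fresh cloud
    (augmented count by default), project pure forward translation with the
    condition's FoE offset, and add directional noise."""
    rng = np.random.default_rng(rng)
    n = condition.dots_per_frame
    if augment:
        n = augment_dot_count(n, config.persistence_factor)
    cloud = sample_dot_cloud(n, config, rng)
    fld = project_flow(cloud, translation=(0, 0, config.translation_speed),
                       foe_offset=condition.foe_offset, config=config,
                       condition=condition)
    return apply_direction_noise(fld, condition.noise_sd, rng)
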