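import numpy as np
import pytest

from headingflow import (HeadingEstimate, SceneConfig, StimulusCondition,
                         make_flow_field, project_flow)
from headingflow.core import DegenerateGeometryError
from headingflow.stimulus import DotCloud


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def scene():
    return SceneConfig()


@pytest.fixture
def radial_field():
    """Factory for noiseless/noisy radial flow fields with augmented count."""

    def make(dots=200, noise=0.0, offset=2.0, seed=0, augment=True):
        cond = StimulusCondition(dots_per_frame=dots, noise_sd=noise,
                                 foe_offset=offset)
        return make_flow_field(cond, rng=np.random.default_rng(seed),
                               augment=augment)

    return make


@pytest.fixture
def coincident_pair_field():
    """Field of image-coincident dot pairs at distinct depths: the exact
    geometry motion-parallax differencing assumes."""

    def make(foe_offset=2.0, rotation=(0.0, 0.0, 0.0), n_pairs=3, seed=0):
        r = np.random.default_rng(seed)
        base = np.column_stack([
            np.tan(np.deg2rad(r.uniform(-15, 15, n_pairs))),
            np.tan(np.deg2rad(r.uniform(-12, 12, n_pairs)))])
        pos = np.repeat(base, 2, axis=0)
        z = np.empty(2 * n_pairs)
        z[0::2] = r.uniform(0.5, 1.5, n_pairs)
        z[1::2] = r.uniform(2.5, 4.5, n_pairs)
        pts = np.column_stack([pos[:, 0] * z, pos[:, 1] * z, z])
        return project_flow(DotCloud(pts), rotation=rotation,
                            foe_offset=foe_offset)

    return make


class GaussianStubModel:
    """Deterministic-protocol stand-in: reports the true FoE plus Gaussian
    error drawn from the trial's own rng stream."""

    def __init__(self, sd=0.5, bias=0.0):
        self.sd = sd
        self.bias = bias

    def __call__(self, field, rng=None):
        rng = np.random.default_rng(rng)
        foe = field.foe_deg
        return HeadingEstimate(
            x_deg=float(foe[0] + self.bias + rng.normal(0.0, self.sd)),
            y_deg=float(foe[1]), model="stub")


class AlwaysDegenerateModel:
    def __call__(self, field, rng=None):
        raise DegenerateGeometryError("stub failure")


@pytest.fixture
def stub_model():
    return GaussianStubModel(sd=0.5)


@pytest.fixture
def exact_model():
    return GaussianStubModel(sd=0.0)


@pytest.fixture
def degenerate_model():
    return AlwaysDegenerateModel()
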