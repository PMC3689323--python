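import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from headingflow import (SceneConfig, StimulusCondition, apply_direction_noise,
                         augment_dot_count, make_flow_field, project_flow,
                         sample_dot_cloud)
from headingflow.stimulus import DotCloud, FlowField


class TestSceneConfig:
    def test_defaults(self, scene):
        assert scene.persistence_factor == pytest.approx(0.4)
        assert scene.estimates_per_trial() == 7

    @pytest.mark.parametrize("kw", [
        {"depth_min": 0.0}, {"depth_min": 2.0, "depth_max": 1.0},
        {"fov_h": -1.0}, {"dot_lifetime": 0.0}])
    def test_invalid(self, kw):
        with pytest.raises(ValueError):
            SceneConfig(**kw)


class TestSampleDotCloud:
    def test_counts_and_depth_range(self, scene, rng):
        cloud = sample_dot_cloud(200, scene, rng)
        assert len(cloud) == 200
        assert np.all(cloud.depths >= 0.5) and np.all(cloud.depths <= 4.5)

    def test_degenerate_depth_range(self):
        config = SceneConfig(depth_min=1.0, depth_max=1.0)
        cloud = sample_dot_cloud(1, config, np.random.default_rng(0))
        assert cloud.depths[0] == pytest.approx(1.0)

    def test_depths_uniform_ks(self, scene):
        cloud = sample_dot_cloud(10_000, scene, np.random.default_rng(123))
        p = stats.kstest(cloud.depths, stats.uniform(0.5, 4.0).cdf).pvalue
        assert p > 0.01

    def test_image_positions_uniform_within_fov(self, scene):
        cloud = sample_dot_cloud(10_000, scene, np.random.default_rng(7))
        fld = project_flow(cloud, config=scene)
        pos = fld.positions_deg
        assert np.all(np.abs(pos[:, 0]) <= 20) and np.all(np.abs(pos[:, 1]) <= 16)
        assert stats.kstest(pos[:, 0], stats.uniform(-20, 40).cdf).pvalue > 0.01

    def test_invalid_n(self, scene):
        with pytest.raises(ValueError):
            sample_dot_cloud(0, scene)

    def test_deterministic_under_seed(self, scene):
        a = sample_dot_cloud(50, scene, np.random.default_rng(99))
        b = sample_dot_cloud(50, scene, np.random.default_rng(99))
        np.testing.assert_array_equal(a.points, b.points)


class TestProjectFlow:
    def test_dot_at_foe_has_zero_velocity(self):
        cloud = DotCloud(points=np.array([[0.0, 0.0, 2.0]]))
        fld = project_flow(cloud, foe_offset=0.0)
        np.testing.assert_allclose(fld.velocities, 0.0, atol=1e-15)

    def test_translational_flow_closed_form(self):
        # tangent point (0.1, 0) at Z=1 under T=(0,0,1): u = x*Tz/Z = 0.1
        cloud = DotCloud(points=np.array([[0.1, 0.0, 1.0]]))
        fld = project_flow(cloud, translation=(0, 0, 1))
        np.testing.assert_allclose(fld.velocities[0], [0.1, 0.0], atol=1e-15)

    def test_rotational_flow_cancels_in_pair_difference(self):
        # same image position, different depth: velocity difference has no
        # rotational component
        pts = np.array([[0.2, 0.1, 1.0], [0.4, 0.2, 2.0]])
        omega = (0.0, 0.05, 0.0)
        with_rot = project_flow(DotCloud(pts), rotation=omega)
        without = project_flow(DotCloud(pts))
        diff_rot = with_rot.velocities[0] - with_rot.velocities[1]
        diff_none = without.velocities[0] - without.velocities[1]
        np.testing.assert_allclose(diff_rot, diff_none, atol=1e-14)

    def test_foe_matches_offset(self, radial_field):
        for off in (-4.0, -0.5, 0.2, 3.0):
            fld = radial_field(dots=10, offset=off, seed=1)
            np.testing.assert_allclose(fld.foe_deg, [off, 0.0], atol=1e-12)

    def test_pure_translation_field_is_radial(self, radial_field):
        fld = radial_field(dots=300, offset=1.5, seed=3)
        rel = fld.positions - fld.foe
        cross = rel[:, 0] * fld.velocities[:, 1] - rel[:, 1] * fld.velocities[:, 0]
        np.testing.assert_allclose(cross, 0.0, atol=1e-12)
        assert np.all((rel * fld.velocities).sum(axis=1) >= 0)

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            project_flow(DotCloud(points=np.array([[0.1, 0.1, 0.0]])))

    def test_zero_translation_rejected(self):
        with pytest.raises(ValueError):
            project_flow(DotCloud(points=np.array([[0.1, 0.1, 1.0]])),
                         translation=(0, 0, 0))


class TestDirectionNoise:
    def test_zero_sd_is_identity(self, radial_field, rng):
        fld = radial_field(dots=50, seed=2)
        out = apply_direction_noise(fld, 0.0, rng)
        np.testing.assert_array_equal(out.velocities, fld.velocities)
        np.testing.assert_array_equal(out.positions, fld.positions)

    def test_speed_and_position_preserved(self, radial_field, rng):
        fld = radial_field(dots=200, seed=2)
        out = apply_direction_noise(fld, 15.0, rng)
        np.testing.assert_allclose(np.linalg.norm(out.velocities, axis=1),
                                   np.linalg.norm(fld.velocities, axis=1),
                                   rtol=1e-12)
        np.testing.assert_array_equal(out.positions, fld.positions)

    def test_circular_sd_matches_request(self):
        cond = StimulusCondition(dots_per_frame=10_000, foe_offset=1.0)
        fld = make_flow_field(cond, rng=np.random.default_rng(5), augment=False)
        out = apply_direction_noise(fld, 7.5, np.random.default_rng(6))
        a0 = np.arctan2(fld.velocities[:, 1], fld.velocities[:, 0])
        a1 = np.arctan2(out.velocities[:, 1], out.velocities[:, 0])
        d = np.rad2deg(np.angle(np.exp(1j * (a1 - a0))))
        assert d.std() == pytest.approx(7.5, abs=0.3)

    def test_negative_sd_rejected(self, radial_field):
        with pytest.raises(ValueError):
            apply_direction_noise(radial_field(dots=5), -1.0)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(sd=st.floats(0.0, 90.0), seed=st.integers(0, 2**16))
    def test_speed_preserved_for_any_sd(self, sd, seed):
        cond = StimulusCondition(dots_per_frame=20, foe_offset=1.0)
        fld = make_flow_field(cond, rng=np.random.default_rng(3),
                              augment=False)
        out = apply_direction_noise(fld, sd, np.random.default_rng(seed))
        np.testing.assert_allclose(np.linalg.norm(out.velocities, axis=1),
                                   np.linalg.norm(fld.velocities, axis=1),
                                   rtol=1e-12)


class TestAugmentDotCount:
    @pytest.mark.parametrize("n,expected", [(100, 140), (5, 7), (50, 70),
                                            (200, 280)])
    def test_persistence_augmentation(self, n, expected):
        assert augment_dot_count(n) == expected

    def test_zero_factor_identity(self):
        assert augment_dot_count(17, persistence_factor=0.0) == 17

    def test_invalid(self):
        with pytest.raises(ValueError):
            augment_dot_count(0)


class TestFlowFieldIO:
    def test_csv_roundtrip(self, radial_field, tmp_path):
        fld = radial_field(dots=20, noise=7.5, offset=1.0, seed=4)
        path = tmp_path / "field.csv"
        fld.write_csv(path, seed=4)
        back = FlowField.read_csv(path)
        np.testing.assert_allclose(back.positions, fld.positions, atol=1e-12)
        np.testing.assert_allclose(back.velocities, fld.velocities, atol=1e-12)
        np.testing.assert_allclose(back.foe, fld.foe, atol=1e-12)
        assert back.condition == fld.condition

    def test_dataframe_columns(self, radial_field):
        df = radial_field(dots=5).to_dataframe()
        assert list(df.columns) == ["x_deg", "y_deg", "vx_degps", "vy_degps"]


class TestStimulusCondition:
    def test_invalid(self):
        with pytest.raises(ValueError):
            StimulusCondition(dots_per_frame=1)
        with pytest.raises(ValueError):
            StimulusCondition(dots_per_frame=5, noise_sd=-1)

    def test_make_flow_field_deterministic(self):
        cond = StimulusCondition(dots_per_frame=30, noise_sd=7.5,
                                 foe_offset=1.0)
        a = make_flow_field(cond, rng=np.random.default_rng(11))
        b = make_flow_field(cond, rng=np.random.default_rng(11))
        np.testing.assert_array_equal(a.velocities, b.velocities)
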