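import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sandswim.kinematics import (
    BODY_MASS,
    ConfigurationError,
    WaveSpec,
    WaveShape,
    calibrate_wave,
    chain_pose,
    deformation_velocity,
    joint_angles,
    make_body,
    shape_in_body_frame,
)


class TestMakeBody:
    def test_uniform_plan(self):
        body = make_body("uniform")
        assert body.n_segments == 60
        assert np.allclose(body.widths, 0.016)
        assert body.masses.sum() == pytest.approx(BODY_MASS, abs=1e-9)
        assert body.head_area == pytest.approx(0.016 * 0.016)

    def test_tapered_widths(self):
        from sandswim.kinematics import _width_profile

        body = make_body("tapered")
        # width 0.2 cm at the tail tip, 1.6 cm at mid-body
        w = _width_profile("tapered", np.array([0.0, 0.5, 1.0]))
        np.testing.assert_allclose(w, [0.002, 0.016, 0.002], rtol=1e-12)
        mid = np.argmin(np.abs(body.positions - 0.5))
        assert body.widths[mid] == pytest.approx(0.016)
        assert body.masses.sum() == pytest.approx(BODY_MASS, abs=1e-9)

    def test_tapered_mass_symmetric(self):
        body = make_body("tapered")
        assert np.allclose(body.masses, body.masses[::-1], rtol=1e-12)

    def test_unknown_plan(self):
        with pytest.raises(ConfigurationError):
            make_body("spherical")


class TestWaveCalibration:
    @pytest.mark.parametrize("ratio", [0.05, 0.2, 0.4])
    def test_realized_amplitude_matches_target(self, ratio):
        """Assembled chain, fit with a sinusoid, recovers A/lambda within 2%."""
        body = make_body("uniform")
        shape = calibrate_wave(WaveSpec(amplitude_ratio=ratio), body)
        assert shape.amplitude / shape.wavelength == pytest.approx(ratio, rel=0.02)
        # one spatial period spans the body: wavelength below arc length
        assert 0 < shape.wavelength < body.length

    def test_zero_amplitude(self):
        body = make_body("uniform")
        shape = calibrate_wave(WaveSpec(amplitude_ratio=0.0), body)
        sample = joint_angles(shape, 0.3)
        assert np.allclose(sample.angles, 0.0)
        assert np.allclose(sample.rates, 0.0)

    def test_invalid_wave(self):
        with pytest.raises(ConfigurationError):
            WaveSpec(amplitude_ratio=0.9)
        with pytest.raises(ConfigurationError):
            WaveSpec(frequency=0.0)


class TestJointAngles:
    def test_periodicity(self):
        shape = calibrate_wave(WaveSpec(), make_body("uniform"))
        t0 = 0.137
        a = joint_angles(shape, t0)
        b = joint_angles(shape, t0 + 1.0 / shape.frequency)
        np.testing.assert_allclose(a.angles, b.angles, atol=1e-12)
        np.testing.assert_allclose(a.rates, b.rates, atol=1e-9)

    def test_mirror_symmetry(self):
        """Negating the wave slope negates every joint angle."""
        body = make_body("uniform")
        shape = calibrate_wave(WaveSpec(), body)
        mirrored = WaveShape(shape.spec, body, -shape.kappa,
                             shape.wavelength, -shape.amplitude)
        a = joint_angles(shape, 0.21)
        b = joint_angles(mirrored, 0.21)
        np.testing.assert_allclose(a.angles, -b.angles, atol=1e-14)

    def test_rates_match_finite_difference(self):
        """Analytic shape-rate agrees with a central difference."""
        shape = calibrate_wave(WaveSpec(), make_body("uniform"))
        t, h = 0.08, 1e-5 / shape.frequency
        fd = (joint_angles(shape, t + h).angles - joint_angles(shape, t - h).angles) / (2 * h)
        np.testing.assert_allclose(joint_angles(shape, t).rates, fd, rtol=1e-4)


class TestChainPose:
    def test_straight_chain(self):
        body = make_body("uniform")
        centers, phi = chain_pose(np.zeros(body.n_segments - 1), (0, 0, 0), body)
        assert np.allclose(centers[:, 1], 0)
        assert np.allclose(phi, 0)
        np.testing.assert_allclose(np.diff(centers[:, 0]), body.segment_length)

    def test_rigid_rotation(self):
        body = make_body("uniform")
        rng = np.random.default_rng(0)
        angles = rng.normal(0, 0.2, body.n_segments - 1)
        c0, _ = chain_pose(angles, (0, 0, 0), body)
        th = 0.7
        c1, _ = chain_pose(angles, (0, 0, th), body)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        np.testing.assert_allclose(c1, c0 @ R.T, atol=1e-12)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_inextensibility(self, seed):
        """Total arc length is 12 cm for any joint-angle set."""
        body = make_body("uniform")
        rng = np.random.default_rng(seed)
        angles = rng.uniform(-0.5, 0.5, body.n_segments - 1)
        centers, phi = chain_pose(angles, (0.1, -0.2, 0.3), body)
        # consecutive segment endpoints coincide by construction; check total
        ends = np.zeros((body.n_segments + 1, 2))
        ends[0] = [0.1, -0.2]
        for i in range(body.n_segments):
            ends[i + 1] = ends[i] + body.segment_length * np.array(
                [np.cos(phi[i]), np.sin(phi[i])])
        length = np.linalg.norm(np.diff(ends, axis=0), axis=1).sum()
        assert length == pytest.approx(body.length, abs=1e-12 * body.length)


class TestDeformationVelocity:
    def test_zero_amplitude_zero_velocity(self):
        shape = calibrate_wave(WaveSpec(amplitude_ratio=0.0), make_body("uniform"))
        assert np.allclose(deformation_velocity(shape, 0.4), 0.0)

    def test_matches_finite_difference(self):
        shape = calibrate_wave(WaveSpec(), make_body("uniform"))
        t, h = 0.11, 1e-5 / shape.frequency
        a = shape_in_body_frame(shape, t - h).centers
        b = shape_in_body_frame(shape, t + h).centers
        fd = (b - a) / (2 * h)
        np.testing.assert_allclose(deformation_velocity(shape, t), fd,
                                   rtol=1e-4, atol=1e-8)

    def test_cycle_mean_displacement_zero(self):
        """Body-frame positions are periodic: zero net displacement per cycle."""
        shape = calibrate_wave(WaveSpec(), make_body("uniform"))
        f = shape.frequency
        ts = np.linspace(0, 1 / f, 400, endpoint=False)
        disp = sum(deformation_velocity(shape, t) for t in ts) / len(ts) / f
        assert np.abs(disp).max() < 1e-6 * shape.wavelength
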