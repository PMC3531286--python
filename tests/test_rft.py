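import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sandswim.rft import (
    REF_DEPTH,
    REF_SIDE_AREA,
    load_coefficients,
    scale_force,
    segment_force,
    unit_forces,
)


@pytest.fixture(scope="module")
def coeffs():
    return load_coefficients()


def eq3_reference(psi, c_s, c_f, c_l, gamma):
    """Independent transcription of the empirical fitting functions."""
    beta0 = np.arctan2(gamma * np.tan(psi), 1.0) if psi < np.pi / 2 else np.pi / 2
    f_perp = c_s * np.sin(beta0)
    f_par = c_f * np.cos(psi) + c_l * (1 - np.sin(psi))
    return f_perp, f_par


class TestUnitForces:
    def test_table_values_loaded(self, coeffs):
        assert (coeffs.body.c_s, coeffs.body.c_f, coeffs.body.c_l, coeffs.body.gamma) == (
            5.57, 2.30, -1.74, 1.93)
        assert (coeffs.head.c_s, coeffs.head.c_f, coeffs.head.c_l, coeffs.head.gamma) == (
            19.52, 1.24, -0.99, 0.14)

    def test_no_lateral_force_at_zero_attack(self, coeffs):
        f_perp, _ = unit_forces(0.0, coeffs.body)
        assert f_perp == 0.0

    def test_broadside_body_values(self, coeffs):
        """At psi = pi/2 the perpendicular force saturates at C_S and the
        parallel force vanishes (direct evaluation of the fitting functions)."""
        f_perp, f_par = unit_forces(np.pi / 2, coeffs.body)
        assert f_perp == pytest.approx(5.57, rel=1e-12)
        assert f_par == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("psi_deg", [10, 25, 40, 55, 70, 85])
    def test_matches_independent_transcription(self, coeffs, psi_deg):
        psi = np.radians(psi_deg)
        for c in (coeffs.body, coeffs.head):
            ref = eq3_reference(psi, c.c_s, c.c_f, c.c_l, c.gamma)
            got = unit_forces(psi, c)
            assert got[0] == pytest.approx(ref[0], rel=1e-12)
            assert got[1] == pytest.approx(ref[1], rel=1e-12)

    def test_normal_exceeds_tangential_above_30deg(self, coeffs):
        """F_perp/F_par > 1 for psi >= 30 deg (thrust-favorable anisotropy)."""
        psi = np.radians(np.linspace(30, 89, 30))
        f_perp, f_par = unit_forces(psi, coeffs.body)
        assert np.all(f_perp / f_par > 1.0)

    def test_symmetry_fold(self, coeffs):
        f1 = unit_forces(np.radians(60), coeffs.body)
        f2 = unit_forces(np.radians(120), coeffs.body)
        assert f1 == pytest.approx(f2)


class TestScaleForce:
    def test_identity_at_reference(self, coeffs):
        assert scale_force(1.7, REF_SIDE_AREA, REF_DEPTH, coeffs.body) == pytest.approx(1.7)

    def test_depth_linearity(self, coeffs):
        f1 = scale_force(1.0, REF_SIDE_AREA, 0.03, coeffs.body)
        f2 = scale_force(1.0, REF_SIDE_AREA, 0.06, coeffs.body)
        assert f2 == pytest.approx(2 * f1)

    def test_segment_scale_factor(self, coeffs):
        """A 0.2 cm x 1.6 cm segment side at 4.7 cm depth scales by
        (0.32/6.4) * (4.7/7.6) relative to the reference rod side."""
        got = scale_force(1.0, 0.002 * 0.016, 0.047, coeffs.body)
        assert got == pytest.approx((0.32 / 6.4) * (4.7 / 7.6), rel=1e-12)

    def test_nonpositive_depth_rejected(self, coeffs):
        with pytest.raises(ValueError):
            scale_force(1.0, REF_SIDE_AREA, 0.0, coeffs.body)


class TestSegmentForce:
    def test_axial_motion_pure_axial_resistance(self, coeffs):
        load = segment_force(0.3, 0.1 * np.array([np.cos(0.3), np.sin(0.3)]),
                             1e-4, 0.05, "body", coeffs)
        n = np.array([-np.sin(0.3), np.cos(0.3)])
        assert abs(load.force @ n) < 1e-14
        assert load.psi == pytest.approx(0.0, abs=1e-12)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_force_opposes_motion(self, seed):
        coeffs = load_coefficients()
        rng = np.random.default_rng(seed)
        angle = rng.uniform(0, 2 * np.pi)
        v = rng.normal(0, 0.2, 2)
        cls = "body" if seed % 2 else "head"
        load = segment_force(angle, v, 1e-4, 0.05, cls, coeffs)
        assert load.force @ v <= 1e-15

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_velocity_reversal_reverses_force(self, seed):
        coeffs = load_coefficients()
        rng = np.random.default_rng(seed)
        angle = rng.uniform(0, 2 * np.pi)
        v = rng.normal(0, 0.2, 2)
        f1 = segment_force(angle, v, 1e-4, 0.05, "body", coeffs).force
        f2 = segment_force(angle, -v, 1e-4, 0.05, "body", coeffs).force
        np.testing.assert_allclose(f1, -f2, atol=1e-14)

    def test_speed_independence(self, coeffs):
        """Scaling the speed by 10 changes no force beyond round-off."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            angle = rng.uniform(0, 2 * np.pi)
            v = rng.normal(0, 0.1, 2)
            f1 = segment_force(angle, v, 1e-4, 0.05, "body", coeffs).force
            f2 = segment_force(angle, 10 * v, 1e-4, 0.05, "body", coeffs).force
            np.testing.assert_allclose(f1, f2, rtol=1e-12)

    def test_oddness_evenness_under_lateral_reversal(self, coeffs):
        """F_perp is odd, F_par even when the lateral velocity flips sign."""
        a = np.array([1.0, 0.0])
        n = np.array([0.0, 1.0])
        v = 0.1 * a + 0.07 * n
        v_flip = 0.1 * a - 0.07 * n
        f = segment_force(0.0, v, 1e-4, 0.05, "body", coeffs).force
        ff = segment_force(0.0, v_flip, 1e-4, 0.05, "body", coeffs).force
        assert f @ a == pytest.approx(ff @ a, rel=1e-12)
        assert f @ n == pytest.approx(-(ff @ n), rel=1e-12)

    def test_zero_velocity_zero_force(self, coeffs):
        load = segment_force(0.5, [0.0, 0.0], 1e-4, 0.05, "body", coeffs, eps=1e-9)
        assert np.allclose(load.force, 0.0)

    def test_zero_area_rejected(self, coeffs):
        with pytest.raises(ValueError):
            segment_force(0.0, [0.1, 0.0], 0.0, 0.05, "body", coeffs)
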