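"""Unit and property tests for the tri-component puncture force model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from needleforce import force_model as fm
from needleforce.params import LIVER, DomainError, TissueParams

LIVER_MU = LIVER  # Table-style liver parameters with mu0 = 0.2


def valid_params(draw):
    return TissueParams(
        f_max=draw(st.floats(0.1, 5.0)),
        lam=draw(st.floats(0.01, 1.0)),
        k0=draw(st.floats(0.001, 1.0)),
        alpha=draw(st.floats(0.01, 0.5)),
        mu0=draw(st.floats(0.0, 1.0)),
    )


params_strategy = st.builds(
    TissueParams,
    f_max=st.floats(0.1, 5.0), lam=st.floats(0.01, 1.0),
    k0=st.floats(0.001, 1.0), alpha=st.floats(0.01, 0.5),
    mu0=st.floats(0.0, 1.0))


class TestCutting:
    def test_zero_depth_gives_zero(self):
        assert fm.cutting_force_saturating(0.0, LIVER_MU) == 0.0

    def test_saturates_at_f_max(self):
        z = 20.0 / LIVER_MU.lam
        assert fm.cutting_force_saturating(z, LIVER_MU) == \
            pytest.approx(LIVER_MU.f_max, abs=1e-6)

    def test_liver_worked_value(self):
        # 1.68 * (1 - exp(-0.12 * 10))
        assert fm.cutting_force_saturating(10.0, LIVER_MU) == \
            pytest.approx(1.68 * (1.0 - np.exp(-1.2)), rel=1e-12)
        assert fm.cutting_force_saturating(10.0, LIVER_MU) == \
            pytest.approx(1.17399, abs=1e-5)

    def test_small_depth_linear_limit(self):
        lam = LIVER_MU.lam
        z = np.linspace(1e-6, 0.01 / lam, 50)
        exact = fm.cutting_force_saturating(z, LIVER_MU)
        linear = LIVER_MU.f_max * lam * z
        assert np.all(np.abs(exact - linear) / exact <= 0.01)

    def test_negative_depth_rejected(self):
        with pytest.raises(DomainError):
            fm.cutting_force_saturating(-1.0, LIVER_MU)

    @pytest.mark.parametrize("gw, expect", [(0.0, 0.0), (0.3, 0.3)])
    def test_constant_model(self, gw, expect):
        p = LIVER_MU.with_values(gamma_w0=gw)
        assert fm.cutting_force_constant(p) == expect

    def test_constant_model_requires_gamma_w0(self):
        with pytest.raises(DomainError):
            fm.cutting_force_constant(LIVER_MU)


class TestStiffness:
    def test_zero_at_surface(self):
        assert fm.stiffness_force(0.0, LIVER_MU, 90.0) == 0.0

    def test_liver_worked_value(self):
        # 0.05 * exp(0.21*5) * 5 * sin(90 deg)
        assert fm.stiffness_force(5.0, LIVER_MU, 90.0) == \
            pytest.approx(0.05 * np.exp(1.05) * 5.0, rel=1e-12)
        assert fm.stiffness_force(5.0, LIVER_MU, 90.0) == \
            pytest.approx(0.71441, abs=1e-5)

    def test_sine_scaling_30_vs_90(self):
        f90 = fm.stiffness_force(7.0, LIVER_MU, 90.0)
        f30 = fm.stiffness_force(7.0, LIVER_MU, 30.0)
        assert f30 == pytest.approx(0.5 * f90, rel=1e-12)

    @pytest.mark.parametrize("theta", [0.0, -5.0, 90.5, 180.0])
    def test_angle_domain(self, theta):
        with pytest.raises(DomainError):
            fm.stiffness_force(1.0, LIVER_MU, theta)


class TestFriction:
    def test_zero_at_surface(self):
        assert fm.friction_force_closed(0.0, LIVER_MU, 90.0) == 0.0

    def test_liver_worked_value(self):
        # mu0*k0*[exp(1.05)*(1.05-1)+1]/0.21^2
        expect = 0.2 * 0.05 * (np.exp(1.05) * 0.05 + 1.0) / 0.21 ** 2
        assert fm.friction_force_closed(5.0, LIVER_MU, 90.0) == \
            pytest.approx(expect, rel=1e-12)
        assert fm.friction_force_closed(5.0, LIVER_MU, 90.0) == \
            pytest.approx(0.259157, abs=1e-6)

    def test_alpha_zero_limit_exact(self):
        p = TissueParams(f_max=1.0, lam=0.1, k0=0.05, alpha=0.0, mu0=0.2)
        assert fm.friction_force_closed(4.0, p, 90.0) == \
            pytest.approx(0.2 * 0.05 * 16.0 / 2.0, rel=1e-12)

    def test_alpha_to_zero_continuity(self):
        p = TissueParams(f_max=1.0, lam=0.1, k0=0.05, alpha=1e-8, mu0=0.2)
        limit = 0.2 * 0.05 * 25.0 / 2.0
        got = fm.friction_force_closed(5.0, p, 90.0)
        assert got == pytest.approx(limit, rel=1e-4)

    @pytest.mark.parametrize("d", [0.1, 1.0, 5.0, 20.0])
    @pytest.mark.parametrize("alpha", [0.05, 0.21, 0.5])
    @pytest.mark.parametrize("theta", [15.0, 30.0, 45.0, 90.0])
    def test_closed_form_matches_quadrature(self, d, alpha, theta):
        p = LIVER_MU.with_values(alpha=alpha)
        closed = fm.friction_force_closed(d, p, theta)
        quad = fm.friction_force_quadrature(d, p, theta)
        assert closed == pytest.approx(quad, rel=1e-8)

    def test_quadrature_monotone_in_depth(self):
        assert fm.friction_force_quadrature(10.0, LIVER_MU) > \
            fm.friction_force_quadrature(5.0, LIVER_MU)


class TestTotal:
    def test_zero_at_surface_saturating(self):
        dec = fm.total_force(0.0, LIVER_MU, 90.0)
        assert dec.total == 0.0

    def test_liver_worked_decomposition(self):
        dec = fm.total_force(5.0, LIVER_MU, 90.0)
        assert dec.cutting == pytest.approx(0.757996, abs=1e-6)
        assert dec.stiffness == pytest.approx(0.714413, abs=1e-6)
        assert dec.friction == pytest.approx(0.259157, abs=1e-6)
        assert dec.total == pytest.approx(1.731566, abs=1e-6)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(p=params_strategy, z=st.floats(0.0, 30.0),
           theta=st.floats(1.0, 90.0))
    def test_components_sum_to_total(self, p, z, theta):
        dec = fm.total_force(z, p, theta)
        assert dec.total == pytest.approx(
            dec.cutting + dec.stiffness + dec.friction, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(p=params_strategy, theta=st.floats(1.0, 90.0))
    def test_components_nonnegative_and_increasing(self, p, theta):
        z = np.linspace(0.0, 20.0, 200)
        dec = fm.total_force(z, p, theta)
        for comp in (dec.cutting, dec.stiffness, dec.friction):
            assert np.all(np.asarray(comp) >= 0.0)
        assert np.all(np.diff(dec.total) > 0.0)

    def test_sine_ratio_exact_for_angle_pair(self):
        z = 6.0
        for func in (fm.stiffness_force, fm.friction_force_closed):
            r = func(z, LIVER_MU, 45.0) / func(z, LIVER_MU, 15.0)
            assert r == pytest.approx(
                np.sin(np.deg2rad(45)) / np.sin(np.deg2rad(15)), rel=1e-12)

    def test_constant_mode_total(self):
        p = LIVER_MU.with_values(gamma_w0=0.3)
        dec = fm.total_force(5.0, p, 90.0, cutting_mode="constant")
        assert dec.cutting == 0.3
        assert dec.total == pytest.approx(
            0.3 + dec.stiffness + dec.friction, abs=1e-12)


class TestProfile:
    def test_single_zero_sample(self):
        curve = fm.force_profile([0.0], LIVER_MU)
        assert len(curve) == 1 and curve.force[0] == 0.0

    def test_last_value_matches_pointwise(self):
        grid = np.linspace(0.0, 40.0, 400)
        curve = fm.force_profile(grid, LIVER_MU, 90.0)
        assert curve.force[-1] == pytest.approx(
            fm.total_force(40.0, LIVER_MU, 90.0).total, rel=1e-12)

    def test_profile_nondecreasing(self):
        grid = np.linspace(0.0, 40.0, 2000)
        curve = fm.force_profile(grid, LIVER_MU, 90.0)
        assert np.all(np.diff(curve.force) >= 0.0)

    def test_unsorted_grid_rejected(self):
        with pytest.raises(DomainError):
            fm.force_profile([0.0, 2.0, 1.0], LIVER_MU)

    def test_metadata_records_parameters(self):
        curve = fm.force_profile([0.0, 1.0], LIVER_MU, 45.0)
        assert curve.meta["param_f_max"] == LIVER_MU.f_max
        assert curve.meta["theta_deg"] == 45.0
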