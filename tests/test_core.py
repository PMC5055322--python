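"""Core model: equilibrium, activation, ODE integration, ladder oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import hill_closed_form, rk4_total_tension
from mechchem import (
    ModelParams,
    SarcomereGeometry,
    activation_fraction,
    ca_tension_curve,
    discrete_ladder,
    equilibrium_constant,
    integrate_tension,
    total_tension,
)

P185 = ModelParams(c_f=1.85, c_s=9.27, k_tnca0=10.09)  # published, SL=1.85
P205 = ModelParams(c_f=1.97, c_s=7.32, k_tnca0=8.63)  # published, SL=2.05


class TestEquilibriumConstant:
    def test_zero_tension_returns_k0(self):
        p = ModelParams(c_f=1.0, c_s=5.0, k_tnca0=10.0)
        assert equilibrium_constant(p, 0.0) == pytest.approx(10.0)

    def test_scalar_evaluation(self):
        assert equilibrium_constant(P185, 0.1) == pytest.approx(
            10.09 * np.exp(-0.927), rel=1e-12
        )

    def test_decoupled_when_cs_zero(self):
        p = ModelParams(c_f=1.0, c_s=0.0, k_tnca0=7.0)
        s = np.linspace(0, 2, 5)
        assert np.allclose(equilibrium_constant(p, s), 7.0)

    def test_strictly_decreasing_in_tension(self):
        s = np.linspace(0, 2, 50)
        k = equilibrium_constant(P185, s)
        assert np.all(np.diff(k) < 0)

    def test_negative_tension_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_constant(P185, -0.1)


class TestActivationFraction:
    def test_half_activation_at_k0_without_tension(self):
        p = ModelParams(c_f=1.0, c_s=4.0, k_tnca0=8.0)
        assert activation_fraction(p, ca=8.0, s=0.0) == pytest.approx(0.5)

    def test_zero_tension_closed_form(self):
        p = ModelParams(c_f=1.0, c_s=4.0, k_tnca0=8.0, n=3)
        for ca in (0.5, 2.0, 8.0, 20.0):
            assert activation_fraction(p, ca, 0.0) == pytest.approx(
                1.0 / (1.0 + (8.0 / ca) ** 3), rel=1e-12
            )

    def test_saturation_limits(self):
        assert activation_fraction(P185, 1e9, 0.0) == pytest.approx(1.0, abs=1e-9)
        assert activation_fraction(P185, 1e-9, 0.0) == pytest.approx(0.0, abs=1e-9)

    def test_extreme_arguments_do_not_overflow(self):
        p = ModelParams(c_f=1.0, c_s=100.0, k_tnca0=1.0, n=10)
        assert activation_fraction(p, 1e-300, 0.0) == 0.0
        assert activation_fraction(p, 1e6, 50.0) == 1.0

    @settings(max_examples=60, derandomize=True)
    @given(
        ca=st.floats(0.01, 100.0),
        s=st.floats(0.0, 2.0),
        n=st.floats(1.0, 8.0),
    )
    def test_bounds_and_monotonicity(self, ca, s, n):
        p = ModelParams(c_f=1.0, c_s=5.0, k_tnca0=8.0, n=n)
        v = activation_fraction(p, ca, s)
        assert 0.0 <= v <= 1.0
        assert activation_fraction(p, ca * 1.5, s) >= v  # increasing in ca
        assert activation_fraction(p, ca, s + 0.1) >= v  # increasing in s

    def test_steeper_in_ca_for_larger_n(self):
        lo = ModelParams(c_f=1.0, c_s=0.0, k_tnca0=8.0, n=2)
        hi = ModelParams(c_f=1.0, c_s=0.0, k_tnca0=8.0, n=6)
        # steepness at the midpoint: finite difference around ca = k0
        d_lo = activation_fraction(lo, 8.8, 0.0) - activation_fraction(lo, 7.2, 0.0)
        d_hi = activation_fraction(hi, 8.8, 0.0) - activation_fraction(hi, 7.2, 0.0)
        assert d_hi > d_lo

    def test_nonpositive_calcium_rejected(self):
        with pytest.raises(ValueError):
            activation_fraction(P185, 0.0, 0.0)


class TestIntegrateTension:
    def test_decoupled_model_is_exactly_linear(self):
        p = ModelParams(c_f=2.0, c_s=0.0, k_tnca0=4.0, n=3)
        prof = integrate_tension(p, ca=4.0, x_max=0.6)
        expected = hill_closed_form(2.0, 4.0, 3, 4.0, 1.0) * prof.x
        assert np.allclose(prof.s, expected, rtol=1e-8, atol=1e-12)

    def test_profile_invariants(self):
        prof = integrate_tension(P205, ca=5.0, x_max=0.65)
        assert prof.s[0] == 0.0
        assert np.all(np.diff(prof.s) >= 0)
        assert np.all((prof.p >= 0) & (prof.p <= 1))
        dx = np.diff(prof.x)
        assert np.all(np.diff(prof.s) <= P205.c_f * dx * (1 + 1e-9))

    def test_activation_plateaus_before_overlap_end(self):
        # at mid-protocol calcium the activation saturates along the filament
        prof = integrate_tension(P205, ca=5.0, x_max=0.65)
        assert prof.p[0] < 0.5
        assert prof.p[-1] > 0.99
        # tension becomes affine (slope ~ c_f) once P has saturated
        tail = np.diff(prof.s[-50:]) / np.diff(prof.x[-50:])
        assert np.allclose(tail, P205.c_f, rtol=1e-2)

    def test_matches_fixed_step_rk4(self, oracle_combos):
        for params, ca, x_max in oracle_combos[:5]:
            ode = total_tension(params, ca, x_max)
            ref = rk4_total_tension(params, ca, x_max, dx=1e-4)
            assert ode == pytest.approx(ref, rel=1e-5)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            integrate_tension(P205, ca=5.0, x_max=0.0)
        with pytest.raises(ValueError):
            integrate_tension(P205, ca=-1.0, x_max=0.5)


class TestTotalTension:
    def test_half_activation_linear_case(self):
        p = ModelParams(c_f=1.85, c_s=0.0, k_tnca0=4.0, n=3)
        # at ca = k0 half of the troponins are active, profile is linear
        assert total_tension(p, ca=4.0, geom=0.55) == pytest.approx(
            1.85 * 0.55 / 2, rel=1e-8
        )

    def test_vanishes_at_low_calcium(self):
        assert total_tension(P185, ca=1e-3, geom=0.55) == pytest.approx(0.0, abs=1e-9)

    def test_accepts_geometry_object(self):
        g = SarcomereGeometry(sl=1.85)
        assert total_tension(P185, 5.0, g) == pytest.approx(
            total_tension(P185, 5.0, g.x_max)
        )

    @pytest.mark.parametrize("bump", ["ca", "x_max", "c_f", "c_s"])
    def test_monotone_in_each_argument(self, bump):
        base = dict(c_f=1.9, c_s=6.0, k_tnca0=8.0, ca=4.0, x_max=0.6)
        t0 = total_tension(
            ModelParams(base["c_f"], base["c_s"], base["k_tnca0"]),
            base["ca"], base["x_max"],
        )
        hi = dict(base)
        hi[bump] *= 1.2
        t1 = total_tension(
            ModelParams(hi["c_f"], hi["c_s"], hi["k_tnca0"]), hi["ca"], hi["x_max"]
        )
        assert t1 >= t0 - 1e-12


class TestDiscreteLadder:
    def test_single_site_step(self):
        p = ModelParams(c_f=2.0, c_s=5.0, k_tnca0=8.0)
        prof = discrete_ladder(p, ca=8.0, x_max=0.5, n_sites=1)
        # the one site sees zero accumulated tension: F = c_f * dx * P(0)
        assert prof.s[-1] == pytest.approx(2.0 * 0.5 * 0.5)

    def test_staircase_monotone(self):
        prof = discrete_ladder(P205, ca=4.0, x_max=0.65, n_sites=64)
        assert prof.s[0] == 0.0
        assert np.all(np.diff(prof.s) >= 0)

    def test_first_order_convergence_to_ode(self):
        ode = total_tension(P205, ca=4.0, geom=0.65)
        errors = []
        for n_sites in (32, 64, 128, 256, 512, 1024, 2048, 4096):
            lad = discrete_ladder(P205, ca=4.0, x_max=0.65, n_sites=n_sites)
            errors.append(abs(lad.s[-1] - ode))
        errors = np.array(errors)
        assert np.all(np.diff(errors) < 0)  # shrinks monotonically
        rates = errors[:-1] / errors[1:]  # ~2 per doubling for first order
        assert np.all(rates > 1.5) and np.all(rates < 3.0)


class TestCaTensionCurve:
    def test_decoupled_curve_is_hill(self):
        p = ModelParams(c_f=1.9, c_s=0.0, k_tnca0=5.0, n=3)
        curve = ca_tension_curve(p, 0.6)
        expected = hill_closed_form(1.9, 5.0, 3, curve.ca, 0.6)
        assert np.allclose(curve.tension, expected, rtol=1e-8)

    def test_invariants_and_shape(self):
        g = SarcomereGeometry(sl=1.85)
        curve = ca_tension_curve(P185, g)
        assert np.all(np.diff(curve.tension) >= -1e-12)
        assert curve.peak_tension < P185.c_f * g.x_max
        assert curve.sl == 1.85

    def test_linearity_in_cf_when_decoupled(self):
        a = ca_tension_curve(ModelParams(1.0, 0.0, 5.0), 0.6)
        b = ca_tension_curve(ModelParams(2.0, 0.0, 5.0), 0.6)
        assert np.allclose(b.tension, 2 * a.tension, rtol=1e-9)

    def test_bad_grids_rejected(self):
        with pytest.raises(ValueError):
            ca_tension_curve(P185, 0.55, [1.0, 0.5, 2.0])  # not ascending
        with pytest.raises(ValueError):
            ca_tension_curve(P185, 0.55, [-1.0, 1.0])

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ModelParams(c_f=-1.0, c_s=1.0, k_tnca0=1.0)
        with pytest.raises(ValueError):
            ModelParams(c_f=1.0, c_s=-0.1, k_tnca0=1.0)
        with pytest.raises(ValueError):
            ModelParams(c_f=1.0, c_s=1.0, k_tnca0=1.0, n=0.5)
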