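"""Closed-form release model: boundary/initial conditions, limits, quadrature."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from relkin.errors import DomainError, NoFiniteAdvectiveTimescale, ValidationError
from relkin.model import (
    ReleaseCurve,
    SpaceTimePoint,
    TransportParams,
    characteristic_time,
    cumulative_release,
    cumulative_release_exact,
    density_profile,
    greens_convolution_density,
    initial_condition_extended,
    release_rate,
    release_rate_short_time,
    transform_to_physical,
)

PARAM_SWEEP = [
    TransportParams(V=v, D=d)
    for v in (0.0, 0.5, 2.0)
    for d in (0.25, 1.0)
]


class TestTransportParams:
    @pytest.mark.parametrize("kwargs", [
        {"V": -0.1, "D": 1.0}, {"V": 1.0, "D": 0.0}, {"V": 1.0, "D": 1.0, "rho0": 0.0},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            TransportParams(**kwargs)

    def test_evaluation_at_t_zero_is_a_domain_error(self):
        with pytest.raises(DomainError):
            SpaceTimePoint(z=1.0, t=0.0)


class TestCharacteristicTime:
    @pytest.mark.parametrize("V,D,expected", [(2.0, 1.0, 1.0), (1.0, 0.25, 1.0)])
    def test_crossover_formula(self, V, D, expected):
        assert characteristic_time(TransportParams(V=V, D=D)) == pytest.approx(expected)

    def test_pure_diffusion_has_no_finite_time_scale(self):
        with pytest.raises(NoFiniteAdvectiveTimescale):
            characteristic_time(TransportParams(V=0.0, D=1.0))


class TestInitialCondition:
    def test_vanishes_at_origin(self, drift_params):
        assert initial_condition_extended(0.0, drift_params) == 0.0

    @pytest.mark.parametrize("z", [0.3, 1.0, 4.2])
    def test_odd_extension(self, z, drift_params):
        n_pos = initial_condition_extended(z, drift_params)
        n_neg = initial_condition_extended(-z, drift_params)
        assert n_pos == pytest.approx(-n_neg)

    @pytest.mark.parametrize("params", PARAM_SWEEP)
    @pytest.mark.parametrize("z", [0.1, 1.0, 3.0])
    def test_physical_initial_density_is_rho0(self, params, z):
        # undoing the exponential substitution at t=0 must give back rho0
        n0 = initial_condition_extended(z, params)
        assert transform_to_physical(n0, z, 0.0, params) == pytest.approx(params.rho0)


class TestGreensConvolution:
    def test_zero_on_the_boundary(self, drift_params):
        val = greens_convolution_density(SpaceTimePoint(0.0, 0.7), drift_params,
                                         quad_tol=1e-10)
        assert abs(val) < 1e-10

    def test_pure_diffusion_reduces_to_erf(self):
        val = greens_convolution_density(SpaceTimePoint(1.0, 0.25), TransportParams(0.0, 1.0))
        assert val == pytest.approx(math.erf(1.0), abs=1e-8)

    @pytest.mark.parametrize("params", PARAM_SWEEP)
    def test_matches_closed_form_after_transform(self, params):
        quad_tol = 1e-9
        for z in (0.2, 1.0, 2.5):
            for t in (0.1, 0.6, 1.5):
                n = greens_convolution_density(SpaceTimePoint(z, t), params, quad_tol)
                rho = transform_to_physical(n, z, t, params)
                assert rho == pytest.approx(
                    density_profile(SpaceTimePoint(z, t), params), abs=10 * quad_tol
                )


class TestDensityProfile:
    @pytest.mark.parametrize("params", PARAM_SWEEP)
    @pytest.mark.parametrize("t", [0.1, 0.5, 3.0])
    def test_absorbing_boundary(self, params, t):
        assert density_profile(SpaceTimePoint(0.0, t), params) == pytest.approx(0.0, abs=1e-14)

    def test_pure_diffusion_limit_is_erf(self):
        val = density_profile(SpaceTimePoint(1.0, 0.25), TransportParams(0.0, 1.0))
        assert val == pytest.approx(math.erf(1.0), rel=1e-12)

    def test_far_field_undisturbed(self, drift_params):
        assert density_profile(SpaceTimePoint(100.0, 1.0), drift_params) == pytest.approx(
            1.0, abs=1e-9
        )

    @pytest.mark.parametrize("params", PARAM_SWEEP)
    @pytest.mark.parametrize("z", [0.5, 2.0])
    def test_initial_data_recovered_at_small_time(self, params, z):
        assert density_profile(SpaceTimePoint(z, 1e-8), params) == pytest.approx(
            params.rho0, rel=1e-9
        )

    def test_negative_z_rejected(self, drift_params):
        with pytest.raises(DomainError):
            density_profile(SpaceTimePoint(-0.5, 1.0), drift_params)

    @pytest.mark.parametrize("params", [TransportParams(0.5, 1.0), TransportParams(2.0, 0.25)])
    def test_satisfies_the_transport_pde(self, params):
        # centred finite differences of the closed form, h = 1e-4
        h = 1e-4

        def f(z, t):
            return density_profile(SpaceTimePoint(z, t), params)

        for z in (0.3, 1.0, 2.5):
            for t in (0.2, 1.0, 3.0):
                dt = (f(z, t + h) - f(z, t - h)) / (2 * h)
                dz = (f(z + h, t) - f(z - h, t)) / (2 * h)
                dzz = (f(z + h, t) - 2 * f(z, t) + f(z - h, t)) / h**2
                assert abs(dt - params.D * dzz - params.V * dz) < 1e-4


class TestReleaseRate:
    def test_pure_diffusion_value(self):
        assert release_rate(1.0, TransportParams(0.0, math.pi)) == pytest.approx(1.0)

    def test_long_time_asymptote(self):
        params = TransportParams(V=2.0, D=1.0)
        assert release_rate(1e6, params) == pytest.approx(2.0, rel=1e-6)

    def test_strictly_decreasing_to_the_drift_asymptote(self, drift_params):
        t = np.linspace(0.01, 50.0, 400)
        rate = release_rate(t, drift_params)
        assert np.all(np.diff(rate) < 0)
        assert np.all(rate > drift_params.rho0 * drift_params.V)

    def test_t_nonpositive_rejected(self, drift_params):
        with pytest.raises(DomainError):
            release_rate(0.0, drift_params)


class TestShortTimeLimit:
    def test_equals_full_rate_at_zero_drift(self):
        params = TransportParams(0.0, math.pi)
        assert release_rate_short_time(1.0, params) == pytest.approx(
            release_rate(1.0, params)
        )

    def test_agrees_with_full_rate_well_below_crossover(self, drift_params):
        t = 1e-4 * characteristic_time(drift_params)
        full = release_rate(t, drift_params)
        approx = release_rate_short_time(t, drift_params)
        assert abs(full - approx) / full < 1e-3

    def test_diverges_at_small_time(self):
        assert release_rate_short_time(1e-8, TransportParams(2.0, 1.0)) >= 1e3


class TestCumulativeRelease:
    def test_vanishes_at_small_time(self, drift_params):
        curve = cumulative_release(np.array([1e-10]), drift_params)
        assert curve.cumulative[0] == pytest.approx(0.0, abs=1e-4)

    def test_zero_drift_closed_form(self):
        params = TransportParams(0.0, 0.7, rho0=1.3)
        t = np.array([0.3, 1.0, 4.0])
        curve = cumulative_release(t, params, amplitude=2.0)
        expected = 2.0 * params.rho0 * 2.0 * np.sqrt(params.D * t / np.pi)
        np.testing.assert_allclose(curve.cumulative, expected, rtol=1e-9)

    def test_matches_brute_force_graded_trapezoid(self, drift_params):
        # oracle: trapezoid on a 10^6-point grid graded as t = u^2
        u = np.linspace(0.0, 1.0, 1_000_001)
        integrand = np.zeros_like(u)
        integrand[1:] = 2.0 * u[1:] * release_rate(u[1:] ** 2, drift_params)
        oracle = np.trapezoid(integrand, u)
        curve = cumulative_release(np.array([1.0]), drift_params)
        assert curve.cumulative[-1] == pytest.approx(oracle, abs=1e-4)

    def test_quadrature_agrees_with_exact_antiderivative(self):
        t = np.array([0.2, 0.9, 2.5, 8.0])
        for params in PARAM_SWEEP:
            curve = cumulative_release(t, params, amplitude=3.0)
            np.testing.assert_allclose(
                curve.cumulative, cumulative_release_exact(t, params, 3.0), rtol=1e-8
            )

    def test_non_monotone_grid_rejected(self, drift_params):
        with pytest.raises(ValidationError):
            cumulative_release(np.array([1.0, 0.5]), drift_params)

    def test_release_curve_invariants_enforced(self):
        with pytest.raises(ValidationError):
            ReleaseCurve(np.array([1.0, 2.0]), np.array([1.0, -0.1]), np.array([0.0, 1.0]))
        with pytest.raises(ValidationError):
            ReleaseCurve(np.array([1.0, 2.0]), np.array([1.0, 0.5]), np.array([1.0, 0.5]))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    v=st.floats(0.0, 5.0),
    d=st.floats(0.05, 5.0),
    t=st.floats(1e-3, 50.0),
)
def test_release_rate_exceeds_its_asymptote_everywhere(v, d, t):
    params = TransportParams(V=v, D=d)
    rate = release_rate(t, params)
    assert rate >= params.rho0 * v
    if v**2 * t / (4 * d) < 20:  # beyond this, erf saturates in floating point
        assert rate > params.rho0 * v
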