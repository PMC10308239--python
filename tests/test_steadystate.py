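"""Flux-balance steady state: closed form vs ODE oracle, limits, properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastidflux.steadystate import (
    KineticParams,
    fixation_rate,
    integrate_dynamics,
    solve_steady_state,
    steady_state_co2_p,
    vcfix_high_uptake_limit,
    vcfix_low_uptake_limit,
)

params_st = st.builds(
    KineticParams,
    Vmax=st.floats(1e-3, 1e5),
    D=st.floats(1e-2, 1e2),
    K=st.floats(1.0, 200.0),
)
co2m_st = st.floats(0.0, 1000.0)


class TestFixationRate:
    def test_half_saturation_and_zero(self):
        p = KineticParams(Vmax=1.0, D=1.0, K=44.0)
        assert fixation_rate(44.0, p) == pytest.approx(0.5)
        assert fixation_rate(0.0, p) == 0.0
        assert fixation_rate(16.93, p) == pytest.approx(0.2778, abs=1e-3)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="CO2_p"):
            fixation_rate(-1.0, KineticParams(Vmax=1.0))


class TestQuadraticRoot:
    def test_no_fixation_equilibrates_with_middle_space(self):
        p = KineticParams(Vmax=0.0, D=1.0, K=44.0)
        assert steady_state_co2_p(123.4, p) == pytest.approx(123.4)

    def test_hand_computed_root(self):
        # b = 44 + 44 - 64.59 = 23.41; root = (-b + sqrt(b^2 + 4*44*64.59))/2
        p = KineticParams.from_ratio(44.0, K=44.0)
        assert steady_state_co2_p(64.59, p) == pytest.approx(42.88, abs=0.05)

    def test_strong_uptake_drains_plastid(self):
        p = KineticParams.from_ratio(1e6, K=44.0)
        assert steady_state_co2_p(100.0, p) < 0.01

    def test_d_zero_degenerate_cases(self):
        assert steady_state_co2_p(50.0, KineticParams(Vmax=1.0, D=0.0)) == 0.0
        assert steady_state_co2_p(50.0, KineticParams(Vmax=0.0, D=0.0)) == 50.0

    @settings(deadline=None)
    @given(co2m_st, params_st)
    def test_root_bounds_residual_and_rejected_root(self, co2_m, params):
        x = steady_state_co2_p(co2_m, params)
        assert 0.0 <= x <= co2_m + 1e-9 * max(1.0, co2_m)
        b = params.ratio + params.K - co2_m
        residual = x * x + b * x - params.K * co2_m
        assert abs(residual) <= 1e-9 * max(1.0, co2_m * co2_m)
        if co2_m > 0:
            other = -b - math.sqrt(b * b + 4 * params.K * co2_m)
            assert other < 0  # the companion root is never physical

    @given(co2m_st, st.floats(1e-3, 1e5), st.floats(1.0, 200.0))
    def test_ratio_and_explicit_parametrization_agree(self, co2_m, ratio, K):
        by_ratio = steady_state_co2_p(co2_m, KineticParams.from_ratio(ratio, K=K))
        explicit = steady_state_co2_p(co2_m, KineticParams(Vmax=3.7 * ratio, D=3.7, K=K))
        assert by_ratio == pytest.approx(explicit, rel=1e-12, abs=1e-300)


class TestSolveSteadyState:
    def test_flux_balance_example(self):
        ss = solve_steady_state(64.59, KineticParams(Vmax=44.0, D=1.0, K=44.0))
        assert ss.VCfix == pytest.approx(21.72, abs=0.05)
        assert ss.VCfix == pytest.approx(1.0 * (64.59 - ss.CO2_p), rel=1e-9)

    def test_empty_middle_space(self):
        ss = solve_steady_state(0.0, KineticParams(Vmax=2.0, D=1.0))
        assert ss.CO2_p == 0.0 and ss.VCfix == 0.0

    @settings(deadline=None, max_examples=1000)
    @given(co2m_st, params_st)
    def test_flux_balance_identity(self, co2_m, params):
        ss = solve_steady_state(co2_m, params)
        assert ss.VCfix == pytest.approx(ss.diffusive_flux, rel=1e-9, abs=1e-9)

    @settings(deadline=None)
    @given(co2m_st.filter(lambda c: c > 0), params_st)
    def test_rate_sandwiched_by_asymptotic_limits(self, co2_m, params):
        ss = solve_steady_state(co2_m, params)
        low_cap = vcfix_low_uptake_limit(co2_m, params)  # MM rate at CO2_p <= CO2_m
        high_cap = vcfix_high_uptake_limit(co2_m, params)  # pure diffusive ceiling
        assert ss.VCfix <= min(low_cap, high_cap) * (1 + 1e-9)

    @settings(deadline=None)
    @given(co2m_st.filter(lambda c: c > 1.0), params_st)
    def test_monotonicity(self, co2_m, params):
        ss = solve_steady_state(co2_m, params)
        # more substrate, more capacity, faster diffusion -> faster fixation
        assert solve_steady_state(co2_m * 1.5, params).VCfix >= ss.VCfix - 1e-12
        bigger_v = KineticParams(Vmax=params.Vmax * 2, D=params.D, K=params.K)
        assert solve_steady_state(co2_m, bigger_v).VCfix >= ss.VCfix - 1e-12
        assert solve_steady_state(co2_m, bigger_v).CO2_p <= ss.CO2_p + 1e-12
        bigger_d = KineticParams(Vmax=params.Vmax, D=params.D * 2, K=params.K)
        assert solve_steady_state(co2_m, bigger_d).VCfix >= ss.VCfix - 1e-12
        bigger_k = KineticParams(Vmax=params.Vmax, D=params.D, K=params.K * 2)
        assert solve_steady_state(co2_m, bigger_k).VCfix <= ss.VCfix + 1e-12


class TestAsymptoticLimits:
    def test_closed_forms(self):
        p = KineticParams(Vmax=2.0, D=1.0, K=44.0)
        assert vcfix_low_uptake_limit(44.0, p) == pytest.approx(1.0)
        assert vcfix_low_uptake_limit(16.93, KineticParams(Vmax=1.0, K=44.0)) == pytest.approx(
            0.2778, abs=1e-3
        )
        assert vcfix_high_uptake_limit(0.0, p) == 0.0
        assert vcfix_high_uptake_limit(64.59, KineticParams(Vmax=5.0, D=1.0)) == pytest.approx(64.59)

    @pytest.mark.parametrize("co2_m", [5.0, 64.59, 500.0])
    def test_steady_state_converges_to_limits(self, co2_m):
        K = 44.0
        weak = KineticParams.from_ratio(1e-6 * K, K=K)
        assert solve_steady_state(co2_m, weak).VCfix == pytest.approx(
            vcfix_low_uptake_limit(co2_m, weak), rel=1e-4
        )
        strong = KineticParams.from_ratio(1e6 * K, K=K)
        assert solve_steady_state(co2_m, strong).VCfix == pytest.approx(
            vcfix_high_uptake_limit(co2_m, strong), rel=1e-3
        )


class TestOdeOracle:
    def test_pure_relaxation(self):
        traj = integrate_dynamics(0.0, 80.0, KineticParams(Vmax=0.0, D=1.0), t_end=60.0)
        assert traj.converged
        assert traj.CO2_p_t[-1] == pytest.approx(80.0, rel=1e-8)

    def test_fixed_point_is_stationary(self):
        p = KineticParams(Vmax=30.0, D=1.0, K=44.0)
        x_star = steady_state_co2_p(64.59, p)
        traj = integrate_dynamics(x_star, 64.59, p, t_end=10.0)
        assert np.allclose(traj.CO2_p_t, x_star, rtol=1e-7)

    def test_nonconvergence_is_flagged(self):
        traj = integrate_dynamics(0.0, 80.0, KineticParams(Vmax=0.0, D=1.0), t_end=1e-3)
        assert not traj.converged

    def test_terminal_state_matches_quadratic_root(self):
        # randomized draws spanning uptake- to diffusion-limited regimes
        rng = np.random.default_rng(20251001)
        for _ in range(100):
            ratio = 10.0 ** rng.uniform(-3, 5)
            K = rng.uniform(5.0, 200.0)
            co2_m = rng.uniform(1.0, 900.0)
            params = KineticParams.from_ratio(ratio, K=K)
            x_star = steady_state_co2_p(co2_m, params)
            for x0 in (0.0, 2.0 * co2_m):
                traj = integrate_dynamics(x0, co2_m, params, t_end=200.0)
                assert traj.converged, (ratio, K, co2_m, x0)
                assert traj.CO2_p_t[-1] == pytest.approx(x_star, rel=1e-6, abs=1e-9)
            # approach is one-sided: no overshoot of the fixed point
            from_below = integrate_dynamics(0.0, co2_m, params, t_end=200.0)
            assert np.all(np.diff(from_below.CO2_p_t) >= -1e-7 * max(1.0, x_star))
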