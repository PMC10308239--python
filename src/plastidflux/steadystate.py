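"""Steady-state balance of CO2 diffusion into the plastid against fixation.

The plastid CO2 pool obeys

    d[CO2]_p/dt = D*([CO2]_m - [CO2]_p) - Vcfix,
    Vcfix = Vmax*[CO2]_p / ([CO2]_p + K),

i.e. passive diffusion across the inner membranes from the middle space,
drained by Michaelis-Menten carbon fixation.  Setting the derivative to
zero gives a quadratic in [CO2]_p,

    x^2 + (Vmax/D + K - [CO2]_m)*x - K*[CO2]_m = 0,

whose unique non-negative root is the steady state.  Only the ratio
Vmax/D (a concentration, umol L-1) matters for the steady state; the time
unit is arbitrary.  Two asymptotic regimes bracket the fixation rate:
uptake-limited (Vmax << D, [CO2]_p ~ [CO2]_m) and diffusion-limited
(Vmax >> D, Vcfix ~ D*[CO2]_m).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "KineticParams",
    "SteadyState",
    "Trajectory",
    "fixation_rate",
    "steady_state_co2_p",
    "solve_steady_state",
    "vcfix_low_uptake_limit",
    "vcfix_high_uptake_limit",
    "integrate_dynamics",
]

#: Default half-saturation constant of carbon fixation, umol L-1.
DEFAULT_K_HALF = 44.0


@dataclass(frozen=True)
class KineticParams:
    """Transport and fixation kinetics.

    Parameters
    ----------
    Vmax : float
        Maximum CO2 fixation rate, umol L-1 time-1.
    D : float
        Diffusion coefficient across the membranes separating the middle
        space from the plastid stroma, time-1.
    K : float
        Half-saturation constant of fixation, umol L-1 (default 44).

    The ratio Vmax/D has concentration units and fully determines the
    steady state; ``KineticParams.from_ratio`` builds parameters with D
    normalized to 1.
    """

    Vmax: float
    D: float = 1.0
    K: float = DEFAULT_K_HALF

    def __post_init__(self) -> None:
        for name in ("Vmax", "D", "K"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be non-negative and finite, got {v!r}")
        if self.K <= 0:
            raise ValueError(f"K must be positive, got {self.K!r}")

    @classmethod
    def from_ratio(cls, vmax_over_d: float, K: float = DEFAULT_K_HALF) -> "KineticParams":
        """Parameters with the given Vmax/D ratio and D normalized to 1."""
        return cls(Vmax=vmax_over_d, D=1.0, K=K)

    @property
    def ratio(self) -> float:
        """Vmax/D, umol L-1 (inf if D == 0 and Vmax > 0)."""
        if self.D == 0:
            return math.inf if self.Vmax > 0 else 0.0
        return self.Vmax / self.D


@dataclass(frozen=True)
class SteadyState:
    """Solution of the flux balance at one (CO2_m, params) point."""

    CO2_p: float  # umol L-1
    VCfix: float  # umol L-1 time-1
    diffusive_flux: float  # umol L-1 time-1, D*(CO2_m - CO2_p)
    residual: float  # quadratic evaluated at CO2_p


@dataclass(frozen=True)
class Trajectory:
    """Time course of the plastid CO2 pool relaxing to steady state."""

    t: np.ndarray
    CO2_p_t: np.ndarray
    converged: bool
    final_derivative: float


def _check_nonneg(value: float, name: str) -> None:
    if not (math.isfinite(value) and value >= 0):
        raise ValueError(f"{name} must be non-negative and finite, got {value!r}")


def fixation_rate(CO2_p: float, params: KineticParams) -> float:
    """Michaelis-Menten fixation rate Vmax*CO2_p/(CO2_p + K)."""
    _check_nonneg(CO2_p, "CO2_p")
    return params.Vmax * CO2_p / (CO2_p + params.K)


def steady_state_co2_p(CO2_m: float, params: KineticParams) -> float:
    """Non-negative root of the steady-state quadratic for plastid CO2.

    With b = Vmax/D + K - CO2_m the root is (-b + sqrt(b^2 + 4*K*CO2_m))/2;
    for b > 0 the algebraically equivalent form 2*K*CO2_m/(b + sqrt(...))
    avoids catastrophic cancellation at large Vmax/D.  The companion root
    is negative whenever CO2_m > 0, so the solution is unique.

    D = 0 is a degenerate, diffusion-free case: fixation drains the pool
    to 0 if Vmax > 0, otherwise the pool equilibrates at CO2_m.
    """
    _check_nonneg(CO2_m, "CO2_m")
    if params.D == 0:
        return 0.0 if params.Vmax > 0 else CO2_m
    K = params.K
    b = params.ratio + K - CO2_m
    disc = math.sqrt(b * b + 4.0 * K * CO2_m)
    if b > 0:
        return 2.0 * K * CO2_m / (b + disc)
    return 0.5 * (-b + disc)


def _quadratic_residual(x: float, CO2_m: float, params: KineticParams) -> float:
    return x * x + (params.ratio + params.K - CO2_m) * x - params.K * CO2_m


def solve_steady_state(CO2_m: float, params: KineticParams) -> SteadyState:
    """Steady-state plastid CO2, fixation rate, and diffusive flux.

    At the fixed point the fixation rate equals the diffusive influx
    D*(CO2_m - CO2_p) exactly (up to roundoff).
    """
    co2_p = steady_state_co2_p(CO2_m, params)
    vcfix = fixation_rate(co2_p, params)
    flux = params.D * (CO2_m - co2_p)
    residual = 0.0 if params.D == 0 else _quadratic_residual(co2_p, CO2_m, params)
    return SteadyState(CO2_p=co2_p, VCfix=vcfix, diffusive_flux=flux, residual=residual)


def vcfix_low_uptake_limit(CO2_m: float, params: KineticParams) -> float:
    """Fixation rate in the uptake-limited regime (Vmax << D).

    Diffusion equilibrates the plastid with the middle space
    (CO2_p ~ CO2_m), so Vcfix ~ Vmax*CO2_m/(CO2_m + K).
    """
    _check_nonneg(CO2_m, "CO2_m")
    return params.Vmax * CO2_m / (CO2_m + params.K)


def vcfix_high_uptake_limit(CO2_m: float, params: KineticParams) -> float:
    """Fixation rate in the diffusion-limited regime (Vmax >> D).

    Fixation consumes CO2 as fast as it arrives (CO2_p ~ 0), so
    Vcfix ~ D*CO2_m.
    """
    _check_nonneg(CO2_m, "CO2_m")
    return params.D * CO2_m


def integrate_dynamics(
    CO2_p0: float,
    CO2_m: float,
    params: KineticParams,
    t_end: float = 1000.0,
    reltol: float = 1e-8,
    n_points: int = 200,
) -> Trajectory:
    """Integrate the plastid CO2 balance ODE as an independent oracle.

    Integrates d[CO2]_p/dt = D*(CO2_m - CO2_p) - Vmax*CO2_p/(CO2_p + K)
    from ``CO2_p0`` with an adaptive implicit scheme (the problem is stiff
    when Vmax/D is large).  Convergence is declared when the terminal
    derivative magnitude drops below reltol * D * max(1, CO2_m); the flag
    is reported, never silently ignored.  The derivative at 0 is
    non-negative for CO2_m >= 0, so positivity is preserved.
    """
    _check_nonneg(CO2_p0, "CO2_p0")
    _check_nonneg(CO2_m, "CO2_m")
    if not (math.isfinite(t_end) and t_end > 0):
        raise ValueError(f"t_end must be positive and finite, got {t_end!r}")

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        x = max(y[0], 0.0)
        return np.array([params.D * (CO2_m - x) - params.Vmax * x / (x + params.K)])

    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [CO2_p0],
        method="Radau",
        t_eval=t_eval,
        rtol=1e-10,
        atol=1e-12,
    )
    traj = np.clip(sol.y[0], 0.0, None)
    final_deriv = float(rhs(sol.t[-1], sol.y[:, -1])[0])
    scale = params.D * max(1.0, CO2_m)
    converged = bool(sol.success) and abs(final_deriv) < reltol * max(scale, 1e-300)
    return Trajectory(
        t=sol.t,
        CO2_p_t=traj,
        converged=converged,
        final_derivative=final_deriv,
    )
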