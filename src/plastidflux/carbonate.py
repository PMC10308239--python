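"""Carbonate chemistry of the plastid middle space.

The middle space — the compartment behind the outermost of the four
membranes surrounding a diatom's complex plastid — holds a pool of
dissolved inorganic carbon (DIC = CO2(aq) + HCO3- + CO3--) whose
speciation is set by the local pH.  A light-driven proton pump on the
outermost membrane can acidify this compartment, shifting the equilibrium
toward CO2(aq), the only species RuBisCO can fix.

This module computes the apparent first and second dissociation constants
of carbonic acid as functions of temperature and salinity, and the
resulting CO2 fraction of DIC at a given pH:

    [CO2] = DIC / (1 + K1/[H+] + K1*K2/[H+]^2)

Units: H+, K1, K2 in mol L-1; DIC and all carbon species in umol L-1.
Only the dimensionless ratios K1/[H+] and K1*K2/[H+]^2 enter the
speciation formula, so DIC units propagate unchanged — do not convert
DIC to mol L-1.  Temperature is absolute (Kelvin); the logarithmic terms
of the pK fits are only valid on that scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "SeawaterConditions",
    "DissociationConstants",
    "MiddleSpaceState",
    "pk1",
    "pk2",
    "dissociation_constants",
    "co2_from_dic",
    "speciation",
    "PK1_COEFFS",
    "PK2_COEFFS",
]

# Coefficients of the apparent-dissociation-constant fits
# pK = a/T + b + c*ln(T) + d*S + e*S^2   (T in Kelvin, S practical salinity)
PK1_COEFFS = (3633.86, -61.2172, 9.6777, -0.011555, 0.0001152)
PK2_COEFFS = (471.78, 25.9290, -3.16967, -0.01781, 0.0001122)

#: Standard-seawater defaults used throughout the package.
DEFAULT_TEMPERATURE_K = 298.15
DEFAULT_SALINITY = 35.0


@dataclass(frozen=True)
class SeawaterConditions:
    """Temperature and salinity driving the carbonic-acid dissociation constants.

    Parameters
    ----------
    T : float
        Absolute temperature in Kelvin. Must be positive and finite.
    S : float
        Practical salinity (dimensionless). Must lie in [0, 50]; values
        outside the typical oceanic range [0, 40] trigger a warning.
    """

    T: float = DEFAULT_TEMPERATURE_K
    S: float = DEFAULT_SALINITY

    def __post_init__(self) -> None:
        if not (math.isfinite(self.T) and self.T > 0):
            raise ValueError(f"temperature must be positive and finite (Kelvin), got {self.T!r}")
        if not (math.isfinite(self.S) and 0 <= self.S <= 50):
            raise ValueError(f"salinity must be finite and within [0, 50], got {self.S!r}")
        if self.S > 40:
            warnings.warn(
                f"salinity {self.S} is outside the typical oceanic range [0, 40]",
                stacklevel=3,
            )


@dataclass(frozen=True)
class DissociationConstants:
    """First and second apparent dissociation constants of carbonic acid."""

    pK1: float
    pK2: float
    K1: float = field(init=False)  # mol L-1
    K2: float = field(init=False)  # mol L-1

    def __post_init__(self) -> None:
        object.__setattr__(self, "K1", 10.0 ** (-self.pK1))
        object.__setattr__(self, "K2", 10.0 ** (-self.pK2))


@dataclass(frozen=True)
class MiddleSpaceState:
    """DIC, pH, and carbonate speciation in the middle space.

    All carbon species in umol L-1; ``H_m`` is 10^-pH in mol L-1.
    """

    DIC_m: float
    pH_m: float
    H_m: float
    CO2_m: float
    HCO3_m: float
    CO3_m: float

    def __post_init__(self) -> None:
        total = self.CO2_m + self.HCO3_m + self.CO3_m
        if self.DIC_m > 0 and abs(total - self.DIC_m) > 1e-10 * self.DIC_m:
            raise ValueError("carbon species do not sum to DIC")


def _eval_pk(coeffs: tuple[float, ...], conditions: SeawaterConditions) -> float:
    a, b, c, d, e = coeffs
    T, S = conditions.T, conditions.S
    return a / T + b + c * math.log(T) + d * S + e * S * S


def pk1(conditions: SeawaterConditions) -> float:
    """First apparent dissociation exponent pK1(T, S) of carbonic acid."""
    return _eval_pk(PK1_COEFFS, conditions)


def pk2(conditions: SeawaterConditions) -> float:
    """Second apparent dissociation exponent pK2(T, S) of carbonic acid."""
    return _eval_pk(PK2_COEFFS, conditions)


def dissociation_constants(conditions: SeawaterConditions) -> DissociationConstants:
    """K1 = 10^-pK1 and K2 = 10^-pK2 at the given temperature and salinity."""
    return DissociationConstants(pK1=pk1(conditions), pK2=pk2(conditions))


def _validate_dic_ph(DIC_m: float, pH_m: float) -> None:
    if not (math.isfinite(DIC_m) and DIC_m >= 0):
        raise ValueError(f"DIC must be non-negative and finite, got {DIC_m!r}")
    if not math.isfinite(pH_m):
        raise ValueError(f"pH must be finite, got {pH_m!r}")


def co2_from_dic(
    DIC_m: float,
    pH_m: float,
    conditions: SeawaterConditions | None = None,
) -> float:
    """CO2(aq) concentration (umol L-1) in a DIC pool at the given pH.

    Evaluates DIC / (1 + K1/H + K1*K2/H^2) with H = 10^-pH mol L-1.
    Strictly decreasing in pH and linear in DIC; bounded by (0, DIC].
    """
    conditions = conditions or SeawaterConditions()
    _validate_dic_ph(DIC_m, pH_m)
    ks = dissociation_constants(conditions)
    H = 10.0 ** (-pH_m)
    return DIC_m / (1.0 + ks.K1 / H + ks.K1 * ks.K2 / (H * H))


def speciation(
    DIC_m: float,
    pH_m: float,
    conditions: SeawaterConditions | None = None,
) -> MiddleSpaceState:
    """Full carbonate speciation of the middle-space DIC pool.

    HCO3- and CO3-- follow from the same equilibria as the CO2 fraction:
    HCO3 = CO2 * K1/H, CO3 = CO2 * K1*K2/H^2, so the three species sum to
    DIC by construction.
    """
    conditions = conditions or SeawaterConditions()
    _validate_dic_ph(DIC_m, pH_m)
    ks = dissociation_constants(conditions)
    H = 10.0 ** (-pH_m)
    r1 = ks.K1 / H
    r2 = ks.K1 * ks.K2 / (H * H)
    co2 = DIC_m / (1.0 + r1 + r2)
    return MiddleSpaceState(
        DIC_m=DIC_m,
        pH_m=pH_m,
        H_m=H,
        CO2_m=co2,
        HCO3_m=co2 * r1,
        CO3_m=co2 * r2,
    )
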