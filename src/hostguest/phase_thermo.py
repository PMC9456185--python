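"""Phase-solubility and Van't Hoff thermodynamics of 1:1 host-guest complexation.

A linear (A_L-type) phase-solubility diagram — dissolved guest concentration
rising linearly with host concentration, slope < 1 — indicates 1:1 inclusion
complexation.  The apparent stability constant follows Higuchi-Connors:

    Kc = slope / (S0 * (1 - slope))

with S0 the intrinsic guest solubility (the diagram's y-intercept).  The
temperature dependence of Kc yields the complexation enthalpy and entropy
through the Van't Hoff relation

    ln Kc = -dH/(R*T) + dS/R

fit by ordinary least squares of ln Kc against 1/T, and the Gibbs energy
dG = dH - T*dS at a reference temperature.

All concentrations are molar (M), temperatures kelvin, and energies kcal/mol
with R = 1.985e-3 kcal mol^-1 K^-1 by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DomainError, InvalidInputError

#: Molar gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.985e-3

#: Default reference temperature (K) for reporting dG.
DEFAULT_REFERENCE_T = 303.0

#: Minimum r-squared for a diagram to be classified A_L-type.
DEFAULT_R2_THRESHOLD = 0.98


def celsius_to_kelvin(t_celsius: float) -> float:
    """Convert Celsius to kelvin using the exact 273.15 offset."""
    return t_celsius + 273.15


@dataclass(frozen=True)
class SolubilityDiagram:
    """Dissolved-guest concentration versus host concentration at one temperature.

    Parameters
    ----------
    host_conc, guest_conc
        Molar concentrations; ``host_conc`` must be strictly increasing.
    temperature
        Kelvin.
    label
        Free-text identity of the host/guest pair.
    """

    host_conc: np.ndarray
    guest_conc: np.ndarray
    temperature: float
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "host_conc", np.asarray(self.host_conc, dtype=float))
        object.__setattr__(self, "guest_conc", np.asarray(self.guest_conc, dtype=float))
        if self.host_conc.ndim != 1 or self.host_conc.shape != self.guest_conc.shape:
            raise InvalidInputError("host_conc and guest_conc must be 1-D and equal length")
        if len(self.host_conc) < 3:
            raise InvalidInputError("a solubility diagram needs at least 3 points")
        if np.any(self.host_conc < 0) or np.any(self.guest_conc < 0):
            raise InvalidInputError("concentrations must be non-negative")
        if np.any(np.diff(self.host_conc) <= 0):
            raise InvalidInputError("host concentrations must be strictly increasing")
        if not self.temperature > 0:
            raise InvalidInputError("temperature must be positive (kelvin)")

    def __len__(self) -> int:
        return len(self.host_conc)


@dataclass(frozen=True)
class PhaseSolubilityFit:
    """OLS line through a solubility diagram and its Higuchi-Connors profile class."""

    slope: float
    intercept_s0: float
    r_squared: float
    profile: str  # "A_L" or "nonlinear"
    temperature: float = DEFAULT_REFERENCE_T
    label: str = ""


@dataclass(frozen=True)
class StabilityConstant:
    """Apparent 1:1 stability constant Kc (M^-1) at one temperature (K)."""

    kc: float
    temperature: float
    label: str = ""

    def __post_init__(self):
        if self.kc < 0:
            raise DomainError("stability constant must be non-negative")
        if not self.temperature > 0:
            raise DomainError("temperature must be positive (kelvin)")


@dataclass(frozen=True)
class VantHoffFit:
    """Enthalpy/entropy of complexation from ln Kc vs 1/T regression.

    ``delta_h`` in kcal/mol, ``delta_s`` in kcal/(mol K).
    """

    delta_h: float
    delta_s: float
    r_squared: float
    n_points: int
    gas_constant: float = GAS_CONSTANT_KCAL

    def __post_init__(self):
        if self.n_points < 2:
            raise InvalidInputError("a Van't Hoff fit needs at least 2 temperatures")
        if not (math.isfinite(self.delta_h) and math.isfinite(self.delta_s)):
            raise DomainError("non-finite thermodynamic parameters")


@dataclass(frozen=True)
class ThermoTable:
    """dH, T*dS and dG bundled at a reference temperature.

    The identity ``delta_g == delta_h - t_delta_s`` holds to machine precision.
    """

    delta_h: float
    t_delta_s: float
    delta_g: float
    reference_t: float
    gas_constant: float = GAS_CONSTANT_KCAL
    label: str = ""


def fit_diagram(
    diagram: SolubilityDiagram,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> PhaseSolubilityFit:
    """Fit an ordinary least-squares line through a phase-solubility diagram.

    The profile is classified ``"A_L"`` when 0 < slope < 1 and the fit is
    sufficiently linear (r^2 >= ``r2_threshold``); otherwise ``"nonlinear"``
    with a warning.  A slope >= 1 makes the Higuchi-Connors denominator
    non-positive, so such diagrams are never classified A_L.
    """
    x = diagram.host_conc
    if np.all(x == x[0]):
        raise InvalidInputError("host concentrations are all equal; cannot fit a line")
    res = stats.linregress(x, diagram.guest_conc)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
    if 0.0 < res.slope < 1.0 and r2 >= r2_threshold:
        profile = "A_L"
    else:
        profile = "nonlinear"
        warnings.warn(
            f"diagram {diagram.label!r} at {diagram.temperature} K is not A_L-type "
            f"(slope={res.slope:.4g}, r2={r2:.4g})",
            stacklevel=2,
        )
    return PhaseSolubilityFit(
        slope=float(res.slope),
        intercept_s0=float(res.intercept),
        r_squared=r2,
        profile=profile,
        temperature=diagram.temperature,
        label=diagram.label,
    )


def stability_constant(fit: PhaseSolubilityFit) -> StabilityConstant:
    """Higuchi-Connors stability constant Kc = slope / (S0 * (1 - slope)).

    Requires 0 <= slope < 1 and S0 > 0 (1:1 complexation regime).
    """
    if not 0.0 <= fit.slope < 1.0:
        raise DomainError(f"slope {fit.slope:.4g} outside [0, 1); Kc undefined for 1:1 model")
    if not fit.intercept_s0 > 0:
        raise DomainError(f"intrinsic solubility S0 must be positive, got {fit.intercept_s0:.4g}")
    kc = fit.slope / (fit.intercept_s0 * (1.0 - fit.slope))
    return StabilityConstant(kc=kc, temperature=fit.temperature, label=fit.label)


def _vant_hoff_regression(series: Sequence[StabilityConstant]):
    if len(series) < 2:
        raise InvalidInputError("Van't Hoff regression needs at least 2 temperatures")
    temps = np.array([s.temperature for s in series], dtype=float)
    kcs = np.array([s.kc for s in series], dtype=float)
    if np.any(kcs <= 0):
        raise DomainError("all stability constants must be positive for ln Kc")
    if len(np.unique(temps)) < 2:
        raise InvalidInputError("Van't Hoff regression needs at least 2 distinct temperatures")
    return stats.linregress(1.0 / temps, np.log(kcs))


def vant_hoff_fit(
    series: Sequence[StabilityConstant],
    gas_constant: float = GAS_CONSTANT_KCAL,
) -> VantHoffFit:
    """OLS of ln Kc against 1/T; dH = -R*slope, dS = R*intercept.

    The intercept of the Van't Hoff line is dS/R — the standard form, and the
    only one consistent with dG = dH - T*dS at the fitted parameters.
    """
    res = _vant_hoff_regression(series)
    return VantHoffFit(
        delta_h=float(-gas_constant * res.slope),
        delta_s=float(gas_constant * res.intercept),
        r_squared=float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0,
        n_points=len(series),
        gas_constant=gas_constant,
    )


def gibbs(fit: VantHoffFit, temperature: float) -> float:
    """Gibbs free energy dG = dH - T*dS (kcal/mol) at ``temperature`` (K)."""
    if not temperature > 0:
        raise DomainError("temperature must be positive (kelvin)")
    return fit.delta_h - temperature * fit.delta_s


def thermo_table(
    series: Sequence[StabilityConstant],
    reference_t: float = DEFAULT_REFERENCE_T,
    gas_constant: float = GAS_CONSTANT_KCAL,
    label: str = "",
) -> ThermoTable:
    """Bundle dH, T*dS and dG from a Kc(T) series at ``reference_t``."""
    fit = vant_hoff_fit(series, gas_constant=gas_constant)
    t_ds = reference_t * fit.delta_s
    return ThermoTable(
        delta_h=fit.delta_h,
        t_delta_s=t_ds,
        delta_g=fit.delta_h - t_ds,
        reference_t=reference_t,
        gas_constant=gas_constant,
        label=label or (series[0].label if series else ""),
    )


def concentration_from_absorbance(
    absorbance: np.ndarray | float,
    calib_slope: float,
    calib_intercept: float = 0.0,
) -> np.ndarray | float:
    """Convert absorbance to molar concentration via a user-supplied linear calibration.

    ``conc = (absorbance - calib_intercept) / calib_slope``.  No extinction
    coefficient is assumed; the calibration must come from the user's standards.
    """
    if calib_slope == 0:
        raise DomainError("calibration slope must be non-zero")
    return (np.asarray(absorbance, dtype=float) - calib_intercept) / calib_slope
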