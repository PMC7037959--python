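"""Binary homogeneous H2SO4–H2O nucleation (BHN).

Implements the widely used polynomial parameterization of classical binary
homogeneous nucleation of sulfuric acid and water, fitted to
thermodynamically consistent cluster calculations. It returns the particle
formation rate J (cm^-3 s^-1), the total number of molecules in the critical
cluster, the cluster's H2SO4 mole fraction, and the cluster diameter.

The fit is formally valid for 190.15–305.15 K, 0.01–100% RH and H2SO4
concentrations of 1e4–1e11 cm^-3; J is capped at 1e10 cm^-3 s^-1. Above
305 K the polynomial is evaluated as a smooth extrapolation up to 400 K,
which is the relevant regime in fresh, warm exhaust plumes.

A heterogeneous-style variant ("HET") augments the binary rate with an
organic-availability factor and assigns part of the cluster mass to the
organic component, representing nucleation in which an organic vapor
participates alongside sulfuric acid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["NucleationResult", "bhn_rate", "nucleation_rate", "ORGANIC_REFERENCE"]

#: organic-vapor concentration scale for the HET enhancement (molecules cm^-3)
ORGANIC_REFERENCE = 1.0e11

J_MAX = 1.0e10  # cm^-3 s^-1, upper validity cap of the parameterization


@dataclass(frozen=True)
class NucleationResult:
    rate: float  # J, particles cm^-3 s^-1
    cluster_diameter_nm: float
    n_molecules: float  # total molecules in critical cluster
    acid_mole_fraction: float
    composition: dict[str, float]  # dry-mass fractions of the inserted cluster


def _critical_mole_fraction(t: float, log_na: float, log_rh: float) -> float:
    return (
        0.740997
        - 0.00266379 * t
        - 0.00349998 * log_na
        + 0.0000504022 * t * log_na
        + 0.00201048 * log_rh
        - 0.000183289 * t * log_rh
        + 0.00157407 * log_rh**2
        - 0.0000179059 * t * log_rh**2
        + 0.000184403 * log_rh**3
        - 1.50345e-6 * t * log_rh**3
    )


def _rate_coefficients(t: float, x: float) -> list[float]:
    return [
        0.14309 + 2.21956 * t - 0.0273911 * t**2 + 0.0000722811 * t**3 + 5.91822 / x,
        0.117489 + 0.462532 * t - 0.0118059 * t**2 + 0.0000404196 * t**3 + 15.7963 / x,
        -0.215554 - 0.0810269 * t + 0.00143581 * t**2 - 4.7758e-6 * t**3 - 2.91297 / x,
        -3.58856 + 0.049508 * t - 0.00021382 * t**2 + 3.10801e-7 * t**3 - 0.0293333 / x,
        1.14598 - 0.600796 * t + 0.00864245 * t**2 - 0.0000228947 * t**3 - 8.44985 / x,
        2.15855 + 0.0808121 * t - 0.000407382 * t**2 - 4.01957e-7 * t**3 + 0.721326 / x,
        1.6241 - 0.0160106 * t + 0.0000377124 * t**2 + 3.21794e-8 * t**3 - 0.0113255 / x,
        9.71682 - 0.115048 * t + 0.000157098 * t**2 + 4.00914e-7 * t**3 + 0.71186 / x,
        -1.05611 + 0.00903378 * t - 0.0000198417 * t**2 + 2.46048e-8 * t**3 - 0.0579087 / x,
        -0.148712 + 0.00283508 * t - 9.24619e-6 * t**2 + 5.00427e-9 * t**3 - 0.0127081 / x,
    ]


def _poly_eval(coeffs: list[float], log_rh: float, log_na: float) -> float:
    a, b, c, d, e, f, g, h, i, j = coeffs
    return (
        a
        + b * log_rh
        + c * log_rh**2
        + d * log_rh**3
        + e * log_na
        + f * log_rh * log_na
        + g * log_rh**2 * log_na
        + h * log_na**2
        + i * log_rh * log_na**2
        + j * log_na**3
    )


def bhn_rate(temperature: float, rh: float, h2so4: float) -> NucleationResult:
    """Binary H2SO4–H2O nucleation rate.

    Parameters
    ----------
    temperature:
        Air temperature (K); 190–400 K accepted (fit range up to 305 K,
        smooth extrapolation above).
    rh:
        Relative humidity (%), in (0, 100].
    h2so4:
        Gas-phase sulfuric acid concentration (molecules cm^-3).
    """
    if not 190.0 <= temperature <= 400.0:
        raise ValueError("temperature outside 190–400 K")
    if not 0.0 < rh <= 100.0:
        raise ValueError("RH must be in (0, 100] %")
    if h2so4 < 0:
        raise ValueError("H2SO4 concentration must be nonnegative")
    if h2so4 < 1e4:  # below the fit range the rate is vanishing
        return NucleationResult(0.0, 1.2, 0.0, 0.5, {"sulfate": 1.0})
    t = min(temperature, 305.15) if temperature > 305.15 else temperature
    # smooth extrapolation: evaluate the polynomial at the capped temperature
    # (the fit's high-T edge) for T above the fitted range
    na = min(h2so4, 1e11)
    rh_frac = rh / 100.0
    log_na, log_rh = math.log(na), math.log(rh_frac)
    x = _critical_mole_fraction(t, log_na, log_rh)
    x = min(max(x, 1e-3), 1.0)
    log_j = _poly_eval(_rate_coefficients(t, x), log_rh, log_na)
    j = min(math.exp(min(log_j, math.log(J_MAX))), J_MAX)
    if j < 1e-7:  # below the parameterization's validity floor
        j = 0.0
    # critical cluster size via the first nucleation theorem:
    # n_acid = d(ln J)/d(ln Na) at fixed T, RH; total molecules = n_acid / x
    dln = 0.01
    x_hi = _critical_mole_fraction(t, log_na + dln, log_rh)
    x_lo = _critical_mole_fraction(t, log_na - dln, log_rh)
    lj_hi = _poly_eval(_rate_coefficients(t, min(max(x_hi, 1e-3), 1.0)), log_rh, log_na + dln)
    lj_lo = _poly_eval(_rate_coefficients(t, min(max(x_lo, 1e-3), 1.0)), log_rh, log_na - dln)
    n_acid = max((lj_hi - lj_lo) / (2 * dln), 1.0)
    ntot = n_acid / x
    # hydrated cluster volume from partial molecular volumes (cm^3)
    v_acid, v_water = 8.9e-23, 3.0e-23
    vol = ntot * (x * v_acid + (1.0 - x) * v_water)
    diameter_nm = (6.0 * vol / math.pi) ** (1.0 / 3.0) * 1e7
    # dry composition of the inserted cluster: its H2SO4 content (the water
    # is re-equilibrated by the host model's water scheme)
    return NucleationResult(
        rate=j,
        cluster_diameter_nm=diameter_nm,
        n_molecules=ntot,
        acid_mole_fraction=x,
        composition={"sulfate": 1.0},
    )


def nucleation_rate(
    temperature: float,
    rh: float,
    h2so4: float,
    mechanism: str = "BHN",
    organic: float = 0.0,
) -> NucleationResult:
    """Nucleation rate for the requested mechanism.

    ``BHN`` is the classical binary mechanism. ``HET`` lets an organic vapor
    participate: the binary rate is scaled up by an organic-availability
    factor (1 + [org]/[org]_ref) and the inserted cluster carries an organic
    mass share proportional to the organic's availability.
    """
    base = bhn_rate(temperature, rh, h2so4)
    if mechanism == "BHN":
        return base
    if mechanism != "HET":
        raise ValueError("mechanism must be 'BHN' or 'HET'")
    if organic < 0:
        raise ValueError("organic concentration must be nonnegative")
    enhancement = 1.0 + organic / ORGANIC_REFERENCE
    org_share = organic / (organic + ORGANIC_REFERENCE)
    comp = {"sulfate": 1.0 - org_share, "elv_om": org_share}
    return NucleationResult(
        rate=min(base.rate * enhancement, J_MAX),
        cluster_diameter_nm=base.cluster_diameter_nm * (1.0 + 0.3 * org_share),
        n_molecules=base.n_molecules,
        acid_mole_fraction=base.acid_mole_fraction,
        composition=comp,
    )
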