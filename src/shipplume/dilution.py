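"""Two-stage dilution model for a ship exhaust plume.

Stage 1 (0–1 s): jet expansion of the stack exhaust. The plume cross-section
grows from the funnel area S0 under the combined action of ambient turbulence
and the jet's own entrainment,

    S(t) = (sqrt(S0) + t * sigma_w)^2 - (t * alpha * V_S)^2,
    sigma_w^2 = (alpha*U)^2 + sigma_wt^2 + (alpha*u_jet)^2,

giving a first-stage dilution ratio DR = S(1 s)/S0 (≈ 8 for typical ROPAX
stack parameters and harbor winds). The in-plume temperature at the end of
the stage follows T_P = T_A + (T_E - T_A)/DR.

Stage 2 (t > 1 s): atmospheric turbulence dominates and the centerline
concentration of an inert tracer decays as a power law y(x) = a * x**-b.
The corresponding mixing tendency applied to every plume scalar is

    dN/dt = -(b/t) * (N - N_background),

and the plume's vertical extent grows as
H_P(t) = sqrt(H_P0^2 + (a' * (1e-3 * U * t)**b)^2), with a' set by the
atmospheric stability class.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "StackSpec",
    "DilutionParams",
    "GridConvergence",
    "SIGMA_Z_SCALE",
    "entrainment_velocity",
    "plume_cross_section",
    "first_stage_dilution_ratio",
    "initial_plume_temperature",
    "coagulation_fraction_remaining",
    "fit_power_law",
    "plume_height",
    "dilution_tendency",
    "grid_convergence_index",
]

#: vertical-dispersion scale a' (m per km^b) by stability class
SIGMA_Z_SCALE: dict[str, float] = {"unstable": 110.62, "neutral": 86.49, "stable": 61.14}


@dataclass(frozen=True)
class StackSpec:
    """Ship funnel/exhaust parameters.

    Defaults represent a large ROPAX ferry: exhaust-pipe cross-section
    0.55 m^2 (diameter ~0.84 m), exit velocity 25 m s^-1, exhaust
    temperature 580 K.
    """

    cross_section: float = 0.55  # S0, m^2
    exhaust_velocity: float = 25.0  # V_S, m s^-1
    exhaust_temperature: float = 580.0  # T_E, K

    def __post_init__(self) -> None:
        if self.cross_section <= 0:
            raise ValueError("stack cross-section must be positive")
        if self.exhaust_velocity < 0:
            raise ValueError("exhaust velocity must be nonnegative")


@dataclass(frozen=True)
class DilutionParams:
    """Parameters of the two-stage dilution model."""

    dr: float = 8.0  # first-stage dilution ratio
    a: float = 5000.0  # power-law scale (concentration units)
    b: float = 1.26  # power-law exponent
    h_p0: float = 5.5  # initial plume height, m
    sigma_z_scale: float = SIGMA_Z_SCALE["neutral"]  # a', m per km^b
    t0: float = 1.0  # reference time, s (end of stage 1)

    def __post_init__(self) -> None:
        if self.dr < 1:
            raise ValueError("DR must be >= 1")
        if self.b <= 0:
            raise ValueError("power-law exponent b must be positive")
        if self.h_p0 <= 0:
            raise ValueError("initial plume height must be positive")
        if not math.isclose(
            self.sigma_z_scale, min(SIGMA_Z_SCALE.values(), key=lambda v: abs(v - self.sigma_z_scale)),
            rel_tol=0, abs_tol=1e-9,
        ) and self.sigma_z_scale not in SIGMA_Z_SCALE.values():
            raise ValueError(f"sigma_z_scale must be one of {sorted(SIGMA_Z_SCALE.values())}")

    @classmethod
    def for_stability(cls, stability: str, **kw) -> "DilutionParams":
        return cls(sigma_z_scale=SIGMA_Z_SCALE[stability], **kw)


@dataclass(frozen=True)
class GridConvergence:
    """Inputs of the grid-convergence-index discretization-error estimate."""

    e21: float  # relative error between the two finest grids
    r21: float  # grid refinement ratio
    p: float  # observed order of convergence
    safety_factor: float = 1.25

    def __post_init__(self) -> None:
        if self.safety_factor < 1:
            raise ValueError("safety factor must be >= 1")
        if self.r21 <= 1:
            raise ValueError("refinement ratio must exceed 1")
        if self.p <= 0:
            raise ValueError("convergence order must be positive")
        if self.e21 < 0:
            raise ValueError("relative error must be nonnegative")


def grid_convergence_index(gc: GridConvergence) -> float:
    """GCI = F_s * e21 / (r21**p - 1)."""
    return gc.safety_factor * gc.e21 / (gc.r21**gc.p - 1.0)


def entrainment_velocity(
    wind_speed: float, u_jet: float, sigma_wt: float = 0.0, alpha: float = 0.1
) -> float:
    """Entrainment velocity sigma_w = sqrt((aU)^2 + sigma_wt^2 + (a*u_jet)^2).

    ``sigma_wt`` is traffic-generated turbulence; for ship events it is
    negligible and defaults to zero.
    """
    if min(wind_speed, u_jet, sigma_wt, alpha) < 0:
        raise ValueError("all inputs must be nonnegative")
    return math.sqrt((alpha * wind_speed) ** 2 + sigma_wt**2 + (alpha * u_jet) ** 2)


def plume_cross_section(
    stack: StackSpec, sigma_w: float, t: float, alpha: float = 0.1
) -> float:
    """Jet-plume cross-sectional area S(t), m^2.

    The jet-momentum term is subtracted from the turbulent expansion; should
    the formula produce S(t) < S0 (pathological inputs), the area is floored
    at S0 with a warning, since a shrinking plume is unphysical here.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    s = (math.sqrt(stack.cross_section) + t * sigma_w) ** 2 - (
        t * alpha * stack.exhaust_velocity
    ) ** 2
    if s <= 0:
        raise ValueError(f"nonpositive plume cross-section ({s:.3g} m^2) at t={t}s")
    if s < stack.cross_section:
        warnings.warn(
            "jet cross-section below stack area; flooring at S0", stacklevel=2
        )
        return stack.cross_section
    return s


def first_stage_dilution_ratio(
    stack: StackSpec,
    wind_speed: float,
    alpha: float = 0.1,
    sigma_wt: float = 0.0,
    t_end: float = 1.0,
) -> float:
    """First-stage dilution ratio DR = S(t_end)/S0.

    The jet velocity is taken equal to the stack exit velocity and held
    constant over the short first stage.
    """
    sigma_w = entrainment_velocity(wind_speed, stack.exhaust_velocity, sigma_wt, alpha)
    return plume_cross_section(stack, sigma_w, t_end, alpha) / stack.cross_section


def initial_plume_temperature(t_ambient: float, t_exhaust: float, dr: float) -> float:
    """Plume temperature after stage 1: T_P = T_A + (T_E - T_A)/DR."""
    if dr < 1:
        raise ValueError("DR must be >= 1")
    return t_ambient + (t_exhaust - t_ambient) / dr


def coagulation_fraction_remaining(
    initial_pn: float,
    stack: StackSpec | None = None,
    wind_speed: float = 4.6,
    diameter_nm: float = 15.0,
    temperature: float = 288.15,
    alpha: float = 0.1,
    t_end: float = 1.0,
    reference_wind: float = 4.6,
    kernel_scale: float = 4.0,
    n_steps: int = 500,
) -> float:
    """Fraction of particles surviving coagulation during the jet expansion.

    Coagulation competes with dilution in the super-linearly expanding
    plume. The loss is integrated as monodisperse Smoluchowski coagulation
    with a Brownian kernel evaluated at the exhaust count-median diameter,
    inside the analytically expanding plume volume (cross-section S(t) times
    along-wind extent, the latter proportional to wind speed):

        dN/dt|_coag = -K(d) * N(t)^2,   N(t) = N_end * S(t_end)/S(t),

    where ``initial_pn`` (= N_end) is the diluted plume particle number at
    the end of the first stage for a plume advected at ``reference_wind``;
    for a fixed source strength the in-plume concentration scales as 1/U, so
    weak-wind events are denser and lose more particles. The returned
    fraction isolates coagulation (the 1/DR dilution factor is reported
    separately), hence it lies in (0, 1].

    ``kernel_scale`` multiplies the monodisperse Fuchs self-kernel to account
    for scavenging across the real, multimodal exhaust spectrum (small-large
    pairs coagulate far faster than equal pairs); the default of 4 is a
    typical polydispersity enhancement for a fresh multimodal exhaust.
    """
    if initial_pn < 0:
        raise ValueError("initial particle number must be nonnegative")
    if initial_pn == 0:
        return 1.0
    if wind_speed < 0:
        raise ValueError("wind speed must be nonnegative")
    if stack is None:
        stack = StackSpec()
    from .kernels import brownian_kernel_monodisperse

    kern = kernel_scale * brownian_kernel_monodisperse(diameter_nm, temperature)  # cm^3 s^-1
    # concentration scaling for the along-wind plume stretching
    n_end = initial_pn * reference_wind / max(wind_speed, 0.5)
    sigma_w = entrainment_velocity(wind_speed, stack.exhaust_velocity, 0.0, alpha)
    ts = np.linspace(0.0, t_end, n_steps + 1)
    areas = np.array([plume_cross_section(stack, sigma_w, t, alpha) for t in ts])
    s_end = areas[-1]
    survival = 1.0
    for i in range(n_steps):
        dt = ts[i + 1] - ts[i]
        conc = n_end * survival * s_end / areas[i]
        survival *= max(1.0 - kern * conc * dt, 0.0)
    return survival


def fit_power_law(
    distances: np.ndarray,
    concentrations: np.ndarray,
    background: float | np.ndarray = 0.0,
) -> dict:
    """Fit y(x) = a * x**-b to background-subtracted concentrations.

    Ordinary least squares of log(y) on log(x). Points at x <= 0 or with
    nonpositive concentration after background subtraction are dropped with
    a warning; at least three valid points are required.

    Returns a dict with keys ``a``, ``b``, ``r2``, ``n_points``.
    """
    x = np.asarray(distances, dtype=float)
    y = np.asarray(concentrations, dtype=float) - np.asarray(background, dtype=float)
    valid = (x > 0) & (y > 0)
    if valid.sum() < len(x):
        warnings.warn(
            f"dropping {len(x) - int(valid.sum())} nonpositive points before log-log fit",
            stacklevel=2,
        )
    x, y = x[valid], y[valid]
    if len(x) < 3:
        raise ValueError("need at least 3 valid (distance, concentration) points")
    lx, ly = np.log(x), np.log(y)
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = float(((ly - pred) ** 2).sum())
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return {"a": float(np.exp(intercept)), "b": float(-slope), "r2": r2, "n_points": int(len(x))}


def plume_height(t: float, wind_speed: float, params: DilutionParams) -> float:
    """Plume vertical extent H_P(t) = sqrt(H_P0^2 + (a'*(1e-3*U*t)^b)^2), m."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    growth = params.sigma_z_scale * (1e-3 * wind_speed * t) ** params.b
    return math.sqrt(params.h_p0**2 + growth**2)


def dilution_tendency(value, background_value, b: float, t: float):
    """Mixing tendency toward background: -(b/t) * (value - background).

    Applies identically to gas concentrations and to every particle
    section/component; ``value`` may be scalar or array.
    """
    if t <= 0:
        raise ValueError("t must be positive")
    return -(b / t) * (np.asarray(value) - np.asarray(background_value))
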