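"""Sectional aerosol microphysics: condensation, coagulation, deposition.

Condensation uses the analytical-predictor scheme: for each vapor the new
gas concentration is solved semi-analytically against the sum of per-section
transition-regime mass-transfer coefficients, and the per-section fluxes are
taken against that predicted concentration. Equilibrium concentrations over
each section include Raoult (mole-fraction) and Kelvin (curvature)
corrections. The scheme conserves gas + particle mass of every species to
machine precision and cannot drive a section's mass negative (evaporation is
limited to the available component mass).

Coagulation is Brownian with a Fuchs kernel and a sequential semi-implicit
(unconditionally positive) sectional solution; coalesced volume is split
between the two fixed sections bracketing it, conserving number and each
component's mass exactly.

Dry deposition is a first-order loss with a size-dependent deposition
velocity (settling plus a smooth-surface resistance model) acting over the
plume height. Background mixing applies the power-law dilution law exactly
(per-step analytic factor), so the plume state relaxes toward the background
state without overshoot for any step size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grids import SizeGrid
from .kernels import (
    BOLTZMANN,
    air_viscosity,
    brownian_kernel_matrix,
    cunningham_slip,
)
from .state import AVOGADRO, COMPONENTS, COMPONENT_DENSITY, AerosolState, GasState

__all__ = [
    "VAPORS",
    "VaporProperties",
    "saturation_concentration",
    "kelvin_factor",
    "equilibrium_vapor_concentration",
    "condensation_step",
    "coagulation_step",
    "deposition_velocity",
    "dry_deposition_step",
    "background_mixing_step",
    "equilibrate_water",
    "rebin",
]


# --------------------------------------------------------------------------
# vapor thermodynamics
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class VaporProperties:
    """Thermophysical constants of a condensing vapor."""

    molar_mass: float  # g mol^-1
    liquid_density: float  # kg m^-3
    component: str  # particle component receiving the mass
    psat_298: float  # saturation vapor pressure at 298.15 K, Pa
    dh_vap: float  # enthalpy of vaporization, J mol^-1
    surface_tension: float  # N m^-1
    diffusivity_298: float  # gas diffusivity in air at 298.15 K, cm^2 s^-1
    accommodation: float = 1.0


#: condensable vapors: sulfuric acid plus two low-volatility n-alkanes and one
#: extremely low-volatility lubricating-oil alkane. Saturation pressures follow
#: Clausius–Clapeyron anchored at 298 K.
VAPORS: dict[str, VaporProperties] = {
    "H2SO4": VaporProperties(98.1, 1830.0, "sulfate", 0.0, 0.0, 0.055, 0.094),
    "C22H46": VaporProperties(310.6, 1000.0, "sv_om", 1.0e-5, 1.20e5, 0.025, 0.051),
    "C28H58": VaporProperties(394.8, 1000.0, "sv_om", 1.0e-8, 1.45e5, 0.025, 0.045),
    "C34H70": VaporProperties(478.9, 1000.0, "elv_om", 1.0e-12, 1.70e5, 0.025, 0.040),
}

R_GAS = 8.314462618  # J mol^-1 K^-1

#: molar masses used for the Raoult mole-fraction bookkeeping (g mol^-1);
#: soot is a solid and takes no part in the liquid mixture
_RAOULT_MOLAR_MASS = {"nv_pom": 300.0, "sv_om": 350.0, "elv_om": 478.9, "sulfate": 98.1, "water": 18.0}

#: hygroscopicity (kappa) per dry component for the water-equilibrium diagnosis
KAPPA = {"soot": 0.0, "nv_pom": 0.01, "sv_om": 0.05, "elv_om": 0.05, "sulfate": 0.5, "water": 0.0}


def saturation_concentration(species: str, temperature: float) -> float:
    """Pure-compound saturation concentration, molecules cm^-3."""
    vp = VAPORS[species]
    if vp.psat_298 == 0.0:
        return 0.0
    psat = vp.psat_298 * math.exp(
        -vp.dh_vap / R_GAS * (1.0 / temperature - 1.0 / 298.15)
    )
    return psat / (BOLTZMANN * temperature) * 1e-6  # molecules m^-3 -> cm^-3


def kelvin_factor(species: str, temperature: float, diameter_nm: float) -> float:
    """Kelvin curvature enhancement exp(4 sigma v_m / (k T d))."""
    if diameter_nm <= 0:
        raise ValueError("diameter must be positive")
    vp = VAPORS[species]
    v_m = vp.molar_mass / 1000.0 / vp.liquid_density / AVOGADRO  # m^3/molecule
    d = diameter_nm * 1e-9
    return math.exp(4.0 * vp.surface_tension * v_m / (BOLTZMANN * temperature * d))


def equilibrium_vapor_concentration(
    species: str, temperature: float, mole_fraction: float, diameter_nm: float
) -> float:
    """Equilibrium vapor concentration over a particle surface (cm^-3).

    Raoult's law scales the pure-compound saturation concentration by the
    species' mole fraction in the particle phase; the Kelvin effect raises
    it over curved surfaces.
    """
    if not 0.0 <= mole_fraction <= 1.0:
        raise ValueError("mole fraction must be in [0, 1]")
    return (
        saturation_concentration(species, temperature)
        * mole_fraction
        * kelvin_factor(species, temperature, diameter_nm)
    )


def _mass_transfer_coefficients(
    state: AerosolState, species: str, diameters_nm: np.ndarray
) -> np.ndarray:
    """Per-section first-order uptake coefficients k_i (s^-1)."""
    vp = VAPORS[species]
    t = state.temperature
    diff = vp.diffusivity_298 * (t / 298.15) ** 1.75  # cm^2 s^-1
    cbar = math.sqrt(8.0 * R_GAS * t / (math.pi * vp.molar_mass * 1e-3)) * 100.0  # cm/s
    lam = 3.0 * diff / cbar  # vapor mean free path, cm
    d_cm = diameters_nm * 1e-7
    kn = 2.0 * lam / d_cm
    a = vp.accommodation
    beta = (1.0 + kn) / (1.0 + (4.0 / (3.0 * a) + 0.377) * kn + 4.0 / (3.0 * a) * kn**2)
    return 2.0 * math.pi * d_cm * diff * state.number * beta


def _mole_fractions(state: AerosolState) -> dict[str, np.ndarray]:
    """Per-section mole fraction of each condensing species in the liquid."""
    moles = np.zeros(state.grid.n_sections)
    per_comp = {}
    for comp, mm in _RAOULT_MOLAR_MASS.items():
        m = state.mass[COMPONENTS.index(comp)] / mm
        per_comp[comp] = m
        moles += m
    out: dict[str, np.ndarray] = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for species, vp in VAPORS.items():
            if vp.component == "sv_om":
                # two alkanes share the SV-OM reservoir; split it evenly
                frac = np.where(moles > 0, 0.5 * per_comp["sv_om"] / moles, 0.0)
            else:
                frac = np.where(moles > 0, per_comp[vp.component] / moles, 0.0)
            out[species] = np.clip(frac, 0.0, 1.0)
    return out


def condensation_step(
    state: AerosolState, gases: GasState, dt: float
) -> tuple[AerosolState, GasState]:
    """Advance gas-particle mass transfer of all condensable vapors by ``dt``.

    Returns updated copies of the aerosol and gas states. Total
    gas + particle mass of each species is conserved exactly; evaporation is
    limited to the mass actually present in each section.
    """
    if dt > 0.1:
        raise ValueError("condensation step limited to dt <= 0.1 s")
    out = state.copy()
    gout = gases.copy()
    diam = state.wet_diameter_nm()
    xmole = _mole_fractions(state)
    occupied = state.number > 0
    for species, vp in VAPORS.items():
        c = gout[species]
        k = np.where(occupied, _mass_transfer_coefficients(state, species, diam), 0.0)
        if not k.any():
            continue
        csat = saturation_concentration(species, gases.temperature)
        if csat > 0.0:
            kelvin = np.array(
                [kelvin_factor(species, gases.temperature, d) for d in diam]
            )
            ceq = csat * xmole[species] * kelvin
        else:
            ceq = np.zeros_like(k)
        # analytical predictor: implicit in the gas concentration
        c_new = (c + dt * float(k @ ceq)) / (1.0 + dt * k.sum())
        flux = dt * k * (c_new - ceq)  # molecules cm^-3 to each section
        # evaporation cannot exceed the section's condensed mass
        to_ug = vp.molar_mass / AVOGADRO * 1e12
        ci = COMPONENTS.index(vp.component)
        avail = out.mass[ci] / to_ug  # molecules cm^-3 equivalent
        if vp.component == "sv_om":
            avail = 0.5 * avail  # each alkane owns half the shared reservoir
        flux = np.maximum(flux, -avail)
        out.mass[ci] += flux * to_ug
        gout[species] = c - float(flux.sum())
    rebin(out)
    return out, gout


def equilibrate_water(state: AerosolState, rh: float | None = None) -> AerosolState:
    """Diagnose particle-bound water by single-parameter (kappa) equilibrium.

    Water volume per section is sum(kappa_c * V_c) * aw/(1-aw) with the water
    activity aw = RH/100, capped at 0.95 to keep the diagnosis bounded near
    saturation.
    """
    out = state.copy()
    aw = min((rh if rh is not None else state.rh) / 100.0, 0.95)
    growth = aw / (1.0 - aw)
    vw = np.zeros(state.grid.n_sections)
    for comp in COMPONENTS[:-1]:
        ci = COMPONENTS.index(comp)
        vw += KAPPA[comp] * state.mass[ci] / COMPONENT_DENSITY[comp] * growth
    out.mass[COMPONENTS.index("water")] = vw * COMPONENT_DENSITY["water"]
    return out


def rebin(state: AerosolState) -> None:
    """Restore number/mass consistency on the fixed grid (in place).

    Condensational growth adds mass to a section without moving its number;
    once a section's mean particle volume leaves the section's bounds, its
    content is redistributed to the two sections bracketing the mean volume,
    conserving number and every component's mass.
    """
    grid = state.grid
    edge_v = grid.edge_volumes_cm3
    center_v = grid.volumes_cm3
    vol = state.volume_per_section()
    n = state.number
    move = np.zeros(grid.n_sections, dtype=bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        vmean = np.where(n > 0, vol / n, center_v)
    move = (n > 0) & ((vmean < edge_v[:-1]) | (vmean >= edge_v[1:]))
    if not move.any():
        return
    number_new = state.number.copy()
    mass_new = state.mass.copy()
    for i in np.where(move)[0]:
        ni, mi, v = n[i], state.mass[:, i].copy(), vmean[i]
        number_new[i] -= ni
        mass_new[:, i] -= mi
        if v <= center_v[0]:
            number_new[0] += ni
            mass_new[:, 0] += mi
            continue
        if v >= center_v[-1]:
            number_new[-1] += ni
            mass_new[:, -1] += mi
            continue
        k = int(np.searchsorted(center_v, v) - 1)
        # split conserving number and volume between sections k and k+1
        f = (center_v[k + 1] - v) / (center_v[k + 1] - center_v[k])
        wv = f * center_v[k] / v  # volume (mass) share to section k
        number_new[k] += f * ni
        number_new[k + 1] += (1.0 - f) * ni
        mass_new[:, k] += wv * mi
        mass_new[:, k + 1] += (1.0 - wv) * mi
    state.number = number_new
    state.mass = mass_new


# --------------------------------------------------------------------------
# coagulation
# --------------------------------------------------------------------------
class _CoagulationTables:
    """Grid-dependent pair-partition tables for the sectional solver."""

    def __init__(self, grid: SizeGrid) -> None:
        v = grid.volumes_cm3
        n = grid.n_sections
        vij = v[:, None] + v[None, :]
        k0 = np.searchsorted(v, vij) - 1  # bracket: v[k0] <= vij < v[k0+1]
        k0 = np.clip(k0, 0, n - 1)
        top = k0 >= n - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            k1 = np.minimum(k0 + 1, n - 1)
            fnum0 = np.where(top, 1.0, (v[k1] - vij) / (v[k1] - v[k0] + 1e-300))
        fnum0 = np.clip(fnum0, 0.0, 1.0)
        fvol0 = np.where(top, 1.0, fnum0 * v[k0] / vij)
        self.k0, self.k1 = k0, k1
        self.fnum0, self.fvol0 = fnum0, fvol0
        self.fnum1, self.fvol1 = 1.0 - fnum0, 1.0 - fvol0
        self.fvol1[top] = 0.0
        self.fnum1[top] = 0.0
        # self-target volume fraction: pair (k, j) whose product stays in k
        self.self_fvol = np.zeros((n, n))
        rows, cols = np.nonzero(k0 == np.arange(n)[:, None])
        self.self_fvol[rows, cols] = fvol0[rows, cols]
        # per-target gain lists: entries (i, j, fvol, fnum) with i < target
        gains: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
        tgt_i: list[list[int]] = [[] for _ in range(n)]
        tgt_j: list[list[int]] = [[] for _ in range(n)]
        tgt_fv: list[list[float]] = [[] for _ in range(n)]
        tgt_fn: list[list[float]] = [[] for _ in range(n)]
        for i in range(n):
            for j in range(n):
                for k, fv, fn in (
                    (k0[i, j], fvol0[i, j], fnum0[i, j]),
                    (k1[i, j], self.fvol1[i, j], self.fnum1[i, j]),
                ):
                    if fv <= 0.0 and fn <= 0.0:
                        continue
                    if i < k:
                        tgt_i[k].append(i)
                        tgt_j[k].append(j)
                        tgt_fv[k].append(fv)
                        tgt_fn[k].append(fn)
        for k in range(n):
            gains.append(
                (
                    np.asarray(tgt_i[k], dtype=int),
                    np.asarray(tgt_j[k], dtype=int),
                    np.asarray(tgt_fv[k], dtype=float),
                    np.asarray(tgt_fn[k], dtype=float),
                )
            )
        self.gains = gains


_tables_cache: dict[tuple, _CoagulationTables] = {}
_kernel_cache: dict[tuple, np.ndarray] = {}


def _tables_for(grid: SizeGrid) -> _CoagulationTables:
    key = (grid.n_sections, grid.d_min_nm, grid.d_max_nm)
    if key not in _tables_cache:
        _tables_cache[key] = _CoagulationTables(grid)
    return _tables_cache[key]


def _kernel_for(grid: SizeGrid, temperature: float) -> np.ndarray:
    key = (grid.n_sections, grid.d_min_nm, grid.d_max_nm, round(temperature, 0))
    if key not in _kernel_cache:
        _kernel_cache[key] = brownian_kernel_matrix(grid.centers_m, round(temperature, 0))
    return _kernel_cache[key]


def coagulation_step(
    state: AerosolState, dt: float, kernel: np.ndarray | None = None
) -> AerosolState:
    """One semi-implicit Brownian coagulation step.

    ``kernel`` overrides the Fuchs kernel matrix (cm^3 s^-1), which the
    closed-form constant-kernel test uses. Total mass of every component is
    conserved exactly; total number strictly decreases whenever any two
    populated sections coagulate.
    """
    if dt > 0.1:
        raise ValueError("coagulation step limited to dt <= 0.1 s")
    grid = state.grid
    tab = _tables_for(grid)
    if kernel is None:
        kernel = _kernel_for(grid, state.temperature)
    n_old = state.number
    if n_old.sum() == 0:
        return state.copy()
    out = state.copy()
    loss = kernel @ n_old  # s^-1 per section
    self_credit = tab.self_fvol * kernel @ n_old if tab.self_fvol.any() else np.zeros_like(loss)
    denom = 1.0 + dt * (loss - self_credit)
    mass_new = np.empty_like(state.mass)
    for k in range(grid.n_sections):
        i_arr, j_arr, fv, _ = tab.gains[k]
        if len(i_arr):
            w = fv * kernel[i_arr, j_arr] * n_old[j_arr]
            gain = mass_new[:, i_arr] @ w  # uses already-updated donors (i < k)
        else:
            gain = 0.0
        mass_new[:, k] = (state.mass[:, k] + dt * gain) / denom[k]
    # number: explicit pair gains (one particle per event), implicit loss
    gain_n = np.zeros(grid.n_sections)
    for k in range(grid.n_sections):
        i_arr, j_arr, _, fn = tab.gains[k]
        if len(i_arr):
            gain_n[k] = float(fn @ (kernel[i_arr, j_arr] * n_old[i_arr] * n_old[j_arr]))
    # each unordered pair appears twice in the ordered gain lists
    number_new = (n_old + 0.5 * dt * gain_n) / (1.0 + dt * loss)
    out.mass = mass_new
    out.number = number_new
    return out


# --------------------------------------------------------------------------
# dry deposition
# --------------------------------------------------------------------------
GRAVITY = 9.81
AIR_KINEMATIC_VISCOSITY = 1.5e-5  # m^2 s^-1
VON_KARMAN = 0.4


def deposition_velocity(
    diameters_m: np.ndarray,
    temperature: float = 288.15,
    friction_velocity: float = 0.3,
    reference_height: float = 10.0,
    roughness_length: float = 1e-3,
    particle_density: float = 1200.0,
) -> np.ndarray:
    """Size-dependent dry deposition velocity over a smooth surface (m s^-1).

    Gravitational settling plus the classical two-resistance formulation with
    Brownian (Schmidt-number) and impaction (Stokes-number) surface uptake.
    """
    d = np.asarray(diameters_m, dtype=float)
    mu = air_viscosity(temperature)
    cc = cunningham_slip(d, temperature)
    v_s = particle_density * d**2 * GRAVITY * cc / (18.0 * mu)
    diff = BOLTZMANN * temperature * cc / (3.0 * np.pi * mu * d)
    sc = AIR_KINEMATIC_VISCOSITY / diff
    st = v_s * friction_velocity**2 / (GRAVITY * AIR_KINEMATIC_VISCOSITY)
    r_a = math.log(reference_height / roughness_length) / (VON_KARMAN * friction_velocity)
    r_b = 1.0 / (friction_velocity * (sc ** (-2.0 / 3.0) + 10.0 ** (-3.0 / np.maximum(st, 1e-10))))
    return v_s + 1.0 / (r_a + r_b + r_a * r_b * v_s)


def dry_deposition_step(
    state: AerosolState, dt: float, plume_height: float, friction_velocity: float = 0.3
) -> AerosolState:
    """First-order deposition loss over the plume depth: rate v_d(Dp)/H_P."""
    if plume_height <= 0:
        raise ValueError("plume height must be positive")
    out = state.copy()
    vd = deposition_velocity(
        state.grid.centers_m, state.temperature, friction_velocity=friction_velocity
    )
    factor = np.exp(-vd * dt / plume_height)
    out.number *= factor
    out.mass *= factor[None, :]
    return out


# --------------------------------------------------------------------------
# background mixing
# --------------------------------------------------------------------------
def background_mixing_step(
    state: AerosolState, background: AerosolState, b: float, t: float, dt: float
) -> AerosolState:
    """Mix the plume state toward the background per the power-law dilution.

    The per-section relaxation dN/dt = -(b/t)(N - N_bg) is integrated
    analytically over [t, t+dt], giving the factor ((t+dt)/t)**-b; masses
    mix with the same factor toward the background masses. The update never
    crosses the background value.
    """
    if t <= 0:
        raise ValueError("t must be positive")
    if b <= 0:
        raise ValueError("b must be positive")
    factor = ((t + dt) / t) ** (-b)
    out = state.copy()
    out.number = background.number + (state.number - background.number) * factor
    out.mass = background.mass + (state.mass - background.mass) * factor
    return out
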