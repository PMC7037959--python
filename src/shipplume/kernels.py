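"""Brownian coagulation kernel (Fuchs transition-regime form).

The kernel interpolates between the continuum (diffusion-limited) and
free-molecular (kinetic) regimes following Fuchs' flux-matching construction,
which is the standard choice for exhaust and urban aerosols whose sizes span
both regimes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "air_viscosity",
    "air_mean_free_path",
    "cunningham_slip",
    "particle_diffusivity",
    "brownian_kernel_matrix",
    "brownian_kernel_monodisperse",
]

BOLTZMANN = 1.380649e-23  # J K^-1
PRESSURE = 101325.0  # Pa (sea-level harbor conditions)


def air_viscosity(temperature: float) -> float:
    """Dynamic viscosity of air (Pa s), Sutherland's law."""
    return 1.458e-6 * temperature**1.5 / (temperature + 110.4)


def air_mean_free_path(temperature: float, pressure: float = PRESSURE) -> float:
    """Mean free path of air molecules (m)."""
    # reference 67.3 nm at 296.15 K, 101325 Pa; T and p scaling
    return 67.3e-9 * (temperature / 296.15) * (101325.0 / pressure) * (
        (1 + 110.4 / 296.15) / (1 + 110.4 / temperature)
    )


def cunningham_slip(diameter_m: np.ndarray, temperature: float) -> np.ndarray:
    """Cunningham slip correction factor."""
    kn = 2.0 * air_mean_free_path(temperature) / diameter_m
    return 1.0 + kn * (1.257 + 0.4 * np.exp(-1.1 / kn))


def particle_diffusivity(diameter_m: np.ndarray, temperature: float) -> np.ndarray:
    """Brownian diffusivity of particles (m^2 s^-1)."""
    mu = air_viscosity(temperature)
    cc = cunningham_slip(diameter_m, temperature)
    return BOLTZMANN * temperature * cc / (3.0 * np.pi * mu * diameter_m)


def brownian_kernel_matrix(
    diameters_m: np.ndarray,
    temperature: float,
    density: float | np.ndarray = 1000.0,
) -> np.ndarray:
    """Pairwise Fuchs Brownian kernel, cm^3 s^-1.

    Parameters
    ----------
    diameters_m:
        Particle diameters (m), shape (n,).
    temperature:
        Air temperature (K).
    density:
        Particle density (kg m^-3), scalar or per-size array.
    """
    d = np.asarray(diameters_m, dtype=float)
    rho = np.broadcast_to(np.asarray(density, dtype=float), d.shape)
    diff = particle_diffusivity(d, temperature)
    mass = rho * np.pi / 6.0 * d**3
    cbar = np.sqrt(8.0 * BOLTZMANN * temperature / (np.pi * mass))
    ell = 8.0 * diff / (np.pi * cbar)  # particle mean free path
    g = ((d + ell) ** 3 - (d**2 + ell**2) ** 1.5) / (3.0 * d * ell) - d

    di, dj = d[:, None], d[None, :]
    dij = di + dj
    diffij = diff[:, None] + diff[None, :]
    gij = np.sqrt(g[:, None] ** 2 + g[None, :] ** 2)
    cij = np.sqrt(cbar[:, None] ** 2 + cbar[None, :] ** 2)

    denom = dij / (dij + 2.0 * gij) + 8.0 * diffij / (cij * dij)
    kernel_m3 = 2.0 * np.pi * diffij * dij / denom
    return kernel_m3 * 1e6  # m^3 s^-1 -> cm^3 s^-1


def brownian_kernel_monodisperse(
    diameter_nm: float, temperature: float, density: float = 1000.0
) -> float:
    """Self-coagulation kernel K(d, d) for a monodisperse population, cm^3 s^-1."""
    k = brownian_kernel_matrix(np.array([diameter_nm * 1e-9]), temperature, density)
    return float(k[0, 0])
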