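"""In-memory state containers for the plume model.

Two states are propagated along the plume trajectory:

* :class:`AerosolState` — per-section particle number (cm^-3) and per-section,
  per-component mass concentrations (µg m^-3) on a fixed :class:`SizeGrid`.
* :class:`GasState` — gas concentrations (molecules cm^-3).

Components follow the usual exhaust-aerosol split: soot (elemental carbon),
nonvolatile primary organic matter (NV-POM), semivolatile organic matter
(SV-OM), extremely low-volatility organic matter (ELV-OM), sulfate (carried
as H2SO4), and particle-bound water.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grids import SizeGrid

__all__ = [
    "COMPONENTS",
    "DRY_COMPONENTS",
    "COMPONENT_DENSITY",
    "GAS_SPECIES",
    "AerosolState",
    "GasState",
    "AVOGADRO",
    "MOLAR_MASS",
]

COMPONENTS: tuple[str, ...] = ("soot", "nv_pom", "sv_om", "elv_om", "sulfate", "water")
DRY_COMPONENTS: tuple[str, ...] = COMPONENTS[:-1]

#: bulk densities, kg m^-3 (standard aerosol values)
COMPONENT_DENSITY: dict[str, float] = {
    "soot": 1800.0,
    "nv_pom": 1000.0,
    "sv_om": 1000.0,
    "elv_om": 1000.0,
    "sulfate": 1830.0,
    "water": 1000.0,
}

GAS_SPECIES: tuple[str, ...] = (
    "NO",
    "NO2",
    "O3",
    "SO2",
    "SO3",
    "H2SO4",
    "OH",
    "C22H46",
    "C28H58",
    "C34H70",
)

AVOGADRO = 6.02214076e23

#: molar masses, g mol^-1
MOLAR_MASS: dict[str, float] = {
    "NO": 30.0,
    "NO2": 46.0,
    "O3": 48.0,
    "SO2": 64.1,
    "SO3": 80.1,
    "H2SO4": 98.1,
    "OH": 17.0,
    "C22H46": 310.6,
    "C28H58": 394.8,
    "C34H70": 478.9,
}

_DENS = np.array([COMPONENT_DENSITY[c] for c in COMPONENTS])


@dataclass
class AerosolState:
    """Sectional number/mass state of the particle population."""

    grid: SizeGrid
    number: np.ndarray  # (n_sections,), cm^-3
    mass: np.ndarray  # (n_components, n_sections), µg m^-3
    temperature: float = 288.15  # K
    rh: float = 70.0  # %

    @classmethod
    def empty(cls, grid: SizeGrid, temperature: float = 288.15, rh: float = 70.0) -> "AerosolState":
        return cls(
            grid=grid,
            number=np.zeros(grid.n_sections),
            mass=np.zeros((len(COMPONENTS), grid.n_sections)),
            temperature=temperature,
            rh=rh,
        )

    def __post_init__(self) -> None:
        self.number = np.asarray(self.number, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.number.shape != (self.grid.n_sections,):
            raise ValueError("number must have shape (n_sections,)")
        if self.mass.shape != (len(COMPONENTS), self.grid.n_sections):
            raise ValueError("mass must have shape (n_components, n_sections)")

    def copy(self) -> "AerosolState":
        return replace(self, number=self.number.copy(), mass=self.mass.copy())

    # -- diagnostics ----------------------------------------------------------
    @property
    def total_number(self) -> float:
        """Total particle number concentration (cm^-3)."""
        return float(self.number.sum())

    def component_index(self, name: str) -> int:
        return COMPONENTS.index(name)

    def dry_mass_per_section(self) -> np.ndarray:
        """Dry (water-free) mass per section, µg m^-3."""
        return self.mass[: len(DRY_COMPONENTS)].sum(axis=0)

    def volume_per_section(self) -> np.ndarray:
        """Total particle volume per section (cm^3 of particle per cm^3 of air).

        µg m^-3 / (kg m^-3) = 1e-9 kg m^-3 / (kg m^-3) = 1e-9 (m^3 per m^3),
        dimensionless volume fraction; identical value in cm^3 cm^-3.
        """
        return 1e-9 * (self.mass / _DENS[:, None]).sum(axis=0)

    def mean_particle_volume(self, floor_to_grid: bool = True) -> np.ndarray:
        """Mean single-particle volume per section (cm^3).

        Sections with no particles report the grid's nominal center volume.
        """
        v = self.grid.volumes_cm3.copy()
        occupied = self.number > 0
        v[occupied] = self.volume_per_section()[occupied] / self.number[occupied]
        if floor_to_grid:
            v = np.clip(v, self.grid.edge_volumes_cm3[0], self.grid.edge_volumes_cm3[-1])
        return v

    def wet_diameter_nm(self) -> np.ndarray:
        """Mass-consistent mean diameter per section (nm)."""
        v = self.mean_particle_volume()
        return (6.0 * v / np.pi) ** (1.0 / 3.0) * 1e7

    def number_below(self, diameter_nm: float) -> float:
        return float(self.number[self.grid.mask_below(diameter_nm)].sum())

    def number_between(self, lo_nm: float, hi_nm: float) -> float:
        return float(self.number[self.grid.mask_between(lo_nm, hi_nm)].sum())

    def validate(self) -> None:
        """Raise if the state is unphysical (negative or non-finite)."""
        if not np.all(np.isfinite(self.number)) or not np.all(np.isfinite(self.mass)):
            raise FloatingPointError("non-finite aerosol state")
        if (self.number < 0).any() or (self.mass < 0).any():
            raise FloatingPointError("negative aerosol state")


@dataclass
class GasState:
    """Gas-phase concentrations in the plume (molecules cm^-3)."""

    conc: dict[str, float] = field(default_factory=dict)
    temperature: float = 288.15  # K
    rh: float = 70.0  # %
    time: float = 1.0  # s since release

    def __post_init__(self) -> None:
        full = {s: 0.0 for s in GAS_SPECIES}
        full.update(self.conc)
        unknown = set(full) - set(GAS_SPECIES)
        if unknown:
            raise ValueError(f"unknown gas species: {sorted(unknown)}")
        self.conc = full

    def copy(self) -> "GasState":
        return GasState(
            conc=dict(self.conc), temperature=self.temperature, rh=self.rh, time=self.time
        )

    def __getitem__(self, species: str) -> float:
        return self.conc[species]

    def __setitem__(self, species: str, value: float) -> None:
        if species not in GAS_SPECIES:
            raise KeyError(species)
        self.conc[species] = value

    def total_sulfur(self) -> float:
        """Gas-phase sulfur (molecules cm^-3) across SO2, SO3, H2SO4."""
        return self.conc["SO2"] + self.conc["SO3"] + self.conc["H2SO4"]

    def validate(self) -> None:
        for s, v in self.conc.items():
            if not np.isfinite(v) or v < 0:
                raise FloatingPointError(f"unphysical {s} concentration: {v}")


def molecules_per_cm3_to_ug_per_m3(n: float, species: str) -> float:
    """Convert molecules cm^-3 to µg m^-3."""
    return n * MOLAR_MASS[species] / AVOGADRO * 1e12


def ug_per_m3_to_molecules_per_cm3(m: float, species: str) -> float:
    """Convert µg m^-3 to molecules cm^-3."""
    return m / MOLAR_MASS[species] * AVOGADRO * 1e-12
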