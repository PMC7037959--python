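"""Short-term population exposure to ship-plume ultrafine particles.

The plume trajectory's ultrafine number concentration (Dp < 100 nm) as a
function of downwind distance is averaged into 40-m concentric rings and
spread uniformly over a wedge of 15 degrees on each side of the plume
centerline, out to 3600 m — a deliberately simple "impact area"
representation that inserts the centerline concentration across the lateral
plume width (it overstates the outer plume, and the exposure numbers are
defined with that convention).

Daily mean concentrations assume the plume is present over each scheduled
ship passage for five minutes and the urban background otherwise. Indoor
exposure in the residential microenvironment applies an infiltration factor
F_inf = C_indoor/C_outdoor (default 0.56 for ultrafine particles in Nordic
homes), and the per-cell population exposure is

    E_i = sum_j F_inf_j * sum_t C_i_t * P_i_j_t    (cm^-3 * persons),

restricted here to the home microenvironment. A linear short-term excess
mortality risk of 4% per 6250 cm^-3 daily-mean ultrafine increment converts
concentration increments to risk estimates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Point, box
from shapely.ops import unary_union

from .fixtures import PopulationGrid
from .simulate import PlumeTrajectory

__all__ = [
    "ExposureField",
    "ExposureResult",
    "build_plume_field",
    "daily_mean_concentration",
    "infiltrate",
    "population_exposure",
    "excess_risk",
    "RING_WIDTH",
    "MAX_RADIUS",
    "SECTOR_HALF_WIDTH",
    "DEFAULT_F_INF",
    "RISK_PER_INCREMENT",
    "RISK_INCREMENT",
]

RING_WIDTH = 40.0  # m
MAX_RADIUS = 3600.0  # m
SECTOR_HALF_WIDTH = 15.0  # degrees each side of the centerline
DEFAULT_F_INF = 0.56
RISK_PER_INCREMENT = 4.0  # % excess mortality risk ...
RISK_INCREMENT = 6250.0  # ... per this many cm^-3 of daily-mean UFP

MINUTES_PER_DAY = 1440.0


@dataclass
class ExposureField:
    """Ring-sector ship-impact concentration field.

    ``ring_concentrations[i]`` is the ultrafine concentration (cm^-3) in the
    ring [i*40, (i+1)*40) m within the plume sector; outside the sector (or
    beyond 3600 m) the field equals ``background``.
    """

    ship_position: tuple[float, float]  # (x, y), m
    centerline_direction: float  # degrees, direction the plume travels toward
    ring_concentrations: np.ndarray  # (n_rings,), cm^-3
    background: float  # cm^-3
    ring_width: float = RING_WIDTH
    sector_half_width: float = SECTOR_HALF_WIDTH

    def __post_init__(self) -> None:
        self.ring_concentrations = np.asarray(self.ring_concentrations, dtype=float)
        if self.ring_width * len(self.ring_concentrations) > MAX_RADIUS + 1e-9:
            raise ValueError(f"field extends beyond the {MAX_RADIUS} m impact radius")
        if self.background < 0:
            raise ValueError("background must be nonnegative")

    @property
    def max_radius(self) -> float:
        return self.ring_width * len(self.ring_concentrations)

    def concentration_at(self, x: float, y: float) -> float:
        """Point evaluation of the field (cm^-3)."""
        dx, dy = x - self.ship_position[0], y - self.ship_position[1]
        r = math.hypot(dx, dy)
        if r == 0.0:
            return max(float(self.ring_concentrations[0]), self.background)
        if r >= self.max_radius:
            return self.background
        bearing = math.degrees(math.atan2(dx, dy)) % 360.0  # compass-style
        delta = (bearing - self.centerline_direction + 180.0) % 360.0 - 180.0
        if abs(delta) > self.sector_half_width:
            return self.background
        return max(float(self.ring_concentrations[int(r // self.ring_width)]), self.background)

    def sector_polygon(self, r_in: float, r_out: float, n_arc: int = 24):
        """Shapely polygon of one annular wedge of the plume sector."""
        cx, cy = self.ship_position
        a0 = math.radians(self.centerline_direction - self.sector_half_width)
        a1 = math.radians(self.centerline_direction + self.sector_half_width)
        angles = np.linspace(a0, a1, n_arc)
        outer = [(cx + r_out * math.sin(a), cy + r_out * math.cos(a)) for a in angles]
        if r_in <= 0:
            ring = outer + [(cx, cy)]
        else:
            inner = [(cx + r_in * math.sin(a), cy + r_in * math.cos(a)) for a in angles[::-1]]
            ring = outer + inner
        return shapely.Polygon(ring)


@dataclass
class ExposureResult:
    """Per-cell daily exposure in the home microenvironment."""

    exposure: np.ndarray  # (ny, nx), cm^-3 * persons
    background_exposure: np.ndarray  # same, background-only counterfactual
    microenvironment: str = "ME_home"
    f_inf: float = DEFAULT_F_INF
    persons_in_impact_area: int = 0

    @property
    def total(self) -> float:
        return float(self.exposure.sum())

    @property
    def excess_percent(self) -> np.ndarray:
        """Per-cell exceedance over the background-only exposure, %."""
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * (self.exposure - self.background_exposure) / self.background_exposure
        return np.where(self.background_exposure > 0, pct, 0.0)


def build_plume_field(
    traj: PlumeTrajectory,
    ship_position: tuple[float, float] = (0.0, 0.0),
    background: float | None = None,
) -> ExposureField:
    """Average the trajectory's UFP concentration into 40-m rings.

    Each ring value is the mean ultrafine (Dp < 100 nm) number concentration
    over the trajectory samples whose downwind distance x = U*t falls in the
    ring; rings beyond the trajectory's reach are padded with the
    background. The plume direction is the event's downwind bearing
    (wind_direction + 180).
    """
    if background is None:
        background = (
            traj.background.number_below(100.0) if traj.background is not None else 0.0
        )
    x = traj.distances
    ufp = traj.ufp_number()
    n_rings = int(MAX_RADIUS / RING_WIDTH)
    rings = np.full(n_rings, float(background))
    for i in range(n_rings):
        mask = (x >= i * RING_WIDTH) & (x < (i + 1) * RING_WIDTH)
        if mask.any():
            rings[i] = float(ufp[mask].mean())
    rings = np.maximum(rings, background)
    direction = (
        (traj.event.wind_direction + 180.0) % 360.0 if traj.event is not None else 0.0
    )
    return ExposureField(
        ship_position=ship_position,
        centerline_direction=direction,
        ring_concentrations=rings,
        background=float(background),
    )


def daily_mean_concentration(
    field: ExposureField,
    schedule: list[float],
    plume_minutes: float = 5.0,
    background: float | None = None,
) -> ExposureField:
    """Compose a daily mean field from scheduled ship passages.

    ``schedule`` lists event times as minutes since midnight (only their
    count matters under the constant-background assumption); each passage
    exposes a cell to the plume field for ``plume_minutes`` and the
    background fills the rest of the day. Overlapping plume windows are
    merged with a warning.
    """
    if background is None:
        background = field.background
    events = sorted(schedule)
    if any(not 0.0 <= e < MINUTES_PER_DAY for e in events):
        raise ValueError("schedule times must lie within one day (minutes 0-1440)")
    # merge overlapping plume windows
    total_minutes = 0.0
    cursor = -math.inf
    overlapped = False
    for e in events:
        start, end = e, e + plume_minutes
        if start < cursor:
            overlapped = True
            start = cursor
        if end > start:
            total_minutes += end - start
            cursor = end
    if overlapped:
        warnings.warn("overlapping plume windows merged", stacklevel=2)
    total_minutes = min(total_minutes, MINUTES_PER_DAY)
    w_plume = total_minutes / MINUTES_PER_DAY
    rings = w_plume * field.ring_concentrations + (1.0 - w_plume) * background
    return ExposureField(
        ship_position=field.ship_position,
        centerline_direction=field.centerline_direction,
        ring_concentrations=rings,
        background=float(w_plume * field.background + (1.0 - w_plume) * background),
    )


def infiltrate(outdoor: float | np.ndarray, f_inf: float = DEFAULT_F_INF):
    """Indoor concentration of ambient origin: F_inf * outdoor."""
    if not 0.0 <= f_inf <= 1.0:
        raise ValueError("infiltration factor must be in [0, 1]")
    return f_inf * np.asarray(outdoor, dtype=float) if np.ndim(outdoor) else f_inf * outdoor


def _cell_mean_concentrations(field: ExposureField, population: PopulationGrid) -> np.ndarray:
    """Area-weighted mean field concentration over each 100-m cell."""
    ny, nx = population.inhabitants.shape
    cs = population.cell_size
    x0, y0 = population.origin
    out = np.full((ny, nx), field.background)
    n_rings = len(field.ring_concentrations)
    # only cells overlapping the sector need geometric treatment
    wedge = unary_union(
        [field.sector_polygon(0.0, field.max_radius)]
    ).buffer(0)
    for iy in range(ny):
        for ix in range(nx):
            cell = box(x0 + ix * cs, y0 + iy * cs, x0 + (ix + 1) * cs, y0 + (iy + 1) * cs)
            if not cell.intersects(wedge):
                continue
            acc = field.background * cell.area
            for ir in range(n_rings):
                c = field.ring_concentrations[ir]
                if c == field.background:
                    continue
                poly = field.sector_polygon(ir * field.ring_width, (ir + 1) * field.ring_width)
                a = cell.intersection(poly).area
                if a > 0:
                    acc += (c - field.background) * a
            out[iy, ix] = acc / cell.area
    return out


def population_exposure(
    field: ExposureField,
    population: PopulationGrid,
    time_at_home: float = 0.6,
    f_inf: float = DEFAULT_F_INF,
) -> ExposureResult:
    """Daily home-microenvironment exposure per population cell.

    The ring-sector field is resampled onto the 100-m population raster by
    exact area-weighted polygon overlap; each cell's exposure is
    F_inf * C_cell * P_cell * time_at_home, with the background-only
    counterfactual returned alongside. ``time_at_home`` is the fraction of
    the day spent in the home microenvironment (flat diurnal profile).
    """
    if not 0.0 <= time_at_home <= 1.0:
        raise ValueError("time_at_home must be a fraction of the day")
    if not 0.0 <= f_inf <= 1.0:
        raise ValueError("infiltration factor must be in [0, 1]")
    conc = _cell_mean_concentrations(field, population)
    pop = population.inhabitants.astype(float)
    exposure = f_inf * conc * pop * time_at_home
    bg_exposure = f_inf * field.background * pop * time_at_home
    # persons in the plume-impacted cells
    impacted = conc > field.background * (1.0 + 1e-9)
    return ExposureResult(
        exposure=exposure,
        background_exposure=bg_exposure,
        f_inf=f_inf,
        persons_in_impact_area=int(pop[impacted].sum()),
    )


def excess_risk(increment: float) -> float:
    """Short-term excess mortality risk (%) for a daily-mean UFP increment.

    Linear at 4% per 6250 cm^-3.
    """
    if increment < 0:
        raise ValueError("increment must be nonnegative")
    return RISK_PER_INCREMENT * increment / RISK_INCREMENT
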