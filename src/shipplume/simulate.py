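"""Plume aerosol-dynamics driver.

Follows an air parcel along the plume centerline from t0 = 1 s (end of the
jet expansion stage) for 15 min, advancing per 0.1-s step: gas chemistry,
nucleation, condensation, coagulation, dry deposition, and power-law mixing
with the background. Downwind distance is x = U*t and the plume depth grows
as H_P(t).

Scenario flags reproduce the standard sensitivity cases:

* ``base``   — 1% of SOx emitted as SO3, binary nucleation, 20:80
  sulfate:organic nucleation-mode exhaust composition;
* ``2XSO3``  — doubled SOx-to-SO3 conversion;
* ``T310K``  — plume starts at 310 K and relaxes to ambient with the
  dilution timescale;
* ``NUHET``  — nucleation involving an organic vapor;
* ``HSULF``  — exhaust nucleation mode composed of pure liquid H2SO4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chemistry import gas_step, oh_level
from .dilution import (
    DilutionParams,
    StackSpec,
    first_stage_dilution_ratio,
    plume_height,
)
from .events import ShipEvent, make_event
from .fixtures import (
    DEFAULT_EXHAUST_TOTAL_PN,
    exhaust_modes,
    make_background_distribution,
    make_exhaust_distribution,
)
from .grids import SizeGrid
from .microphysics import (
    background_mixing_step,
    coagulation_step,
    condensation_step,
    dry_deposition_step,
    equilibrate_water,
)
from .nucleation import nucleation_rate
from .state import (
    AVOGADRO,
    COMPONENTS,
    DRY_COMPONENTS,
    AerosolState,
    GasState,
    ug_per_m3_to_molecules_per_cm3,
)

__all__ = [
    "SCENARIOS",
    "STABILITY_B",
    "PlumeTrajectory",
    "ProcessFlags",
    "initial_conditions",
    "simulate_plume",
    "simulate_event",
    "summarize",
    "mass_fractions",
    "growth_rate",
]

SCENARIOS = ("base", "2XSO3", "T310K", "NUHET", "HSULF")

#: power-law dilution exponent by stability class (the fitted exponents span
#: 0.99–1.47 with mean 1.26; higher in unstable, lower in stable conditions)
STABILITY_B = {"unstable": 1.40, "neutral": 1.26, "stable": 1.00}

#: diluted-plume initial gas concentrations (molecules cm^-3) at t0
_INITIAL_GASES = {
    "SO2": 3.0e12,
    "SO3": 3.0e10,  # 1% of SOx emitted as SO3
    "H2SO4": 0.0,
    "NO": 4.0e12,
    "NO2": 4.4e11,  # NOx emitted as 90% NO / 10% NO2 (molar)
    "O3": ug_per_m3_to_molecules_per_cm3(10.0, "O3"),  # titrated plume core
    "C22H46": 2.0e11,
    "C28H58": 2.0e11,
    "C34H70": 3.3e11,
}

_BACKGROUND_GASES = {
    "NO": 1.0e10,
    "NO2": 5.0e10,
    "SO2": 2.5e10,
    "O3": ug_per_m3_to_molecules_per_cm3(60.0, "O3"),
}


@dataclass
class ProcessFlags:
    """Per-process switches, mainly for verification runs."""

    chemistry: bool = True
    nucleation: bool = True
    condensation: bool = True
    coagulation: bool = True
    deposition: bool = True
    dilution: bool = True


@dataclass
class PlumeTrajectory:
    """Recorded time series of the plume state."""

    times: np.ndarray  # s since release
    states: list[AerosolState]
    gases: list[GasState]
    wind_speed: float
    params: DilutionParams
    event: ShipEvent | None = None
    scenario: str = "base"
    background: AerosolState | None = None

    @property
    def distances(self) -> np.ndarray:
        """Downwind distance x = U * t (m)."""
        return self.wind_speed * self.times

    @property
    def plume_heights(self) -> np.ndarray:
        return np.array([plume_height(t, self.wind_speed, self.params) for t in self.times])

    def index_at(self, t: float) -> int:
        i = int(np.argmin(np.abs(self.times - t)))
        return i

    def state_at(self, t: float) -> AerosolState:
        return self.states[self.index_at(t)]

    def gas_at(self, t: float) -> GasState:
        return self.gases[self.index_at(t)]

    def ufp_number(self) -> np.ndarray:
        """Total number below 100 nm at each recorded time (cm^-3)."""
        return np.array([s.number_below(100.0) for s in self.states])

    def to_dataset(self):
        """Trajectory as an xarray.Dataset (time, section, component)."""
        import xarray as xr

        grid = self.states[0].grid
        number = np.stack([s.number for s in self.states])
        mass = np.stack([s.mass for s in self.states])
        gas_names = sorted(self.gases[0].conc)
        gas = np.array([[g[name] for name in gas_names] for g in self.gases])
        return xr.Dataset(
            {
                "number": (("time", "section"), number),
                "mass": (("time", "component", "section"), mass),
                "gas": (("time", "species"), gas),
                "plume_height": (("time",), self.plume_heights),
                "distance": (("time",), self.distances),
            },
            coords={
                "time": self.times,
                "section": grid.centers_nm,
                "component": list(COMPONENTS),
                "species": gas_names,
            },
            attrs={
                "scenario": self.scenario,
                "wind_speed": self.wind_speed,
                "b": self.params.b,
                "event": self.event.event_id if self.event else "",
            },
        )


def initial_conditions(
    event: ShipEvent,
    scenario: str = "base",
    grid: SizeGrid | None = None,
    total_pn: float = DEFAULT_EXHAUST_TOTAL_PN,
) -> tuple[AerosolState, GasState, AerosolState, GasState, DilutionParams]:
    """Diluted-exhaust and background states plus dilution parameters.

    The exhaust size distribution is the default three-mode preset (total
    particle number ``total_pn`` after the first dilution stage); gases are
    initialized at diluted-stack concentrations. The background is the urban
    Helsinki-type preset.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    grid = grid or SizeGrid()
    t_start = 310.0 if scenario == "T310K" else event.air_temperature
    nuc_comp = "hsulf" if scenario == "HSULF" else "base"
    exhaust = make_exhaust_distribution(
        exhaust_modes(total_pn, nucleation_composition=nuc_comp),
        grid,
        temperature=t_start,
        rh=event.relative_humidity,
    )
    background = make_background_distribution(
        "helsinki", grid, temperature=event.air_temperature, rh=event.relative_humidity
    )
    background = equilibrate_water(background)
    conc = dict(_INITIAL_GASES)
    if scenario == "2XSO3":
        conc["SO3"] *= 2.0
    conc["OH"] = oh_level(event)
    gases = GasState(conc, temperature=t_start, rh=event.relative_humidity, time=1.0)
    bg_gas = GasState(
        dict(_BACKGROUND_GASES, OH=conc["OH"]),
        temperature=event.air_temperature,
        rh=event.relative_humidity,
    )
    stability = event.stability_class
    params = DilutionParams.for_stability(
        stability,
        dr=first_stage_dilution_ratio(StackSpec(), event.wind_speed),
        b=STABILITY_B[stability],
    )
    return exhaust, gases, background, bg_gas, params


def simulate_plume(
    exhaust: AerosolState,
    gases: GasState,
    event: ShipEvent,
    params: DilutionParams,
    background: AerosolState | None = None,
    background_gases: GasState | None = None,
    scenario: str = "base",
    duration: float = 900.0,
    dt: float = 0.1,
    output_interval: float = 1.0,
    flags: ProcessFlags | None = None,
) -> PlumeTrajectory:
    """Integrate the plume aerosol from t0 = 1 s to ``duration``.

    Operator sequence per step: chemistry -> nucleation -> condensation ->
    coagulation -> deposition -> dilution. The trajectory is recorded every
    ``output_interval`` seconds with particle water re-equilibrated for the
    output snapshot.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    flags = flags or ProcessFlags()
    grid = exhaust.grid
    if background is None:
        background = AerosolState.empty(grid, exhaust.temperature, exhaust.rh)
    if background.grid.n_sections != grid.n_sections:
        raise ValueError("exhaust and background grids differ")
    if background_gases is None:
        background_gases = GasState(temperature=exhaust.temperature, rh=exhaust.rh)
    mechanism = "HET" if scenario == "NUHET" else "BHN"
    j_no2 = 8.0e-3 if (event.is_daytime and not event.is_winter) else (
        2.0e-3 if event.is_daytime else 0.0
    )

    t = params.t0
    state = exhaust.copy()
    gas = gases.copy()
    times = [t]
    states = [equilibrate_water(state)]
    gas_records = [gas.copy()]
    next_output = t + output_interval
    n_steps = int(round((duration - params.t0) / dt))
    t_ambient = event.air_temperature

    for istep in range(n_steps):
        if flags.chemistry:
            gas = gas_step(gas, background_gases, params.b, t, dt, j_no2=j_no2)
        else:
            gas.time = t + dt
        if flags.nucleation:
            _apply_nucleation(state, gas, mechanism, dt)
        if flags.condensation:
            state, gas = condensation_step(state, gas, dt)
        if flags.coagulation:
            state = coagulation_step(state, dt)
        if flags.deposition:
            h_p = plume_height(t, event.wind_speed, params)
            state = dry_deposition_step(state, dt, h_p)
        if flags.dilution:
            state = background_mixing_step(state, background, params.b, t, dt)
        t += dt
        # plume temperature relaxes toward ambient with the dilution timescale
        if abs(state.temperature - t_ambient) > 1e-6:
            factor = (t / (t - dt)) ** (-params.b)
            new_t = t_ambient + (state.temperature - t_ambient) * factor
            state.temperature = new_t
            gas.temperature = new_t
        if istep % 100 == 99:
            try:
                state.validate()
                gas.validate()
            except FloatingPointError as err:
                raise FloatingPointError(
                    f"unphysical state at t={t:.1f} s ({scenario}): {err}"
                ) from err
        if t >= next_output - 1e-9:
            times.append(t)
            states.append(equilibrate_water(state))
            gas_records.append(gas.copy())
            next_output += output_interval

    return PlumeTrajectory(
        times=np.array(times),
        states=states,
        gases=gas_records,
        wind_speed=event.wind_speed,
        params=params,
        event=event,
        scenario=scenario,
        background=background,
    )


def _apply_nucleation(state: AerosolState, gas: GasState, mechanism: str, dt: float) -> None:
    """Insert freshly nucleated clusters into the sectional state (in place)."""
    res = nucleation_rate(
        min(max(state.temperature, 190.0), 400.0),
        min(max(state.rh, 0.1), 100.0),
        gas["H2SO4"],
        mechanism=mechanism,
        organic=gas["C34H70"],
    )
    if res.rate <= 0.0:
        return
    dn = res.rate * dt  # particles cm^-3 formed this step
    acid_per_cluster = res.n_molecules * res.acid_mole_fraction
    need_acid = dn * acid_per_cluster
    if need_acid > gas["H2SO4"]:
        dn *= gas["H2SO4"] / need_acid
        need_acid = gas["H2SO4"]
    sec = state.grid.section_of(
        min(max(res.cluster_diameter_nm, state.grid.d_min_nm), state.grid.d_max_nm)
    )
    sulf_mass = need_acid * 98.1 / AVOGADRO * 1e12  # µg m^-3
    state.number[sec] += dn
    state.mass[COMPONENTS.index("sulfate"), sec] += sulf_mass
    gas["H2SO4"] -= need_acid
    org_frac = res.composition.get("elv_om", 0.0)
    if org_frac > 0.0:
        org_mass = sulf_mass * org_frac / max(res.composition.get("sulfate", 1.0), 1e-12)
        org_molecules = org_mass / (478.9 / AVOGADRO * 1e12)
        org_molecules = min(org_molecules, gas["C34H70"])
        state.mass[COMPONENTS.index("elv_om"), sec] += org_molecules * 478.9 / AVOGADRO * 1e12
        gas["C34H70"] -= org_molecules


def simulate_event(
    event: ShipEvent | str,
    scenario: str = "base",
    duration: float = 900.0,
    dt: float = 0.1,
    grid: SizeGrid | None = None,
    output_interval: float = 1.0,
    flags: ProcessFlags | None = None,
    total_pn: float = DEFAULT_EXHAUST_TOTAL_PN,
) -> PlumeTrajectory:
    """Convenience wrapper: build event initial conditions and simulate."""
    if isinstance(event, str):
        event = make_event(event)
    exhaust, gases, background, bg_gas, params = initial_conditions(
        event, scenario, grid=grid, total_pn=total_pn
    )
    return simulate_plume(
        exhaust,
        gases,
        event,
        params,
        background=background,
        background_gases=bg_gas,
        scenario=scenario,
        duration=duration,
        dt=dt,
        output_interval=output_interval,
        flags=flags,
    )


# --------------------------------------------------------------------------
# diagnostics
# --------------------------------------------------------------------------
def mass_fractions(masses: dict[str, float]) -> dict[str, float]:
    """Normalize a component-mass mapping to fractions summing to 1."""
    total = sum(masses.values())
    if total <= 0:
        return {k: 0.0 for k in masses}
    return {k: v / total for k, v in masses.items()}


def summarize(traj: PlumeTrajectory, t: float) -> dict:
    """Standard diagnostics of the plume state at travel time ``t``.

    Returns nucleation-size number (Dp < 25 nm), Aitken/accumulation
    ultrafine number (25–100 nm), total particle number, the diameter of the
    freshly nucleated mode (if identifiable), per-component ultrafine dry
    mass and dry-mass fractions, and the ultrafine water mass fraction.
    """
    state = traj.state_at(t)
    grid = state.grid
    ufp_mask = grid.mask_below(100.0)
    np_mask = grid.mask_below(25.0)
    dry = {
        comp: float(state.mass[COMPONENTS.index(comp), ufp_mask].sum())
        for comp in DRY_COMPONENTS
    }
    np_dry = {
        comp: float(state.mass[COMPONENTS.index(comp), np_mask].sum())
        for comp in DRY_COMPONENTS
    }
    water = float(state.mass[COMPONENTS.index("water"), ufp_mask].sum())
    wet_total = sum(dry.values()) + water
    return {
        "time": float(traj.times[traj.index_at(t)]),
        "np_number": state.number_below(25.0),
        "ufp_25_100_number": state.number_between(25.0, 100.0),
        "total_number": state.total_number,
        "nuc1_diameter_nm": _mode_peak_diameter(state, below_nm=4.0),
        "ufp_dry_mass": dry,
        "ufp_dry_fractions": mass_fractions(dry),
        "np_dry_mass": np_dry,
        "np_dry_fractions": mass_fractions(np_dry),
        "water_mass_fraction": water / wet_total if wet_total > 0 else 0.0,
    }


def _mode_peak_diameter(state: AerosolState, below_nm: float = 4.0) -> float | None:
    """Interpolated peak diameter of the sub-``below_nm`` (fresh) mode, nm."""
    grid = state.grid
    mask = grid.centers_nm < below_nm
    idx = np.where(mask)[0]
    if len(idx) < 3:
        return None
    dndlog = state.number[idx] / grid.dlog10d[idx]
    if dndlog.max() <= 0:
        return None
    m = int(np.argmax(dndlog))
    # require a genuine local maximum (falling off on the large side)
    if m == len(idx) - 1:
        return None
    logd = np.log10(grid.centers_nm[idx])
    if 0 < m < len(idx) - 1:
        y0, y1, y2 = dndlog[m - 1], dndlog[m], dndlog[m + 1]
        denom = y0 - 2 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        shift = float(np.clip(shift, -0.5, 0.5))
        return float(10 ** (logd[m] + shift * (logd[1] - logd[0])))
    return float(10 ** logd[m])


def growth_rate(
    traj: PlumeTrajectory,
    window: tuple[float, float] = (30.0, 900.0),
    below_nm: float = 15.0,
) -> float | None:
    """Growth rate of the nucleation-size mode, nm h^-1.

    The peak diameter of the sub-``below_nm`` spectrum (parabola-interpolated
    on the log-diameter grid) is fitted linearly against time over
    ``window``; the slope is returned in nm per hour. The window starts after
    the initial vapor burst by default, so the rate describes the slow,
    vapor-limited growth phase that measured plume growth rates refer to.
    Returns None (with a warning) when fewer than five snapshots show an
    identifiable mode.
    """
    import warnings as _warnings

    ts, ds = [], []
    for t, state in zip(traj.times, traj.states):
        if not window[0] <= t <= window[1]:
            continue
        d = _mode_peak_diameter(state, below_nm=below_nm)
        if d is not None:
            ts.append(t)
            ds.append(d)
    if len(ts) < 5:
        _warnings.warn("no identifiable nucleation-size mode; growth rate undefined")
        return None
    slope = np.polyfit(ts, ds, 1)[0]  # nm s^-1
    return float(slope * 3600.0)
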