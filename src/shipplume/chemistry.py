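"""Reduced in-plume gas-phase chemistry.

Only the processes that control the condensable-vapor supply and the
plume/background gas exchange are kept:

* fast hydration of co-emitted SO3 to H2SO4 (pseudo-first-order),
* OH-driven oxidation of SO2 to H2SO4 (termolecular rate),
* the NO–NO2–O3 photostationary state (PSSA), and
* the power-law mixing of every gas toward its background value.

OH is prescribed (daytime plumes reach 1–5 x 10^6 cm^-3 from O3 photolysis;
dark winter events sit near 1 x 10^4 cm^-3) rather than computed from a full
photochemical mechanism. Gases are carried as molecules cm^-3.
"""

from __future__ import annotations

import math

import numpy as np

from .dilution import dilution_tendency
from .events import ShipEvent
from .state import GAS_SPECIES, GasState

__all__ = [
    "rate_no_o3",
    "rate_so2_oh",
    "photostationary_state",
    "h2so4_production_step",
    "oh_level",
    "gas_step",
    "SO3_HYDRATION_RATE",
    "OH_DAYTIME",
    "OH_NIGHTTIME",
]

#: pseudo-first-order SO3 + H2O -> H2SO4 rate at ambient humidity (s^-1);
#: fast relative to dilution, so essentially all SO3 converts within ~1 s
SO3_HYDRATION_RATE = 5.0

#: prescribed OH levels (molecules cm^-3)
OH_DAYTIME = 3.0e6
OH_NIGHTTIME = 1.0e4

_AIR_NUMBER_DENSITY_298 = 2.46e19  # molecules cm^-3 at 298 K, 1 atm


def _air_density(temperature: float) -> float:
    return _AIR_NUMBER_DENSITY_298 * 298.15 / temperature


def rate_no_o3(temperature: float) -> float:
    """NO + O3 -> NO2 rate coefficient, cm^3 s^-1 (Arrhenius)."""
    return 3.0e-12 * math.exp(-1500.0 / temperature)


def rate_so2_oh(temperature: float) -> float:
    """Effective SO2 + OH termolecular rate coefficient at 1 atm, cm^3 s^-1."""
    m = _air_density(temperature)
    k0 = 3.3e-31 * (300.0 / temperature) ** 4.3 * m
    kinf = 1.6e-12
    ratio = k0 / kinf
    broadening = 0.6 ** (1.0 / (1.0 + math.log10(ratio) ** 2))
    return k0 / (1.0 + ratio) * broadening


def photostationary_state(
    no: float, no2: float, o3: float, j_no2: float, temperature: float
) -> tuple[float, float, float]:
    """Repartition NO/NO2/O3 to the photostationary state.

    Conserves total NOx (NO + NO2) and total oxidant (O3 + NO2). At
    j_NO2 = 0 the O3 titrates NO to NO2 up to the limiting reagent. The PSS
    solves j*[NO2] = k*[NO]*[O3] as a quadratic in the NO2 concentration.
    """
    if min(no, no2, o3) < 0:
        raise ValueError("concentrations must be nonnegative")
    nox = no + no2
    oxidant = o3 + no2
    k = rate_no_o3(temperature)
    if j_no2 <= 0:
        x = min(nox, oxidant)  # full titration
    else:
        # k*(nox - x)*(ox - x) = j*x
        a, b, c = k, -(k * (nox + oxidant) + j_no2), k * nox * oxidant
        disc = b * b - 4 * a * c
        x = (-b - math.sqrt(max(disc, 0.0))) / (2 * a)
        x = min(max(x, 0.0), min(nox, oxidant))
    return nox - x, x, oxidant - x


def h2so4_production_step(state: GasState, dt: float) -> GasState:
    """Advance SO3 hydration and SO2 + OH oxidation by ``dt``.

    Sulfur is conserved exactly across SO2 + SO3 + H2SO4 (condensation and
    nucleation sinks act on the returned H2SO4 elsewhere).
    """
    if dt > 0.1:
        raise ValueError("chemistry step limited to dt <= 0.1 s")
    out = state.copy()
    # SO3 + H2O -> H2SO4, exact exponential decay over the step
    so3 = state["SO3"]
    converted = so3 * (1.0 - math.exp(-SO3_HYDRATION_RATE * dt))
    out["SO3"] = so3 - converted
    # SO2 + OH -> ... -> H2SO4 (OH prescribed, not consumed)
    k = rate_so2_oh(state.temperature)
    so2 = state["SO2"]
    oxidized = so2 * (1.0 - math.exp(-k * state["OH"] * dt))
    out["SO2"] = so2 - oxidized
    out["H2SO4"] = state["H2SO4"] + converted + oxidized
    return out


def oh_level(event: ShipEvent, t: float = 0.0) -> float:
    """Prescribed OH concentration for an event (molecules cm^-3)."""
    return OH_DAYTIME if event.is_daytime else OH_NIGHTTIME


def gas_step(
    state: GasState,
    background: GasState,
    b: float,
    t: float,
    dt: float,
    j_no2: float = 0.0,
) -> GasState:
    """One plume gas step: chemistry, PSSA, then dilution toward background.

    Emitted gases decay toward their background values; background O3
    entrains (rises toward background). Background composition is treated as
    chemically unreactive on the step timescale.
    """
    out = h2so4_production_step(state, dt)
    no, no2, o3 = photostationary_state(
        out["NO"], out["NO2"], out["O3"], j_no2, out.temperature
    )
    out["NO"], out["NO2"], out["O3"] = no, no2, o3
    for sp in GAS_SPECIES:
        if sp == "OH":
            continue  # prescribed
        tendency = float(dilution_tendency(out[sp], background[sp], b, t))
        new = out[sp] + dt * tendency
        # exact-relaxation guard: the explicit step must not cross background
        lo, hi = sorted((out[sp], background[sp]))
        out[sp] = min(max(new, lo), hi)
    out.time = t + dt
    out.validate()
    return out
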