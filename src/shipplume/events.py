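"""Ship-event records: per-event meteorology and derived classifications.

Fourteen monitored arrival/departure events of ROPAX ferries in the harbors
of Helsinki (sites H*) and Turku (sites T*), winter and summer 2010–2011.
Each record carries the event-averaged meteorology; the atmospheric
stability class and the day/night flag are derived from wind speed, season,
and time of day (the full boundary-layer diagnosis of the dispersion model
is outside this package's scope — the mapping is documented in the default
config).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time

__all__ = ["ShipEvent", "EVENT_TABLE", "make_event", "list_events"]


@dataclass(frozen=True)
class ShipEvent:
    """One monitored ship arrival/departure with event-mean meteorology."""

    event_id: str
    site: str
    direction: str  # "arr" or "dep"
    start: datetime
    end: datetime
    air_temperature: float  # K
    relative_humidity: float  # %
    wind_speed: float  # m s^-1
    wind_direction: float  # degrees
    emission_rates: dict[str, float] = field(default_factory=dict)  # species -> s^-1 units

    def __post_init__(self) -> None:
        if not 200.0 < self.air_temperature < 330.0:
            raise ValueError("air temperature out of plausible range")
        if not 0.0 <= self.relative_humidity <= 100.0:
            raise ValueError("relative humidity must be in [0, 100]")
        if self.wind_speed < 0:
            raise ValueError("wind speed must be nonnegative")
        if not 0.0 <= self.wind_direction < 360.0:
            raise ValueError("wind direction must be in [0, 360)")

    # -- derived classifications ---------------------------------------------
    @property
    def is_winter(self) -> bool:
        return self.start.month in (11, 12, 1, 2, 3)

    @property
    def is_daytime(self) -> bool:
        """Crude daylight flag for high-latitude harbors.

        Winter daylight window 9–16 local, otherwise 7–19.
        """
        h = self.start.hour
        return (9 <= h < 16) if self.is_winter else (7 <= h < 19)

    @property
    def stability_class(self) -> str:
        """Stability from wind speed and time of day.

        U >= 4 m/s in daytime -> unstable; 2–4 m/s -> neutral; U < 2 m/s or a
        winter early morning -> stable.
        """
        if self.wind_speed < 2.0 or (self.is_winter and self.start.hour < 9):
            return "stable"
        if self.wind_speed >= 4.0 and self.is_daytime:
            return "unstable"
        return "neutral"


#: representative per-event emission rates for a ROPAX ferry (order of
#: magnitude values: NOx and SOx in g s^-1, particle number in s^-1)
_DEFAULT_EMISSIONS = {"NOx": 30.0, "SOx": 10.0, "PN": 1.0e16}

# event-averaged meteorology per event:
# (site, direction, start, end, T_A (K), RH (%), U (m/s), WD (deg))
EVENT_TABLE: dict[str, tuple] = {
    "A_20110111": ("H2", "dep", "11:25", "11:55", 271, 90, 4.3, 289),
    "A_20110912": ("H1", "dep", "11:30", "11:47", 290, 73, 6.3, 130),
    "A_20110913": ("H2", "dep", "11:20", "11:45", 290, 82, 4.8, 213),
    "B_20100803": ("H7", "dep", "18:30", "18:40", 292, 80, 5.4, 145),
    "D_20110111": ("H2", "dep", "17:30", "17:50", 274, 81, 5.1, 232),
    "D_20110908": ("H2", "dep", "17:25", "17:50", 289, 78, 2.0, 187),
    "H_20100811": ("T8", "dep", "08:40", "08:50", 292, 71, 5.5, 249),
    "H_20100817": ("T2", "dep", "08:30", "08:40", 289, 69, 3.5, 173),
    "I_20100812": ("T2", "arr", "19:18", "19:35", 295, 61, 3.0, 233),
    "I_20110207": ("T7", "arr", "19:20", "19:30", 272, 94, 3.6, 250),
    "J_20100811": ("T7", "dep", "09:00", "09:10", 292, 72, 4.6, 219),
    "J_20100817": ("T4", "dep", "09:00", "09:10", 290, 65, 5.7, 47),
    "J_20110217": ("T2", "arr", "07:00", "07:25", 258, 79, 2.4, 175),
    "K_20110802": ("T6", "arr", "20:00", "20:30", 293, 49, 0.8, 34),
}


def list_events() -> list[str]:
    return sorted(EVENT_TABLE)


def make_event(event_id: str) -> ShipEvent:
    """Build a :class:`ShipEvent` from one of the named harbor events."""
    try:
        site, direction, t0, t1, ta, rh, u, wd = EVENT_TABLE[event_id]
    except KeyError:
        raise KeyError(
            f"unknown event {event_id!r}; known events: {', '.join(list_events())}"
        ) from None
    day = date.fromisoformat(event_id.split("_")[1][:4] + "-" +
                             event_id.split("_")[1][4:6] + "-" +
                             event_id.split("_")[1][6:8])
    return ShipEvent(
        event_id=event_id,
        site=site,
        direction=direction,
        start=datetime.combine(day, time.fromisoformat(t0)),
        end=datetime.combine(day, time.fromisoformat(t1)),
        air_temperature=float(ta),
        relative_humidity=float(rh),
        wind_speed=float(u),
        wind_direction=float(wd),
        emission_rates=dict(_DEFAULT_EMISSIONS),
    )
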