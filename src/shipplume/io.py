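"""File I/O: CSV distributions, NetCDF trajectories, JSON manifests."""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .grids import SizeGrid
from .state import AerosolState, COMPONENTS
from .simulate import PlumeTrajectory

__all__ = [
    "distribution_to_frame",
    "write_distribution_csv",
    "read_distribution_csv",
    "write_trajectory_netcdf",
    "write_summary_csv",
    "write_manifest",
]


def distribution_to_frame(state: AerosolState) -> pd.DataFrame:
    """Sectional state as a tidy table (one row per section)."""
    df = pd.DataFrame({"bin_center_nm": state.grid.centers_nm, "dN": state.number})
    for i, comp in enumerate(COMPONENTS):
        df[f"mass_{comp}"] = state.mass[i]
    return df


def write_distribution_csv(state: AerosolState, path: str | Path) -> Path:
    path = Path(path)
    distribution_to_frame(state).to_csv(path, index=False)
    return path


def read_distribution_csv(path: str | Path, grid: SizeGrid | None = None) -> AerosolState:
    df = pd.read_csv(path)
    grid = grid or SizeGrid(n_sections=len(df))
    if len(df) != grid.n_sections:
        raise ValueError("CSV row count does not match the size grid")
    state = AerosolState.empty(grid)
    state.number = df["dN"].to_numpy(dtype=float)
    for i, comp in enumerate(COMPONENTS):
        col = f"mass_{comp}"
        if col in df:
            state.mass[i] = df[col].to_numpy(dtype=float)
    return state


def write_trajectory_netcdf(traj: PlumeTrajectory, path: str | Path) -> Path:
    """Trajectory as NetCDF3 (scipy backend, dims time/section/component)."""
    path = Path(path)
    traj.to_dataset().to_netcdf(path, engine="scipy")
    return path


def write_summary_csv(
    traj: PlumeTrajectory, path: str | Path, travel_times: tuple[float, ...] = (1, 30, 120, 300)
) -> Path:
    """Composition summary table at standard travel times."""
    from .simulate import summarize

    rows = []
    for t in travel_times:
        s = summarize(traj, t)
        row = {
            "travel_time_s": s["time"],
            "np_number_cm3": s["np_number"],
            "ufp_25_100_number_cm3": s["ufp_25_100_number"],
            "total_number_cm3": s["total_number"],
            "water_mass_fraction": s["water_mass_fraction"],
        }
        for comp, m in s["ufp_dry_mass"].items():
            row[f"mass_{comp}_ugm3"] = m
        for comp, f in s["ufp_dry_fractions"].items():
            row[f"fraction_{comp}"] = f
        rows.append(row)
    df = pd.DataFrame(rows)
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.6g")
    return path


def write_manifest(path: str | Path, config_hash: str, seed: int, outputs: dict[str, str]) -> Path:
    """JSON manifest recording provenance of a run."""
    manifest = {
        "package": "shipplume",
        "version": __version__,
        "config_hash": config_hash,
        "seed": seed,
        "created_utc": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "outputs": outputs,
    }
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
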