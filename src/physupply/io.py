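"""Trajectory serialization: per-year summary tables as CSV or JSON."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .demography import PopulationProjection, density_per_100k, population_at
from .scenarios import Trajectory

__all__ = ["trajectory_frame", "write_trajectory", "read_trajectory"]


def trajectory_frame(
    trajectory: Trajectory,
    projection: PopulationProjection | None = None,
    bin_width: int = 5,
) -> pd.DataFrame:
    """Per-year summary with an added per-100k density column when a
    population projection covering the horizon is supplied."""
    frame = trajectory.summary(bin_width)
    if projection is not None:
        frame["density_per_100k"] = [
            density_per_100k(count, population_at(projection, year))
            for year, count in frame["physicians"].items()
        ]
    return frame


def write_trajectory(
    trajectory: Trajectory,
    path: str | Path,
    format: str = "csv",
    projection: PopulationProjection | None = None,
    bin_width: int = 5,
) -> Path:
    """Write one row per simulated year (baseline included).

    Columns: year, every stock level, the physician head-count, density
    (if a projection is given), every flow, and the 5-year age bins.
    The file reads back losslessly at float precision.
    """
    path = Path(path)
    frame = trajectory_frame(trajectory, projection, bin_width)
    if format == "csv":
        frame.to_csv(path, float_format="%.9f")
    elif format == "json":
        payload = {
            "scenario": trajectory.scenario.name,
            "years": [int(y) for y in frame.index],
            "columns": {col: [float(v) for v in frame[col]] for col in frame.columns},
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError(f"format must be 'csv' or 'json', got '{format}'")
    return path


def read_trajectory(path: str | Path, format: str = "csv") -> pd.DataFrame:
    """Read a summary written by :func:`write_trajectory`."""
    path = Path(path)
    if format == "csv":
        return pd.read_csv(path, index_col="year")
    if format == "json":
        payload = json.loads(path.read_text())
        frame = pd.DataFrame(payload["columns"], index=payload["years"])
        frame.index.name = "year"
        return frame
    raise ValueError(f"format must be 'csv' or 'json', got '{format}'")
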