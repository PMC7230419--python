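"""Population projections and per-capita physician densities.

The model consumes external demographic projections; it does not build
them. A projection is a set of year -> population anchors with linear
interpolation in between, used only to convert head-counts to
physicians per 100 000 inhabitants (the unit in which national supply
is benchmarked; the EU-average reference level is 360).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping

import numpy as np

__all__ = ["PopulationProjection", "population_at", "density_per_100k"]


@dataclass(frozen=True)
class PopulationProjection:
    """Piecewise-linear population trajectory through fixed anchors."""

    anchors: Mapping[int, float]

    def __post_init__(self) -> None:
        if not self.anchors:
            raise ValueError("projection needs at least one anchor")
        for year, pop in self.anchors.items():
            if pop <= 0:
                raise ValueError(f"population must be positive, got {pop} for {year}")

    @property
    def start_year(self) -> int:
        return min(self.anchors)

    @property
    def end_year(self) -> int:
        return max(self.anchors)

    def covers(self, start_year: int, end_year: int) -> bool:
        return self.start_year <= start_year and self.end_year >= end_year


def population_at(projection: PopulationProjection, year: int | float) -> float:
    """Population in ``year``: exact at anchors, linear in between."""
    if not projection.start_year <= year <= projection.end_year:
        raise ValueError(
            f"year {year} outside the anchor range "
            f"[{projection.start_year}, {projection.end_year}]"
        )
    years = np.array(sorted(projection.anchors), dtype=float)
    pops = np.array([projection.anchors[int(y)] for y in years], dtype=float)
    return float(np.interp(year, years, pops))


def density_per_100k(count: float, population: float) -> float:
    """Physicians per 100 000 inhabitants (unrounded; round for reports)."""
    if population <= 0:
        raise ValueError(f"population must be positive, got {population}")
    return count / population * 100_000.0
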