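"""Named policy scenarios: definition, simulation, comparison.

A scenario is a parameter overlay — enrollment and ST-license schedules
over a horizon — run deterministically from a common baseline. Reported
yearly values are end-of-year states; "the 2041 count" is the state
after the update of calendar year 2041.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List

import pandas as pd

from .model import (
    ModelParameters,
    Schedule,
    WorkforceState,
    age_distribution_report,
    annual_update,
    count_physicians,
)
from .sd_core import FlowLedger

__all__ = [
    "Scenario",
    "Trajectory",
    "scenario_1",
    "scenario_2",
    "run_scenario",
    "compare_scenarios",
]


@dataclass(frozen=True)
class Scenario:
    """A named policy overlay over the baseline parameterization."""

    name: str
    enrollment_schedule: Schedule = field(default_factory=lambda: Schedule.constant(590.0))
    license_schedule: Schedule = field(default_factory=lambda: Schedule.constant(450.0))
    start_year: int = 2017
    end_year: int = 2041

    def __post_init__(self) -> None:
        if self.end_year <= self.start_year:
            raise ValueError(
                f"end_year ({self.end_year}) must exceed start_year ({self.start_year})"
            )
        for label, schedule in (
            ("enrollment_schedule", self.enrollment_schedule),
            ("license_schedule", self.license_schedule),
        ):
            if not schedule.defined_on(self.start_year, self.end_year):
                raise ValueError(f"{label} is not defined over the whole horizon")


def scenario_1(end_year: int = 2041) -> Scenario:
    """Status quo: 590 enrolled and 450 ST licenses per year."""
    return Scenario(
        name="scenario-1",
        enrollment_schedule=Schedule.constant(590.0),
        license_schedule=Schedule.constant(450.0),
        end_year=end_year,
    )


def scenario_2(end_year: int = 2041) -> Scenario:
    """Expanded training: 590 enrolled; ST licenses raised to 550 from 2020."""
    return Scenario(
        name="scenario-2",
        enrollment_schedule=Schedule.constant(590.0),
        license_schedule=Schedule({2017: 450.0, 2020: 550.0}),
        end_year=end_year,
    )


@dataclass(frozen=True)
class Trajectory:
    """A simulated run: states, per-year flow ledgers, summary table."""

    scenario: Scenario
    states: List[WorkforceState]
    ledgers: List[FlowLedger]

    @property
    def years(self) -> List[int]:
        return [s.year for s in self.states]

    def physician_counts(self) -> pd.Series:
        counts = pd.Series(
            {s.year: count_physicians(s) for s in self.states}, name="physicians"
        )
        counts.index.name = "year"
        return counts

    def summary(self, bin_width: int = 5) -> pd.DataFrame:
        """Per-year table: stocks, physician head-count, flows, age bins."""
        rows = []
        flow_names = list(FlowLedger().as_dict())
        for i, s in enumerate(self.states):
            row: Dict[str, float] = {"year": s.year}
            for stock in ("students", "waiting", "on_st", "specialists", "gps_no_st", "outside_care"):
                row[stock] = s.stock_level(stock)
            row["physicians"] = count_physicians(s)
            flows = self.ledgers[i - 1].as_dict() if i > 0 else dict.fromkeys(flow_names, 0.0)
            for name in flow_names:
                row[f"flow_{name}"] = flows[name]
            for label, count in age_distribution_report(s, bin_width).items():
                row[f"age_{label}"] = count
            rows.append(row)
        frame = pd.DataFrame(rows).fillna(0.0)
        return frame.set_index("year")


def run_scenario(
    scenario: Scenario,
    params: ModelParameters,
    init: WorkforceState,
) -> Trajectory:
    """Simulate a scenario over its horizon. Deterministic."""
    if init.year != scenario.start_year:
        raise ValueError(
            f"initial state is for {init.year}, scenario starts in {scenario.start_year}"
        )
    states = [init]
    ledgers: List[FlowLedger] = []
    state = init
    for year in range(scenario.start_year + 1, scenario.end_year + 1):
        year_params = replace(
            params,
            enrollment=scenario.enrollment_schedule(year),
            license_schedule=scenario.license_schedule,
        )
        state, ledger = annual_update(state, year_params)
        states.append(state)
        ledgers.append(ledger)
    return Trajectory(scenario=scenario, states=states, ledgers=ledgers)


def compare_scenarios(a: Trajectory, b: Trajectory, bin_width: int = 5) -> pd.DataFrame:
    """Per-year differences (a − b) of physician counts and age bins.

    Antisymmetric by construction; horizons must match.
    """
    if a.years != b.years:
        raise ValueError("trajectories cover different year ranges")
    sa, sb = a.summary(bin_width), b.summary(bin_width)
    age_cols = sorted(
        {c for c in sa.columns if c.startswith("age_")}
        | {c for c in sb.columns if c.startswith("age_")}
    )
    cols = ["physicians", "specialists"] + age_cols
    sa = sa.reindex(columns=cols, fill_value=0.0)
    sb = sb.reindex(columns=cols, fill_value=0.0)
    return sa - sb
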