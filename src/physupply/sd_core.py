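"""Generic discrete-time stock-and-flow machinery.

Three building blocks recur in compartmental workforce models:

* a *conveyor* — a stock with a fixed transit time (a training stage):
  material entering now exits after exactly ``duration`` annual steps,
  optionally leaking a fraction each step (drop-out during the stage);
* an *aging chain* — a stock disaggregated by single year of age whose
  contents advance one age per step, shedding a proportional attrition
  flow and retiring every cohort that reaches the retirement age in force
  that calendar year;
* a *flow ledger* — the named per-year flows of one simulated year, kept
  so that mass balance (persons in == persons out + change in content)
  can be audited after the fact.

Everything here is deterministic, synchronous (all flows are computed
from start-of-year stocks and applied together) and continuous-valued:
persons are fractional internally and rounded only in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Callable, Dict, Mapping, Tuple

import pandas as pd

__all__ = [
    "Conveyor",
    "AgingChain",
    "FlowLedger",
    "conveyor_step",
    "aging_chain_step",
    "mass_balance_audit",
    "STOCK_FLOW_MAP",
]

#: Audit tolerance for per-step conservation, in persons.
CONSERVATION_TOL = 1e-9


@dataclass(frozen=True)
class Conveyor:
    """A fixed-duration pipeline stock with optional per-step leakage.

    ``cohorts[i]`` holds the persons that entered ``i`` steps ago;
    ``cohorts[-1]`` exits at the next step. ``leak_rate`` is the fraction
    of every cohort lost per step (applied before advancement, so a unit
    entering the conveyor is leaked exactly ``duration`` times before it
    exits).
    """

    duration: int
    cohorts: Tuple[float, ...]
    leak_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.duration < 1:
            raise ValueError(f"duration must be >= 1, got {self.duration}")
        if len(self.cohorts) != self.duration:
            raise ValueError(
                f"conveyor needs {self.duration} cohort slots, got {len(self.cohorts)}"
            )
        if not 0.0 <= self.leak_rate < 1.0:
            raise ValueError(f"leak_rate must be in [0, 1), got {self.leak_rate}")
        if any(c < 0 for c in self.cohorts):
            raise ValueError("conveyor cohorts must be non-negative")

    @property
    def content(self) -> float:
        """Total persons currently in transit."""
        return float(sum(self.cohorts))

    @classmethod
    def uniform(cls, total: float, duration: int, leak_rate: float = 0.0) -> "Conveyor":
        """Spread ``total`` persons evenly across the transit slots.

        Used to initialise a stage whose internal cohort composition is
        unknown at baseline.
        """
        if total < 0:
            raise ValueError(f"total must be non-negative, got {total}")
        return cls(duration=duration, cohorts=(total / duration,) * duration, leak_rate=leak_rate)

    @classmethod
    def empty(cls, duration: int, leak_rate: float = 0.0) -> "Conveyor":
        return cls(duration=duration, cohorts=(0.0,) * duration, leak_rate=leak_rate)


def conveyor_step(conveyor: Conveyor, inflow: float) -> Tuple[Conveyor, float, float]:
    """Advance a conveyor one step.

    Each cohort loses ``leak_rate`` of its content, then advances one
    slot; the final cohort exits as outflow and ``inflow`` occupies the
    first slot.

    Returns ``(new_conveyor, outflow, leaked)`` with the conservation
    guarantee ``new.content + outflow + leaked == old.content + inflow``
    to within 1e-9 persons.
    """
    if inflow < 0:
        raise ValueError(f"conveyor inflow must be non-negative, got {inflow}")
    survive = 1.0 - conveyor.leak_rate
    after_leak = [c * survive for c in conveyor.cohorts]
    leaked = conveyor.content - sum(after_leak)
    outflow = after_leak[-1]
    new_cohorts = (inflow, *after_leak[:-1])
    new = replace(conveyor, cohorts=new_cohorts)
    assert abs(new.content + outflow + leaked - (conveyor.content + inflow)) < CONSERVATION_TOL
    return new, outflow, leaked


@dataclass(frozen=True)
class AgingChain:
    """A stock disaggregated by single year of age, driving retirement.

    ``retirement_age_fn`` maps a calendar year to the retirement age in
    force that year, so statutory changes (a retirement-age extension)
    enter as data, not code.
    """

    counts_by_age: Mapping[int, float]
    entry_age: int
    retirement_age_fn: Callable[[int], int]

    def __post_init__(self) -> None:
        for age, count in self.counts_by_age.items():
            if count < 0:
                raise ValueError(f"negative count {count} at age {age}")

    @property
    def total(self) -> float:
        return float(sum(self.counts_by_age.values()))

    def binned(self, bin_width: int = 5) -> Dict[str, float]:
        """Aggregate to age bins aligned at multiples of ``bin_width``.

        Bin totals conserve the chain total exactly (same additions, no
        rounding).
        """
        if bin_width < 1:
            raise ValueError(f"bin_width must be >= 1, got {bin_width}")
        out: Dict[str, float] = {}
        for age, count in sorted(self.counts_by_age.items()):
            lo = age - age % bin_width
            label = f"{lo}-{lo + bin_width - 1}"
            out[label] = out.get(label, 0.0) + count
        return out


def aging_chain_step(
    chain: AgingChain,
    entries: float,
    attrition_rate: float,
    year: int,
) -> Tuple[AgingChain, float, float]:
    """Advance an aging chain one calendar year.

    Order of operations (the contract, stated exactly): every age count
    loses ``attrition_rate``; survivors age one year; counts at or above
    ``retirement_age_fn(year)`` exit as retirees; ``entries`` join at the
    entry age. Entries therefore suffer no attrition in their entry year.

    Returns ``(new_chain, retirees, attrition_losses)``.
    """
    if not 0.0 <= attrition_rate < 1.0:
        raise ValueError(f"attrition_rate must be in [0, 1), got {attrition_rate}")
    if entries < 0:
        raise ValueError(f"entries must be non-negative, got {entries}")
    retirement_age = chain.retirement_age_fn(year)
    survive = 1.0 - attrition_rate
    new_counts: Dict[int, float] = {}
    retirees = 0.0
    losses = 0.0
    for age, count in chain.counts_by_age.items():
        kept = count * survive
        losses += count - kept
        new_age = age + 1
        if new_age >= retirement_age:
            retirees += kept
        elif kept > 0.0:
            new_counts[new_age] = new_counts.get(new_age, 0.0) + kept
    if entries > 0.0:
        new_counts[chain.entry_age] = new_counts.get(chain.entry_age, 0.0) + entries
    new = replace(chain, counts_by_age=new_counts)
    assert abs(new.total - (chain.total + entries - retirees - losses)) < CONSERVATION_TOL
    return new, retirees, losses


@dataclass(frozen=True)
class FlowLedger:
    """Every named flow of one simulated year, in persons/year."""

    enrollment: float = 0.0
    graduations: float = 0.0
    student_dropout: float = 0.0
    immigration: float = 0.0
    waiting_emigration: float = 0.0
    waiting_other: float = 0.0
    st_starts: float = 0.0
    st_dropout: float = 0.0
    st_completions: float = 0.0
    specialist_attrition: float = 0.0
    specialist_retirement: float = 0.0
    gp_retirement: float = 0.0
    outside_retirement: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"flow {f.name} must be non-negative, got {v}")

    def as_dict(self) -> Dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}


#: Sign convention of each flow for each stock: +1 inflow, -1 outflow.
STOCK_FLOW_MAP: Dict[str, Dict[str, int]] = {
    "students": {"enrollment": +1, "graduations": -1, "student_dropout": -1},
    "waiting": {
        "graduations": +1,
        "immigration": +1,
        "waiting_emigration": -1,
        "waiting_other": -1,
        "st_starts": -1,
    },
    "on_st": {"st_starts": +1, "st_dropout": -1, "st_completions": -1},
    "specialists": {
        "st_completions": +1,
        "specialist_attrition": -1,
        "specialist_retirement": -1,
    },
    "gps_no_st": {"gp_retirement": -1},
    "outside_care": {"outside_retirement": -1},
}


def mass_balance_audit(trajectory) -> pd.DataFrame:
    """Conservation audit of a full run.

    For every simulated year and stock, the residual is the change in the
    stock minus (inflows − outflows) recorded in that year's ledger. A
    valid run has all residual magnitudes below 1e-6 persons.

    Returns a DataFrame indexed by year with one column per stock.
    Raises ``ValueError`` naming year and stock if a ledger entry needed
    by a stock is missing.
    """
    states = trajectory.states
    ledgers = trajectory.ledgers
    if len(states) < 2 or len(ledgers) != len(states) - 1:
        raise ValueError(
            "trajectory needs >= 1 transition with one ledger per transition; "
            f"got {len(states)} states and {len(ledgers)} ledgers"
        )
    rows = {}
    for before, after, ledger in zip(states, states[1:], ledgers):
        flows = ledger.as_dict()
        residuals = {}
        for stock, signs in STOCK_FLOW_MAP.items():
            for flow_name in signs:
                if flow_name not in flows:
                    raise ValueError(
                        f"year {after.year}: ledger is missing flow "
                        f"'{flow_name}' required by stock '{stock}'"
                    )
            net = sum(sign * flows[name] for name, sign in signs.items())
            delta = after.stock_level(stock) - before.stock_level(stock)
            residuals[stock] = delta - net
        rows[after.year] = residuals
    frame = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    frame.index.name = "year"
    return frame
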