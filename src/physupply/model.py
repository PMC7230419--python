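"""The physician-supply pipeline: stocks, parameters, one-year update.

The national workforce is modelled as a training pipeline feeding an
aging specialist stock, with two legacy side stocks:

    medical schools (6-y conveyor)
        -> waiting for specialization-training (ST) license (pool)
        -> on ST (5-y conveyor, small per-year drop-out)
        -> specialists (single-year-of-age chain, attrition + retirement)

    GPs without specialization   (drains linearly to retirement)
    MDs outside health care      (drains linearly; not counted as
                                  practicing physicians)

"Physicians" are medical doctors directly providing care: the waiting
pool, those on ST, specialists and GPs without specialization. Students
and MDs outside health care are excluded from the head-count.

All rates are annual; the update is synchronous (flows computed from
start-of-year stocks, applied together); persons are continuous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Mapping, Tuple

from .sd_core import AgingChain, Conveyor, FlowLedger, aging_chain_step, conveyor_step

__all__ = [
    "Schedule",
    "default_retirement_age",
    "ModelParameters",
    "WorkforceState",
    "build_initial_state",
    "graduates",
    "licenses_granted",
    "annual_update",
    "count_physicians",
    "age_distribution_report",
]


class Schedule:
    """A piecewise-constant year -> value mapping.

    Defined by breakpoints: ``Schedule({2017: 450})`` is the constant
    450; ``Schedule({2017: 450, 2020: 550})`` is 450 for 2017-2019 and
    550 from 2020 on. Years before the first breakpoint raise.
    """

    def __init__(self, breakpoints: Mapping[int, float]):
        if not breakpoints:
            raise ValueError("schedule needs at least one breakpoint")
        self._steps = sorted((int(y), float(v)) for y, v in breakpoints.items())

    @classmethod
    def constant(cls, value: float) -> "Schedule":
        return cls({-10**9: value})

    def __call__(self, year: int) -> float:
        value = None
        for y, v in self._steps:
            if year >= y:
                value = v
            else:
                break
        if value is None:
            raise ValueError(f"schedule not defined for year {year}")
        return value

    def defined_on(self, start_year: int, end_year: int) -> bool:
        return self._steps[0][0] <= start_year and end_year >= start_year

    def scaled(self, factor: float) -> "Schedule":
        return Schedule({y: v * factor for y, v in self._steps})

    def breakpoints(self) -> Dict[int, float]:
        return dict(self._steps)

    def __eq__(self, other) -> bool:
        return isinstance(other, Schedule) and self._steps == other._steps

    def __repr__(self) -> str:
        return f"Schedule({dict(self._steps)!r})"


def default_retirement_age(year: int) -> int:
    """Statutory retirement age: 65, extended to 67 from 2038."""
    return 67 if year >= 2038 else 65


@dataclass(frozen=True)
class ModelParameters:
    """Every rate, duration and schedule of the model, with the national
    baseline values as defaults.

    Durations are whole years, rates are fractions per year, schedules
    map calendar year to persons/year.
    """

    enrollment: float = 590.0
    study_duration: int = 6
    student_dropout_frac: float = 0.10
    immigrants: float = 20.0
    waiting_emigration_rate: float = 0.05
    waiting_other_outflow: float = 20.0
    license_schedule: Schedule = field(default_factory=lambda: Schedule.constant(450.0))
    st_duration: int = 5
    st_dropout_rate: float = 0.002
    specialist_attrition_rate: float = 0.01
    specialist_entry_age: int = 30
    retirement_age_schedule: Callable[[int], int] = default_retirement_age
    gp_retirement_horizon: int = 20
    outside_care_horizon: int = 35

    def __post_init__(self) -> None:
        for name in (
            "student_dropout_frac",
            "waiting_emigration_rate",
            "st_dropout_rate",
            "specialist_attrition_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1], got {v}")
        for name in ("study_duration", "st_duration", "gp_retirement_horizon", "outside_care_horizon"):
            v = getattr(self, name)
            if v < 1:
                raise ValueError(f"{name} must be >= 1 year, got {v}")
        for name in ("enrollment", "immigrants", "waiting_other_outflow"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")


#: Baseline (2017) stock levels.
BASELINE_STOCKS: Dict[str, float] = {
    "students": 3761.0,
    "waiting": 1246.0,
    "on_st": 2268.0,
    "specialists": 9648.0,
    "gps_no_st": 1232.0,
    "outside_care": 1200.0,
}
BASELINE_YEAR = 2017


@dataclass(frozen=True)
class WorkforceState:
    """All stock levels at one point in time (end of ``year``)."""

    year: int
    students: Conveyor
    waiting: float
    on_st: Conveyor
    specialists: AgingChain
    gps_no_st: float
    outside_care: float
    # Linear drain rates fixed at initialisation (initial stock / horizon).
    gp_drain_per_year: float = 0.0
    outside_drain_per_year: float = 0.0

    def __post_init__(self) -> None:
        if self.waiting < 0 or self.gps_no_st < 0 or self.outside_care < 0:
            raise ValueError("stocks must be non-negative")

    def stock_level(self, name: str) -> float:
        """Scalar level of a named stock (conveyor/chain content summed)."""
        value = getattr(self, name)
        if isinstance(value, Conveyor):
            return value.content
        if isinstance(value, AgingChain):
            return value.total
        return float(value)


def build_initial_state(
    params: ModelParameters,
    specialist_age_distribution: Mapping[int, float],
    *,
    year: int = BASELINE_YEAR,
    stocks: Mapping[str, float] | None = None,
) -> WorkforceState:
    """Assemble a starting state from stock totals and a specialist age
    distribution.

    Conveyor contents are spread uniformly across transit slots (their
    cohort composition at baseline is unobserved). The age distribution
    must sum to the specialist stock within 0.5 persons and lie within
    the working range [entry age, retirement age).
    """
    levels = dict(BASELINE_STOCKS)
    if stocks is not None:
        unknown = set(stocks) - set(levels)
        if unknown:
            raise ValueError(f"unknown stocks: {sorted(unknown)}")
        levels.update(stocks)

    dist_total = float(sum(specialist_age_distribution.values()))
    if abs(dist_total - levels["specialists"]) > 0.5:
        raise ValueError(
            f"age distribution sums to {dist_total:.2f} but the specialist "
            f"stock is {levels['specialists']:.2f}"
        )
    retirement_age = params.retirement_age_schedule(year)
    for age in specialist_age_distribution:
        if not params.specialist_entry_age <= age < retirement_age:
            raise ValueError(
                f"age {age} outside the working range "
                f"[{params.specialist_entry_age}, {retirement_age})"
            )

    chain = AgingChain(
        counts_by_age=dict(specialist_age_distribution),
        entry_age=params.specialist_entry_age,
        retirement_age_fn=params.retirement_age_schedule,
    )
    return WorkforceState(
        year=year,
        students=Conveyor.uniform(levels["students"], params.study_duration),
        waiting=levels["waiting"],
        on_st=Conveyor.uniform(levels["on_st"], params.st_duration, params.st_dropout_rate),
        specialists=chain,
        gps_no_st=levels["gps_no_st"],
        outside_care=levels["outside_care"],
        gp_drain_per_year=levels["gps_no_st"] / params.gp_retirement_horizon,
        outside_drain_per_year=levels["outside_care"] / params.outside_care_horizon,
    )


def graduates(params: ModelParameters) -> float:
    """Steady-state graduate flow: enrollment net of generational drop-out.

    590 enrolled with 10% drop-out gives 531/year ("approximately 530").
    """
    return params.enrollment * (1.0 - params.student_dropout_frac)


def licenses_granted(year: int, params: ModelParameters, waiting: float) -> float:
    """ST licenses actually taken up in ``year``.

    The schedule is capped by the persons still in the waiting pool after
    that year's emigration and constant outflow, and is never negative.
    """
    if waiting < 0:
        raise ValueError(f"waiting stock must be non-negative, got {waiting}")
    emigration = params.waiting_emigration_rate * waiting
    other = min(params.waiting_other_outflow, waiting - emigration)
    available = max(waiting - emigration - other, 0.0)
    return max(min(params.license_schedule(year), available), 0.0)


def annual_update(
    state: WorkforceState, params: ModelParameters
) -> Tuple[WorkforceState, FlowLedger]:
    """Advance the workforce one calendar year.

    The step takes the end-of-year state of ``state.year`` to the end of
    ``state.year + 1``; schedules and the retirement age are evaluated at
    the new year. All flows are computed from start-of-year stocks
    (synchronous update), so ordering within the year only matters where
    an outflow could exhaust a stock: the waiting pool's emigration and
    constant outflow are taken before ST starts, and license grants are
    capped by the remainder.
    """
    year = state.year + 1

    # Medical schools: 6-y conveyor; the 10% generational loss is applied
    # at graduation (intra-study timing is unobservable from outside).
    students, grads_gross, _ = conveyor_step(state.students, params.enrollment)
    graduations = grads_gross * (1.0 - params.student_dropout_frac)
    student_dropout = grads_gross * params.student_dropout_frac

    # Waiting pool: emigration and the constant outflow leave first,
    # licenses are capped by what remains; graduates and immigrants
    # arrive within the same year.
    w0 = state.waiting
    emigration = params.waiting_emigration_rate * w0
    other = max(min(params.waiting_other_outflow, w0 - emigration), 0.0)
    starts = licenses_granted(year, params, w0)
    waiting = w0 - emigration - other - starts + graduations + params.immigrants
    if waiting < -1e-9:
        raise ValueError(f"waiting pool would go negative in {year}: {waiting}")
    waiting = max(waiting, 0.0)

    # Specialization training: 5-y conveyor with per-year drop-out. The
    # leak rate is taken from the current parameters (not the one frozen
    # into the conveyor at initialisation) so parameter perturbations act.
    on_st_in = replace(state.on_st, leak_rate=params.st_dropout_rate)
    on_st, completions, st_dropout = conveyor_step(on_st_in, starts)

    # Specialists: attrition, aging, retirement; completions enter at 30.
    specialists, retirees, attrition = aging_chain_step(
        state.specialists, completions, params.specialist_attrition_rate, year
    )

    # Legacy stocks drain linearly until exhausted.
    gp_retirement = min(state.gp_drain_per_year, state.gps_no_st)
    outside_retirement = min(state.outside_drain_per_year, state.outside_care)

    ledger = FlowLedger(
        enrollment=params.enrollment,
        graduations=graduations,
        student_dropout=student_dropout,
        immigration=params.immigrants,
        waiting_emigration=emigration,
        waiting_other=other,
        st_starts=starts,
        st_dropout=st_dropout,
        st_completions=completions,
        specialist_attrition=attrition,
        specialist_retirement=retirees,
        gp_retirement=gp_retirement,
        outside_retirement=outside_retirement,
    )
    new_state = replace(
        state,
        year=year,
        students=students,
        waiting=waiting,
        on_st=on_st,
        specialists=specialists,
        gps_no_st=state.gps_no_st - gp_retirement,
        outside_care=state.outside_care - outside_retirement,
    )
    return new_state, ledger


def count_physicians(state: WorkforceState) -> float:
    """Head-count of practicing physicians.

    Waiting pool + on ST + specialists + GPs without specialization;
    students and MDs outside health care are excluded.
    """
    return (
        state.waiting
        + state.on_st.content
        + state.specialists.total
        + state.gps_no_st
    )


def age_distribution_report(state: WorkforceState, bin_width: int = 5) -> Dict[str, float]:
    """Specialist age distribution aggregated to ``bin_width``-year bins.

    Bin totals conserve the specialist stock exactly.
    """
    return state.specialists.binned(bin_width)
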