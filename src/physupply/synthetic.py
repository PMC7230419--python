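"""Reconstruction and generation of inputs that are not directly observed.

Three generators live here:

* ``reconstruct_age_distribution`` — the baseline specialist age
  distribution. The published aggregates pin down the mean age (49.7 y),
  the share aged 55+ (29.5%), and the ordering of the two largest 5-year
  bins (55-59 first, 50-54 second), but not the single-year counts. The
  reconstruction takes the maximum-entropy distribution over single ages
  subject to exactly those constraints: the least-informative
  distribution consistent with what is known. It is a deterministic
  convex program with no tuning knobs.

* ``generate_population_anchors`` — default national population anchors,
  back-computed from published (head-count, per-100k density) pairs so
  that densities are reproducible without external demographic data.
  Users with access to real projections should override them.

* ``random_model`` — seeded random model instances within plausible
  bounds, for property-based testing (mass balance, non-negativity).

The age reconstruction applies aggregates published for all physicians
to the specialist chain (the only age-structured stock); that proxy is
the main acknowledged source of forecast tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

import numpy as np
from scipy.optimize import LinearConstraint, minimize

from .demography import PopulationProjection
from .model import (
    BASELINE_STOCKS,
    ModelParameters,
    Schedule,
    WorkforceState,
    build_initial_state,
)

__all__ = [
    "AgeConstraints",
    "reconstruct_age_distribution",
    "generate_population_anchors",
    "random_model",
    "PUBLISHED_COUNT_DENSITY_PAIRS",
]


@dataclass(frozen=True)
class AgeConstraints:
    """Published aggregates that the reconstructed distribution must hit."""

    mean_age: float = 49.7
    share_55_plus: float = 0.295
    modal_bin: Tuple[int, int] = (55, 59)
    second_bin: Tuple[int, int] = (50, 54)
    age_min: int = 30
    age_max: int = 65  # exclusive: working ages are [age_min, age_max)
    bin_width: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.share_55_plus < 1.0:
            raise ValueError(f"share_55_plus must be in (0, 1), got {self.share_55_plus}")
        if self.age_max <= self.age_min:
            raise ValueError("age range is empty")
        if not self.age_min <= self.mean_age < self.age_max:
            raise ValueError(
                f"mean age {self.mean_age} outside the age range "
                f"[{self.age_min}, {self.age_max})"
            )


def _bin_indicator(ages: np.ndarray, bin_lo: int, bin_width: int) -> np.ndarray:
    return ((ages >= bin_lo) & (ages < bin_lo + bin_width)).astype(float)


def reconstruct_age_distribution(
    total: float, constraints: AgeConstraints | None = None
) -> Dict[int, float]:
    """Maximum-entropy single-year age distribution matching published
    aggregates.

    Maximizes Shannon entropy over probabilities on the integer ages
    [age_min, age_max) subject to: unit mass; the published mean; the
    published 55+ share; and the bin ordering (modal bin largest,
    second bin larger than every remaining bin). Deterministic: a convex
    program solved from a uniform start.

    Returns age -> count scaled to ``total``. Raises ``ValueError`` with
    the violated constraint named if the set is infeasible.
    """
    if total <= 0:
        raise ValueError(f"total must be positive, got {total}")
    c = constraints if constraints is not None else AgeConstraints()

    ages = np.arange(c.age_min, c.age_max)
    n = ages.size
    if n == 1:
        return {int(ages[0]): float(total)}

    tail = (ages >= 55).astype(float)
    if not ages.min() <= c.mean_age <= ages.max():
        raise ValueError("infeasible: mean age outside the attainable range")

    # Equality constraints: total mass, mean age, 55+ share.
    eq = LinearConstraint(
        np.vstack([np.ones(n), ages.astype(float), tail]),
        [1.0, c.mean_age, c.share_55_plus],
        [1.0, c.mean_age, c.share_55_plus],
    )

    # Ordering constraints: modal bin >= every other bin,
    # second bin >= every bin except the modal one.
    bin_lows = list(range(c.age_min - c.age_min % c.bin_width, c.age_max, c.bin_width))
    indicators = {lo: _bin_indicator(ages, lo, c.bin_width) for lo in bin_lows}
    modal_lo, second_lo = c.modal_bin[0], c.second_bin[0]
    if modal_lo not in indicators or second_lo not in indicators:
        raise ValueError("infeasible: modal/second bins outside the age range")
    rows = []
    for lo in bin_lows:
        if lo != modal_lo:
            rows.append(indicators[modal_lo] - indicators[lo])
        if lo not in (modal_lo, second_lo):
            rows.append(indicators[second_lo] - indicators[lo])
    order = LinearConstraint(np.vstack(rows), 0.0, np.inf)

    def neg_entropy(p: np.ndarray) -> float:
        q = np.clip(p, 1e-300, None)
        return float(np.sum(q * np.log(q)))

    def grad(p: np.ndarray) -> np.ndarray:
        q = np.clip(p, 1e-300, None)
        return np.log(q) + 1.0

    p0 = np.full(n, 1.0 / n)
    res = minimize(
        neg_entropy,
        p0,
        jac=grad,
        method="trust-constr",
        constraints=[eq, order],
        bounds=[(1e-12, 1.0)] * n,
        options={"gtol": 1e-10, "xtol": 1e-12, "maxiter": 5000},
    )
    p = np.clip(res.x, 0.0, None)
    p /= p.sum()

    # Feasibility check on the solution itself (reports which published
    # aggregate could not be met).
    if abs(float(ages @ p) - c.mean_age) > 0.1:
        raise ValueError(f"infeasible: mean age constraint ({c.mean_age}) not met")
    if abs(float(tail @ p) - c.share_55_plus) > 0.005:
        raise ValueError(f"infeasible: 55+ share constraint ({c.share_55_plus}) not met")
    bins = {lo: float(indicators[lo] @ p) for lo in bin_lows}
    if any(bins[modal_lo] < bins[lo] - 1e-6 for lo in bin_lows if lo != modal_lo):
        raise ValueError("infeasible: modal-bin ordering not met")
    if any(
        bins[second_lo] < bins[lo] - 1e-6
        for lo in bin_lows
        if lo not in (modal_lo, second_lo)
    ):
        raise ValueError("infeasible: second-bin ordering not met")

    return {int(a): float(total * pi) for a, pi in zip(ages, p)}


#: Published (year, physician head-count, per-100k density) pairs from
#: which default population anchors are back-computed.
PUBLISHED_COUNT_DENSITY_PAIRS: Dict[int, Tuple[int, int]] = {
    2017: (14394, 346),
    2021: (14637, 353),
    2031: (15098, 381),
    2041: (15998, 430),
}


def generate_population_anchors() -> PopulationProjection:
    """Default population anchors implied by published head-count /
    density pairs: population = count / density × 100 000.

    The anchors decrease monotonically (a depopulation context). They
    stand in for external demographic projections and are overridable
    per run.
    """
    anchors = {
        year: count / density * 100_000.0
        for year, (count, density) in PUBLISHED_COUNT_DENSITY_PAIRS.items()
    }
    return PopulationProjection(anchors=anchors)


def random_model(
    seed: int, bounds: Mapping[str, Tuple[float, float]] | None = None
) -> Tuple[ModelParameters, WorkforceState]:
    """A seeded random (parameters, initial state) pair for property tests.

    ``bounds`` maps parameter or stock names to (low, high) ranges;
    omitted entries get plausible defaults around the baseline values.
    Collapsing every bound to a point reproduces that exact model. The
    returned instances satisfy all parameter/state invariants.
    """
    defaults: Dict[str, Tuple[float, float]] = {
        "enrollment": (0.0, 1200.0),
        "student_dropout_frac": (0.0, 0.5),
        "immigrants": (0.0, 100.0),
        "waiting_emigration_rate": (0.0, 0.2),
        "waiting_other_outflow": (0.0, 100.0),
        "license": (0.0, 800.0),
        "st_dropout_rate": (0.0, 0.05),
        "specialist_attrition_rate": (0.0, 0.05),
        "students": (0.0, 8000.0),
        "waiting": (0.0, 3000.0),
        "on_st": (0.0, 5000.0),
        "specialists": (1.0, 20000.0),
        "gps_no_st": (0.0, 3000.0),
        "outside_care": (0.0, 3000.0),
    }
    if bounds is not None:
        unknown = set(bounds) - set(defaults)
        if unknown:
            raise ValueError(f"unknown bound names: {sorted(unknown)}")
        for name, (lo, hi) in bounds.items():
            if hi < lo:
                raise ValueError(f"empty bounds for {name}: ({lo}, {hi})")
        defaults.update(bounds)

    rng = np.random.default_rng(seed)

    def draw(name: str) -> float:
        lo, hi = defaults[name]
        return float(rng.uniform(lo, hi))

    params = ModelParameters(
        enrollment=draw("enrollment"),
        student_dropout_frac=draw("student_dropout_frac"),
        immigrants=draw("immigrants"),
        waiting_emigration_rate=draw("waiting_emigration_rate"),
        waiting_other_outflow=draw("waiting_other_outflow"),
        license_schedule=Schedule.constant(draw("license")),
        st_dropout_rate=draw("st_dropout_rate"),
        specialist_attrition_rate=draw("specialist_attrition_rate"),
    )

    specialists_total = draw("specialists")
    ages = np.arange(params.specialist_entry_age, 65)
    weights = rng.dirichlet(np.ones(ages.size))
    age_distribution = {int(a): float(specialists_total * w) for a, w in zip(ages, weights)}
    stocks = {name: draw(name) for name in
              ("students", "waiting", "on_st", "gps_no_st", "outside_care")}
    stocks["specialists"] = specialists_total
    state = build_initial_state(params, age_distribution, stocks=stocks)
    return params, state
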