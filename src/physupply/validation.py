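"""Model validation and sensitivity analysis.

Validation compares simulated head-counts with historical observations
using the relative error |simulated − observed| / observed; a run is
considered reliable when the relative error is below 0.1. Sensitivity
is measured as an elasticity: the relative change in the long-run
annual specialist-completion flow per unit relative change in a
perturbed input. License volume feeds completions through a pure
fixed-delay stage, so its elasticity is 1 whenever licenses are not
capped by the waiting pool.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .model import ModelParameters, WorkforceState
from .scenarios import Scenario, Trajectory, run_scenario

__all__ = [
    "RELIABILITY_THRESHOLD",
    "ValidationResult",
    "relative_error",
    "validate_series",
    "sensitivity",
]

#: Maximum relative error at which a simulated series counts as reliable.
RELIABILITY_THRESHOLD = 0.1


@dataclass(frozen=True)
class ValidationResult:
    simulated: float
    observed: float
    relative_error: float

    @property
    def passed(self) -> bool:
        return self.relative_error < RELIABILITY_THRESHOLD


def relative_error(simulated: float, observed: float) -> float:
    """|simulated − observed| / observed. Requires observed > 0."""
    if observed <= 0:
        raise ValueError(f"observed value must be positive, got {observed}")
    return abs(simulated - observed) / observed


def validate_series(
    simulated: Mapping[int, float], observed: Mapping[int, float]
) -> pd.DataFrame:
    """Relative errors for every observed year present in the simulation.

    Returns a DataFrame indexed by year with columns simulated,
    observed, relative_error, passed. Observed years missing from the
    simulated series raise.
    """
    missing = sorted(set(observed) - set(simulated))
    if missing:
        raise ValueError(f"no simulated value for observed years {missing}")
    rows = {}
    for year in sorted(observed):
        res = ValidationResult(
            simulated=float(simulated[year]),
            observed=float(observed[year]),
            relative_error=relative_error(simulated[year], observed[year]),
        )
        rows[year] = {
            "simulated": res.simulated,
            "observed": res.observed,
            "relative_error": res.relative_error,
            "passed": res.passed,
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "year"
    return frame


#: Parameters accepted by :func:`sensitivity` and how they are perturbed.
_PERTURBABLE = (
    "license_schedule",
    "enrollment",
    "immigrants",
    "waiting_emigration_rate",
    "st_dropout_rate",
    "specialist_attrition_rate",
    "outside_care_horizon",
)

#: Window (years) over which the long-run completion flow is averaged.
LONG_RUN_WINDOW = 5


def _long_run_completions(trajectory: Trajectory) -> float:
    flows = [ledger.st_completions for ledger in trajectory.ledgers]
    return float(np.mean(flows[-LONG_RUN_WINDOW:]))


def sensitivity(
    base_scenario: Scenario,
    params: ModelParameters,
    init: WorkforceState,
    parameter_name: str,
    perturbation: float,
) -> float:
    """Elasticity of long-run specialist completions to one parameter.

    Runs the base and a perturbed scenario and returns
    (relative change in the final-5-year mean completion flow) /
    ``perturbation``. The horizon should exceed about twice the total
    training delay so the perturbation has fully propagated.
    """
    if perturbation == 0:
        raise ValueError("perturbation must be nonzero")
    if parameter_name not in _PERTURBABLE:
        raise ValueError(
            f"unknown parameter '{parameter_name}'; choose from {_PERTURBABLE}"
        )

    factor = 1.0 + perturbation
    scenario = base_scenario
    if parameter_name == "license_schedule":
        scenario = replace(
            base_scenario,
            name=f"{base_scenario.name}+{parameter_name}",
            license_schedule=base_scenario.license_schedule.scaled(factor),
        )
        perturbed = params
    elif parameter_name == "enrollment":
        scenario = replace(
            base_scenario,
            name=f"{base_scenario.name}+{parameter_name}",
            enrollment_schedule=base_scenario.enrollment_schedule.scaled(factor),
        )
        perturbed = params
    elif parameter_name == "outside_care_horizon":
        perturbed = replace(
            params, outside_care_horizon=max(int(round(params.outside_care_horizon * factor)), 1)
        )
    else:
        perturbed = replace(params, **{parameter_name: getattr(params, parameter_name) * factor})

    base_run = run_scenario(base_scenario, params, init)
    pert_run = run_scenario(scenario, perturbed, init)
    base_out = _long_run_completions(base_run)
    pert_out = _long_run_completions(pert_run)
    if base_out == 0:
        raise ValueError("base completion flow is zero; elasticity undefined")
    return (pert_out / base_out - 1.0) / perturbation
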