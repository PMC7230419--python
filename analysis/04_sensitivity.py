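#!/usr/bin/env python
"""Sensitivity of the long-run specialist-completion flow.

Perturbs each input parameter by ±5% around the scenario-1 baseline and
reports the elasticity of the final-5-year mean annual completion flow.
License volume should show unit elasticity (completions are a pure
fixed delay of license grants); parameters off the training path should
show zero.

Output: results/sensitivity.csv
"""

from pathlib import Path

import pandas as pd

from physupply import (
    ModelParameters,
    build_initial_state,
    reconstruct_age_distribution,
    scenario_1,
    sensitivity,
)
from physupply.synthetic import AgeConstraints

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)

PARAMETERS = [
    "license_schedule",
    "enrollment",
    "immigrants",
    "waiting_emigration_rate",
    "st_dropout_rate",
    "specialist_attrition_rate",
    "outside_care_horizon",
]


def main() -> None:
    params = ModelParameters()
    init = build_initial_state(
        params, reconstruct_age_distribution(9648.0, AgeConstraints())
    )
    rows = []
    for name in PARAMETERS:
        for perturbation in (0.05, -0.05):
            e = sensitivity(scenario_1(), params, init, name, perturbation)
            rows.append(
                {"parameter": name, "perturbation": perturbation, "elasticity": e}
            )
    frame = pd.DataFrame(rows)
    out = RESULTS / "sensitivity.csv"
    frame.to_csv(out, index=False, float_format="%.6f")
    print(frame.round(4).to_string(index=False))
    print(
        "\nlicense volume shows unit elasticity: completions in the long run "
        "track license grants one for one. Enrollment shows zero because "
        "graduates exceed license demand, so licenses, not graduates, are "
        f"the binding constraint. -> {out}"
    )


if __name__ == "__main__":
    main()
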