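# physupply

System-dynamics forecasting of the supply and age distribution of
physicians in a national workforce, built for health-workforce planners
who set medical-school enrollment and specialization-training (ST)
license quotas. The reference parameterization is the Croatian physician
workforce, projected 2017–2041 under two license-policy scenarios.

## The model

The workforce is a discrete-time stock-and-flow pipeline, advanced one
calendar year at a time with synchronous (start-of-year) flow
evaluation:

```
enrollment ──▶ [medical schools]──▶ (10% of a generation drops out)
  590/y         6-y conveyor    │
                                ▼ graduates ≈ 531/y        + 20 immigrants/y
               [waiting for ST license] ──▶ emigration 5%/y, other 20/y
                                │
        licenses (450/y, or 550/y from 2020)
                                ▼
               [on ST]  5-y conveyor, 0.2%/y drop-out
                                ▼ completions, enter at age 30
               [specialists]  single-year-of-age chain,
                              1%/y attrition, retire at 65 (67 from 2038)

   [GPs without specialization: 1232]  linear retirement over 20 y
   [MDs outside health care:   1200]   linear drain; not counted
```

Training stages are *conveyors* (fixed transit time with per-year
leakage); the specialist stock is an *aging chain* at single-year age
resolution, so retirement is driven by actual cohort ages rather than a
smeared bin-level outflow. The physician head-count is
waiting + on ST + specialists + GPs (students and MDs outside health
care excluded); per-100 000 densities use population anchors with
linear interpolation. Every run keeps a per-year flow ledger so that
mass balance (Δstock = inflows − outflows) can be audited to 1e-6
persons.

The baseline single-year age distribution is not published, only its
aggregates (mean age 49.7 y, 29.5% aged 55+, modal 5-year bin 55–59
followed by 50–54). The `synthetic` module reconstructs it as the
maximum-entropy distribution over ages 30–64 subject to exactly those
constraints — a deterministic convex program. See `docs/methods.md` for
what this reconstruction does and does not pin down.

## Worked example

```python
from physupply import (
    ModelParameters, build_initial_state, count_physicians,
    reconstruct_age_distribution, run_scenario, scenario_1, scenario_2,
)

params = ModelParameters()                      # national baseline values
ages = reconstruct_age_distribution(9648.0)     # baseline specialist ages
init = build_initial_state(params, ages)        # 2017 state
print(count_physicians(init))                   # 14394.0

s1 = run_scenario(scenario_1(), params, init)   # 450 licenses/y
s2 = run_scenario(scenario_2(), params, init)   # 550/y from 2020
print(s1.physician_counts()[[2021, 2031, 2041]].round())
# year
# 2021    15099.0
# 2031    14379.0
# 2041    14819.0
print((s2.physician_counts() - s1.physician_counts())[2041].round())
# 640.0
```

The 2017 count of 14 394 is the exact sum of the in-workforce stocks.
The projections say supply stays near or above the 2017 level through
2041 and that raising license volume from 450 to 550/year adds ~640
physicians by 2041 — more training retains people in lower-loss stocks,
so the expanded scenario dominates every year. The dip around 2023–2037
is the retirement wave implied by the published age aggregates under
sharp retirement at 65; the corresponding published projections rise
monotonically instead, a discrepancy discussed in `docs/methods.md`.

The same runs are available from a shell:

```sh
physupply run --scenario scenario-2 --out results/run.csv
physupply compare                         # scenario 2 minus scenario 1
physupply sensitivity                     # elasticity of completions
physupply reconstruct-ages --total 9648   # baseline age distribution
physupply validate observed.csv           # year,value historical series
```

and the full analysis sequence lives in `analysis/01_reconstruct_ages.py`
… `04_sensitivity.py`, each writing its tables under `results/`.

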