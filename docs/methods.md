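# Methods

## Model structure and update rule

The workforce is simulated as a deterministic discrete-time
compartmental system with a one-calendar-year step. All flows of a year
are computed from start-of-year stocks and applied together
(synchronous updating); persons are continuous-valued internally and
rounded only in reports. The step from the end-of-year state of year
*t* to year *t+1* evaluates schedules and the retirement age at *t+1*.

**Conveyors (training stages).** Medical school (6 y) and specialization
training (ST, 5 y) are fixed-delay conveyors: `duration` cohort slots,
one step each. Per step, every cohort first loses the leak fraction,
then advances; the final cohort exits. A unit entering a conveyor is
therefore leaked exactly `duration` times, so the cumulative throughput
of a 5-y stage with 0.2 %/y leakage is (1 − 0.002)⁵ ≈ 0.990 of intake.
The 10 % generational drop-out of medical school is applied at
graduation rather than as a per-year leak: students are not counted as
physicians, so intra-study timing is unobservable in every reported
quantity, and the gross outflow times 0.9 is the only identifiable
object (590 × 0.9 = 531 graduates/year at steady state).

**Waiting pool ordering.** Within a year the waiting pool loses
emigration (5 % of the start-of-year stock) and the constant other
outflow (20/y, capped by availability) first; license grants are capped
by the remainder; graduates and immigrants (20/y) arrive within the
same year. This ordering prevents negative stocks and makes the license
cap well-defined. Start-of-year stock is used for the emigration base.

**Specialist aging chain.** Ages are tracked at single-year resolution
and aggregated to 5-year bins only for reporting. Per step: attrition
(1 %/y) on every age, then aging by +1, then retirement of every count
at or above the retirement age in force (65; 67 from 2038), then entry
of ST completions at exactly age 30. Cohorts aged 65–66 when the 2038
extension takes effect are retained until 67; nobody already retired
returns. The closed form follows: mass at age *k* below retirement with
attrition *a* delivers (1 − a)ᵏ of itself to retirement after *k*
steps. Single-year resolution is a deliberate choice over per-bin
stocks with proportional outflows: proportional bin outflows are
first-order delays that disperse a cohort exponentially and let part of
it linger far beyond its true retirement year.

**Side stocks.** GPs without specialization (1232 at baseline) retire
linearly over 20 years (61.6/y, fixed at initialisation); MDs outside
health care (1200) drain linearly over a configurable horizon (default
35 y) and are excluded from the physician head-count, so that stock
affects no reported quantity. Neither has an inflow.

**Head-count and density.** Physicians = waiting + on ST + specialists
+ GPs without specialization. Densities divide by a piecewise-linear
population projection; the default anchors are back-computed from
published (head-count, per-100 000) pairs — 2017: 14 394/346, 2021:
14 637/353, 2031: 15 098/381, 2041: 15 998/430 — giving ≈ 4.16 M
falling to ≈ 3.72 M, and are overridable with real projections.
End-of-year (anchor-year) populations are used.

## Baseline age reconstruction

Only aggregates of the baseline age structure are available: mean age
49.7 y, 29.5 % aged 55+, modal 5-year bin 55–59 followed by 50–54. The
baseline specialist distribution is reconstructed as the
maximum-entropy distribution over single ages 30–64 subject to exactly
these constraints (equalities for mass, mean and tail share;
inequalities for the bin ordering), solved as a convex program
(`scipy` trust-region constrained, uniform start, no randomness). The
solution is piecewise exponential with bin-level jumps where ordering
constraints bind; at the optimum bins 45-49, 50-54 and 55-59 tie at
≈ 2100 persons each, with 60-64 at ≈ 746. Feasibility is re-verified on
the output (mean within ±0.1 y, tail share within ±0.5 pp, ordering
within 1e-6), and an infeasible constraint set raises an error naming
the violated constraint.

Two approximations are built into this choice and documented rather
than hidden. First, the published aggregates describe *all* physicians
(including under-30s and 65+), but they are applied to the specialist
chain, the only age-structured stock. Second, maximum entropy is the
least-informative feasible distribution, not the true registry
distribution; any discrepancy propagates directly into retirement
timing, which is the model's dominant outflow.

## What the published aggregates imply — and the known discrepancy

The reconstruction cannot be blamed freely: the constraints themselves
force a retirement wave. The 29.5 % tail (≈ 2846 specialists aged
55–64) retires during 2018–2027. A mean of 49.7 over [30, 65) then
forces most remaining mass into 45–54 — by the second-bin ordering
constraint every feasible distribution has at least 0.705/5 ≈ 14.1 % of
mass in 50–54 alone — so retirements run at ≈ 300–530/y through
2023–2037, against a net non-retirement input of ≈ 350/y (531
graduates + 20 immigrants − emigration − other outflows − 1 %
attrition). The simulated head-count therefore dips in 2023–2037 and
recovers after the 2038 retirement-age extension, while the published
projections for the same parameterization rise monotonically
(S1: 14 637 → 15 098 → 15 998). Simulated milestones land at
S1: 15 099 / 14 379 / 14 819 and S2: 15 104 / 14 630 / 15 459, i.e.
within ≈ +3 % early and ≈ −8 % by 2041.

A monotone published trajectory together with the published age
aggregates is only reconcilable if the original implementation's aging
stage disperses cohorts (per-bin proportional outflows), spreading the
55+ wave over decades. This package keeps sharp single-age retirement
as the scientifically preferable mechanism and reports the discrepancy
instead of re-fitting the initial distribution or the update rule to
the published curve. Users with registry single-year age data should
supply it to `build_initial_state` directly (the CLI's
`reconstruct-ages --out` format is the exchange format); the qualitative
conclusions — no shortage relative to the 2017 level, expanded
licensing dominating pointwise, rejuvenation of the specialist age
structure (share under 45 rises from 27 % to 57 % by 2041) — are stable
across this uncertainty.

## Validation and sensitivity

Validation uses the relative error |simulated − observed| / observed
with a 0.1 reliability threshold; the published historical benchmark
pairs give 0.019 (1984→1991) and 0.005 (1993→2011). The historical runs
themselves are not re-simulated here because their initial conditions
are not available; a harness accepts any year,value series instead.

Sensitivity is reported as an elasticity: base and perturbed runs of a
scenario, with the output defined as the final-5-year mean of the
annual specialist-completion flow (the horizon should exceed about
twice the total training delay of 11 y; the default 24-y horizon does).
The completion flow is a pure fixed delay of license grants, so license
volume has elasticity exactly 1 while graduates exceed license demand;
enrollment correspondingly shows 0 in that regime (licenses, not
graduates, bind), and the ST drop-out rate matches its closed form
d log(1 − l)⁵ ≈ −0.01 per 5 % perturbation.

## Synthetic fixtures and their limits

`random_model(seed, bounds)` draws parameter sets and initial states
(Dirichlet age compositions, uniform stock levels) within plausible
bounds around the baseline for property testing: mass-balance residuals
below 1e-6 persons, non-negativity of every stock, cohort and age
count, and determinism. These fixtures exercise the bookkeeping, not
realism: they do not emulate correlated demographic structure, policy
feedback, demand-side constraints, or regional/specialty heterogeneity
(all outside this model's scope), so passing them certifies
conservation and contract behaviour, not forecast accuracy on real
registries.

## Numerical choices

Conservation is asserted at 1e-9 persons per step and audited at 1e-6
per year and stock over full runs. The entropy objective clips
probabilities at 1e-300 to keep p log p finite; solver tolerances are
gtol 1e-10 / xtol 1e-12. Schedules are piecewise-constant in calendar
year and must cover the whole horizon (checked before simulation).
Degenerate inputs are defined: an empty aging chain steps to an empty
chain with zero flows; a one-age reconstruction range returns a point
mass; zero-everything scenarios yield identically zero trajectories.
Counts are printed as plain integers.
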