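"""The wired workforce pipeline: initial state, flows, one-year update."""

import dataclasses

import pytest

from physupply import (
    ModelParameters,
    Schedule,
    age_distribution_report,
    annual_update,
    build_initial_state,
    count_physicians,
    graduates,
    licenses_granted,
    run_scenario,
)
from physupply.model import BASELINE_STOCKS
from physupply.scenarios import Scenario, scenario_1


class TestInitialState:
    def test_baseline_stock_levels(self, baseline_state):
        for stock, level in BASELINE_STOCKS.items():
            assert baseline_state.stock_level(stock) == pytest.approx(level, abs=0.5)
        assert baseline_state.year == 2017

    def test_baseline_physician_count(self, baseline_state):
        # waiting + on ST + specialists + GPs; students and MDs outside
        # health care excluded
        assert count_physicians(baseline_state) == pytest.approx(14394.0, abs=1e-6)

    def test_conveyors_initialised_uniformly(self, baseline_state):
        assert baseline_state.students.cohorts == (3761.0 / 6,) * 6
        assert baseline_state.on_st.cohorts == (2268.0 / 5,) * 5

    def test_all_zero_stocks_valid(self, baseline_params):
        state = build_initial_state(
            baseline_params, {}, stocks={name: 0.0 for name in BASELINE_STOCKS}
        )
        assert count_physicians(state) == 0.0

    def test_mismatched_age_total_rejected(self, baseline_params):
        dist = {age: 9000.0 / 35 for age in range(30, 65)}
        with pytest.raises(ValueError, match="9000"):
            build_initial_state(baseline_params, dist)

    def test_out_of_range_ages_rejected(self, baseline_params):
        dist = {70: 9648.0}
        with pytest.raises(ValueError, match="age 70"):
            build_initial_state(baseline_params, dist)


class TestFlows:
    def test_graduate_flow_nets_out_dropout(self, baseline_params):
        # 590 enrolled, 10% generational drop-out -> 531/year
        assert graduates(baseline_params) == pytest.approx(531.0)

    @pytest.mark.parametrize(
        "enrollment,dropout,expected",
        [(590.0, 1.0, 0.0), (100.0, 0.25, 75.0)],
    )
    def test_graduate_flow_arithmetic(self, enrollment, dropout, expected):
        params = ModelParameters(enrollment=enrollment, student_dropout_frac=dropout)
        assert graduates(params) == pytest.approx(expected)

    def test_licenses_follow_schedule_when_pool_suffices(self, baseline_params):
        assert licenses_granted(2018, baseline_params, 1246.0) == pytest.approx(450.0)

    def test_licenses_capped_by_pool_availability(self):
        params = ModelParameters(license_schedule=Schedule.constant(550.0))
        granted = licenses_granted(2018, params, 100.0)
        assert 0.0 <= granted <= 100.0

    def test_zero_schedule_grants_nothing(self, baseline_params):
        params = dataclasses.replace(
            baseline_params, license_schedule=Schedule.constant(0.0)
        )
        assert licenses_granted(2018, params, 1246.0) == 0.0


class TestAnnualUpdate:
    def test_one_step_hand_ledger(self):
        # all rates zero, durations 1: the waiting pool must grow by
        # exactly graduations + immigrants - starts
        params = ModelParameters(
            enrollment=10.0,
            study_duration=1,
            student_dropout_frac=0.0,
            immigrants=3.0,
            waiting_emigration_rate=0.0,
            waiting_other_outflow=0.0,
            license_schedule=Schedule.constant(5.0),
            st_duration=1,
            st_dropout_rate=0.0,
            specialist_attrition_rate=0.0,
        )
        state = build_initial_state(
            params,
            {40: 50.0},
            stocks={
                "students": 10.0,
                "waiting": 100.0,
                "on_st": 0.0,
                "specialists": 50.0,
                "gps_no_st": 0.0,
                "outside_care": 0.0,
            },
        )
        new, ledger = annual_update(state, params)
        assert ledger.graduations == pytest.approx(10.0)
        assert ledger.st_starts == pytest.approx(5.0)
        assert new.waiting == pytest.approx(100.0 + 10.0 + 3.0 - 5.0)
        assert new.year == 2018

    def test_empty_model_only_linear_drains_act(self, baseline_params):
        params = dataclasses.replace(
            baseline_params,
            enrollment=0.0,
            immigrants=0.0,
            waiting_other_outflow=0.0,
            license_schedule=Schedule.constant(0.0),
        )
        state = build_initial_state(
            params,
            {},
            stocks={
                "students": 0.0,
                "waiting": 0.0,
                "on_st": 0.0,
                "specialists": 0.0,
                "gps_no_st": 1232.0,
                "outside_care": 1200.0,
            },
        )
        new, ledger = annual_update(state, params)
        assert new.gps_no_st == pytest.approx(1232.0 - 1232.0 / 20)
        assert new.outside_care == pytest.approx(1200.0 - 1200.0 / 35)
        for name, value in ledger.as_dict().items():
            if name not in ("gp_retirement", "outside_retirement"):
                assert value == 0.0

    def test_gp_stock_exhausts_after_horizon_then_stops(self, s1_trajectory):
        by_year = {s.year: s.gps_no_st for s in s1_trajectory.states}
        assert by_year[2037] == pytest.approx(0.0, abs=1e-9)
        assert by_year[2041] == pytest.approx(0.0, abs=1e-9)
        assert all(level >= 0 for level in by_year.values())

    def test_retirees_only_from_eligible_ages(self, s1_trajectory):
        # retirement flow in year t is bounded by the mass that was
        # within one year of the year-t threshold
        for before, after, ledger in zip(
            s1_trajectory.states, s1_trajectory.states[1:], s1_trajectory.ledgers
        ):
            threshold = before.specialists.retirement_age_fn(after.year)
            eligible = sum(
                v for a, v in before.specialists.counts_by_age.items()
                if a + 1 >= threshold
            )
            assert ledger.specialist_retirement <= eligible + 1e-9

    def test_no_negative_stocks_over_full_run(self, s1_trajectory):
        for state in s1_trajectory.states:
            for stock in BASELINE_STOCKS:
                assert state.stock_level(stock) >= -1e-12
            assert all(v >= 0 for v in state.specialists.counts_by_age.values())
            assert all(c >= 0 for c in state.students.cohorts)
            assert all(c >= 0 for c in state.on_st.cohorts)


class TestProperties:
    def test_monotone_in_license_schedule(self, baseline_params, baseline_state):
        # a pointwise-larger license schedule never lowers the count:
        # training moves people from the leakier waiting pool inward
        low = run_scenario(scenario_1(), baseline_params, baseline_state)
        high = run_scenario(
            Scenario(name="high", license_schedule=Schedule.constant(500.0)),
            baseline_params,
            baseline_state,
        )
        diff = high.physician_counts() - low.physician_counts()
        assert (diff >= -1e-9).all()

    def test_supply_decays_without_training_or_enrollment(self, baseline_params):
        params = dataclasses.replace(
            baseline_params,
            enrollment=0.0,
            license_schedule=Schedule.constant(0.0),
        )
        # empty student stage: otherwise graduates of the initial stock
        # keep arriving for six more years and the count still rises
        state = build_initial_state(
            params,
            {age: 9648.0 / 35 for age in range(30, 65)},
            stocks={"students": 0.0},
        )
        counts = run_scenario(
            Scenario(
                name="no-training",
                enrollment_schedule=Schedule.constant(0.0),
                license_schedule=Schedule.constant(0.0),
            ),
            params,
            state,
        ).physician_counts()
        assert (counts.diff().dropna() <= 1e-9).all()

    def test_doubling_stocks_doubles_count(self, baseline_params):
        dist = {age: 9648.0 / 35 for age in range(30, 65)}
        base = build_initial_state(baseline_params, dist)
        doubled = build_initial_state(
            baseline_params,
            {a: 2 * v for a, v in dist.items()},
            stocks={k: 2 * v for k, v in BASELINE_STOCKS.items()},
        )
        assert count_physicians(doubled) == pytest.approx(2 * count_physicians(base))


class TestAgeReport:
    def test_point_mass_lands_in_its_bin(self, baseline_params):
        state = build_initial_state(
            baseline_params, {52: 10.0}, stocks={"specialists": 10.0}
        )
        report = age_distribution_report(state)
        assert report["50-54"] == pytest.approx(10.0)

    def test_bins_conserve_specialist_total(self, s1_trajectory):
        for state in s1_trajectory.states:
            report = age_distribution_report(state)
            assert sum(report.values()) == pytest.approx(state.specialists.total)

    def test_reconstructed_baseline_55_plus_share(self, baseline_state):
        report = age_distribution_report(baseline_state)
        total = sum(report.values())
        share = sum(
            v for k, v in report.items() if int(k.split("-")[0]) >= 55
        ) / total
        assert share == pytest.approx(0.295, abs=0.005)
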