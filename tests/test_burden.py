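"""Group-rate calibration, event/diabetes attribution and cost aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metsburden.burden import (
    CostBreakdown,
    DrugClass,
    OutcomeRates,
    TreatmentMix,
    UnitCosts,
    annual_costs,
    calibrate_group_rates,
    cost_shares,
    event_rate_per_1000,
    expected_events,
    mets_cost_share,
    per_patient_cost,
    prevalent_t2d,
    treatment_attributable_new_onset_t2d,
)


def simple_mix(proportion_treated=1.0, continuation=1.0, rr_nod=1.0, cost=100.0,
               visits=4.0, visit_cost=25.0):
    return TreatmentMix(
        proportion_treated=proportion_treated,
        classes=(DrugClass("arb", 1.0, cost, continuation, rr_nod),),
        visits_per_year=visits,
        visit_cost_eur=visit_cost,
    )


class TestCalibrateGroupRates:
    def test_flat_relative_risks_give_overall_rate_everywhere(self):
        rates = calibrate_group_rates(27.0, [0.2] * 5, [1.0] * 5)
        assert rates == pytest.approx([27.0] * 5)

    def test_two_group_toy(self):
        rates = calibrate_group_rates(15.0, [0.5, 0.5, 0, 0, 0], [1, 2, 2, 2, 2])
        assert rates[:2] == pytest.approx([10.0, 20.0])

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(0.01, 1.0), min_size=5, max_size=5),
        st.lists(st.floats(0.1, 20.0), min_size=5, max_size=5),
        st.floats(0.0, 500.0),
    )
    def test_weighted_mean_reproduces_overall_exactly(self, raw_w, rr, overall):
        w = np.array(raw_w) / np.sum(raw_w)
        rates = calibrate_group_rates(overall, w, rr)
        assert float(w @ rates) == pytest.approx(overall, rel=1e-12, abs=1e-12)

    def test_zero_exposure_is_an_error(self):
        with pytest.raises(ValueError, match="zero"):
            calibrate_group_rates(10.0, [1, 0, 0, 0, 0], [0, 1, 1, 1, 1])


class TestExpectedEvents:
    def test_rate_definition(self):
        assert expected_events([100_000], [27.0])[0] == pytest.approx(2700.0)

    def test_empty_group_reports_nan_rate(self):
        events = expected_events([0.0], [27.0])
        assert events[0] == 0.0
        assert np.isnan(event_rate_per_1000(events[0], 0.0))

    def test_two_group_aggregate_rate(self):
        rates = calibrate_group_rates(15.0, [0.5, 0.5, 0, 0, 0], [1, 2, 2, 2, 2])
        events = expected_events([500.0, 500.0], rates[:2])
        assert events.tolist() == pytest.approx([5.0, 10.0])
        assert event_rate_per_1000(events.sum(), 1000.0) == pytest.approx(15.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            expected_events([-1.0], [1.0])

    def test_prevalent_pool_applies_rate_to_unit_pool(self):
        assert prevalent_t2d([1000.0], [248.0])[0] == pytest.approx(248.0)

    def test_zero_overall_rate_zero_everywhere(self):
        rates = calibrate_group_rates(0.0, [0.2] * 5, [1, 2, 3, 4, 5])
        assert prevalent_t2d([1e6] * 5, rates).tolist() == [0.0] * 5


class TestNewOnsetDiabetes:
    def test_null_relative_risk_gives_zero(self):
        cases = treatment_attributable_new_onset_t2d([1e5] * 5, simple_mix(rr_nod=1.0), [10.0] * 5)
        assert cases.tolist() == [0.0] * 5

    def test_direct_formula(self):
        cases = treatment_attributable_new_onset_t2d([1000.0], simple_mix(rr_nod=2.0), [10.0])
        assert cases[0] == pytest.approx(10.0)

    def test_untreated_population_generates_none(self):
        mix = simple_mix(proportion_treated=0.0, rr_nod=3.0)
        assert treatment_attributable_new_onset_t2d([1e5], mix, [10.0])[0] == 0.0

    def test_protective_classes_floored_at_zero(self):
        cases = treatment_attributable_new_onset_t2d([1000.0], simple_mix(rr_nod=0.5), [10.0])
        assert cases[0] == 0.0

    def test_negative_rr_rejected_at_construction(self):
        with pytest.raises(ValueError, match="rr_new_onset_diabetes"):
            DrugClass("x", 1.0, 10.0, 1.0, -0.1)


class TestOutcomeRates:
    def test_reference_group_rr_must_be_one(self):
        with pytest.raises(ValueError, match="rr for k=0"):
            OutcomeRates("ami", 5.0, (1.5, 2, 3, 4, 5))

    def test_rr_must_not_decrease_with_k(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            OutcomeRates("ami", 5.0, (1.0, 2.0, 1.5, 3.0, 4.0))


class TestAnnualCosts:
    def setup_method(self):
        self.persons = np.array([100.0, 200.0, 300.0, 250.0, 150.0]) * 1000
        self.mix = simple_mix(proportion_treated=0.5, continuation=0.8, cost=200.0)
        self.costs = UnitCosts(
            event_cost_eur={"ami": 6000.0, "stroke": 9000.0, "chf": 5000.0,
                            "unstable_angina": 4000.0, "cv_death": 0.0},
            t2d_annual_cost_eur=2500.0,
        )
        self.events = {
            o: expected_events(self.persons, calibrate_group_rates(
                6.0, self.persons / self.persons.sum(), [1, 1.5, 2, 2.5, 3]))
            for o in ("ami", "stroke", "chf", "unstable_angina", "cv_death")
        }
        self.t2d = prevalent_t2d(
            self.persons,
            calibrate_group_rates(150.0, self.persons / self.persons.sum(), [1, 3, 9, 16, 24]),
        )

    def breakdowns(self):
        return annual_costs(self.persons, self.events, self.t2d, self.mix, self.costs)

    def test_total_is_exact_component_sum(self):
        for b in self.breakdowns():
            assert b.total == pytest.approx(b.drug + b.physician + b.cvd + b.t2d, abs=1e-9)

    def test_mets_and_non_mets_sum_to_overall(self):
        by_k = self.breakdowns()
        mets = by_k[2] + by_k[3] + by_k[4]
        non = by_k[0] + by_k[1]
        pooled = annual_costs(
            [self.persons.sum()],
            {o: [ev.sum()] for o, ev in self.events.items()},
            [self.t2d.sum()],
            self.mix,
            self.costs,
        )[0]
        for field in ("drug", "physician", "cvd", "t2d", "total"):
            assert getattr(mets + non, field) == pytest.approx(getattr(pooled, field), rel=1e-12)

    def test_drug_and_physician_costs_flat_per_treated_patient(self):
        """Even distribution across risk groups: per-treated-patient drug and
        physician spend is identical in every group."""
        by_k = self.breakdowns()
        treated = self.persons * 0.5
        per_treated = [(b.drug * 1e6 / t, b.physician * 1e6 / t) for b, t in zip(by_k, treated)]
        for pt in per_treated[1:]:
            assert pt == pytest.approx(per_treated[0], rel=1e-12)

    def test_zero_unit_costs_zero_breakdown(self):
        zero = UnitCosts(event_cost_eur={o: 0.0 for o in self.events}, t2d_annual_cost_eur=0.0)
        mix = simple_mix(proportion_treated=0.5, cost=0.0, visits=0.0, visit_cost=0.0)
        for b in annual_costs(self.persons, self.events, self.t2d, mix, zero):
            assert b.total == 0.0


class TestPerPatientCost:
    def test_flat_when_rates_flat(self):
        persons = np.array([10.0, 20.0, 30.0, 25.0, 15.0]) * 1000
        mix = simple_mix(proportion_treated=0.6)
        costs = UnitCosts(event_cost_eur={"ami": 5000.0}, t2d_annual_cost_eur=2000.0)
        events = {"ami": expected_events(persons, [7.0] * 5)}
        t2d = prevalent_t2d(persons, [100.0] * 5)
        pp = per_patient_cost(annual_costs(persons, events, t2d, mix, costs), persons)
        assert pp == pytest.approx([pp[0]] * 5, rel=1e-12)

    def test_intensive_quantity_unchanged_by_population_doubling(self):
        persons = np.array([10.0, 20.0, 30.0, 25.0, 15.0]) * 1000
        mix = simple_mix(proportion_treated=0.6)
        costs = UnitCosts(event_cost_eur={"ami": 5000.0}, t2d_annual_cost_eur=2000.0)

        def pp(scale):
            p = persons * scale
            events = {"ami": expected_events(p, [5, 7, 9, 11, 13])}
            t2d = prevalent_t2d(p, [50, 100, 200, 300, 400])
            return per_patient_cost(annual_costs(p, events, t2d, mix, costs), p)

        assert pp(2.0) == pytest.approx(pp(1.0), rel=1e-12)

    def test_monotone_rates_give_monotone_per_patient_cost(self):
        persons = np.array([10.0, 20.0, 30.0, 25.0, 15.0]) * 1000
        mix = simple_mix(proportion_treated=0.6)
        costs = UnitCosts(event_cost_eur={"ami": 5000.0}, t2d_annual_cost_eur=2000.0)
        events = {"ami": expected_events(persons, [5, 7, 9, 11, 13])}
        t2d = prevalent_t2d(persons, [50, 100, 200, 300, 400])
        pp = per_patient_cost(annual_costs(persons, events, t2d, mix, costs), persons)
        assert (np.diff(pp) >= 0).all()

    def test_empty_group_is_nan_not_zero(self):
        persons = np.array([0.0, 100.0, 100.0, 100.0, 100.0])
        mix = simple_mix()
        costs = UnitCosts(event_cost_eur={}, t2d_annual_cost_eur=1000.0)
        pp = per_patient_cost(annual_costs(persons, {}, [0, 1, 2, 3, 4], mix, costs), persons)
        assert np.isnan(pp[0]) and not np.isnan(pp[1:]).any()


class TestCostShares:
    def test_shares_sum_to_100(self):
        shares = cost_shares(CostBreakdown(628, 1952, 5265, 16582))
        assert sum(shares.values()) == pytest.approx(100.0, abs=1e-9)

    def test_single_nonzero_component_is_100(self):
        shares = cost_shares(CostBreakdown(0, 0, 0, 42.0))
        assert shares["t2d"] == 100.0
        assert shares["drug"] == shares["physician"] == shares["cvd"] == 0.0

    def test_zero_total_is_an_error(self):
        with pytest.raises(ValueError):
            cost_shares(CostBreakdown(0, 0, 0, 0))
        with pytest.raises(ValueError):
            mets_cost_share(0.0, 0.0)


def test_treatment_mix_shares_must_sum_to_one():
    with pytest.raises(ValueError, match="sum to 1"):
        TreatmentMix(
            proportion_treated=0.5,
            classes=(
                DrugClass("arb", 0.5, 100, 0.8, 1.0),
                DrugClass("ccb", 0.4, 100, 0.8, 1.0),
            ),
            visits_per_year=4,
            visit_cost_eur=25,
        )
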