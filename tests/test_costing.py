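"""Unit-cost table, cost categories, friction costing, arm summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trialcea import reference
from trialcea.costing import (CostBreakdown, FrictionParams, UnitCostTable,
                              arm_cost_summary, direct_medical_cost,
                              direct_nonmedical_cost, indirect_cost,
                              participant_costs, total_cost)


class TestUnitCostTable:
    def test_nonmedical_reconstruction_all_services_within_5_cents(
            self, unit_costs):
        """km*0.17 + hours*8.83 + 2.64*1{km>0} reproduces every printed
        per-visit nonmedical cost."""
        errors = unit_costs.reconstruction_errors()
        assert len(errors) == 13
        assert max(abs(e) for e in errors.values()) <= 0.05

    def test_no_travel_services_match_exactly(self, unit_costs):
        # no km -> no parking surcharge; time only
        assert unit_costs.nonmedical_per_visit("company_doctor") == 8.83
        assert unit_costs.nonmedical_per_visit("home_care") == 0.0

    def test_mental_health_visit_value(self, unit_costs):
        # 10 km * 0.17 + 3 h * 8.83 + 2.64 parking = 30.83 (printed 30.84)
        assert unit_costs.nonmedical_per_visit("mental_health") == \
            pytest.approx(30.83, abs=1e-9)

    def test_unknown_service_lists_known(self, unit_costs):
        with pytest.raises(KeyError, match="gp"):
            unit_costs.service("acupuncture")

    def test_csv_round_trip(self, unit_costs, tmp_path):
        path = tmp_path / "costs.csv"
        unit_costs.to_csv(path)
        back = UnitCostTable.from_csv(path)
        for slug, svc in unit_costs.services.items():
            assert back.services[slug].unit_cost == svc.unit_cost
            assert back.services[slug].nonmedical == svc.nonmedical

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("service,unit\ngp,Consultation\n")
        with pytest.raises(ValueError, match="missing columns"):
            UnitCostTable.from_csv(path)


class TestDirectMedical:
    def test_two_gp_consultations(self, unit_costs):
        assert direct_medical_cost({"gp": 2}, unit_costs, arm="WL") == 42.72

    def test_zero_use_intervention_arm_costs_intervention(self, unit_costs):
        assert direct_medical_cost({}, unit_costs, arm="CBT") == 501.0
        assert direct_medical_cost({}, unit_costs, arm="PST") == 338.0

    def test_zero_use_waiting_list_costs_nothing(self, unit_costs):
        assert direct_medical_cost({}, unit_costs, arm="WL") == 0.0

    def test_medication_priced_per_dose_month(self, unit_costs):
        got = direct_medical_cost({}, unit_costs, arm="WL",
                                  medication_months=2.0)
        assert got == pytest.approx(2.0 * unit_costs.medication_price)

    def test_unknown_service_error_lists_known(self, unit_costs):
        with pytest.raises(KeyError, match="known services"):
            direct_medical_cost({"reiki": 1}, unit_costs)

    def test_negative_count_rejected(self, unit_costs):
        with pytest.raises(ValueError, match="negative"):
            direct_medical_cost({"gp": -1}, unit_costs)


class TestDirectNonmedical:
    def test_examples(self, unit_costs):
        assert direct_nonmedical_cost({"mental_health": 1}, unit_costs) == \
            pytest.approx(30.83)
        assert direct_nonmedical_cost({"company_doctor": 1}, unit_costs) == \
            pytest.approx(8.83)
        assert direct_nonmedical_cost({}, unit_costs) == 0.0


class TestIndirect:
    def test_cutback_days_weighted_by_inefficiency(self):
        f = FrictionParams(day_rate=100.0)
        got = indirect_cost(0, 5.0, 0.4, 0.0, f)
        assert got == pytest.approx(2.0 * f.day_rate)

    def test_domestic_hours_at_hourly_rate(self):
        assert indirect_cost(0, 0, 0.0, 10.0) == pytest.approx(88.30)

    def test_all_zero(self):
        assert indirect_cost(0, 0, 0.0, 0.0) == 0.0

    @pytest.mark.parametrize("score", [-0.1, 1.1])
    def test_inefficiency_out_of_range(self, score):
        with pytest.raises(ValueError, match="inefficiency"):
            indirect_cost(0, 1.0, score, 0.0)


class TestTotals:
    def test_published_category_sums(self):
        total = CostBreakdown(958.0, 156.0, 1701.0).total
        assert total == 2815.0
        assert abs(total - 2814.0) <= 1.0  # printed total, rounding
        assert CostBreakdown(888.0, 175.0, 1642.0).total == 2705.0

    def test_period_accumulation_is_categorywise(self):
        acc = total_cost([CostBreakdown(10.0, 1.0, 5.0),
                          CostBreakdown(20.0, 2.0, 0.0)])
        assert (acc.direct_medical, acc.direct_nonmedical, acc.indirect) == \
            (30.0, 3.0, 5.0)
        assert acc.total == 38.0

    def test_empty_sum_is_zero(self):
        assert total_cost([]).total == 0.0

    @given(st.dictionaries(st.sampled_from(list(reference.SERVICES)),
                           st.integers(0, 8), max_size=5),
           st.sampled_from(list(reference.SERVICES)))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_adding_use_never_decreases_costs(self, use, extra):
        costs = UnitCostTable.default()
        more = dict(use)
        more[extra] = more.get(extra, 0) + 1
        assert direct_medical_cost(more, costs) >= \
            direct_medical_cost(use, costs)
        assert direct_nonmedical_cost(more, costs) >= \
            direct_nonmedical_cost(use, costs)


class TestCohortCosting:
    def test_total_equals_category_sum_for_every_participant(
            self, cohort, unit_costs):
        pc = participant_costs(cohort, unit_costs)
        recomputed = (pc["direct_medical"] + pc["direct_nonmedical"]
                      + pc["indirect"]).round(2)
        assert (pc["total"] == recomputed).all()

    def test_intervention_cost_added_once(self, cohort, unit_costs):
        with_iv = participant_costs(cohort, unit_costs)
        without = participant_costs(cohort, unit_costs,
                                    include_intervention=False)
        delta = (with_iv["direct_medical"] - without["direct_medical"])
        expected = cohort["arm"].map(reference.INTERVENTION_COST)
        assert np.allclose(delta, expected, atol=0.011)

    def test_arm_summary_differences(self):
        df = pd.DataFrame({
            "arm": ["CBT"] * 2 + ["PST"] * 2 + ["WL"] * 2,
            "direct_medical": [958.0] * 2 + [888.0] * 2 + [490.0] * 2,
            "direct_nonmedical": [156.0] * 2 + [175.0] * 2 + [168.0] * 2,
            "indirect": [1701.0] * 2 + [1642.0] * 2 + [1900.0] * 2,
        })
        # printed totals (2814 etc. carry their own rounding; the category
        # sums differ from them by at most 1 EUR)
        df["total"] = [2814.0] * 2 + [2705.0] * 2 + [2558.0] * 2
        summary = arm_cost_summary(df)
        diffs = {d["contrast"]: d for d in summary.attrs["differences"]}
        assert diffs["CBT-WL"]["total"] == pytest.approx(256.0)
        assert diffs["PST-WL"]["total"] == pytest.approx(147.0)
        assert diffs["CBT-WL"]["indirect"] == pytest.approx(-199.0)
        assert diffs["CBT-WL"]["indirect"] == pytest.approx(-201.0, abs=2.0)
        assert diffs["PST-WL"]["indirect"] == pytest.approx(-258.0)

    def test_identical_arms_give_zero_differences(self):
        df = pd.DataFrame({
            "arm": ["CBT", "CBT", "PST", "PST", "WL", "WL"],
            "direct_medical": [10.0, 20.0] * 3,
            "direct_nonmedical": [1.0, 2.0] * 3,
            "indirect": [5.0, 5.0] * 3,
        })
        df["total"] = df[["direct_medical", "direct_nonmedical",
                          "indirect"]].sum(axis=1)
        diffs = arm_cost_summary(df).attrs["differences"]
        assert all(abs(d["total"]) < 1e-12 for d in diffs)

    def test_no_recognised_arm_errors(self):
        df = pd.DataFrame({"arm": ["X"], "direct_medical": [1.0],
                           "direct_nonmedical": [0.0], "indirect": [0.0],
                           "total": [1.0]})
        with pytest.raises(ValueError, match="arm"):
            arm_cost_summary(df)
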