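"""Cohort selection, DDD computation and monthly aggregation."""

import numpy as np
import pandas as pd
import pytest

import priceits as p
from priceits.cohort import descriptive_summary
from priceits.synthetic import SeriesSpec


def claim(pid, date, dx, setting="outpatient", age=60, drug=None, qty=0.0,
          cost=0.0, copay=0.0, inst="clinic", ins="NHI"):
    return {
        "patient_id": pid, "age": age, "service_date": date, "setting": setting,
        "institution_type": inst, "insurance": ins, "diagnosis_code": dx,
        "drug_code": drug, "quantity": qty, "cost": cost, "copayment": copay,
    }


SIX_PATIENTS = pd.DataFrame([
    claim("A", "2010-05-01", "E11", age=65),                      # qualifies
    claim("B", "2010-05-01", "E11", age=19),                      # under age
    claim("C", "2011-02-10", "E14.9", age=20),                    # boundary age, sub-code
    claim("D", "2011-02-10", "E10", age=65),                      # wrong diagnosis
    claim("E", "2012-06-10", "E11", age=65, setting="inpatient"),  # inpatient only
    claim("F", "2009-06-10", "E14", age=65),                      # outside index window
])


def brute_force_cohort(frame, window=("2010-01", "2012-12"), min_age=20,
                       codes=("E11", "E14")):
    """Exhaustive rule application over individual records."""
    lo, hi = window
    members = set()
    for _, r in frame.iterrows():
        ym = r.service_date[:7]
        if (
            r.setting == "outpatient"
            and r.institution_type != "excluded_type"
            and lo <= ym <= hi
            and r.diagnosis_code[:3] in codes
            and r.age >= min_age
        ):
            members.add(r.patient_id)
    return members


class TestSelectCohort:
    def test_six_patient_fixture_matches_brute_force(self):
        got = p.select_cohort(SIX_PATIENTS)
        assert got == brute_force_cohort(SIX_PATIENTS) == {"A", "C"}

    def test_inpatient_only_patient_is_excluded(self):
        assert "E" not in p.select_cohort(SIX_PATIENTS)

    def test_empty_input_gives_empty_cohort(self):
        assert p.select_cohort(SIX_PATIENTS.iloc[0:0]) == set()

    def test_excluded_institution_claims_are_ignored(self):
        frame = pd.DataFrame([claim("G", "2011-01-05", "E11", inst="excluded_type")])
        assert p.select_cohort(frame) == set()

    def test_malformed_dates_are_rejected_not_fatal(self, caplog):
        frame = pd.DataFrame([
            claim("A", "2011-13-40", "E11"),
            claim("B", "2011-03-05", "E11"),
        ])
        with caplog.at_level("WARNING"):
            got = p.select_cohort(frame)
        assert got == {"B"}
        assert any("malformed" in m for m in caplog.messages)

    @pytest.mark.parametrize("wider_codes, lower_age", [
        (("E10", "E11", "E14"), 20), (("E11", "E14"), 15),
        (("E10", "E11", "E14"), 15),
    ])
    def test_enlarging_filters_never_shrinks_the_cohort(self, wider_codes, lower_age):
        base = p.select_cohort(SIX_PATIENTS)
        wider = p.select_cohort(SIX_PATIENTS, diagnosis_codes=wider_codes, min_age=lower_age)
        assert base <= wider


class TestComputeDDD:
    def test_zero_quantity_is_zero_ddd(self):
        entry = p.DrugEntry("X1", "constant", 100, 100, who_ddd_units=2.0)
        assert p.compute_ddd(entry, 0.0) == 0.0

    def test_standard_daily_dose_fallback(self):
        entry = p.DrugEntry("X2", "constant", 100, 100,
                            standard_daily_dose_units=2.0)
        assert p.compute_ddd(entry, 60.0) == 30.0

    def test_twenty_record_sum_matches_hand_total(self):
        rng = np.random.default_rng(0)
        entries = [
            p.DrugEntry(f"X{i}", "constant", 100, 100,
                        who_ddd_units=float(d) if i % 2 else None,
                        standard_daily_dose_units=None if i % 2 else float(d))
            for i, d in enumerate(rng.choice([0.5, 1.0, 2.0], size=20), start=1)
        ]
        qtys = rng.uniform(0, 90, size=20)
        hand_total = sum(
            q / (e.who_ddd_units or e.standard_daily_dose_units)
            for e, q in zip(entries, qtys)
        )
        got = sum(p.compute_ddd(e, q) for e, q in zip(entries, qtys))
        assert got == pytest.approx(hand_total, rel=1e-12)

    def test_missing_both_dose_fields_is_rejected_at_construction(self):
        with pytest.raises(p.ConfigurationError, match="X9"):
            p.DrugEntry("X9", "constant", 100, 100)


REGISTRY_2 = [
    p.DrugEntry("R1", "reduced", 100, 70, who_ddd_units=1.0),
    p.DrugEntry("C1", "constant", 200, 200, who_ddd_units=2.0),
]

TEN_RECORDS = pd.DataFrame([
    claim("A", "2010-01-05", "E11", drug="R1", qty=30, cost=3000),
    claim("A", "2010-01-20", "E11", drug="R1", qty=10, cost=1000),  # same month
    claim("B", "2010-01-06", "E14", drug="C1", qty=20, cost=4000),
    claim("C", "2010-01-07", "E11", drug="R1", qty=15, cost=1500),
    claim("C", "2010-01-08", "E11", drug="C1", qty=8, cost=1600),   # both groups
    claim("A", "2010-02-05", "E11", drug="R1", qty=30, cost=3000),
    claim("B", "2010-02-06", "E14", drug="C1", qty=10, cost=2000),
    claim("B", "2010-02-10", "E14", drug="R1", qty=5, cost=500),
    claim("D", "2010-02-11", "E11", drug="C1", qty=40, cost=8000),
    claim("A", "2010-02-12", "E11", qty=0, cost=100),  # diagnosis-only, no drug
])


@pytest.fixture(scope="module")
def series():
    cohort = {"A", "B", "C", "D"}
    return p.aggregate_monthly(TEN_RECORDS, cohort, REGISTRY_2,
                               origin="2010-01", n_months=2)


class TestAggregateMonthly:

    def test_distinct_patient_count_not_claim_count(self, series):
        # A has two reduced claims in 2010-01 but counts once
        assert series[("n_patients", "reduced")].values.tolist() == [2, 2]
        assert series[("n_patients", "constant")].values.tolist() == [2, 2]
        # overall counts distinct patients across both groups
        assert series[("n_patients", "overall")].values.tolist() == [3, 3]

    def test_totals_match_spreadsheet_computation(self, series):
        # month 1: reduced cost 3000+1000+1500, constant 4000+1600
        assert series[("cost_total", "reduced")].values.tolist() == [5500, 3500]
        assert series[("cost_total", "constant")].values.tolist() == [5600, 10000]
        # DDD: reduced qty/1.0; constant qty/2.0
        assert series[("ddd_total", "reduced")].values.tolist() == [55, 35]
        assert series[("ddd_total", "constant")].values.tolist() == [14, 25]

    def test_per_patient_is_total_over_distinct_patients(self, series):
        np.testing.assert_allclose(
            series[("cost_per_patient", "reduced")].values, [5500 / 2, 3500 / 2]
        )
        np.testing.assert_allclose(
            series[("ddd_per_patient", "overall")].values, [69 / 3, 60 / 3]
        )

    def test_overall_equals_reduced_plus_constant(self, series):
        for outcome in ("cost_total", "ddd_total"):
            np.testing.assert_allclose(
                series[(outcome, "overall")].values,
                series[(outcome, "reduced")].values + series[(outcome, "constant")].values,
            )

    def test_months_without_patients_are_missing_not_zero(self):
        series = p.aggregate_monthly(TEN_RECORDS, {"A", "B", "C", "D"}, REGISTRY_2,
                                     origin="2010-01", n_months=3)
        assert series[("n_patients", "overall")].values[2] == 0
        assert np.isnan(series[("cost_per_patient", "overall")].values[2])

    def test_unknown_drug_code_raises_with_offender_named(self):
        bad = pd.concat(
            [TEN_RECORDS, pd.DataFrame([claim("Z", "2010-01-09", "E11", drug="MYSTERY")])],
            ignore_index=True,
        )
        with pytest.raises(p.AggregationError, match="MYSTERY"):
            p.aggregate_monthly(bad, {"A", "B", "C", "D", "Z"}, REGISTRY_2,
                                origin="2010-01", n_months=2)

    def test_non_cohort_patients_are_excluded(self, series):
        smaller = p.aggregate_monthly(TEN_RECORDS, {"A"}, REGISTRY_2,
                                      origin="2010-01", n_months=2)
        assert smaller[("cost_total", "reduced")].values.tolist() == [4000, 3000]


class TestRoundTrip:
    def test_claims_aggregation_reproduces_generator_targets(self):
        """Counts exactly; DDD/cost totals within stated rounding bounds."""
        cfg = p.SyntheticConfig(seed=31).scaled(0.0002)
        registry = p.make_default_registry()
        claims = p.generate_claims(cfg, registry)
        cohort = p.select_cohort(claims, index_window=cfg.index_window)
        series = p.aggregate_monthly(claims, cohort, registry,
                                     origin=cfg.schedule.origin,
                                     n_months=cfg.n_months)
        from priceits.synthetic import _target_counts, _target_totals
        for group in ("reduced", "constant"):
            target_n = _target_counts(cfg, group, 10**9).astype(float)
            np.testing.assert_array_equal(series[("n_patients", group)].values, target_n)
            target_ddd = _target_totals(cfg, "ddd_total", group, raw=True)
            np.testing.assert_allclose(series[("ddd_total", group)].values,
                                       target_ddd, rtol=1e-9)


class TestDescriptiveSummary:
    def make_series(self, values):
        return {("cost_total", "overall"): p.MonthlyOutcomeSeries(
            "cost_total", "overall", "2009-01", np.asarray(values, dtype=float))}

    def test_constant_series_has_zero_sd(self):
        out = descriptive_summary(self.make_series([5] * 12),
                                  [("y1", "2009-01", "2009-12")])
        assert out.loc[0, "mean"] == 5 and out.loc[0, "sd"] == 0

    def test_mean_and_sd_match_hand_computation(self):
        vals = [3, 1, 4, 1, 5, 9, 2, 6, 5, 3, 5, 8]
        out = descriptive_summary(self.make_series(vals),
                                  [("y1", "2009-01", "2009-12")])
        assert out.loc[0, "mean"] == pytest.approx(np.mean(vals))
        assert out.loc[0, "sd"] == pytest.approx(np.std(vals, ddof=1))

    def test_single_month_period_reports_missing_sd(self):
        out = descriptive_summary(self.make_series([7.0, 8.0]),
                                  [("m1", "2009-01", "2009-01")])
        assert out.loc[0, "mean"] == 7.0 and np.isnan(out.loc[0, "sd"])

    def test_overlapping_periods_rejected(self):
        with pytest.raises(p.AggregationError):
            descriptive_summary(self.make_series([1.0] * 12),
                                [("a", "2009-01", "2009-06"), ("b", "2009-06", "2009-12")])
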