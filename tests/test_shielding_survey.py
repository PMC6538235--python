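"""Workload, survey annual-dose, leakage, and TVL-thickness arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srsphys.shielding_survey import (ShieldingSource, ShieldingSpec,
                                      SurveyRecord, WorkloadModel,
                                      allowable_rate, annual_beam_hours,
                                      annual_dose, annual_mu, leakage_fraction,
                                      rad_on_hours, required_thickness,
                                      survey_report, thickness_profile,
                                      utilization, weekly_workload)
from srsphys.synthetic import make_survey_table


@pytest.fixture
def heavy_operation():
    # standard heavy operating conditions: 2,250 single-fraction patients/year
    return WorkloadModel(np_patients=2250.0, mu_per_treatment=6250.0,
                         dose_rate=1500.0, work_hours_per_year=2000.0)


class TestWorkloadChain:
    def test_annual_mu(self, heavy_operation):
        assert annual_mu(heavy_operation) == pytest.approx(1.40625e7)

    def test_daily_consistency(self):
        # 9 patients/day x 250 days at 6,250 MU reproduces the annual total
        model = WorkloadModel(np_patients=9 * 250, mu_per_treatment=6250.0)
        assert annual_mu(model) == pytest.approx(56250.0 * 250)

    def test_rad_on_hours(self, heavy_operation):
        assert rad_on_hours(heavy_operation) == pytest.approx(156.25)

    def test_utilization(self, heavy_operation):
        assert utilization(heavy_operation) == pytest.approx(0.078125)
        assert round(utilization(heavy_operation), 4) == 0.0781

    def test_utilization_inverse_in_dose_rate(self, heavy_operation):
        slow = WorkloadModel(np_patients=2250.0, mu_per_treatment=6250.0,
                             dose_rate=750.0)
        assert utilization(slow) == pytest.approx(
            2 * utilization(heavy_operation))

    def test_utilization_saturates_at_one(self):
        model = WorkloadModel(np_patients=1.0,
                              mu_per_treatment=1500.0 * 60 * 2000,
                              dose_rate=1500.0)
        assert utilization(model) == pytest.approx(1.0)

    def test_allowable_rate_for_public_limit(self, heavy_operation):
        # 500 mrem/yr budget at utilization 0.0781 -> 3.2 mrem/hr at 1 m
        assert allowable_rate(500.0, heavy_operation) == pytest.approx(3.2)

    def test_allowable_rate_quintupled_census(self):
        model = WorkloadModel(np_patients=5 * 2250.0, mu_per_treatment=6250.0)
        assert allowable_rate(500.0, model) == pytest.approx(0.64)

    def test_allowable_rate_at_full_utilization(self):
        model = WorkloadModel(np_patients=1.0,
                              mu_per_treatment=1500.0 * 60 * 2000,
                              dose_rate=1500.0)
        assert allowable_rate(500.0, model) == pytest.approx(500.0 / 2000.0)

    def test_weekly_workload_formula(self):
        model = WorkloadModel(np_patients=50 * 50.0, treatment_time_T=30.0,
                              qual_time_Tqc=2.0, weeks_Nw=50.0)
        assert weekly_workload(model) == pytest.approx(50 * 0.5 + 2.0)

    def test_annual_beam_hours_scales_with_factors(self):
        model = WorkloadModel(np_patients=50 * 50.0, treatment_time_T=30.0,
                              qual_time_Tqc=2.0, weeks_Nw=50.0,
                              use_factor_U=0.5, safety_factor_SF=2.0)
        assert annual_beam_hours(model) == pytest.approx(
            0.5 * 27.0 * 2.0 * 50.0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(limit=st.floats(min_value=1.0, max_value=1e4),
       patients=st.floats(min_value=1.0, max_value=1e4))
def test_algebraic_closure_of_rate_chain(limit, patients):
    # utilization x allowable_rate x work_hours == annual_limit exactly
    model = WorkloadModel(np_patients=patients, mu_per_treatment=6250.0)
    product = (utilization(model) * allowable_rate(limit, model)
               * model.work_hours_per_year)
    assert product == pytest.approx(limit, rel=1e-12)


class TestAnnualDose:
    def test_highest_rate_station(self):
        r = SurveyRecord(1, "Foot End Table Shield", "G=45", 3.0, 0.2, 0.078)
        assert annual_dose(r, 2000.0) == pytest.approx(0.936)

    def test_zero_rate(self):
        r = SurveyRecord(2, "quiet", "G=0", 0.0, 0.2, 0.078)
        assert annual_dose(r, 2000.0) == 0.0

    def test_rounding_to_3_decimals(self):
        r = SurveyRecord(10, "Left - Head", "G=45", 2.80, 0.2, 0.078)
        assert round(annual_dose(r, 2000.0), 3) == 0.874

    def test_linearity_in_each_factor(self):
        base = SurveyRecord(1, "a", "G=0", 1.0, 0.5, 0.1)
        doubled = SurveyRecord(1, "a", "G=0", 2.0, 0.5, 0.1)
        assert annual_dose(doubled, 2000.0) == pytest.approx(
            2 * annual_dose(base, 2000.0))
        assert annual_dose(base, 4000.0) == pytest.approx(
            2 * annual_dose(base, 2000.0))


class TestSurveyReport:
    def test_canonical_table_all_pass(self):
        report = survey_report(make_survey_table(), limit_msv=1.0,
                               rate_limit=3.2)
        assert report.all_pass
        assert report.max_rate == pytest.approx(3.0)
        assert report.max_rate_station == 1
        assert (report.table["annual_dose_msv"] < 1.0).all()

    def test_order_independence(self):
        records = make_survey_table()
        a = survey_report(records).table.sort_values("station").reset_index(drop=True)
        b = survey_report(records[::-1]).table.sort_values("station").reset_index(drop=True)
        assert a.equals(b)

    def test_rate_limit_violation_flagged(self):
        r = SurveyRecord(99, "hot spot", "G=0", 3.3, 0.2, 0.05)
        report = survey_report([r], rate_limit=3.2)
        assert not report.all_pass
        assert not report.table.loc[0, "rate_pass"]
        assert report.table.loc[0, "dose_pass"]

    def test_empty_records_raise(self):
        with pytest.raises(ValueError):
            survey_report([])


class TestLeakage:
    def test_patient_plane_maximum(self):
        assert leakage_fraction(10.4, 1000.0, 1.0) == pytest.approx(0.00104)

    def test_along_linac_maximum(self):
        assert leakage_fraction(6.8, 1000.0, 1.0) == pytest.approx(0.00068)

    def test_regulatory_boundary(self):
        # 1 R leakage against 1,000 R primary is the 0.1% regulatory limit
        assert leakage_fraction(1000.0, 1000.0, 1.0) == pytest.approx(0.1)

    def test_zero_mu_raises(self):
        with pytest.raises(ValueError):
            leakage_fraction(10.4, 0.0)


@pytest.fixture
def tungsten_spec():
    return ShieldingSpec(
        sources=[ShieldingSource("target-scatter", {"tungsten": 30.0})],
        required_attenuation=1e-5)


class TestRequiredThickness:
    def test_five_tvls(self, tungsten_spec):
        assert required_thickness(tungsten_spec, 0.0, "tungsten") == \
            pytest.approx(150.0)

    def test_single_tvl_definition(self):
        spec = ShieldingSpec(
            sources=[ShieldingSource("leakage", {"iron": 50.0})],
            required_attenuation=0.1)
        assert required_thickness(spec, 0.0, "iron") == pytest.approx(50.0)

    def test_no_attenuation_needs_no_shield(self):
        spec = ShieldingSpec(
            sources=[ShieldingSource("leakage", {"iron": 50.0})],
            required_attenuation=1.0)
        assert required_thickness(spec, 0.0, "iron") == 0.0

    def test_attenuation_above_one_rejected(self):
        with pytest.raises(ValueError):
            ShieldingSpec(sources=[ShieldingSource("leakage", {"iron": 50.0})],
                          required_attenuation=1.5)

    def test_max_over_sources(self):
        spec = ShieldingSpec(
            sources=[ShieldingSource("target-scatter", {"iron": 20.0}),
                     ShieldingSource("patient-scatter", {"iron": 35.0})],
            required_attenuation=0.01)
        assert required_thickness(spec, 0.0, "iron") == pytest.approx(70.0)

    def test_angular_tvl_interpolation(self):
        source = ShieldingSource(
            "patient-scatter", {"iron": ([0.0, 90.0, 180.0], [40.0, 20.0, 10.0])})
        spec = ShieldingSpec(sources=[source], required_attenuation=0.1)
        assert required_thickness(spec, 45.0, "iron") == pytest.approx(30.0)
        profile = thickness_profile(spec, "iron", angles=[0, 90, 180])
        assert profile["thickness_mm"].tolist() == [40.0, 20.0, 10.0]

    def test_monotone_in_attenuation(self):
        def t(a):
            spec = ShieldingSpec(
                sources=[ShieldingSource("leakage", {"iron": 30.0})],
                required_attenuation=a)
            return required_thickness(spec, 0.0, "iron")
        assert t(1e-4) > t(1e-3) > t(1e-2)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(a=st.floats(min_value=1e-8, max_value=1.0),
       b=st.floats(min_value=1e-8, max_value=1.0))
def test_thickness_additive_over_attenuation_product(a, b):
    def t(att):
        spec = ShieldingSpec(
            sources=[ShieldingSource("leakage", {"iron": 30.0})],
            required_attenuation=att)
        return required_thickness(spec, 0.0, "iron")
    assert t(a * b) == pytest.approx(t(a) + t(b), rel=1e-9, abs=1e-9)


def test_workload_model_validation():
    with pytest.raises(ValueError):
        WorkloadModel(np_patients=-1.0)
    with pytest.raises(ValueError):
        WorkloadModel(use_factor_U=1.5)
    with pytest.raises(ValueError):
        SurveyRecord(1, "x", "G=0", -0.1, 0.2, 0.078)
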