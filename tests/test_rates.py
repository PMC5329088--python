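from datetime import date

import numpy as np
import pandas as pd
import pytest

from adtrends.cohort import build_person_time_table
from adtrends.config import SimulationConfig, StudyConfig
from adtrends.drugs import classify_table
from adtrends.episodes import build_episodes, flag_incident
from adtrends.rates import (
    apply_sensitivity,
    cochran_armitage_trend,
    duration_trend,
    incidence,
    period_prevalence,
    sex_ratio_series,
)
from adtrends.synthetic import simulate_study
from conftest import make_patients, make_therapy


def _registered_patients(n, sex="F"):
    return make_patients(
        [(f"p{i}", sex, date(1950, 1, 1), date(1992, 1, 1), None) for i in range(n)]
    )


class TestPeriodPrevalence:
    def test_no_prescriptions_gives_all_zero_rates(self, study):
        pats = _registered_patients(3)
        pt = build_person_time_table(pats, study, "none")
        out = period_prevalence(make_therapy([]), pt, pats, study)
        assert (out["rate_per_1000py"] == 0).all()
        assert len(out) == 17

    def test_two_of_ten_patients_gives_200_per_1000py(self, study):
        pats = _registered_patients(10)
        pt = build_person_time_table(pats, study, "none")
        rx = classify_table(
            make_therapy(
                [
                    ("p0", date(2000, 3, 1), "fluoxetine", 20.0, 28, 1.0),
                    ("p1", date(2000, 9, 1), "dosulepin", 75.0, 28, 1.0),
                ]
            )
        )
        out = period_prevalence(rx, pt, pats, study).set_index("year")
        assert out.loc[2000, "numerator"] == 2
        assert out.loc[2000, "rate_per_1000py"] == pytest.approx(200.0)

    def test_patient_with_many_scripts_counts_once_per_year(self, study):
        pats = _registered_patients(10)
        pt = build_person_time_table(pats, study, "none")
        rx = classify_table(
            make_therapy(
                [
                    ("p0", date(2000, m, 1), "fluoxetine", 20.0, 28, 1.0)
                    for m in range(1, 13)
                ]
            )
        )
        out = period_prevalence(rx, pt, pats, study).set_index("year")
        assert out.loc[2000, "numerator"] == 1

    def test_rate_identity_holds_on_simulated_data(self, study):
        pats, rx, _ = simulate_study(SimulationConfig(n_patients=600, seed=9))
        rx = classify_table(rx)
        pt = build_person_time_table(pats, study, "none")
        out = period_prevalence(rx, pt, pats, study)
        ok = out["person_years"] > 0
        np.testing.assert_allclose(
            out.loc[ok, "rate_per_1000py"],
            1000.0 * out.loc[ok, "numerator"] / out.loc[ok, "person_years"],
            rtol=1e-9,
        )

    def test_zero_person_years_with_events_is_an_error(self, study):
        pats = _registered_patients(1)
        rx = classify_table(
            make_therapy([("p0", date(2000, 3, 1), "fluoxetine", 20.0, 28, 1.0)])
        )
        pt = build_person_time_table(pats, study, "none")
        pt.loc[pt["year"] == 2000, "person_years"] = 0.0
        with pytest.raises(ValueError, match="zero person-years"):
            period_prevalence(rx, pt, pats, study)

    def test_class_stratified_numerators_bound_overall(self, study):
        """A patient may appear under several classes, so per-class numerators
        sum to at least the overall distinct-patient numerator."""
        pats, rx, _ = simulate_study(SimulationConfig(n_patients=800, seed=13))
        rx = classify_table(rx)
        pt = build_person_time_table(pats, study, "none")
        overall = period_prevalence(rx, pt, pats, study, "none")
        byclass = period_prevalence(rx, pt, pats, study, "drug_class")
        merged = (
            byclass.groupby("year")["numerator"].sum().rename("by_class").to_frame()
            .join(overall.set_index("year")["numerator"])
        )
        assert (merged["by_class"] >= merged["numerator"]).all()


class TestIncidence:
    def test_one_start_among_fifty_person_years(self, study):
        pats = _registered_patients(50)
        pt = build_person_time_table(pats, study, "none")
        assert pt.loc[pt["year"] == 2000, "person_years"].iloc[0] == 50.0
        rx = classify_table(
            make_therapy([("p0", date(2000, 6, 1), "fluoxetine", 20.0, 28, 1.0)])
        )
        eps = flag_incident(build_episodes(rx, study), pats, study)
        out = incidence(eps, pt, pats, study).set_index("year")
        assert out.loc[2000, "rate_per_1000py"] == pytest.approx(20.0)

    def test_non_incident_episodes_contribute_nothing(self, study):
        pats = _registered_patients(5)
        pt = build_person_time_table(pats, study, "none")
        rx = classify_table(
            make_therapy([("p0", date(2000, 6, 1), "fluoxetine", 20.0, 28, 1.0)])
        )
        eps = build_episodes(rx, study)
        eps["incident"] = False
        out = incidence(eps, pt, pats, study)
        assert (out["rate_per_1000py"] == 0).all()

    def test_prevalence_dominates_incidence_everywhere(self, study):
        pats, rx, _ = simulate_study(SimulationConfig(n_patients=1000, seed=17))
        rx = classify_table(rx)
        pt = build_person_time_table(pats, study, "none")
        eps = flag_incident(build_episodes(rx, study), pats, study)
        prev = period_prevalence(rx, pt, pats, study).set_index("year")
        inc = incidence(eps, pt, pats, study).set_index("year")
        assert (inc["numerator"] <= prev["numerator"]).all()
        assert (inc["rate_per_1000py"] <= prev["rate_per_1000py"] + 1e-12).all()


class TestSexRatio:
    def _series(self, counts):
        rows = []
        for year, (f, m) in counts.items():
            rows.append((year, "F", f, 1000.0, f))
            rows.append((year, "M", m, 1000.0, m))
        return pd.DataFrame(
            rows, columns=["year", "stratum", "numerator", "person_years", "rate_per_1000py"]
        )

    def test_equal_rates_give_unit_ratio_and_null_trend(self):
        series = self._series({y: (30, 30) for y in range(1995, 2012)})
        ratios, test = sex_ratio_series(series)
        assert (ratios["fm_ratio"] == 1.0).all()
        assert test["chi2"] == pytest.approx(0.0, abs=1e-12)

    def test_double_female_rate_gives_ratio_two(self):
        series = self._series({2000: (40, 20), 2001: (40, 20)})
        ratios, _ = sex_ratio_series(series)
        assert (ratios["fm_ratio"] == 2.0).all()

    def test_zero_male_rate_reported_as_missing(self):
        series = self._series({2000: (40, 0), 2001: (40, 20)})
        ratios, _ = sex_ratio_series(series)
        assert np.isnan(ratios.loc[ratios["year"] == 2000, "fm_ratio"]).all()

    def test_trend_statistic_matches_textbook_computation(self):
        """Cochran-Armitage with year scores, cross-checked against an explicit
        per-cell computation of the score-correlation form chi2 = N * r^2."""
        years = np.arange(1995, 2012)
        f = np.round(np.linspace(60, 40, len(years))).astype(int)
        m = np.round(np.linspace(30, 38, len(years))).astype(int)
        got = cochran_armitage_trend(f, m, years)

        # brute force: expand to one row per event, correlate outcome with score
        outcome, score = [], []
        for y, a, b in zip(years, f, m):
            outcome += [1] * a + [0] * b
            score += [y] * (a + b)
        outcome, score = np.array(outcome, float), np.array(score, float)
        r = np.corrcoef(outcome, score)[0, 1]
        assert got["chi2"] == pytest.approx(len(outcome) * r**2, rel=1e-9)
        assert got["pvalue"] < 0.01  # the constructed counts converge

    def test_trend_statistic_agrees_with_linear_by_linear_association(self):
        """Independent route: the linear-by-linear association statistic
        (N-1)r^2 rescales to the trend chi-square by N/(N-1)."""
        from statsmodels.stats.contingency_tables import Table

        years = np.arange(1995, 2012)
        rng = np.random.default_rng(3)
        f = rng.integers(20, 80, len(years))
        m = rng.integers(20, 80, len(years))
        got = cochran_armitage_trend(f, m, years)
        res = Table(np.column_stack([f, m])).test_ordinal_association(
            row_scores=years, col_scores=np.array([1, 0])
        )
        n = int((f + m).sum())
        assert got["chi2"] == pytest.approx(res.zscore**2 * n / (n - 1), rel=1e-9)


class TestDurationTrend:
    def test_uniform_short_episodes(self, study):
        eps = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(30)],
                "start_date": [date(1995 + i % 15, 3, 1) for i in range(30)],
                "start_year": [1995 + i % 15 for i in range(30)],
                "duration_days": [10] * 30,
                "incident": [True] * 30,
            }
        )
        out = duration_trend(eps, study)
        props = out["proportions"]
        short = props[props["category"] == "<=30"]
        assert (short["proportion"] == 1.0).all()
        assert (out["medians"]["median_duration_days"] == 10).all()

    def test_proportions_sum_to_one_per_start_year(self, study):
        pats, rx, _ = simulate_study(SimulationConfig(n_patients=1500, seed=23))
        rx = classify_table(rx)
        eps = flag_incident(build_episodes(rx, study), pats, study)
        props = duration_trend(eps, study)["proportions"]
        sums = props.groupby("start_year")["proportion"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_years_without_incident_episodes_warn_and_are_omitted(self, study):
        eps = pd.DataFrame(
            {
                "patient_id": ["p0"],
                "start_date": [date(1995, 3, 1)],
                "start_year": [1995],
                "duration_days": [40],
                "incident": [True],
            }
        )
        with pytest.warns(UserWarning, match="1996"):
            out = duration_trend(eps, study)
        assert out["medians"]["start_year"].tolist() == [1995]

    def test_restricted_to_last_duration_start_year(self, study):
        eps = pd.DataFrame(
            {
                "patient_id": ["p0", "p1"],
                "start_date": [date(2009, 3, 1), date(2010, 3, 1)],
                "start_year": [2009, 2010],
                "duration_days": [40, 40],
                "incident": [True, True],
            }
        )
        with pytest.warns(UserWarning):
            out = duration_trend(eps, study)
        assert 2010 not in set(out["medians"]["start_year"])


class TestSensitivity:
    def test_no_amitriptyline_is_a_no_op(self, study):
        rx = make_therapy([("p0", date(2000, 1, 1), "fluoxetine", 20.0, 28, 1.0)])
        pats = _registered_patients(1)
        rx2, pats2 = apply_sensitivity(rx, pats, "exclude_low_dose_ami", study)
        pd.testing.assert_frame_equal(rx2.reset_index(drop=True), rx)
        assert len(pats2) == len(pats)

    def test_low_dose_scripts_removed_high_dose_kept(self, study):
        rx = make_therapy(
            [
                ("p0", date(2000, 1, 1), "amitriptyline", 50.0, 28, 1.0),
                ("p0", date(2001, 1, 1), "amitriptyline", 150.0, 28, 1.0),
            ]
        )
        rx2, _ = apply_sensitivity(rx, _registered_patients(1), "exclude_low_dose_ami", study)
        assert rx2["daily_dose_mg"].tolist() == [150.0]

    def test_patient_level_exclusion_drops_all_flagged_patients(self):
        study = StudyConfig(low_dose_exclusion_level="patient")
        rx = make_therapy(
            [
                ("p0", date(2000, 1, 1), "amitriptyline", 50.0, 28, 1.0),
                ("p1", date(2000, 1, 1), "amitriptyline", 50.0, 28, 1.0),
                ("p1", date(2003, 1, 1), "fluoxetine", 20.0, 28, 1.0),
            ]
        )
        rx2, pats2 = apply_sensitivity(rx, _registered_patients(3), "exclude_low_dose_ami", study)
        # p0's only script was low-dose: the patient goes; p1 keeps fluoxetine
        assert set(pats2["patient_id"]) == {"p1", "p2"}
        assert rx2["product_name"].tolist() == ["fluoxetine"]

    def test_full_depression_flagging_is_a_no_op(self, study):
        pats = _registered_patients(4)
        pats["depression_flag"] = True
        rx = make_therapy([("p0", date(2000, 1, 1), "fluoxetine", 20.0, 28, 1.0)])
        rx2, pats2 = apply_sensitivity(rx, pats, "depression_subgroup", study)
        assert len(pats2) == 4 and len(rx2) == 1

    def test_depression_subgroup_keeps_flagged_patients_only(self, study):
        pats = _registered_patients(10)
        pats.loc[:2, "depression_flag"] = True
        rx = make_therapy(
            [(f"p{i}", date(2000, 1, 1), "fluoxetine", 20.0, 28, 1.0) for i in range(10)]
        )
        rx2, pats2 = apply_sensitivity(rx, pats, "depression_subgroup", study)
        assert len(pats2) == 3 and len(rx2) == 3

    def test_unknown_mode_rejected(self, study):
        with pytest.raises(ValueError, match="unknown sensitivity mode"):
            apply_sensitivity(make_therapy([]), _registered_patients(1), "bootstrap", study)
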