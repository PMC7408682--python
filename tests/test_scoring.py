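"""Cox fitting, Sullivan risk points, comorbidity score, and strata."""

import numpy as np
import pandas as pd
import pytest

from comorisk import reference
from comorisk.markers import ComorbidityProfile, classify_cohort
from comorisk.scoring import (
    CoxModelFit,
    RiskPointTable,
    comorbidity_score,
    fit_comorbidity_model,
    fit_cox,
    round_half_away,
    score_cohort_points,
    stratify,
    sullivan_points,
)

from conftest import clean_config
from comorisk.simulate import generate_cohort


def test_round_half_away():
    assert round_half_away(2.5) == 3
    assert round_half_away(-2.5) == -3
    assert round_half_away(2.49) == 2
    assert round_half_away(-0.5) == -1


class TestFitCox:
    def test_toy_closed_form_maximizer(self):
        # risk sets give L = 1/(2+e^b) * e^b/(1+e^b); maximized at b = ln(2)/2
        df = pd.DataFrame(
            {"followup_years": [1.0, 2.0, 3.0], "cancer_event": [True, True, False],
             "x": [0.0, 1.0, 0.0]}
        )
        fit = fit_cox(df, ["x"])
        assert fit.terms["x"] == pytest.approx(np.log(2) / 2, abs=1e-8)
        assert fit.n_events == 2

    def test_null_data_gives_near_zero_coefficient(self, rng):
        n = 800
        df = pd.DataFrame(
            {"followup_years": rng.exponential(1.0, n), "cancer_event": True,
             "x": rng.permutation(np.repeat([0.0, 1.0], n // 2))}
        )
        fit = fit_cox(df, ["x"])
        assert abs(fit.terms["x"]) < 3 * fit.standard_errors["x"]

    def test_time_scale_invariance(self):
        df = pd.DataFrame(
            {"followup_years": [1.0, 2.0, 3.0, 4.0], "cancer_event": [1, 1, 0, 1],
             "x": [0.0, 1.0, 0.0, 1.0]}
        )
        f1 = fit_cox(df, ["x"])
        df2 = df.assign(followup_years=df["followup_years"] * 7.3)
        f2 = fit_cox(df2, ["x"])
        assert f1.terms["x"] == pytest.approx(f2.terms["x"], abs=1e-10)

    def test_breslow_ties_available_and_differs_with_ties(self):
        df = pd.DataFrame(
            {"followup_years": [1.0, 1.0, 1.0, 2.0, 3.0],
             "cancer_event": [1, 1, 1, 0, 1], "x": [1.0, 1.0, 0.0, 0.0, 1.0]}
        )
        fe = fit_cox(df, ["x"], ties="efron")
        fb = fit_cox(df, ["x"], ties="breslow")
        assert fe.ties_method == "efron" and fb.ties_method == "breslow"
        assert fe.terms["x"] != pytest.approx(fb.terms["x"], abs=1e-12)

    def test_requires_events_and_positive_times(self):
        df = pd.DataFrame({"followup_years": [1.0], "cancer_event": [False], "x": [0.0]})
        with pytest.raises(ValueError, match="event"):
            fit_cox(df, ["x"])

    def test_known_coefficient_coverage_in_simulation(self):
        """Joint marker model covers each true log-hazard in its 95% Wald CI
        in >= 90 of 100 seeded replicates."""
        terms = {
            "bp_category[elevated]": ("blood_pressure", "elevated"),
            "bp_category[hypertension]": ("blood_pressure", "hypertension"),
            "chol_category[low]": ("cholesterol", "low"),
            "chol_category[normal]": ("cholesterol", "normal"),
            "glucose_category[prediabetes_diabetes]": ("glucose", "prediabetes_diabetes"),
            "gfr_category[b60_89]": ("gfr", "b60_89"),
            "gfr_category[ge90]": ("gfr", "ge90"),
        }
        covered = {t: 0 for t in list(terms) + ["age"]}
        n_rep = 100
        for rep in range(n_rep):
            cfg = clean_config(n_subjects=2500, seed=70_000 + rep, baseline_hazard=6e-4)
            df = classify_cohort(generate_cohort(cfg))
            fit = fit_comorbidity_model(df, model="adjusted")
            for term in covered:
                if term == "age":
                    true = cfg.beta_age
                else:
                    marker, cat = terms[term]
                    true = cfg.category_log_hazards[marker][cat]
                lo = fit.terms[term] - 1.96 * fit.standard_errors[term]
                hi = fit.terms[term] + 1.96 * fit.standard_errors[term]
                covered[term] += lo <= true <= hi
        for term, count in covered.items():
            assert count >= 90, (term, count)


class TestSullivanPoints:
    def _fit(self, coefs: dict[str, float]) -> CoxModelFit:
        s = pd.Series(coefs)
        return CoxModelFit(
            terms=s, standard_errors=pd.Series(0.1, index=s.index),
            log_likelihood=0.0, n_events=100, ties_method="efron",
        )

    def _full(self, beta_age: float, ratios: dict[str, float]) -> CoxModelFit:
        coefs = {"age": beta_age}
        for col_level, hr in ratios.items():
            coefs[col_level] = np.log(hr)
        return self._fit(coefs)

    def test_unit_ratio_scores_one_point(self):
        fit = self._full(0.05, {
            "bp_category[elevated]": np.exp(0.05), "bp_category[hypertension]": np.exp(0.05),
            "chol_category[low]": np.exp(0.05), "chol_category[normal]": np.exp(0.05),
            "glucose_category[prediabetes_diabetes]": np.exp(0.05),
            "gfr_category[b60_89]": np.exp(0.05), "gfr_category[ge90]": np.exp(0.05),
        })
        table = sullivan_points(fit)
        assert all(pt in (0, 1) for cats in table.points.values() for pt in cats.values())

    def test_published_hazard_ratios_reproduce_published_points(self):
        """At beta_age = 0.0556, the printed fully adjusted HRs round to the
        printed points for the prediabetes/diabetes and elevated-BP rows."""
        fit = self._full(0.0556, {
            "bp_category[elevated]": 1.12, "bp_category[hypertension]": 1.56,
            "chol_category[low]": 1.31, "chol_category[normal]": 1.51,
            "glucose_category[prediabetes_diabetes]": 1.32,
            "gfr_category[b60_89]": 1.11, "gfr_category[ge90]": 1.65,
        })
        table = sullivan_points(fit)
        assert table.points["glucose"]["prediabetes_diabetes"] == 5
        assert table.points["blood_pressure"]["elevated"] == 2
        assert table.points["blood_pressure"]["hypertension"] == 8
        assert table.points["gfr"]["ge90"] == 9

    def test_reference_categories_score_zero(self):
        table = RiskPointTable.from_reference("main")
        assert table.points["blood_pressure"]["normal"] == 0
        assert table.points["cholesterol"]["elevated"] == 0
        assert table.points["glucose"]["normal"] == 0
        assert table.points["gfr"]["lt60"] == 0

    def test_negative_points_retained_not_clamped(self):
        fit = self._full(0.05, {
            "bp_category[elevated]": np.exp(-0.12), "bp_category[hypertension]": 1.5,
            "chol_category[low]": 1.2, "chol_category[normal]": 1.3,
            "glucose_category[prediabetes_diabetes]": 1.1,
            "gfr_category[b60_89]": 1.05, "gfr_category[ge90]": 1.4,
        })
        assert sullivan_points(fit).points["blood_pressure"]["elevated"] == -2

    def test_nonpositive_age_coefficient_fails(self):
        fit = self._fit({"age": -0.01, "bp_category[elevated]": 0.1})
        with pytest.raises(ValueError, match="age coefficient"):
            sullivan_points(fit, markers=("blood_pressure",))


class TestComorbidityScore:
    def test_all_reference_categories_score_zero(self):
        table = RiskPointTable.from_reference("main")
        profile = ComorbidityProfile("normal", "elevated", "normal", 50.0, "lt60")
        assert comorbidity_score(profile, table) == 0

    def test_maximum_attainable_combination(self):
        table = RiskPointTable.from_reference("main")
        cats = {"blood_pressure": "hypertension", "cholesterol": "normal",
                "glucose": "prediabetes_diabetes", "gfr": "ge90"}
        assert comorbidity_score(cats, table) == 30 == table.max_score

    def test_cholesterol_excluded_maximum(self):
        table = RiskPointTable.from_reference("no_cholesterol")
        cats = {"blood_pressure": "hypertension", "cholesterol": "normal",
                "glucose": "prediabetes_diabetes", "gfr": "ge90"}
        assert comorbidity_score(cats, table) == 23 == table.max_score
        assert "cholesterol" not in table.included_markers

    def test_score_is_additive_over_included_markers(self):
        table = RiskPointTable.from_reference("main")
        cats = {"blood_pressure": "elevated", "cholesterol": "low",
                "glucose": "prediabetes_diabetes", "gfr": "b60_89"}
        total = comorbidity_score(cats, table)
        parts = 0
        for marker in table.included_markers:
            solo = RiskPointTable(points=table.points, included_markers=(marker,))
            parts += comorbidity_score(cats, solo)
        assert total == parts == 2 + 5 + 5 + 2

    def test_unknown_category_fails(self):
        table = RiskPointTable.from_reference("main")
        with pytest.raises(KeyError):
            comorbidity_score({"blood_pressure": "nope", "cholesterol": "low",
                               "glucose": "normal", "gfr": "lt60"}, table)

    def test_vectorized_scoring_matches_scalar(self, clean_cohort):
        table = RiskPointTable.from_reference("main")
        df = classify_cohort(clean_cohort.iloc[:200])
        vec = score_cohort_points(df, table)
        for idx, row in df.iloc[:50].iterrows():
            cats = {"blood_pressure": row["bp_category"], "cholesterol": row["chol_category"],
                    "glucose": row["glucose_category"], "gfr": row["gfr_category"]}
            assert vec[idx] == comorbidity_score(cats, table)


class TestStratify:
    @pytest.mark.parametrize("score,label", [(0, "0-8"), (8, "0-8"), (9, "9-10"),
                                             (10, "9-10"), (11, "11-15"), (15, "11-15"),
                                             (16, "16-30"), (30, "16-30")])
    def test_printed_cutpoints(self, score, label):
        assert stratify(np.array([score]))[0] == label

    def test_empty_input(self):
        assert len(stratify(np.array([], dtype=int))) == 0

    def test_out_of_range_fails_loudly(self):
        with pytest.raises(ValueError, match="outside"):
            stratify(np.array([31]))
        with pytest.raises(ValueError, match="outside"):
            stratify(np.array([-1]))

    def test_non_contiguous_cutpoints_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            stratify(np.array([1]), [("0-3", 0, 3), ("5-9", 5, 9)])
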