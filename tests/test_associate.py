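"""Regression battery: standardization, OLS/LMM recovery, BH-FDR, comparisons."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from abimbalance.associate import (
    AssociationResult,
    ModelSpecification,
    chi_square_2x2,
    compare_groups,
    fdr_adjust,
    fit_cross_sectional,
    fit_longitudinal,
    run_analysis_suite,
    standardize_for_regression,
    t_test_from_summary,
    wilcoxon_rank_sum,
)
from abimbalance.simulate import SimulationConfig, simulate_cohort, simulate_longitudinal


def _linear_cohort(n=300, seed=0, beta_age=0.3, beta_female=-0.4):
    rng = np.random.default_rng(seed)
    age = rng.normal(70, 7, n)
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    apoe = rng.choice(3, n, p=[0.5, 0.4, 0.1])
    y = beta_age * (age - 70) / 7 + beta_female * (sex == "F") + rng.normal(0, 1, n)
    return pd.DataFrame(
        {"outcome": y, "age": age, "sex": sex, "apoe_e4_copies": apoe}
    )


class TestStandardize:
    def test_already_standardized_unchanged(self):
        rng = np.random.default_rng(1)
        z = rng.normal(0, 1, 100)
        z = (z - z.mean()) / z.std(ddof=1)
        t = pd.DataFrame({"outcome": z, "x": z.copy()})
        spec = ModelSpecification(outcome="outcome", predictors=["x"])
        df, info = standardize_for_regression(t, spec)
        assert np.allclose(df["x"], t["x"], atol=1e-12)
        assert info["n"] == 100

    def test_standardized_beta_identity(self):
        """beta_std equals beta_raw * SD_x / SD_y from the raw-units fit."""
        t = _linear_cohort()
        spec = ModelSpecification(outcome="outcome", predictors=["age"])
        df, info = standardize_for_regression(t, spec)
        std_fit = sm.OLS(df["outcome"], sm.add_constant(df[["age"]])).fit()
        raw_fit = sm.OLS(t["outcome"], sm.add_constant(t[["age"]])).fit()
        want = raw_fit.params["age"] * t["age"].std(ddof=1) / t["outcome"].std(ddof=1)
        assert std_fit.params["age"] == pytest.approx(want, rel=1e-10)

    def test_treatment_coding_against_fixed_references(self):
        t = _linear_cohort(n=50)
        t["fazekas"] = [0, 1, 2, 3, 0] * 10
        spec = ModelSpecification(
            outcome="outcome", predictors=["sex", "apoe_e4_copies", "fazekas"]
        )
        df, info = standardize_for_regression(t, spec)
        assert info["term_map"]["sex"] == ["sex_F"]
        assert info["term_map"]["apoe_e4_copies"] == [
            "apoe_e4_copies_1",
            "apoe_e4_copies_2",
        ]
        assert info["term_map"]["fazekas"] == ["fazekas_1", "fazekas_2_3"]
        # dummies unscaled: 0/1 values
        assert set(np.unique(df["sex_F"])) <= {0.0, 1.0}
        # fazekas 2 and 3 share one indicator
        assert df["fazekas_2_3"].sum() == ((t["fazekas"] >= 2).sum())

    def test_zero_variance_named(self):
        t = _linear_cohort(n=40)
        t["flat"] = 3.14
        spec = ModelSpecification(outcome="outcome", predictors=["flat"])
        with pytest.raises(ValueError, match="flat"):
            standardize_for_regression(t, spec)

    def test_unknown_categorical_level_rejected(self):
        t = _linear_cohort(n=40)
        t.loc[0, "sex"] = "X"
        spec = ModelSpecification(outcome="outcome", predictors=["sex"])
        with pytest.raises(ValueError, match="X"):
            standardize_for_regression(t, spec)


class TestCrossSectional:
    def test_recovers_simulated_effects(self):
        t = _linear_cohort(n=2000, seed=3)
        spec = ModelSpecification(
            outcome="outcome", predictors=["age", "sex", "apoe_e4_copies"]
        )
        rows = fit_cross_sectional(t, spec)
        by_term = {r.term: r for r in rows}
        sd_y = t["outcome"].std(ddof=1)
        age_row = by_term["age"]
        assert abs(age_row.beta - 0.3 / sd_y) < 2 * age_row.se
        fem = by_term["sex_F"]
        assert abs(fem.beta - (-0.4) / sd_y) < 2 * fem.se
        assert all(r.n == 2000 for r in rows)
        assert all(0 < r.p <= 1 for r in rows)

    def test_duplicate_predictor_rank_error(self):
        t = _linear_cohort(n=60)
        t["age2"] = t["age"]
        spec = ModelSpecification(outcome="outcome", predictors=["age", "age2"])
        with pytest.raises(ValueError, match="collinear"):
            fit_cross_sectional(t, spec)

    def test_interaction_terms_present(self):
        t = _linear_cohort(n=200, seed=5)
        t["severity"] = np.random.default_rng(0).normal(0, 1, 200)
        spec = ModelSpecification(
            outcome="outcome",
            predictors=["age"],
            covariates=["severity"],
            interactions=[("age", "severity")],
        )
        rows = fit_cross_sectional(t, spec)
        assert any(r.term == "age:severity" for r in rows)


class TestLongitudinal:
    def test_deterministic_limit_recovers_fixed_effects(self):
        cog = dict(
            random_intercept_sd=0.0,
            random_slope_sd=0.0,
            residual_sd=1e-6,
            agg_coef=0.25,
            sev_coef=-0.3,
            agg_time_coef=0.14,
            sev_time_coef=0.0,
            time_slope=-0.2,
            intercept=0.5,
        )
        cfg = SimulationConfig(n=80, seed=9, cognition=cog)
        cohort, truth = simulate_cohort(cfg)
        visits = simulate_longitudinal(cohort, truth, cfg)
        table = truth.rename(
            columns={"true_aggregation": "aggregation", "true_severity": "severity"}
        )
        spec = ModelSpecification(outcome="score", family="cognition")
        rows = fit_longitudinal(
            visits, table, spec, standardize_outcome=False
        )
        by_term = {r.term: r for r in rows}
        assert by_term["aggregation"].beta == pytest.approx(0.25, abs=1e-5)
        assert by_term["aggregation:time_years"].beta == pytest.approx(0.14, abs=1e-5)
        assert by_term["time_years"].beta == pytest.approx(-0.2, abs=1e-5)

    def test_slope_recovery_with_noise(self):
        cfg = SimulationConfig(n=300, seed=17)
        cohort, truth = simulate_cohort(cfg)
        visits = simulate_longitudinal(cohort, truth, cfg)
        table = truth.rename(
            columns={"true_aggregation": "aggregation", "true_severity": "severity"}
        )
        spec = ModelSpecification(outcome="score", family="cognition")
        rows = fit_longitudinal(visits, table, spec, standardize_outcome=False)
        slope = next(r for r in rows if r.term == "aggregation:time_years")
        assert abs(slope.beta - cfg.cognition.agg_time_coef) < 2.5 * slope.se
        assert slope.converged

    def test_three_way_interaction_terms(self):
        cfg = SimulationConfig(n=150, seed=23)
        cohort, truth = simulate_cohort(cfg)
        visits = simulate_longitudinal(cohort, truth, cfg)
        table = truth.rename(
            columns={"true_aggregation": "aggregation", "true_severity": "severity"}
        )
        spec = ModelSpecification(outcome="score", family="cognition")
        rows = fit_longitudinal(visits, table, spec, three_way=True)
        terms = {r.term for r in rows}
        assert "aggregation:severity:time_years" in terms
        assert {"aggregation:severity", "severity:time_years"} <= terms


class TestFdr:
    def test_worked_example(self):
        out = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])
        assert fdr_adjust([0.123]) == pytest.approx([0.123])
        assert len(fdr_adjust([])) == 0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 40))
    def test_matches_brute_force(self, seed, n):
        from conftest import bh_step_up_oracle

        p = np.random.default_rng(seed).uniform(1e-12, 1.0, n)
        assert np.allclose(fdr_adjust(p), bh_step_up_oracle(p), atol=1e-12)

    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(0.0001, 1.0, 100)
        adj = fdr_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)
        with pytest.raises(ValueError):
            fdr_adjust([0.0, 0.5])


class TestGroupComparisons:
    def test_pooled_t_from_printed_summaries(self):
        t, p = t_test_from_summary(73.0, 7.4, 822, 65.2, 6.9, 383)
        assert round(t, 1) == 17.4
        assert p < 0.001

    def test_identical_groups_null(self):
        t, p = t_test_from_summary(5.0, 1.0, 50, 5.0, 1.0, 50)
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_chi_square_with_continuity(self):
        stat, p = chi_square_2x2([[384, 438], [224, 159]])
        assert stat == pytest.approx(14.0125, abs=1e-3)
        stat_nc, _ = chi_square_2x2([[384, 438], [224, 159]], correction=False)
        assert stat_nc > stat

    def test_rank_sum_matches_r_convention(self):
        # W = sum of ranks of x in the combined sample minus n1(n1+1)/2
        x = np.array([1.0, 3.0, 5.0, 7.0])
        y = np.array([2.0, 4.0, 6.0])
        w, p = wilcoxon_rank_sum(x, y)
        assert w == 6.0  # rank-sum of x is 16, minus n1(n1+1)/2 = 10
        assert 0 < p <= 1

    def test_dispatcher(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(1, 1, 40)
        t1, _ = compare_groups(values=np.r_[a, b], groups=np.r_[[0] * 40, [1] * 40])
        t2, _ = compare_groups(
            summary=(a.mean(), a.std(ddof=1), 40, b.mean(), b.std(ddof=1), 40)
        )
        assert t1 == pytest.approx(t2)
        with pytest.raises(ValueError, match="n >= 2"):
            t_test_from_summary(0, 1, 1, 0, 1, 50)


class TestResultValidation:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="SE"):
            AssociationResult("m", "f", "all", "y", "x", 0.1, 0.0, 0.5, None, 0.1, 10)
        with pytest.raises(ValueError, match="adjusted"):
            AssociationResult("m", "f", "all", "y", "x", 0.1, 0.1, 0.5, 0.3, 0.1, 10)


@pytest.fixture(scope="module")
def scored_suite_inputs():
    cfg = SimulationConfig(n=400, seed=31)
    cohort, truth = simulate_cohort(cfg)
    visits = simulate_longitudinal(cohort, truth, cfg)
    # analysis path uses model-free stand-in scores from the ground truth,
    # merged the same way the scoring stage would
    cohort = cohort.assign(
        aggregation=truth["true_aggregation"], severity=truth["true_severity"]
    )
    return cohort, visits


class TestSuite:
    def test_all_families_present(self, scored_suite_inputs):
        cohort, visits = scored_suite_inputs
        rep = run_analysis_suite(cohort, visits, strata=("all",))
        fams = set(rep.results["family"])
        assert {
            "methodological",
            "demographics",
            "csf",
            "vascular",
            "cognition_baseline",
            "cognition_longitudinal",
        } <= fams
        # CSF family carries FDR-adjusted p-values
        csf = rep.results[rep.results["family"] == "csf"]
        assert csf["p_adj"].notna().all()
        assert (csf["p_adj"] >= csf["p"] - 1e-12).all()
        # raw and /Ab40 variants both appear
        models = set(csf["model"])
        assert any("over_ab40" in m for m in models)

    def test_stratified_reruns(self, scored_suite_inputs):
        cohort, visits = scored_suite_inputs
        rep = run_analysis_suite(cohort, None, strata=("all", "CU", "CI"), min_n=40)
        strata = set(rep.results["stratum"])
        assert "CU" in strata and "CI" in strata

    def test_missing_vascular_columns_disable_family(self, scored_suite_inputs):
        cohort, _ = scored_suite_inputs
        rep = run_analysis_suite(
            cohort.drop(columns=["wmh_volume_mm3", "fazekas"]), None, strata=("all",)
        )
        assert "vascular" not in set(rep.results["family"])
        assert any("vascular" in line for line in rep.log)

    def test_fazekas_used_when_wmh_absent(self, scored_suite_inputs):
        cohort, _ = scored_suite_inputs
        rep = run_analysis_suite(
            cohort.drop(columns=["wmh_volume_mm3"]), None, strata=("all",)
        )
        vasc = rep.results[rep.results["family"] == "vascular"]
        assert any(vasc["term"].str.startswith("fazekas"))

    def test_rerun_is_identical(self, scored_suite_inputs):
        cohort, visits = scored_suite_inputs
        r1 = run_analysis_suite(cohort, visits, strata=("all",))
        r2 = run_analysis_suite(cohort, visits, strata=("all",))
        pd.testing.assert_frame_equal(r1.results, r2.results)

    def test_unscored_cohort_rejected(self, scored_suite_inputs):
        cohort, _ = scored_suite_inputs
        with pytest.raises(KeyError, match="scored"):
            run_analysis_suite(cohort.drop(columns=["aggregation"]), None)

    def test_ab42_40_sensitivity_rerun(self, scored_suite_inputs):
        """The CSF-dynamics sensitivity variant refits the curve on the
        Aβ42/40 ratio and reruns the families with ratio-derived scores."""
        cohort, _ = scored_suite_inputs
        rep = run_analysis_suite(
            cohort,
            None,
            strata=("all",),
            interactions=False,
            sensitivity_ab42_40=True,
            fit_kwargs={"n_restarts": 1, "maxfev": 400},
        )
        sources = set(rep.results["score_source"])
        assert sources == {"ab42", "ab42_40"}
        sens = rep.results[rep.results["score_source"] == "ab42_40"]
        assert {"demographics", "csf"} <= set(sens["family"])
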