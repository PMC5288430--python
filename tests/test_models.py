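"""Nested model sequence, interaction test, anova, descriptives, aggregates."""

import numpy as np
import pandas as pd
import pytest

from silnet import (GeneratorConfig, compute_metrics_table, descriptive_tests,
                    exposure_anova, fit_model_sequence, generate_cohort,
                    interaction_test, school_aggregates, score_cohort)
from silnet.models import ModelError, prepare_model_frame


def metrics_for(**cfg_kwargs):
    base = dict(n_schools=4, roster_size_range=(120, 160), seed=42)
    base.update(cfg_kwargs)
    records, edges = generate_cohort(GeneratorConfig(**base))
    records, comps = score_cohort(records)
    return compute_metrics_table(records, edges, comps)


class TestModelSequence:
    def test_loglik_never_decreases_along_the_nested_sequence(
            self, default_metrics):
        fits = fit_model_sequence(default_metrics, "regular")
        lls = [f.loglik for f in fits]
        assert all(b >= a - 1e-8 for a, b in zip(lls, lls[1:]))

    def test_identical_estimation_sample_across_models(self, default_metrics):
        fits = fit_model_sequence(default_metrics, "regular")
        assert len({f.n_used for f in fits}) == 1
        dropped = default_metrics["exp_deg1"].isna().sum()
        assert fits[0].n_used <= len(default_metrics) - dropped

    def test_terms_nest_m1_through_m4(self, default_metrics):
        fits = fit_model_sequence(default_metrics, "regular")
        base = [set(f.coefficients["term"]) - {"Intercept"} for f in fits]
        # clustering terms differ in M4 (school replaces country dummies)
        strip = [
            {t for t in terms if "country" not in t and "school" not in t}
            for terms in base
        ]
        assert strip[0] < strip[1] < strip[2] < strip[3]

    def test_random_effects_route_reports_variance_components(
            self, default_metrics):
        fits = fit_model_sequence(default_metrics, "regular", method="re")
        assert set(fits[3].variance_components) == {"country", "network"}
        assert set(fits[0].variance_components) == {"country"}
        for f in fits:
            assert np.isfinite(f.coefficients["estimate"]).all()

    def test_dependence_outcome_uses_negative_binomial(self, default_metrics):
        fits = fit_model_sequence(default_metrics, "dependence")
        assert all(f.outcome == "dependence" for f in fits)
        assert fits[0].loglik is not None

    def test_null_ses_effect_covers_one(self):
        """With no SES mechanism the M1 band ORs stay near 1."""
        covered = total = 0
        for s in range(12):
            table = metrics_for(
                n_schools=6, roster_size_range=(140, 180), seed=600 + s,
                ses_effect=0.0, household_smoker_gradient=0.0,
                homophily_strength=0.0, ses_homophily_strength=0.0)
            fit = fit_model_sequence(table, "regular")[0]
            ors = fit.odds_ratios[
                fit.odds_ratios["term"].str.contains("ses_band", regex=False)]
            covered += int(((ors["or_lo"] <= 1.0) & (ors["or_hi"] >= 1.0)).sum())
            total += len(ors)
        assert covered / total >= 0.9

    def test_empty_sample_raises(self, default_metrics):
        empty = default_metrics.assign(exp_deg1=np.nan)
        with pytest.raises(ModelError):
            fit_model_sequence(empty, "regular")

    def test_unknown_outcome_rejected(self, default_metrics):
        with pytest.raises(ValueError):
            prepare_model_frame(default_metrics, "vaping")


class TestInteractionTest:
    def test_strong_built_in_interaction_is_detected(self):
        rejections = 0
        n_rep = 12
        for s in range(n_rep):
            table = metrics_for(n_schools=12, roster_size_range=(150, 200),
                                interaction_beta=1.2, household_effect=0.0,
                                seed=900 + s)
            _, p = interaction_test(table)
            rejections += p < 0.05
        assert rejections / n_rep > 0.8

    def test_constant_homophily_column_rejected(self, default_metrics):
        degenerate = default_metrics.assign(coleman_parental_edu=0.5)
        with pytest.raises(ModelError, match="homophily"):
            interaction_test(degenerate)

    def test_statistic_is_single_df_wald(self, default_metrics):
        wald, p = interaction_test(default_metrics)
        import scipy.stats as st
        assert p == pytest.approx(st.chi2.sf(wald, df=1))


class TestExposureAnova:
    def test_identical_exposure_gives_f_near_zero(self, default_metrics):
        flat = default_metrics.assign(exp_deg1=25.0)
        out = exposure_anova(flat, measures=("exp_deg1",))
        f = float(out.loc[out["ses_band"] == "F", "exp_deg1"].iloc[0])
        p = float(out.loc[out["ses_band"] == "p", "exp_deg1"].iloc[0])
        assert f < 1e-8 and p > 0.99

    def test_household_gradient_yields_monotone_adjusted_means(self):
        table = metrics_for(n_schools=8, roster_size_range=(150, 200), seed=77)
        out = exposure_anova(table, measures=("household_smokers",))
        means = out[out["ses_band"].isin(["0", "1", "2", "3"])][
            "household_smokers"].astype(float)
        assert means.is_monotonic_increasing

    def test_single_band_rejected(self, default_metrics):
        one_band = default_metrics.assign(ses_band="0")
        with pytest.raises(ModelError):
            exposure_anova(one_band)

    def test_empty_band_flagged_as_nan(self, default_metrics):
        sub = default_metrics[default_metrics["ses_band"] != "5+"]
        out = exposure_anova(sub, measures=("exp_deg1",))
        val = out.loc[out["ses_band"] == "5+", "exp_deg1"].iloc[0]
        assert np.isnan(float(val))


class TestDescriptives:
    def test_random_smoker_placement_gives_null_paired_difference(self):
        rng = np.random.default_rng(1)
        diffs = []
        for s in range(10):
            table = metrics_for(n_schools=2, seed=300 + s, peer_effect_beta=0.0,
                                ses_effect=0.0, household_effect=0.0,
                                household_smoker_gradient=0.0,
                                homophily_strength=0.0,
                                ses_homophily_strength=0.0)
            out = descriptive_tests(table)
            row = out[out["test"] == "distance_smokers_vs_all_alters"].iloc[0]
            diffs.append(row["mean_1"] - row["mean_2"])
        assert abs(np.mean(diffs)) < 0.1

    def test_homophilous_ties_reject_zero_coleman(self, default_metrics):
        out = descriptive_tests(default_metrics)
        row = out[out["test"] == "coleman_vs_zero"].iloc[0]
        assert row["mean_1"] > 0.2 and row["p"] < 1e-6

    def test_too_few_observations_rejected(self, default_metrics):
        with pytest.raises(ModelError):
            descriptive_tests(default_metrics.iloc[:1])


class TestSchoolAggregates:
    def test_two_schools_give_correlation_plus_minus_one(self, default_metrics):
        two = default_metrics[default_metrics["school_id"].isin(
            default_metrics["school_id"].unique()[:2])]
        _, corr = school_aggregates(two)
        assert np.allclose(np.abs(corr["pearson_r"]), 1.0)

    def test_single_school_gives_missing_correlations(self, default_metrics):
        one = default_metrics[default_metrics["school_id"] ==
                              default_metrics["school_id"].iloc[0]]
        _, corr = school_aggregates(one)
        assert corr["pearson_r"].isna().all()

    def test_ses_gradient_gives_positive_exposure_correlation(self):
        table = metrics_for(n_schools=30, roster_size_range=(150, 220),
                            country_sd=0.0, school_ses_sd=0.8, seed=51)
        _, corr = school_aggregates(table)
        r = corr.loc[(corr["x"] == "mean_exp_deg1") &
                     (corr["y"] == "mean_lowest_count"), "pearson_r"].iloc[0]
        assert r > 0.1
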