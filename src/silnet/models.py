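"""Nested model sequence and descriptive tests for smoking inequalities.

The mediation sequence regresses regular smoking (or having tried smoking,
or the nicotine-dependence score) on the banded SES composite and adds the
candidate network mediators step by step:

* **M1**: SES bands + age band + sex,
* **M2**: + peer-smoking exposure at separation degrees 1-3 and the
  relative distance to smokers,
* **M3**: + the individual Coleman homophily index on parental education,
* **M4**: + the number of smoking household members, with a
  school-network component.

Attenuation of the low-SES odds ratios from M1 to M3/M4 is read as the
share of the SES-smoking association carried by the network terms.

Country clustering is handled either by country fixed effects (``method=
"fe"``, the default: with only six countries a random-intercept variance
is weakly identified, so dummies are the primary inference route) or by a
variational-Bayes random-intercept logit (``method="re"``, which also
reports the country/school variance components).  The fixed-effects route
uses ordinary ML Wald errors: school-level cluster-robust covariances were
evaluated but are singular whenever the parameter count approaches the
number of schools (the sandwich has rank at most the cluster count), and
they did not change the calibration of the exposure terms.  The dependence
score is over-dispersed and is fitted by negative-binomial regression.

Exposure covariates enter per 10 percentage points of smoking prevalence;
the relative distance enters as a proportion; SES bands are indicators
with "0 lowest categories" as the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

MODEL_IDS = ("M1", "M2", "M3", "M4")
OUTCOME_COLUMNS = {
    "regular": "regular_smoker",
    "tried": "tried_smoking",
    "dependence": "dependence_score",
}
SES_LEVELS = ("0", "1", "2", "3", "4", "5+")
AGE_LEVELS = ("<14", "14-15", "16+")

_BASE_TERMS = ('C(ses_band, Treatment("0"))', 'C(age_band, Treatment("<14"))',
               "male")
_EXPOSURE_TERMS = ("exp1_10", "exp2_10", "exp3_10", "rel_prop")
_HOMOPHILY_TERM = "coleman"
_HOUSEHOLD_TERM = "household_smokers"

#: columns that must be observed for a student to enter the estimation
#: sample; identical across M1-M4 so the odds ratios are comparable.
_REQUIRED = ["outcome", "ses_band", "age_band", "male", "exp1_10", "exp2_10",
             "exp3_10", "rel_prop", "coleman", "household_smokers",
             "country", "school_id", "lowest_count"]


class ModelError(RuntimeError):
    """Estimation failed (separation, rank deficiency, non-convergence)."""


@dataclass
class ModelFit:
    """One fitted model of the nested sequence."""

    model_id: str
    outcome: str
    method: str
    formula: str
    coefficients: pd.DataFrame        # term, estimate, se, ci_lo, ci_hi, p
    odds_ratios: pd.DataFrame         # term, or, or_lo, or_hi (exp scale)
    variance_components: dict = field(default_factory=dict)
    n_used: int = 0
    loglik: Optional[float] = None
    converged: bool = True
    notes: list = field(default_factory=list)

    def coef(self, term_substring: str) -> pd.Series:
        """First coefficient row whose term contains ``term_substring``."""
        hits = self.coefficients[
            self.coefficients["term"].str.contains(term_substring, regex=False)]
        if hits.empty:
            raise KeyError(f"no term matching {term_substring!r}")
        return hits.iloc[0]


def prepare_model_frame(metrics_table: pd.DataFrame,
                        outcome: str = "regular") -> pd.DataFrame:
    """Transform the metrics table into the estimation sample.

    Scales exposures per 10%, the relative distance to a proportion, codes
    the SES and age bands, and applies listwise deletion on the union of
    all M1-M4 terms so every model is fitted on the same students.
    """
    if outcome not in OUTCOME_COLUMNS:
        raise ValueError(f"unknown outcome {outcome!r}")
    df = metrics_table.copy()
    for col in ("ses_band", "exp_deg1", "coleman_parental_edu"):
        if col not in df.columns:
            raise ValueError(f"metrics table lacks column {col!r}")
    frame = pd.DataFrame({
        "outcome": df[OUTCOME_COLUMNS[outcome]],
        "ses_band": pd.Categorical(df["ses_band"].astype(str),
                                   categories=SES_LEVELS),
        "lowest_count": df["lowest_count"],
        "age_band": pd.Categorical(df["age_band"], categories=AGE_LEVELS),
        "male": (df["sex"] == "male").astype(float),
        "exp1_10": df["exp_deg1"] / 10.0,
        "exp2_10": df["exp_deg2"] / 10.0,
        "exp3_10": df["exp_deg3"] / 10.0,
        "rel_prop": df["rel_dist_smokers"] / 100.0,
        "coleman": df["coleman_parental_edu"],
        "household_smokers": df["household_smokers"].astype(float),
        "country": df["country"].astype(str),
        "school_id": df["school_id"].astype(str),
    })
    frame = frame.dropna(subset=_REQUIRED)
    # drop empty categorical levels so design matrices stay full rank
    frame["ses_band"] = frame["ses_band"].cat.remove_unused_categories()
    frame["age_band"] = frame["age_band"].cat.remove_unused_categories()
    return frame.reset_index(drop=True)


def _formula_terms(model_id: str) -> list:
    terms = list(_BASE_TERMS)
    if model_id in ("M2", "M3", "M4"):
        terms += list(_EXPOSURE_TERMS)
    if model_id in ("M3", "M4"):
        terms.append(_HOMOPHILY_TERM)
    if model_id == "M4":
        terms.append(_HOUSEHOLD_TERM)
    return terms


def model_formula(model_id: str, method: str = "fe") -> str:
    """Right-hand side of the model, including the clustering terms."""
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model id {model_id!r}")
    terms = _formula_terms(model_id)
    if method == "fe":
        # school dummies in M4 absorb the country dummies (schools nest
        # in countries), mirroring the added network component
        terms.append("C(school_id)" if model_id == "M4" else "C(country)")
    return "outcome ~ " + " + ".join(terms)


def _check_fit(res, formula: str):
    bse = np.asarray(res.bse)
    if not np.all(np.isfinite(bse)) or np.any(np.abs(res.params) > 30):
        raise ModelError(
            f"separation or rank deficiency in {formula!r}: "
            f"max |coef| = {np.max(np.abs(res.params)):.2f}, "
            f"non-finite standard errors = {int(np.sum(~np.isfinite(bse)))}"
        )


def _coef_table(params, bse, pvalues) -> pd.DataFrame:
    z = st.norm.ppf(0.975)
    out = pd.DataFrame({
        "term": params.index,
        "estimate": params.values,
        "se": np.asarray(bse),
    })
    out["ci_lo"] = out["estimate"] - z * out["se"]
    out["ci_hi"] = out["estimate"] + z * out["se"]
    out["p"] = np.asarray(pvalues)
    return out


def _exp_table(coefs: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({
        "term": coefs["term"],
        "or": np.exp(coefs["estimate"]),
        "or_lo": np.exp(coefs["ci_lo"]),
        "or_hi": np.exp(coefs["ci_hi"]),
    })


def _fit_binomial_fe(formula, frame, check=True):
    model = smf.glm(formula, data=frame, family=sm.families.Binomial())
    res = model.fit()
    if check:
        _check_fit(res, formula)
    return res


def _fe_formula(model_id: str, frame: pd.DataFrame) -> str:
    """Fixed-effects formula, dropping single-level cluster factors."""
    terms = _formula_terms(model_id)
    cluster = "school_id" if model_id == "M4" else "country"
    if frame[cluster].nunique() > 1:
        terms.append(f"C({cluster})")
    return "outcome ~ " + " + ".join(terms)


def _fit_negbin(formula, frame):
    model = smf.negativebinomial(formula, data=frame)
    res = model.fit(disp=0, maxiter=200)
    if not res.mle_retvals.get("converged", True):
        raise ModelError(f"negative-binomial fit did not converge: {formula!r}")
    return res


def _fit_binomial_re(model_id, frame):
    terms = _formula_terms(model_id)
    formula = "outcome ~ " + " + ".join(terms)
    vc = {"country": "0 + C(country)"}
    if model_id == "M4":
        vc["network"] = "0 + C(school_id)"
    model = BinomialBayesMixedGLM.from_formula(formula, vc, frame)
    res = model.fit_vb()
    k = len(res.fe_mean)
    params = pd.Series(res.fe_mean, index=model.exog_names[:k])
    bse = res.fe_sd
    z = params.values / bse
    pvals = 2 * st.norm.sf(np.abs(z))
    coefs = _coef_table(params, bse, pvals)
    # vcp are posterior normals on log-sd; report the implied variance
    vcomp = {}
    for name, m, s in zip(model.vcp_names, res.vcp_mean, res.vcp_sd):
        var_mean = float(np.exp(2 * m + 2 * s ** 2))
        var_sd = float(var_mean * np.sqrt(np.exp(4 * s ** 2) - 1))
        vcomp[name] = (var_mean, var_sd)
    return coefs, vcomp, formula


def fit_model_sequence(metrics_table: pd.DataFrame, outcome: str = "regular",
                       method: str = "fe") -> list:
    """Fit M1-M4 on one estimation sample; returns a list of ModelFit.

    ``method="fe"`` (default) uses country dummies (school dummies in M4);
    ``method="re"`` uses variational-Bayes random intercepts and reports
    variance components.  The dependence outcome is always fitted by
    fixed-effects negative-binomial regression.
    """
    if method not in ("fe", "re"):
        raise ValueError(f"unknown method {method!r}")
    frame = prepare_model_frame(metrics_table, outcome)
    if frame.empty:
        raise ModelError("estimation sample is empty after listwise deletion")
    fits = []
    for model_id in MODEL_IDS:
        notes = []
        vcomp = {}
        converged = True
        if outcome == "dependence":
            formula = _fe_formula(model_id, frame)
            if method == "re":
                notes.append("dependence outcome: no mixed negative binomial "
                             "available; fitted with fixed effects")
            res = _fit_negbin(formula, frame)
            drop = [t for t in res.params.index if t == "alpha"]
            params = res.params.drop(drop)
            coefs = _coef_table(params, res.bse.drop(drop),
                                res.pvalues.drop(drop))
            loglik = float(res.llf)
        elif method == "re":
            coefs, vcomp, formula = _fit_binomial_re(model_id, frame)
            loglik = None
            notes.append("variational-Bayes approximation")
        else:
            formula = _fe_formula(model_id, frame)
            model = smf.glm(formula, data=frame,
                            family=sm.families.Binomial())
            res = model.fit()
            try:
                _check_fit(res, formula)
            except ModelError as err:
                # reported, never silent: flagged with diagnostics so the
                # rest of the sequence (and pipeline) still completes
                converged = False
                notes.append(str(err))
            coefs = _coef_table(res.params, res.bse, res.pvalues)
            loglik = float(res.llf)
            notes.append("country clustering by fixed effects")
        fits.append(ModelFit(
            model_id=model_id,
            outcome=outcome,
            method=method,
            formula=formula,
            coefficients=coefs,
            odds_ratios=_exp_table(coefs),
            variance_components=vcomp,
            n_used=len(frame),
            loglik=loglik,
            converged=converged,
            notes=notes,
        ))
    return fits


def interaction_test(metrics_table: pd.DataFrame,
                     method: str = "fe") -> tuple:
    """Single-df Wald test of homophily x SES in the M3 specification.

    SES enters the product linearly (the 0-5 lowest-category count), so
    the interaction carries one degree of freedom.  Returns
    ``(wald_chi2, p)``.
    """
    frame = prepare_model_frame(metrics_table, "regular")
    for col, label in (("coleman", "homophily index"),
                       ("lowest_count", "SES score")):
        if frame[col].nunique() < 2:
            raise ModelError(f"constant {label}: interaction not estimable")
    formula = _fe_formula("M3", frame) + " + coleman:lowest_count"
    res = _fit_binomial_fe(formula, frame)
    b = res.params["coleman:lowest_count"]
    se = res.bse["coleman:lowest_count"]
    wald = float((b / se) ** 2)
    return wald, float(st.chi2.sf(wald, df=1))


EXPOSURE_MEASURES = ("exp_deg1", "exp_deg2", "exp_deg3", "rel_dist_smokers",
                     "household_smokers", "coleman_parental_edu")


def exposure_anova(metrics_table: pd.DataFrame,
                   measures=EXPOSURE_MEASURES) -> pd.DataFrame:
    """Age- and sex-adjusted means of each exposure measure by SES band.

    For each measure, an OLS of the measure on SES band + age band + sex
    gives the band F-test; adjusted band means are standardised to the
    sample's age/sex distribution (g-computation).  Bands with no students
    are flagged as NaN rows.
    """
    df = metrics_table.copy()
    df["male"] = (df["sex"] == "male").astype(float)
    df["ses_band"] = pd.Categorical(df["ses_band"].astype(str),
                                    categories=SES_LEVELS)
    present = [b for b in SES_LEVELS if (df["ses_band"] == b).any()]
    if len(present) < 2:
        raise ModelError("need at least two SES bands for the exposure anova")
    rows = {b: {"ses_band": b} for b in SES_LEVELS}
    stats = {}
    for measure in measures:
        sub = df.dropna(subset=[measure, "ses_band", "age_band", "male"]).copy()
        sub["ses_band"] = sub["ses_band"].cat.remove_unused_categories()
        if np.ptp(sub[measure].to_numpy()) == 0:
            # constant measure: no band differences by definition
            stats[measure] = (0.0, 1.0)
            for b in SES_LEVELS:
                rows[b][measure] = (float(sub[measure].iloc[0])
                                    if b in sub["ses_band"].cat.categories
                                    else np.nan)
            continue
        res = smf.ols(f"{measure} ~ C(ses_band) + C(age_band) + male",
                      data=sub).fit()
        aov = sm.stats.anova_lm(res, typ=2)
        stats[measure] = (float(aov.loc["C(ses_band)", "F"]),
                          float(aov.loc["C(ses_band)", "PR(>F)"]))
        for b in SES_LEVELS:
            if b in sub["ses_band"].cat.categories:
                counterfactual = sub.copy()
                counterfactual["ses_band"] = b
                rows[b][measure] = float(res.predict(counterfactual).mean())
            else:
                rows[b][measure] = np.nan
    out = pd.DataFrame([rows[b] for b in SES_LEVELS])
    ftest = {"ses_band": "F"}
    pvals = {"ses_band": "p"}
    for measure in measures:
        ftest[measure], pvals[measure] = stats[measure]
    return pd.concat([out, pd.DataFrame([ftest, pvals])], ignore_index=True)


def descriptive_tests(metrics_table: pd.DataFrame) -> pd.DataFrame:
    """The two headline t-tests on the network measures.

    Paired t-test of each student's mean distance to smoking alters
    against their mean distance to all alters, and a one-sample t-test of
    the individual Coleman index against zero.
    """
    paired = metrics_table.dropna(
        subset=["dist_smoking_alters", "dist_all_alters"])
    coleman = metrics_table["coleman_parental_edu"].dropna()
    if len(paired) < 2 or len(coleman) < 2:
        raise ModelError("need at least two observations for the t-tests")
    t1 = st.ttest_rel(paired["dist_smoking_alters"], paired["dist_all_alters"])
    t2 = st.ttest_1samp(coleman, 0.0)
    return pd.DataFrame([
        {"test": "distance_smokers_vs_all_alters",
         "mean_1": paired["dist_smoking_alters"].mean(),
         "mean_2": paired["dist_all_alters"].mean(),
         "t": float(t1.statistic), "p": float(t1.pvalue), "n": len(paired)},
        {"test": "coleman_vs_zero",
         "mean_1": coleman.mean(), "mean_2": 0.0,
         "t": float(t2.statistic), "p": float(t2.pvalue), "n": len(coleman)},
    ])


def school_aggregates(metrics_table: pd.DataFrame):
    """School-level means and their pairwise Pearson correlations.

    Returns ``(aggregates, correlations)``: per-school means of
    first-degree exposure, the SES composite and the Coleman index (plus
    smoking prevalence), and correlations across schools (NaN with fewer
    than two schools).
    """
    agg = metrics_table.groupby("school_id").agg(
        mean_exp_deg1=("exp_deg1", "mean"),
        mean_lowest_count=("lowest_count", "mean"),
        mean_coleman=("coleman_parental_edu", "mean"),
        smoking_prevalence=("regular_smoker", "mean"),
        n=("student_id", "count"),
    ).reset_index()
    cols = ("mean_exp_deg1", "mean_lowest_count", "mean_coleman")
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            if len(agg) < 2:
                r, p = np.nan, np.nan
            else:
                r, p = st.pearsonr(agg[a], agg[b])
            rows.append({"x": a, "y": b, "pearson_r": r, "p": p,
                         "n_schools": len(agg)})
    return agg, pd.DataFrame(rows)
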