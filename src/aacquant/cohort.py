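"""Downstream cohort statistics on AAC scores.

Implements the epidemiological layer: prevalence summaries of the score
distribution, statin adjustment of measured lipids, cystatin-C-based eGFR,
per-SD linear biomarker associations, a phenome-wide Cox
proportional-hazards prognosis screen with Bonferroni correction, and the
joint AAC x LDL myocardial-infarction hazard model.

Continuous exposures are standardized to the analysis cohort's SD before
hazard modelling, so hazard ratios are reported per standard deviation.
Event-time ties use the Efron approximation (lifelines' default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from sklearn.linear_model import LinearRegression

# --------------------------------------------------------------------------
# Statin adjustment constants

#: Additive LDL/triglyceride lowering attributed to statin therapy (mmol/L).
STATIN_ABSOLUTE_REDUCTION = 1.25
#: Primary stored constant: statins reduce LDL by ~35%; the equivalent
#: relative *increase* used to undo it is 1/(1-0.35) - 1 ~ 54%.
STATIN_RELATIVE_REDUCTION = 0.35
STATIN_MULTIPLIER = 1.0 / (1.0 - STATIN_RELATIVE_REDUCTION)

MODEL1_COVARIATES = ["age", "sex_female"]
MODEL2_EXTRA = ["bmi", "ses_index"]  # + smoking & ethnicity dummies


@dataclass
class PrevalenceSummary:
    mean: float
    sd: float
    threshold: float           # mean + 1 sd
    frac_above_3: float
    n: int
    stratified: pd.DataFrame | None = None


def prevalence_summary(scores, ages=None, sexes=None) -> PrevalenceSummary:
    """Moments, the mean+1sd threshold, the score>3 exceedance fraction and
    (when ages/sexes are given) per-(age decade x sex) score quantiles."""
    s = np.asarray(list(scores), dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 scores")
    mean = float(s.mean())
    sd = float(s.std(ddof=1))
    strat = None
    if ages is not None and sexes is not None:
        df = pd.DataFrame({"score": s, "decade": (np.asarray(ages) // 10) * 10,
                           "sex": list(sexes)})
        strat = (df.groupby(["decade", "sex"])["score"]
                 .quantile([0.25, 0.5, 0.75]).unstack())
    return PrevalenceSummary(mean=mean, sd=sd, threshold=mean + sd,
                             frac_above_3=float(np.mean(s > 3)), n=s.size,
                             stratified=strat)


# --------------------------------------------------------------------------
# Lipid adjustment


class LipidImputer:
    """Predicts untreated LDL and triglycerides from blood pressure, pulse,
    age, sex and non-lipid biomarkers; fitted on statin non-users."""

    COVARIATES = ["sbp", "dbp", "pulse", "age_baseline", "sex_female",
                  "glucose", "hba1c", "phosphate", "calcium", "creatinine",
                  "cystatin_c"]

    def __init__(self) -> None:
        self._ldl = LinearRegression()
        self._trig = LinearRegression()
        self.fitted = False

    def fit(self, cohort: pd.DataFrame) -> "LipidImputer":
        non_users = cohort[cohort["statin_user"] == 0]
        X = non_users[self.COVARIATES].to_numpy(float)
        self._ldl.fit(X, non_users["ldl"].to_numpy(float))
        self._trig.fit(X, non_users["trig"].to_numpy(float))
        self.fitted = True
        return self

    def predict(self, cohort: pd.DataFrame):
        X = cohort[self.COVARIATES].to_numpy(float)
        return self._ldl.predict(X), self._trig.predict(X)


def fit_lipid_imputer(cohort: pd.DataFrame) -> LipidImputer:
    return LipidImputer().fit(cohort)


def adjust_ldl_statin(ldl, trig, statin_user, model: int = 1,
                      imputer: LipidImputer | None = None,
                      cohort: pd.DataFrame | None = None):
    """Reconstruct untreated lipid levels for statin users.

    Model 1 adds 1.25 mmol/L to LDL and triglycerides of users; model 2
    scales them by 1/(1-0.35) (a ~54% relative increase, inverting a 35%
    on-treatment reduction); model 3 replaces them with regression
    predictions from non-lipid covariates (requires a fitted imputer and the
    cohort frame carrying its covariates).  Non-users pass through unchanged
    under every model.
    """
    ldl = np.asarray(ldl, dtype=float)
    trig = np.asarray(trig, dtype=float)
    on_statin = np.asarray(statin_user).astype(bool)
    if np.any(ldl < 0) or np.any(trig < 0):
        raise ValueError("lipid levels must be non-negative")
    if model == 1:
        adj_l = np.where(on_statin, ldl + STATIN_ABSOLUTE_REDUCTION, ldl)
        adj_t = np.where(on_statin, trig + STATIN_ABSOLUTE_REDUCTION, trig)
    elif model == 2:
        adj_l = np.where(on_statin, ldl * STATIN_MULTIPLIER, ldl)
        adj_t = np.where(on_statin, trig * STATIN_MULTIPLIER, trig)
    elif model == 3:
        if imputer is None or not imputer.fitted:
            raise ValueError("model 3 requires a fitted LipidImputer")
        if cohort is None:
            raise ValueError("model 3 requires the cohort frame")
        pred_l, pred_t = imputer.predict(cohort)
        adj_l = np.where(on_statin, pred_l, ldl)
        adj_t = np.where(on_statin, pred_t, trig)
    else:
        raise ValueError(f"unknown statin model {model!r}")
    return adj_l, adj_t


# --------------------------------------------------------------------------
# Kidney function


def egfr_from_cystatin(cystatin_c, age, sex_female):
    """CKD-EPI 2012 cystatin-C-only eGFR (mL/min/1.73 m^2).

    eGFR = 133 x min(Scys/0.8, 1)^-0.499 x max(Scys/0.8, 1)^-1.328
                x 0.996^age x (0.932 if female)
    """
    cys = np.asarray(cystatin_c, dtype=float)
    if np.any(cys <= 0):
        raise ValueError("cystatin C must be positive")
    ratio = cys / 0.8
    egfr = (133.0 * np.minimum(ratio, 1.0) ** -0.499
            * np.maximum(ratio, 1.0) ** -1.328
            * 0.996 ** np.asarray(age, dtype=float))
    egfr = egfr * np.where(np.asarray(sex_female).astype(bool), 0.932, 1.0)
    return egfr if egfr.ndim else float(egfr)


# --------------------------------------------------------------------------
# Linear biomarker associations


@dataclass
class AssociationEstimate:
    covariate: str
    beta_per_sd: float       # SD of AAC per SD of the covariate
    ci_low: float
    ci_high: float
    p: float
    p_bonf: float | None
    model: str
    n: int


def _model_covariate_frame(cohort: pd.DataFrame, model: int,
                           age_col: str) -> pd.DataFrame:
    if model == 0:  # unadjusted (crude association)
        return pd.DataFrame(index=cohort.index)
    X = pd.DataFrame({"age": cohort[age_col].to_numpy(float),
                      "sex_female": cohort["sex_female"].to_numpy(float)},
                     index=cohort.index)
    if model == 2:
        for col in MODEL2_EXTRA:
            X[col] = cohort[col].to_numpy(float)
        X["smoking_previous"] = (cohort["smoking"] == "previous").astype(float)
        X["smoking_current"] = (cohort["smoking"] == "current").astype(float)
        for eth in ("asian", "black", "other"):
            X[f"eth_{eth}"] = (cohort["ethnicity"] == eth).astype(float)
    elif model != 1:
        raise ValueError(f"unknown covariate model {model!r}")
    return X


def biomarker_association(cohort: pd.DataFrame, biomarker: str,
                          model: int = 1, n_tests: int | None = None,
                          age_col: str = "age_imaging") -> AssociationEstimate:
    """Linear association of AAC with one standardized biomarker.

    AAC is regressed (OLS) on the standardized biomarker plus the model-1
    (age, sex) or model-2 (plus BMI, socioeconomic index, smoking,
    ethnicity) covariates; both AAC and the biomarker are standardized so
    the effect reads SD-of-AAC per SD-of-biomarker.  ``smoking`` is accepted
    as an ever-smoked indicator.
    """
    if biomarker == "smoking":
        x = (cohort["smoking"] != "never").to_numpy(float)
    else:
        x = cohort[biomarker].to_numpy(float)
    if np.std(x) == 0:
        raise ValueError(f"biomarker {biomarker!r} is constant")
    zx = (x - x.mean()) / x.std()
    y = cohort["aac_score"].to_numpy(float)
    zy = (y - y.mean()) / y.std()

    X = _model_covariate_frame(cohort, model, age_col)
    if biomarker == "smoking" and model == 2:
        X = X.drop(columns=["smoking_previous", "smoking_current"])
    design = sm.add_constant(pd.concat(
        [pd.Series(zx, name="biomarker", index=cohort.index), X], axis=1))
    fit = sm.OLS(zy, design.to_numpy(float)).fit()
    beta, se = fit.params[1], fit.bse[1]
    p = float(fit.pvalues[1])
    return AssociationEstimate(
        covariate=biomarker, beta_per_sd=float(beta),
        ci_low=float(beta - 1.959963984540054 * se),
        ci_high=float(beta + 1.959963984540054 * se), p=p,
        p_bonf=None if n_tests is None else min(1.0, p * n_tests),
        model=f"model{model}", n=len(cohort))


def associate_biomarkers(cohort: pd.DataFrame, biomarkers, model: int = 1):
    """Run :func:`biomarker_association` over a set, Bonferroni-corrected
    across the tested set."""
    m = len(list(biomarkers))
    return [biomarker_association(cohort, b, model=model, n_tests=m)
            for b in biomarkers]


# --------------------------------------------------------------------------
# Proportional-hazards prognosis screen


@dataclass
class HazardEstimate:
    disease: str
    term: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    p_bonf: float | None
    n_events: int
    n: int


def _cox_fit(df: pd.DataFrame, duration_col: str, event_col: str) -> CoxPHFitter:
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    return cph


def _hazard_estimate(summary: pd.DataFrame, term: str, disease: str,
                     n_events: int, n: int, n_tests: int | None) -> HazardEstimate:
    s = summary.loc[term]
    p = float(s["p"])
    return HazardEstimate(
        disease=disease, term=term, hr=float(s["exp(coef)"]),
        ci_low=float(s["exp(coef) lower 95%"]),
        ci_high=float(s["exp(coef) upper 95%"]), p=p,
        p_bonf=None if n_tests is None else min(1.0, p * n_tests),
        n_events=n_events, n=n)


def _disease_frame(cohort: pd.DataFrame, disease: str, index: str):
    """Per-disease analysis frame: prior-history exclusion and index shift.

    Event times are generated/stored from the baseline visit.  With the
    imaging-visit index, events occurring before imaging count as prior
    history and are excluded; surviving times are re-referenced to imaging.
    """
    prior = cohort[f"{disease}_prior"].astype(bool).copy()
    time = cohort[f"{disease}_time"].to_numpy(float).copy()
    event = cohort[f"{disease}_event"].to_numpy(int).copy()
    if index == "imaging":
        gap = (cohort["age_imaging"] - cohort["age_baseline"]).to_numpy(float)
        pre_imaging = (event == 1) & (time < gap)
        prior = prior | pre_imaging
        time = np.clip(time - gap, 1e-6, None)
    elif index != "baseline":
        raise ValueError(f"unknown index visit {index!r}")
    keep = ~prior.to_numpy()
    return keep, time, event


def prognosis_screen(cohort: pd.DataFrame, diseases=None, model: int = 1,
                     min_events: int = 25, index: str = "imaging",
                     alpha: float = 0.05):
    """Phenome-wide Cox screen of AAC (per SD) across disease outcomes.

    Per disease: participants with prior history are excluded; diseases
    with <= ``min_events`` post-index events are dropped; the hazard of the
    standardized AAC score is fit with model-1 or model-2 covariates; raw
    two-tailed p-values are Bonferroni-corrected across the diseases tested.
    """
    if diseases is None:
        diseases = [c[:-6] for c in cohort.columns if c.endswith("_event")]
    age_col = "age_imaging" if index == "imaging" else "age_baseline"
    z_aac = cohort["aac_score"].to_numpy(float)
    z_aac = (z_aac - z_aac.mean()) / z_aac.std()

    prepared = []
    for disease in diseases:
        keep, time, event = _disease_frame(cohort, disease, index)
        n_events = int(event[keep].sum())
        if n_events <= min_events:
            continue
        prepared.append((disease, keep, time, event, n_events))
    if not prepared:
        warnings.warn("no disease passes the event filter; empty screen")
        return []

    n_tests = len(prepared)
    out = []
    covars = _model_covariate_frame(cohort, model, age_col)
    for disease, keep, time, event, n_events in prepared:
        df = covars[keep].copy()
        df["aac_sd"] = z_aac[keep]
        df["T"] = time[keep]
        df["E"] = event[keep]
        cph = _cox_fit(df, "T", "E")
        out.append(_hazard_estimate(cph.summary, "aac_sd", disease, n_events,
                                    int(keep.sum()), n_tests))
    return out


def significant(estimates, alpha: float = 0.05):
    """Bonferroni-significant subset of screen results."""
    return [e for e in estimates if e.p_bonf is not None and e.p_bonf < alpha]


# --------------------------------------------------------------------------
# Joint AAC x LDL myocardial-infarction model


def joint_mi_model(cohort: pd.DataFrame, statin_model: int | None = 1,
                   subset: str = "all", imputer: LipidImputer | None = None,
                   disease: str = "myocardial_infarction",
                   index: str = "baseline") -> dict:
    """Joint Cox model of MI on standardized AAC, adjusted LDL and
    triglycerides with age and sex covariates, plus the AAC x LDL
    interaction test.

    ``statin_model=None`` uses measured lipids unadjusted; ``subset`` is
    ``"all"`` or ``"non_users"`` (the statin-free subgroup, analysed with
    measured lipids).
    """
    df = cohort
    if subset == "non_users":
        df = cohort[cohort["statin_user"] == 0]
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")

    if statin_model is None or subset == "non_users":
        ldl, trig = df["ldl"].to_numpy(float), df["trig"].to_numpy(float)
    else:
        if statin_model == 3 and (imputer is None or not imputer.fitted):
            raise ValueError("statin model 3 requires a fitted imputer")
        ldl, trig = adjust_ldl_statin(df["ldl"], df["trig"],
                                      df["statin_user"], model=statin_model,
                                      imputer=imputer, cohort=df)

    keep, time, event = _disease_frame(df, disease, index)
    age_col = "age_imaging" if index == "imaging" else "age_baseline"

    def z(v):
        v = np.asarray(v, float)
        return (v - v.mean()) / v.std()

    frame = pd.DataFrame({
        "aac_sd": z(df["aac_score"])[keep],
        "ldl_sd": z(ldl)[keep],
        "trig_sd": z(trig)[keep],
        "age": df[age_col].to_numpy(float)[keep],
        "sex_female": df["sex_female"].to_numpy(float)[keep],
        "T": time[keep], "E": event[keep],
    })
    frame["aac_x_ldl"] = frame["aac_sd"] * frame["ldl_sd"]
    cph = _cox_fit(frame, "T", "E")
    summary = cph.summary
    n_events = int(frame["E"].sum())
    n = len(frame)
    return {
        "aac": _hazard_estimate(summary, "aac_sd", disease, n_events, n, None),
        "ldl": _hazard_estimate(summary, "ldl_sd", disease, n_events, n, None),
        "trig": _hazard_estimate(summary, "trig_sd", disease, n_events, n, None),
        "interaction_p": float(summary.loc["aac_x_ldl", "p"]),
        "statin_model": statin_model, "subset": subset,
    }
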