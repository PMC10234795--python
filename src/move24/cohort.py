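"""Cohort-level comparisons and non-compositional association models.

Group comparisons (sex, age group) of movement-behaviour characteristics
use linear mixed models with a school random intercept, reporting
covariate-adjusted means with 95% CIs.  Associations between a single
characteristic and a mental-health outcome use the same mixed-model
machinery, with sex-stratified refits when sex is a significant
predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor


def _mixed_or_ols(endog, exog, groups):
    if groups is not None and len(np.unique(groups)) >= 2:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = MixedLM(endog, exog, groups=groups).fit(reml=False)
            if np.all(np.isfinite(np.asarray(res.bse)[: exog.shape[1]])):
                return res, "mixed"
        except np.linalg.LinAlgError:
            pass
        warnings.warn("mixed fit degenerate (cluster variance ~ 0); using OLS")
    else:
        warnings.warn("fewer than 2 clusters; using OLS")
    return sm.OLS(endog, exog).fit(), "ols"


def adjusted_group_means(df: pd.DataFrame, metric: str, group: str,
                         covariates=(), school_col: str = "school_id") -> pd.DataFrame:
    """Adjusted means (at covariate means) with 95% CI per group level,
    plus the group-contrast p-value.

    Returns one row per group level with columns mean, ci_low, ci_high,
    p_contrast (p of each non-reference level vs the reference; the
    reference row carries the overall contrast p as well for 2-level
    groups).
    """
    data = df.dropna(subset=[metric, group, *covariates]).reset_index(drop=True)
    levels = sorted(data[group].astype(str).unique())
    if len(levels) < 2:
        raise ValueError("group comparison requires >= 2 levels")
    exog = pd.DataFrame({"const": np.ones(len(data))})
    for lev in levels[1:]:
        exog[f"{group}[{lev}]"] = (data[group].astype(str) == lev).astype(float)
    for c in covariates:
        exog[c] = data[c].to_numpy(dtype=float)
    groups = data[school_col].to_numpy() if school_col in data else None
    res, _method = _mixed_or_ols(data[metric].to_numpy(dtype=float), exog, groups)

    params = np.asarray(res.params)[: exog.shape[1]]
    cov = np.asarray(res.cov_params())[: exog.shape[1], : exog.shape[1]]
    pvals = np.asarray(res.pvalues)[: exog.shape[1]]
    names = list(exog.columns)

    cov_means = {c: float(data[c].mean()) for c in covariates}
    rows = []
    for lev in levels:
        l_vec = np.zeros(len(names))
        l_vec[0] = 1.0
        if lev != levels[0]:
            l_vec[names.index(f"{group}[{lev}]")] = 1.0
        for c in covariates:
            l_vec[names.index(c)] = cov_means[c]
        mean = float(l_vec @ params)
        se = float(np.sqrt(l_vec @ cov @ l_vec))
        p = (float(pvals[names.index(f"{group}[{lev}]")])
             if lev != levels[0] else
             float(pvals[names.index(f"{group}[{levels[1]}]")]))
        rows.append({group: lev, "mean": mean, "ci_low": mean - 1.96 * se,
                     "ci_high": mean + 1.96 * se, "p_contrast": p})
    return pd.DataFrame(rows).set_index(group)


@dataclass
class AssociationResult:
    """Mixed-model association of one exposure with one outcome."""
    exposure: str
    outcome: str
    beta: float
    ci_low: float
    ci_high: float
    p: float
    covariates: list
    vif_range: tuple
    n_obs: int
    method: str
    sex_p: float | None = None
    stratified: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {"exposure": self.exposure, "outcome": self.outcome,
                "beta": self.beta, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "p": self.p,
                "vif_low": self.vif_range[0], "vif_high": self.vif_range[1],
                "n": self.n_obs}


def metric_association(df: pd.DataFrame, exposure: str, outcome: str,
                       covariates=("sex_girl", "age", "eimd_decile"),
                       school_col: str = "school_id",
                       stratify_on_sex: bool = True,
                       sex_col: str = "sex_girl") -> AssociationResult:
    """Association between one movement-behaviour characteristic and a
    mental-health outcome, school-clustered and covariate-adjusted.

    When ``stratify_on_sex`` and the sex coefficient has p < 0.05, the
    model is refitted within each sex.
    """
    covariates = list(covariates)
    data = df.dropna(subset=[exposure, outcome, *covariates]).reset_index(drop=True)
    exog = pd.DataFrame({"const": np.ones(len(data)),
                         exposure: data[exposure].to_numpy(dtype=float)})
    for c in covariates:
        exog[c] = data[c].to_numpy(dtype=float)
    groups = data[school_col].to_numpy() if school_col in data else None
    res, method = _mixed_or_ols(data[outcome].to_numpy(dtype=float), exog, groups)

    names = list(exog.columns)
    k = names.index(exposure)
    ci = np.asarray(res.conf_int())[: exog.shape[1]]
    xm = exog.to_numpy()
    vifs = [variance_inflation_factor(xm, j) for j in range(1, xm.shape[1])]
    result = AssociationResult(
        exposure=exposure, outcome=outcome,
        beta=float(np.asarray(res.params)[k]),
        ci_low=float(ci[k, 0]), ci_high=float(ci[k, 1]),
        p=float(np.asarray(res.pvalues)[k]),
        covariates=covariates, vif_range=(float(min(vifs)), float(max(vifs))),
        n_obs=len(data), method=method)

    if sex_col in covariates:
        result.sex_p = float(np.asarray(res.pvalues)[names.index(sex_col)])
        if stratify_on_sex and result.sex_p < 0.05:
            reduced = [c for c in covariates if c != sex_col]
            for label, val in (("boys", 0.0), ("girls", 1.0)):
                sub = df[df[sex_col] == val]
                if len(sub) < len(covariates) + 3:
                    continue
                result.stratified[label] = metric_association(
                    sub, exposure, outcome, covariates=reduced,
                    school_col=school_col, stratify_on_sex=False)
    return result
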