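"""Compositional data analysis for 5-part daily time use.

A day is treated as a composition of sleep, sedentary time (ST), light
(LPA), moderate (MPA) and vigorous (VPA) physical activity, closed to
1440 minutes.  Associations with mental-health outcomes are estimated by
the "one-for-remaining" approach: the composition is expressed in five
alternative pivot isometric log-ratio (ILR) bases, each placing one
behaviour first so that its first coordinate contrasts that behaviour
against the geometric mean of the remaining four.  The model fit (log
likelihood, fitted values, omnibus test) is identical across bases; only
the interpretation of the first coordinate changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.outliers_influence import variance_inflation_factor

PARTS = ("sleep", "st", "lpa", "mpa", "vpa")
DAY_MINUTES = 1440.0


# ---------------------------------------------------------------------------
# elementary compositional operations
# ---------------------------------------------------------------------------

def close(parts, total: float = DAY_MINUTES) -> np.ndarray:
    """Rescale positive parts to sum to ``total`` (the closure operation)."""
    parts = np.asarray(parts, dtype=float)
    s = parts.sum(axis=-1, keepdims=True)
    if np.any(s <= 0):
        raise ValueError("composition with non-positive total")
    return parts * (total / s)


def replace_zeros(parts, delta=None, total: float = DAY_MINUTES) -> np.ndarray:
    """Multiplicative zero replacement.

    Zeros are set to ``delta`` and the non-zero parts of each affected row
    are shrunk by ``(total - k*delta)/total`` (k = number of zeros in the
    row) so the row total is preserved; rows are then re-closed.

    ``delta`` defaults to half the smallest positive observed value of each
    part across the dataset (a per-column delta).
    """
    x = np.atleast_2d(np.asarray(parts, dtype=float)).copy()
    if np.any(x < 0):
        raise ValueError("negative part")
    if delta is None:
        delta = np.empty(x.shape[1])
        for j in range(x.shape[1]):
            pos = x[:, j][x[:, j] > 0]
            if pos.size == 0:
                raise ValueError(f"part {j} is zero everywhere; no delta derivable")
            delta[j] = 0.5 * pos.min()
    delta = np.broadcast_to(np.asarray(delta, dtype=float), (x.shape[1],))
    if np.any(delta <= 0):
        raise ValueError("delta must be positive")
    smallest_pos = np.where(x > 0, x, np.inf).min(axis=0)
    if np.any(delta > smallest_pos):
        raise ValueError("delta exceeds smallest positive value of a part")
    zeros = x == 0
    rows = zeros.any(axis=1)
    if rows.any():
        totals = x[rows].sum(axis=1, keepdims=True)
        dsum = (zeros[rows] * delta).sum(axis=1, keepdims=True)
        x[rows] = np.where(zeros[rows], delta, x[rows] * (totals - dsum) / totals)
    out = close(x, total)
    return out if np.asarray(parts).ndim > 1 else out[0]


def geometric_mean_composition(compositions, total: float = DAY_MINUTES) -> np.ndarray:
    """Part-wise geometric mean of a set of compositions, closed to ``total``."""
    x = np.atleast_2d(np.asarray(compositions, dtype=float))
    if np.any(x <= 0):
        raise ValueError("geometric mean requires positive parts")
    return close(np.exp(np.log(x).mean(axis=0)), total)


def variation_matrix(compositions) -> np.ndarray:
    """Compositional variation matrix: T[i,j] = var(ln(x_i / x_j))."""
    x = np.atleast_2d(np.asarray(compositions, dtype=float))
    if np.any(x <= 0):
        raise ValueError("variation matrix requires positive parts")
    lx = np.log(x)
    d = lx.shape[1]
    t = np.zeros((d, d))
    for i in range(d):
        for j in range(i + 1, d):
            t[i, j] = t[j, i] = np.var(lx[:, i] - lx[:, j], ddof=1)
    return t


# ---------------------------------------------------------------------------
# pivot ILR coordinates
# ---------------------------------------------------------------------------

def _pivot_order(pivot: str, parts=PARTS) -> list[str]:
    if pivot not in parts:
        raise ValueError(f"unknown pivot behaviour {pivot!r}")
    return [pivot] + [p for p in parts if p != pivot]


def pivot_basis(pivot: str, parts=PARTS) -> np.ndarray:
    """Orthonormal clr basis (D x D-1) for the pivot ordering.

    Column j (1-indexed) is the clr representation of the j-th pivot
    coordinate: positive weight on the j-th part of the permuted order,
    balanced against the parts after it.
    """
    order = _pivot_order(pivot, parts)
    idx = [list(parts).index(p) for p in order]
    d = len(parts)
    v = np.zeros((d, d - 1))
    for j in range(1, d):
        a = np.sqrt((d - j) / (d - j + 1.0))
        v[idx[j - 1], j - 1] = a
        for k in range(j, d):
            v[idx[k], j - 1] = -a / (d - j)
    return v


def pivot_ilr(composition, pivot: str, parts=PARTS) -> np.ndarray:
    """Pivot ILR coordinates z1..z_{D-1}.

    z_j = sqrt((D-j)/(D-j+1)) * ln( x_(j) / geometric mean of the parts
    after it in the pivot ordering ).  z1 contrasts the pivot behaviour
    against the geometric mean of all remaining behaviours.
    """
    x = np.atleast_2d(np.asarray(composition, dtype=float))
    if np.any(x <= 0):
        raise ValueError("ILR requires strictly positive parts")
    z = np.log(x) @ pivot_basis(pivot, parts)
    return z if np.asarray(composition).ndim > 1 else z[0]


def inverse_pivot_ilr(z, pivot: str, parts=PARTS, total: float = DAY_MINUTES) -> np.ndarray:
    """Map pivot ILR coordinates back to a closed composition."""
    z2 = np.atleast_2d(np.asarray(z, dtype=float))
    x = np.exp(z2 @ pivot_basis(pivot, parts).T)
    out = close(x, total)
    return out if np.asarray(z).ndim > 1 else out[0]


def pivot_beta_from_clr_gradient(gradient, parts=PARTS) -> dict[str, float]:
    """First-pivot coefficient per behaviour implied by a clr-scale gradient.

    If the linear predictor is g . ln(x) with sum(g)=0, the coefficient on
    the first pivot coordinate of behaviour b is sqrt(D/(D-1)) * g_b.
    """
    g = np.asarray(gradient, dtype=float)
    if abs(g.sum()) > 1e-9:
        raise ValueError("clr gradient must sum to zero")
    d = len(parts)
    scale = np.sqrt(d / (d - 1.0))
    return {p: scale * g[i] for i, p in enumerate(parts)}


def clr_gradient_for_betas(betas: dict[str, float], parts=PARTS) -> np.ndarray:
    """clr-scale gradient whose implied first-pivot coefficients match ``betas``.

    Behaviours absent from ``betas`` share the remainder equally so the
    gradient sums to zero.
    """
    d = len(parts)
    scale = np.sqrt(d / (d - 1.0))
    g = np.full(d, np.nan)
    for i, p in enumerate(parts):
        if p in betas:
            g[i] = betas[p] / scale
    free = np.isnan(g)
    if free.sum() == 0:
        if abs(np.nansum(g)) > 1e-9:
            raise ValueError("fully specified betas must imply a zero-sum gradient")
    else:
        g[free] = -np.nansum(g) / free.sum()
    return g


# ---------------------------------------------------------------------------
# one-for-remaining compositional regression
# ---------------------------------------------------------------------------

@dataclass
class BehaviourEffect:
    """First-pivot coefficient for one behaviour relative to the rest."""
    behaviour: str
    beta: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class CompositionModelResults:
    """Fit of a mental-health outcome on the 5-part time-use composition.

    Carries the omnibus test of the four ILR terms, the per-behaviour
    "one-for-remaining" coefficients, covariate estimates, collinearity
    diagnostics and enough state to predict new compositions.
    """

    outcome: str
    method: str                      # "mixed" or "ols"
    parts: tuple
    covariate_names: list
    omnibus_stat: float
    omnibus_df: int
    omnibus_p: float
    loglik: float
    loglik_by_pivot: dict
    r_squared: float
    effects: dict                    # behaviour -> BehaviourEffect
    covariates: pd.DataFrame         # estimates from the first-pivot model
    vif_range: tuple
    params_by_pivot: dict            # pivot -> pd.Series of fixed-effect params
    school_var: float | None
    n_obs: int
    n_schools: int | None
    covariate_reference: pd.Series
    stratified: dict = field(default_factory=dict)
    sex_p: float | None = None

    @property
    def follow_up_performed(self) -> bool:
        """Behaviour-level follow-ups are interpreted only when the omnibus
        test shows the ILR set is associated with the outcome."""
        return bool(self.omnibus_p < 0.05)

    def effects_frame(self) -> pd.DataFrame:
        rows = [
            {"behaviour": e.behaviour, "beta": e.beta, "ci_low": e.ci_low,
             "ci_high": e.ci_high, "p": e.p}
            for e in self.effects.values()
        ]
        return pd.DataFrame(rows).set_index("behaviour")

    def predict(self, compositions, covariates: pd.Series | None = None,
                zero_delta=None) -> np.ndarray:
        """Fixed-effect prediction for new compositions.

        Covariates default to the reference profile stored at fit time
        (sample means / proportions).  Compositions containing zeros are
        routed through multiplicative zero replacement.
        """
        x = np.atleast_2d(np.asarray(compositions, dtype=float))
        if np.any(x == 0):
            x = np.atleast_2d(replace_zeros(x, delta=zero_delta))
        z = pivot_ilr(x, self.parts[0], self.parts)
        cov = self.covariate_reference if covariates is None else covariates
        params = self.params_by_pivot[self.parts[0]]
        pred = np.full(x.shape[0], params["const"], dtype=float)
        for j in range(len(self.parts) - 1):
            pred += params[f"z{j + 1}"] * z[:, j]
        for name in self.covariate_names:
            pred += params[name] * float(cov[name])
        return pred

    def summary(self) -> str:
        lines = []
        lines.append(f"Composition model: {self.outcome}  ({self.method})")
        lines.append(f"n = {self.n_obs}"
                     + (f", schools = {self.n_schools}" if self.n_schools else ""))
        lines.append(f"log-likelihood = {self.loglik:.3f}   R^2 = {self.r_squared:.3f}")
        lines.append(
            f"Omnibus (4 ILR terms): stat = {self.omnibus_stat:.3f}, "
            f"df = {self.omnibus_df}, p = {self.omnibus_p:.4f}")
        lines.append(f"VIF range = {self.vif_range[0]:.2f}-{self.vif_range[1]:.2f}")
        lines.append("")
        lines.append("One-for-remaining effects (behaviour vs geometric mean of the rest):")
        lines.append(self.effects_frame().to_string(float_format=lambda v: f"{v: .3f}"))
        lines.append("")
        lines.append("Covariates (first-pivot model):")
        lines.append(self.covariates.to_string(float_format=lambda v: f"{v: .3f}"))
        if self.stratified:
            lines.append("")
            lines.append("Sex-stratified refits: " + ", ".join(self.stratified))
        return "\n".join(lines)


class CompositionMentalHealthModel:
    """One-for-remaining compositional regression of an outcome on time use.

    For each of the five pivot ILR bases the outcome is regressed on the
    four ILR coordinates plus covariates, with a school random intercept
    (``method="mixed"``, the default) or plain/cluster-robust OLS.  The
    omnibus association between the outcome and the whole composition is a
    likelihood-ratio test (mixed, ML) or Wald F-test (OLS) of the four ILR
    terms; the per-behaviour effect is the first-pivot coefficient.
    """

    def __init__(self, compositions, outcome, covariates=None, school_ids=None,
                 outcome_name: str = "outcome", parts=PARTS, zero_delta=None):
        comp = np.atleast_2d(np.asarray(compositions, dtype=float))
        if comp.shape[1] != len(parts):
            raise ValueError(f"expected {len(parts)} parts")
        self.parts = tuple(parts)
        self.compositions = np.atleast_2d(replace_zeros(comp, delta=zero_delta))
        self.outcome = np.asarray(outcome, dtype=float)
        if covariates is None:
            covariates = pd.DataFrame(index=range(len(self.outcome)))
        self.covariates = pd.DataFrame(covariates).reset_index(drop=True)
        self.school_ids = None if school_ids is None else np.asarray(school_ids)
        self.outcome_name = outcome_name
        mask = ~np.isnan(self.outcome)
        if self.covariates.shape[1]:
            mask &= ~self.covariates.isna().any(axis=1).to_numpy()
        self._mask = mask

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str, parts=PARTS,
                       covariates=(), school_col: str | None = "school_id",
                       zero_delta=None) -> "CompositionMentalHealthModel":
        comp = df[list(parts)].to_numpy(dtype=float)
        cov = df[list(covariates)] if covariates else None
        schools = df[school_col].to_numpy() if school_col and school_col in df else None
        return cls(comp, df[outcome].to_numpy(dtype=float), cov, schools,
                   outcome_name=outcome, parts=parts, zero_delta=zero_delta)

    # -- design construction ------------------------------------------------

    def _design(self, pivot: str, mask) -> pd.DataFrame:
        z = pivot_ilr(self.compositions[mask], pivot, self.parts)
        x = pd.DataFrame({f"z{j + 1}": z[:, j] for j in range(len(self.parts) - 1)})
        cov = self.covariates.loc[mask].reset_index(drop=True)
        for c in cov.columns:
            x[c] = cov[c].to_numpy(dtype=float)
        x.insert(0, "const", 1.0)
        return x

    def _fit_one(self, endog, exog, groups, method, check_bse=True):
        if method == "mixed":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = MixedLM(endog, exog, groups=groups).fit(reml=False)
            # a zero cluster-variance boundary fit has valid llf but no
            # usable standard errors
            if check_bse and not np.all(
                    np.isfinite(np.asarray(res.bse)[: exog.shape[1]])):
                raise np.linalg.LinAlgError("degenerate mixed fit")
            return res
        cov_kw = {}
        if method == "cluster":
            cov_kw = {"cov_type": "cluster", "cov_kwds": {"groups": groups}}
        return sm.OLS(endog, exog).fit(**cov_kw)

    def omnibus_test(self) -> float:
        """Omnibus p-value of the four ILR terms only (one full and one
        reduced mixed fit; much cheaper than the five-pivot `fit`)."""
        mask = self._mask
        endog = self.outcome[mask]
        groups = self.school_ids[mask] if self.school_ids is not None else None
        nz = len(self.parts) - 1
        full = self._design(self.parts[0], mask)
        reduced = full.drop(columns=[f"z{j + 1}" for j in range(nz)])
        if groups is not None and len(np.unique(groups)) >= 2:
            res1 = self._fit_one(endog, full, groups, "mixed", check_bse=False)
            res0 = self._fit_one(endog, reduced, groups, "mixed", check_bse=False)
            stat = 2.0 * (res1.llf - res0.llf)
            return float(stats.chi2.sf(max(stat, 0.0), nz))
        res1 = self._fit_one(endog, full, None, "ols")
        rmat = np.zeros((nz, full.shape[1]))
        for j in range(nz):
            rmat[j, list(full.columns).index(f"z{j + 1}")] = 1.0
        return float(res1.f_test(rmat).pvalue)

    def fit(self, method: str | None = None, stratify_on_sex: bool = True,
            sex_col: str = "sex_girl") -> CompositionModelResults:
        """Fit all five pivot models and the omnibus test.

        method: "mixed" (school random intercept; default when school ids
        with >=2 schools are available), "ols", or "cluster" (OLS with
        cluster-robust SEs by school).
        """
        mask = self._mask
        endog = self.outcome[mask]
        groups = self.school_ids[mask] if self.school_ids is not None else None
        if method is None:
            method = "mixed" if groups is not None else "ols"
        if method == "mixed" and (groups is None or len(np.unique(groups)) < 2):
            warnings.warn("fewer than 2 schools; falling back to fixed-effects OLS")
            method = "ols"
        if method == "mixed":
            # guard against boundary (zero cluster variance) degeneracies in
            # either the full or the ILR-free reduced design
            try:
                full = self._design(self.parts[0], mask)
                reduced = full.drop(
                    columns=[f"z{j + 1}" for j in range(len(self.parts) - 1)])
                self._fit_one(endog, full, groups, "mixed")
                self._fit_one(endog, reduced, groups, "mixed")
            except np.linalg.LinAlgError:
                warnings.warn("mixed fit degenerate; falling back to OLS")
                method = "ols"

        nz = len(self.parts) - 1
        params_by_pivot, loglik_by_pivot, effects = {}, {}, {}
        cov_table = None
        vif_lo, vif_hi = np.inf, -np.inf
        first_res = None
        for pivot in self.parts:
            exog = self._design(pivot, mask)
            res = self._fit_one(endog, exog, groups, method)
            fe = res.fe_params if hasattr(res, "fe_params") else res.params
            params_by_pivot[pivot] = pd.Series(np.asarray(fe)[: exog.shape[1]],
                                               index=exog.columns)
            loglik_by_pivot[pivot] = float(res.llf)
            ci = res.conf_int()
            ci = np.asarray(ci)[:exog.shape[1]]
            pvals = np.asarray(res.pvalues)[: exog.shape[1]]
            j = list(exog.columns).index("z1")
            effects[pivot] = BehaviourEffect(
                behaviour=pivot, beta=float(params_by_pivot[pivot]["z1"]),
                ci_low=float(ci[j, 0]), ci_high=float(ci[j, 1]), p=float(pvals[j]))
            # VIF over the fixed-effects design (excluding the intercept)
            xm = exog.to_numpy()
            for k in range(1, xm.shape[1]):
                v = variance_inflation_factor(xm, k)
                vif_lo, vif_hi = min(vif_lo, v), max(vif_hi, v)
            if pivot == self.parts[0]:
                first_res = res
                names = list(exog.columns)
                cov_names = [c for c in names if c == "const" or c in self.covariates.columns]
                rows = []
                for c in cov_names:
                    k = names.index(c)
                    rows.append({"term": c, "beta": float(np.asarray(fe)[k]),
                                 "ci_low": float(ci[k, 0]), "ci_high": float(ci[k, 1]),
                                 "p": float(pvals[k])})
                cov_table = pd.DataFrame(rows).set_index("term")

        # omnibus: ILR terms jointly
        exog_first = self._design(self.parts[0], mask)
        if method == "mixed":
            reduced = exog_first.drop(columns=[f"z{j + 1}" for j in range(nz)])
            res0 = self._fit_one(endog, reduced, groups, "mixed")
            stat = 2.0 * (first_res.llf - res0.llf)
            om_p = float(stats.chi2.sf(max(stat, 0.0), nz))
            om_df = nz
        else:
            rmat = np.zeros((nz, exog_first.shape[1]))
            for j in range(nz):
                rmat[j, list(exog_first.columns).index(f"z{j + 1}")] = 1.0
            ftest = first_res.f_test(rmat)
            stat, om_p, om_df = float(ftest.fvalue), float(ftest.pvalue), nz

        fitted = exog_first.to_numpy() @ params_by_pivot[self.parts[0]].to_numpy()
        ssr = float(np.sum((endog - fitted) ** 2))
        sst = float(np.sum((endog - endog.mean()) ** 2))
        r2 = 1.0 - ssr / sst if sst > 0 else np.nan

        school_var = None
        if method == "mixed":
            school_var = float(np.asarray(first_res.cov_re)[0, 0])

        ref = {}
        for c in self.covariates.columns:
            ref[c] = float(self.covariates.loc[mask, c].mean())
        results = CompositionModelResults(
            outcome=self.outcome_name, method=method, parts=self.parts,
            covariate_names=list(self.covariates.columns),
            omnibus_stat=float(stat), omnibus_df=om_df, omnibus_p=om_p,
            loglik=float(first_res.llf), loglik_by_pivot=loglik_by_pivot,
            r_squared=r2, effects=effects, covariates=cov_table,
            vif_range=(float(vif_lo), float(vif_hi)),
            params_by_pivot=params_by_pivot, school_var=school_var,
            n_obs=int(mask.sum()),
            n_schools=None if groups is None else int(len(np.unique(groups))),
            covariate_reference=pd.Series(ref))

        if sex_col in self.covariates.columns:
            names = list(exog_first.columns)
            k = names.index(sex_col)
            results.sex_p = float(np.asarray(first_res.pvalues)[k])
            if stratify_on_sex and results.sex_p < 0.05:
                for label, val in (("boys", 0.0), ("girls", 1.0)):
                    sub = mask & (self.covariates[sex_col].to_numpy() == val)
                    if sub.sum() < len(self.parts) + 3:
                        continue
                    m = CompositionMentalHealthModel(
                        self.compositions[sub], self.outcome[sub],
                        self.covariates.loc[sub].drop(columns=[sex_col]),
                        None if self.school_ids is None else self.school_ids[sub],
                        outcome_name=f"{self.outcome_name} ({label})",
                        parts=self.parts)
                    results.stratified[label] = m.fit(method=method,
                                                      stratify_on_sex=False)
        return results
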