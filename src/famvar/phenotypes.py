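"""Derived healthy-aging phenotypes and analysis-ready transformations.

Implements the composite Healthy Aging Index (HAI) and its
mortality-weighted variant, standard derived clinical traits (telomere
length from the qPCR T/S ratio, Friedewald LDL, BMI, pulse pressure,
type-2-diabetes status), the rank-based inverse-normal transform, and
covariate residualization (full or forward-stepwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "MortalityWeights",
    "HAI_COMPONENTS",
    "tertile_cutpoints",
    "hai_component_scores",
    "hai_score",
    "mortality_weighted_hai",
    "telomere_bp",
    "friedewald_ldl",
    "pulse_pressure",
    "bmi",
    "t2d_status",
    "inverse_normal_transform",
    "adjust_covariates",
]

#: HAI components and whether *higher* values are unhealthy
HAI_COMPONENTS = {
    "systolic_bp": True,
    "vital_capacity": False,
    "creatinine": True,
    "fasting_glucose": True,
    "mmse": False,
}


@dataclass(frozen=True)
class MortalityWeights:
    """Cox-model hazard coefficients weighting each HAI component."""

    systolic_bp: float = 0.17085
    vital_capacity: float = 0.38386
    mmse: float = 0.42873
    creatinine: float = 0.13397
    fasting_glucose: float = 0.23880

    def as_dict(self) -> dict:
        return {
            "systolic_bp": self.systolic_bp,
            "vital_capacity": self.vital_capacity,
            "mmse": self.mmse,
            "creatinine": self.creatinine,
            "fasting_glucose": self.fasting_glucose,
        }


def tertile_cutpoints(
    values: pd.Series,
    age: pd.Series | None = None,
    sex: pd.Series | None = None,
    age_adjusted: bool = True,
) -> tuple[float, float] | pd.DataFrame:
    """Tertile boundaries for one HAI component.

    With ``age_adjusted`` (the default) the boundaries are tertiles of the
    residuals from a linear age regression fit within sex, returned as a
    per-sex DataFrame of residual cutpoints plus the fitted line; otherwise
    plain tertiles of the raw values, returned as a (lower, upper) pair.
    """
    v = pd.Series(values).astype(float)
    if not age_adjusted:
        lo, hi = np.nanquantile(v, [1 / 3, 2 / 3])
        return float(lo), float(hi)
    if age is None or sex is None:
        raise ValueError("age-adjusted cutpoints require age and sex")
    rows = []
    for s, grp in pd.DataFrame({"v": v, "age": age, "sex": sex}).groupby("sex"):
        ok = grp[["v", "age"]].notna().all(axis=1)
        g = grp[ok]
        slope, intercept = np.polyfit(g["age"], g["v"], 1)
        resid = g["v"] - (intercept + slope * g["age"])
        lo, hi = np.quantile(resid, [1 / 3, 2 / 3])
        rows.append({"sex": s, "intercept": intercept, "slope": slope, "lo": lo, "hi": hi})
    return pd.DataFrame(rows).set_index("sex")


def _score_one(value: float, lo: float, hi: float, higher_is_unhealthy: bool) -> int:
    # ties go to the lower (healthier) score
    if higher_is_unhealthy:
        if value <= lo:
            return 0
        return 1 if value <= hi else 2
    if value >= hi:
        return 0
    return 1 if value > lo else 2


def hai_component_scores(components: dict, cutpoints: dict, directions: dict | None = None) -> dict:
    """Score each component 0/1/2 by tertile (0 = healthiest).

    ``cutpoints`` maps component -> (lower, upper) tertile boundaries on the
    same scale as the supplied values (raw or age-adjusted residuals).
    """
    directions = directions or HAI_COMPONENTS
    scores = {}
    for name, unhealthy_up in directions.items():
        val = components.get(name)
        if val is None or (isinstance(val, float) and np.isnan(val)):
            scores[name] = None
            continue
        lo, hi = cutpoints[name]
        scores[name] = _score_one(float(val), float(lo), float(hi), unhealthy_up)
    return scores


def hai_score(components: dict, cutpoints: dict, directions: dict | None = None):
    """Healthy Aging Index: sum of the five 0/1/2 tertile scores, 0 (healthy)
    to 10 (unhealthy). Any missing component makes the index missing —
    partial sums are not comparable across individuals."""
    scores = hai_component_scores(components, cutpoints, directions)
    if any(s is None for s in scores.values()):
        return None, scores
    return int(sum(scores.values())), scores


def mortality_weighted_hai(per_trait_scores: dict, weights: MortalityWeights | None = None):
    """Mortality-weighted HAI: sum of Cox-weighted component scores."""
    weights = weights or MortalityWeights()
    w = weights.as_dict()
    if any(per_trait_scores.get(k) is None for k in w):
        return None
    for k, s in per_trait_scores.items():
        if k in w and s not in (0, 1, 2):
            raise ValueError(f"component score for {k} must be 0, 1 or 2; got {s}")
    return float(sum(w[k] * per_trait_scores[k] for k in w))


def telomere_bp(ts_ratio):
    """Leukocyte telomere length in base pairs from the qPCR T/S ratio."""
    ts = np.asarray(ts_ratio, dtype=float)
    if np.any(ts < 0):
        raise ValueError("T/S ratio must be non-negative")
    out = 1585.0 * ts + 3582.0
    return float(out) if np.isscalar(ts_ratio) else out


def friedewald_ldl(total_chol, hdl, trig):
    """Friedewald LDL: total - HDL - trig/5, undefined (NaN) at trig >= 400 mg/dL."""
    tc = np.asarray(total_chol, dtype=float)
    h = np.asarray(hdl, dtype=float)
    t = np.asarray(trig, dtype=float)
    if np.any(tc[~np.isnan(tc)] < 0) or np.any(h[~np.isnan(h)] < 0) or np.any(t[~np.isnan(t)] < 0):
        raise ValueError("lipid inputs must be non-negative")
    ldl = tc - h - t / 5.0
    ldl = np.where(t < 400.0, ldl, np.nan)
    return float(ldl) if np.isscalar(total_chol) else ldl


def pulse_pressure(sbp, dbp):
    """Pulse pressure: systolic minus diastolic, mmHg."""
    return np.asarray(sbp, dtype=float) - np.asarray(dbp, dtype=float) \
        if not np.isscalar(sbp) else float(sbp) - float(dbp)


def bmi(weight_kg, height_m):
    """Body mass index: weight (kg) / height (m) squared."""
    w = np.asarray(weight_kg, dtype=float)
    h = np.asarray(height_m, dtype=float)
    if np.any(h[~np.isnan(h)] <= 0):
        raise ValueError("height must be positive")
    out = w / h**2
    return float(out) if np.isscalar(weight_kg) else out


def t2d_status(diabetes_meds, fasting_glucose):
    """Type 2 diabetes: on diabetes medication or fasting glucose >= 126 mg/dL."""
    meds = np.asarray(diabetes_meds, dtype=bool)
    gluc = np.asarray(fasting_glucose, dtype=float)
    out = meds | (gluc >= 126.0)
    return bool(out) if np.isscalar(fasting_glucose) else out


def inverse_normal_transform(values, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform with Blom offset.

    Rank r maps to Phi^-1((r - c) / (n + 1 - 2c)); ties share their average
    rank; missing values stay missing and do not consume ranks.
    """
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    obs = ~np.isnan(v)
    n = int(obs.sum())
    if n < 2:
        raise ValueError("inverse-normal transform needs >= 2 non-missing values")
    ranks = stats.rankdata(v[obs], method="average")
    out[obs] = stats.norm.ppf((ranks - c) / (n + 1.0 - 2.0 * c))
    return out


def adjust_covariates(
    trait,
    covariates: pd.DataFrame | None,
    mode: str = "full",
    alpha: float = 0.05,
    standardize: bool = True,
) -> np.ndarray:
    """Residualize a trait on covariates; the residuals are the analysis phenotype.

    ``full`` regresses on every covariate; ``stepwise`` forward-selects
    covariates at p < alpha and residualizes on the selected set. Categorical
    (object/category) columns are one-hot expanded. Residuals are
    standardized to unit variance unless ``standardize=False``. Rows with
    missing trait or covariate values come back NaN.
    """
    y = pd.Series(np.asarray(trait, dtype=float))
    if covariates is None or covariates.shape[1] == 0:
        X = pd.DataFrame(index=y.index)
    else:
        X = pd.get_dummies(covariates.reset_index(drop=True), drop_first=True, dtype=float)
    ok = y.notna()
    if len(X.columns):
        ok &= X.notna().all(axis=1)
    yv = y[ok].to_numpy()
    Xv = X.loc[ok]
    if mode == "stepwise":
        selected = _forward_select(yv, Xv, alpha)
        Xv = Xv[selected]
    elif mode != "full":
        raise ValueError(f"unknown adjustment mode {mode!r}")
    design = sm.add_constant(Xv.to_numpy(), has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = _collinear_columns(Xv)
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    fit = sm.OLS(yv, design).fit()
    resid = fit.resid
    if standardize:
        sd = resid.std(ddof=1)
        if sd > 0:
            resid = resid / sd
    out = np.full(len(y), np.nan)
    out[ok.to_numpy()] = resid
    return out


def _forward_select(y: np.ndarray, X: pd.DataFrame, alpha: float) -> list:
    selected: list = []
    remaining = list(X.columns)
    while remaining:
        best_p, best_col = None, None
        for col in remaining:
            design = sm.add_constant(X[selected + [col]].to_numpy(), has_constant="add")
            if np.linalg.matrix_rank(design) < design.shape[1]:
                continue
            fit = sm.OLS(y, design).fit()
            p = fit.pvalues[-1]
            if best_p is None or p < best_p:
                best_p, best_col = p, col
        if best_col is None or best_p >= alpha:
            break
        selected.append(best_col)
        remaining.remove(best_col)
    return selected


def _collinear_columns(X: pd.DataFrame) -> list:
    """Name columns that do not increase the design rank."""
    bad = []
    base = np.ones((len(X), 1))
    kept = base
    for col in X.columns:
        cand = np.column_stack([kept, X[col].to_numpy()])
        if np.linalg.matrix_rank(cand) == kept.shape[1]:
            bad.append(col)
        else:
            kept = cand
    return bad
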