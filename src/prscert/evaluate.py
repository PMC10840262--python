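"""Downstream impact: covariate-adjusted odds ratios and cross-validated AUC.

Odds ratios contrast PRS-based risk groups (certain extremes, or mean-based
deciles against the lowest) by multivariable logistic regression adjusted
for age, gender and smoking status, with Wald 95% intervals; stratified
analyses restrict to subgroups first. Risk-prediction performance is the
AUC of incremental logistic models (risk group alone, then +age, +gender,
+smoking status or pack-years) under stratified five-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from ._utils import design_matrix


@dataclass
class ORResult:
    odds_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    n: int
    covariates: list[str] = field(default_factory=list)
    subgroup: str = "all"
    quasi_separation: bool = False

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")


@dataclass
class AUCResult:
    auc: float
    ci_lower: float
    ci_upper: float
    fold_aucs: np.ndarray
    predictors: list[str]
    subset: str
    n: int


def fit_or(
    phenotype: np.ndarray,
    group_indicator: np.ndarray,
    covariates: pd.DataFrame | None = None,
    subgroup_filter: np.ndarray | None = None,
    subgroup_label: str = "all",
) -> ORResult:
    """Adjusted odds ratio of the group indicator by logistic regression.

    Fits case status on the 0/1 group indicator plus covariates (within the
    optional subgroup) and returns exp(coef) with its Wald 95% interval and
    p-value. Quasi-separation (non-convergence or runaway coefficient) is
    flagged, not raised.
    """
    y = np.asarray(phenotype, dtype=float)
    g = np.asarray(group_indicator, dtype=float)
    if subgroup_filter is not None:
        mask = np.asarray(subgroup_filter, dtype=bool)
        if not mask.any():
            raise ValueError(f"subgroup {subgroup_label!r} is empty")
        y, g = y[mask], g[mask]
        covariates = covariates.loc[mask] if covariates is not None else None
    if len(np.unique(g)) < 2:
        raise ValueError("both levels of the group indicator must be present")
    if len(np.unique(y)) < 2:
        raise ValueError("both phenotype classes must be present")

    cov_names: list[str] = []
    x = g.reshape(-1, 1)
    if covariates is not None and covariates.shape[1] > 0:
        x = np.hstack([x, design_matrix(covariates)])
        cov_names = list(covariates.columns)
    x = sm.add_constant(x, prepend=False)

    quasi = False
    try:
        res = sm.Logit(y, x).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", True) or abs(res.params[0]) > 15:
            quasi = True
    except Exception:
        # separation: stabilize with a tiny ridge and report with the flag set
        quasi = True
        res = sm.Logit(y, x).fit_regularized(alpha=1e-4, disp=0, maxiter=500)

    coef = float(res.params[0])
    try:
        se = float(res.bse[0])
    except Exception:
        se = np.nan
    if not np.isfinite(se) or se == 0:
        quasi = True
        se = np.nan
    z = coef / se if np.isfinite(se) else np.nan
    pval = 2.0 * norm.sf(abs(z)) if np.isfinite(z) else np.nan
    half = 1.959963984540054 * se
    return ORResult(
        odds_ratio=float(np.exp(coef)),
        ci_lower=float(np.exp(coef - half)) if np.isfinite(se) else np.nan,
        ci_upper=float(np.exp(coef + half)) if np.isfinite(se) else np.nan,
        p_value=float(pval) if np.isfinite(z) else np.nan,
        n=int(len(y)),
        covariates=cov_names,
        subgroup=subgroup_label,
        quasi_separation=quasi,
    )


def or_table_mean_deciles(
    phenotype: np.ndarray,
    decile: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Each decile versus the lowest, one pairwise adjusted logistic fit per row."""
    y = np.asarray(phenotype)
    decile = np.asarray(decile)
    rows = []
    for d in range(2, 11):
        mask = (decile == 1) | (decile == d)
        res = fit_or(
            y[mask],
            (decile[mask] == d).astype(int),
            covariates.loc[mask] if covariates is not None else None,
            subgroup_label=f"decile {d} vs 1",
        )
        rows.append(
            {
                "decile": d,
                "odds_ratio": res.odds_ratio,
                "ci_lower": res.ci_lower,
                "ci_upper": res.ci_upper,
                "p_value": res.p_value,
                "n": res.n,
            }
        )
    return pd.DataFrame(rows)


def cv_auc(
    phenotype: np.ndarray,
    feature_sets: dict[str, np.ndarray | pd.DataFrame],
    k: int = 5,
    subset: np.ndarray | None = None,
    subset_label: str = "all",
    seed: int = 0,
) -> list[AUCResult]:
    """Stratified k-fold cross-validated AUC for an ordered list of models.

    Each feature set is fit by logistic regression on the training folds and
    scored by AUC on the held-out fold; the interval is the normal
    approximation over fold AUCs. Deterministic given ``seed``.
    """
    y = np.asarray(phenotype, dtype=int)
    if subset is not None:
        mask = np.asarray(subset, dtype=bool)
    else:
        mask = np.ones(y.shape[0], dtype=bool)
    y_sub = y[mask]
    if len(np.unique(y_sub)) < 2:
        raise ValueError("subset must contain both phenotype classes")

    results = []
    for name, feats in feature_sets.items():
        if isinstance(feats, pd.DataFrame):
            x = design_matrix(feats.loc[mask])
            predictors = list(feats.columns)
        else:
            x = np.atleast_2d(np.asarray(feats, dtype=float))
            if x.shape[0] == 1:
                x = x.T
            x = x[mask]
            predictors = [name]
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % 2**32)
        fold_aucs = []
        for train, test in skf.split(x, y_sub):
            if len(np.unique(y_sub[test])) < 2:
                raise ValueError("degenerate fold: held-out data has one class")
            mu, sd = x[train].mean(axis=0), x[train].std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
            model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=500)
            model.fit((x[train] - mu) / sd, y_sub[train])
            prob = model.predict_proba((x[test] - mu) / sd)[:, 1]
            fold_aucs.append(roc_auc_score(y_sub[test], prob))
        fold_aucs = np.array(fold_aucs)
        half = 1.959963984540054 * fold_aucs.std(ddof=1) / np.sqrt(k)
        results.append(
            AUCResult(
                auc=float(fold_aucs.mean()),
                ci_lower=float(fold_aucs.mean() - half),
                ci_upper=float(fold_aucs.mean() + half),
                fold_aucs=fold_aucs,
                predictors=predictors,
                subset=subset_label,
                n=int(mask.sum()),
            )
        )
    return results


def auc_model_grid(
    phenotype: np.ndarray,
    risk_group: np.ndarray,
    covariates: pd.DataFrame,
    subset: np.ndarray | None = None,
    subset_label: str = "all",
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """The incremental model ladder: PRS risk group, then +age, +gender,
    +smoking status / +pack-years, and covariates-only."""
    risk = np.asarray(risk_group, dtype=float)
    base = pd.DataFrame({"prs_risk": risk}, index=covariates.index)
    sets = {
        "prs_risk": base,
        "prs_risk+age": base.assign(age=covariates["age"]),
        "prs_risk+age+gender": base.assign(
            age=covariates["age"], gender=covariates["gender"]
        ),
        "prs_risk+age+gender+smoking_status": base.assign(
            age=covariates["age"],
            gender=covariates["gender"],
            smoking_status=covariates["smoking_status"],
        ),
        "prs_risk+age+gender+packyears": base.assign(
            age=covariates["age"],
            gender=covariates["gender"],
            pack_years=covariates["pack_years"],
        ),
        "age+gender+smoking_status": covariates[["age", "gender", "smoking_status"]],
    }
    results = cv_auc(
        phenotype, sets, k=k, subset=subset, subset_label=subset_label, seed=seed
    )
    return pd.DataFrame(
        {
            "model": list(sets.keys()),
            "auc": [r.auc for r in results],
            "ci_lower": [r.ci_lower for r in results],
            "ci_upper": [r.ci_upper for r in results],
            "n": [r.n for r in results],
        }
    )
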