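"""Cross-validated bootstrap PRS: per-individual score distributions.

Effect sizes come from multivariable logistic regression of case status on
all scored SNP dosages jointly, adjusted for covariates (age, gender,
smoking status, principal components), estimated by stratified k-fold
cross-validation. Within each fold, B stratified bootstrap resamples of the
training folds are refit; scoring the held-out individuals with each
resample's SNP coefficients yields B score draws per individual — the
individual-level PRS distribution summarized by its mean, s.d. and
empirical p-level confidence interval. Covariate coefficients never enter
the score: the PRS is genetics-only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from ._utils import child_seeds, design_matrix
from .containers import GenotypeMatrix, PRSDraws, summarize_draws

__all__ = [
    "CVBootConfig",
    "CVBootDiagnostics",
    "cv_bootstrap_prs",
    "summarize_draws",
]


@dataclass(frozen=True)
class CVBootConfig:
    k_folds: int = 5
    n_boot: int = 1000
    level: float = 0.95
    seed: int = 0
    marginal: bool = False  # per-SNP fits instead of one joint model
    max_iter: int = 200

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0.0 <= self.level <= 1.0:
            raise ValueError("level must lie in [0, 1]")


@dataclass
class CVBootDiagnostics:
    """Per-fold point estimates and fit bookkeeping for the bootstrap arm."""

    fold_assignment: np.ndarray  # held-out fold per individual
    point_weights: np.ndarray  # (k_folds, m) full-training-fold SNP coefficients
    point_scores: np.ndarray  # held-out scores under the fold point weights
    boot_weights: np.ndarray  # (k_folds, n_boot, m) bootstrap SNP coefficients
    n_ridge_refits: int = 0


def _fit_snp_coefs(
    features: np.ndarray, y: np.ndarray, m_snps: int, max_iter: int
) -> tuple[np.ndarray, bool]:
    """Logistic fit returning per-allele SNP coefficients; ridge fallback.

    Features are z-scaled internally for conditioning and coefficients
    mapped back to the raw scale. Non-convergence or runaway coefficients
    (quasi-separation) trigger a lightly L2-penalized refit.
    """
    mu = features.mean(axis=0)
    sd = features.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    fs = (features - mu) / sd
    used_ridge = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model = LogisticRegression(
                C=np.inf, solver="lbfgs", max_iter=max_iter
            ).fit(fs, y)
            coef_scaled = model.coef_[0]
            if np.abs(coef_scaled).max() > 30:
                raise ConvergenceWarning("runaway coefficients")
        except (ConvergenceWarning, Warning):
            used_ridge = True
            model = LogisticRegression(
                C=100.0, solver="lbfgs", max_iter=max(500, max_iter)
            ).fit(fs, y)
            coef_scaled = model.coef_[0]
    return coef_scaled[:m_snps] / sd[:m_snps], used_ridge


def _fit_weights(
    x_snp: np.ndarray,
    cov: np.ndarray,
    y: np.ndarray,
    marginal: bool,
    max_iter: int,
) -> tuple[np.ndarray, int]:
    m = x_snp.shape[1]
    if not marginal:
        w, used = _fit_snp_coefs(np.hstack([x_snp, cov]), y, m, max_iter)
        return w, int(used)
    w = np.empty(m)
    n_ridge = 0
    for j in range(m):
        wj, used = _fit_snp_coefs(
            np.hstack([x_snp[:, [j]], cov]), y, 1, max_iter
        )
        w[j] = wj[0]
        n_ridge += int(used)
    return w, n_ridge


def cv_bootstrap_prs(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    covariates: pd.DataFrame,
    variant_ids: list[str] | None = None,
    config: CVBootConfig = CVBootConfig(),
) -> tuple[PRSDraws, CVBootDiagnostics]:
    """Individual-level bootstrap PRS distributions via k-fold CV.

    Folds are stratified by case status. For each fold, B stratified
    bootstrap resamples (cases and controls resampled separately, preserving
    the training class balance) of the other k-1 folds are refit; each
    held-out individual is scored with each resample's SNP coefficients and
    receives draws only from the fold where they were held out.
    Deterministic given ``config.seed``.
    """
    y = np.asarray(phenotype, dtype=int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("phenotype must be binary 0/1")
    if variant_ids is None:
        col_idx = np.arange(genotypes.m)
    else:
        indexer = genotypes.variant_indexer()
        missing = [v for v in variant_ids if v not in indexer]
        if missing:
            raise ValueError(f"variants absent from genotypes: {missing[:5]}")
        col_idx = np.array([indexer[v] for v in variant_ids])

    x_snp = genotypes.imputed_dosages()[:, col_idx]
    cov = design_matrix(covariates)
    n, m = x_snp.shape
    k, B = config.k_folds, config.n_boot

    draws = np.empty((n, B))
    point_scores = np.empty(n)
    point_weights = np.empty((k, m))
    boot_weights = np.empty((k, B, m))
    fold_assignment = np.empty(n, dtype=int)
    n_ridge = 0

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed % 2**31)
    fold_seeds = child_seeds(config.seed, k)
    for f, (train, test) in enumerate(skf.split(x_snp, y)):
        if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
            raise ValueError(f"fold {f} lacks both phenotype classes")
        fold_assignment[test] = f
        w_point, used = _fit_weights(
            x_snp[train], cov[train], y[train], config.marginal, config.max_iter
        )
        n_ridge += used
        point_weights[f] = w_point
        point_scores[test] = x_snp[test] @ w_point

        rng = np.random.default_rng(fold_seeds[f])
        cases = train[y[train] == 1]
        controls = train[y[train] == 0]
        for b in range(B):
            res = np.concatenate(
                [
                    rng.choice(cases, size=len(cases), replace=True),
                    rng.choice(controls, size=len(controls), replace=True),
                ]
            )
            w, used = _fit_weights(
                x_snp[res], cov[res], y[res], config.marginal, config.max_iter
            )
            n_ridge += used
            boot_weights[f, b] = w
            draws[test, b] = x_snp[test] @ w

    prs = PRSDraws(draws=draws, samples=list(genotypes.samples), source="bootstrap")
    diag = CVBootDiagnostics(
        fold_assignment=fold_assignment,
        point_weights=point_weights,
        point_scores=point_scores,
        boot_weights=boot_weights,
        n_ridge_refits=n_ridge,
    )
    return prs, diag
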