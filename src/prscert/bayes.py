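"""Posterior PRS via a spike-slab Gibbs sampler over per-SNP effects.

The LDpred-style model: marginal GWAS effects ``beta_hat`` on standardized
genotypes are noisy observations of true effects ``beta`` coupled through
the LD (correlation) matrix, ``beta_hat ~ N(R beta, R sigma_e^2 / n)``. The
prior on each effect is a spike-slab: exactly zero with probability
``1 - p_causal``, otherwise N(0, h2 / (M * p_causal)). A systematic-scan
Gibbs sampler draws each coordinate from its conditional (a point mass or a
normal), and every retained effect-vector draw is turned into a full PRS
for each individual, giving a per-individual posterior score distribution
whose credible interval is the empirical quantile interval.

Summary statistics come from linear regression of the covariate-residualized
0/1 phenotype on standardized dosages — the standard continuous-trait
approximation used by LDpred-style pipelines on case-control data — which
keeps the sampler's Gaussian likelihood exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from ._utils import child_seeds, design_matrix
from .containers import GenotypeMatrix, PRSDraws


@dataclass
class SummaryStats:
    """Per-variant marginal effects on the standardized-genotype scale."""

    beta_hat: np.ndarray
    se: np.ndarray
    n: int
    variant_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.beta_hat = np.asarray(self.beta_hat, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if self.beta_hat.shape != self.se.shape:
            raise ValueError("beta_hat and se must align")
        if not np.isfinite(self.beta_hat).all() or not np.isfinite(self.se).all():
            raise ValueError("summary statistics must be finite")
        if np.any(self.se <= 0):
            raise ValueError("standard errors must be positive")

    @property
    def m(self) -> int:
        return self.beta_hat.shape[0]


@dataclass
class LDMatrix:
    """Block-diagonal LD: per-block correlation matrices plus ridge epsilon."""

    blocks: list[np.ndarray]  # index arrays partitioning the variants
    matrices: list[np.ndarray]  # correlation matrix per block, ridge added
    epsilon: float

    @property
    def m(self) -> int:
        return sum(len(b) for b in self.blocks)

    def dense(self) -> np.ndarray:
        """Full (M x M) matrix; intended for small M."""
        out = np.zeros((self.m, self.m))
        for idx, mat in zip(self.blocks, self.matrices):
            out[np.ix_(idx, idx)] = mat
        return out


@dataclass(frozen=True)
class SpikeSlabPrior:
    """p_causal, h2 and variant count; slab variance is h2 / (M * p_causal)."""

    p_causal: float
    h2: float
    m: int

    def __post_init__(self) -> None:
        if not 0.0 < self.p_causal <= 1.0:
            raise ValueError("p_causal must lie in (0, 1]")
        if not 0.0 <= self.h2 < 1.0:
            raise ValueError("h2 must lie in [0, 1)")
        if self.m < 1:
            raise ValueError("m must be positive")

    @property
    def slab_var(self) -> float:
        return self.h2 / (self.m * self.p_causal)


@dataclass
class PosteriorEffectDraws:
    """Retained posterior samples of the effect-size vector."""

    draws: np.ndarray  # (n_draws, M)
    burn_in: int
    thin: int
    seed: int
    variant_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.draws = np.atleast_2d(np.asarray(self.draws, dtype=float))
        if self.draws.shape[0] < 1:
            raise ValueError("at least one retained draw is required")
        if not np.isfinite(self.draws).all():
            raise ValueError("posterior draws must be finite")


def marginal_stats(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> SummaryStats:
    """Marginal per-variant effects of the residualized phenotype.

    The 0/1 phenotype is residualized on the covariates (with intercept) by
    least squares and scaled to unit variance; dosages are standardized by
    their empirical mean and s.d. Then ``beta_hat_j = x_j' y / n`` and
    ``se_j = sqrt((var(y) - beta_hat_j^2) / n)``. Variants constant after
    standardization are dropped with a warning.
    """
    y = np.asarray(phenotype, dtype=float)
    n = y.shape[0]
    if covariates is not None and covariates.shape[1] > 0:
        c = design_matrix(covariates, add_intercept=True)
        y = y - c @ np.linalg.lstsq(c, y, rcond=None)[0]
    else:
        y = y - y.mean()
    sd_y = y.std()
    if sd_y == 0:
        raise ValueError("phenotype is constant after residualization")
    y = y / sd_y

    x = genotypes.imputed_dosages()
    col_sd = x.std(axis=0)
    keep = col_sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} constant variant(s) from summary statistics"
        )
    x = (x[:, keep] - x[:, keep].mean(axis=0)) / col_sd[keep]
    beta_hat = x.T @ y / n
    resid_var = np.maximum(1.0 - beta_hat**2, 1e-12)
    se = np.sqrt(resid_var / n)
    ids = [v for v, k in zip(genotypes.variants["id"], keep) if k]
    return SummaryStats(beta_hat=beta_hat, se=se, n=n, variant_ids=ids)


def ld_matrix(
    genotypes: GenotypeMatrix,
    blocks: list[np.ndarray] | None = None,
    epsilon: float = 0.01,
) -> LDMatrix:
    """Within-block sample correlations of standardized dosages.

    ``blocks`` is a partition of variant indices; by default the simulator's
    ``block`` metadata column is used (one block per label), falling back to
    a single block. Correlations across blocks are structurally zero;
    ``epsilon`` is added to each diagonal for numerical stability.
    """
    if blocks is None:
        if "block" in genotypes.variants.columns:
            labels = genotypes.variants["block"].to_numpy()
            blocks = [np.flatnonzero(labels == b) for b in pd.unique(labels)]
        else:
            blocks = [np.arange(genotypes.m)]
    covered = np.sort(np.concatenate(blocks))
    if not np.array_equal(covered, np.arange(genotypes.m)):
        raise ValueError("blocks must partition the variant indices")

    x = genotypes.standardized()
    matrices = []
    for idx in blocks:
        xb = x[:, idx]
        r = np.corrcoef(xb, rowvar=False) if len(idx) > 1 else np.ones((1, 1))
        r = np.atleast_2d(r)
        r = r + epsilon * np.eye(len(idx))
        if np.linalg.eigvalsh(r).min() <= 0:
            raise ValueError(
                "LD block is singular after regularization; increase epsilon"
            )
        matrices.append(r)
    return LDMatrix(blocks=[np.asarray(b) for b in blocks], matrices=matrices, epsilon=epsilon)


def gibbs_sample_effects(
    stats: SummaryStats,
    ld: LDMatrix,
    prior: SpikeSlabPrior,
    n_iter: int = 700,
    burn_in: int = 200,
    thin: int = 1,
    seed: int = 0,
    sigma_e2: float = 1.0,
) -> PosteriorEffectDraws:
    """Systematic-scan spike-slab Gibbs sampler over per-SNP effects.

    For each variant j the LD-residualized marginal estimate
    ``beta_tilde_j = beta_hat_j - sum_{k != j} R_jk beta_k`` has likelihood
    N(beta_j, sigma_e^2 / n); combined with the spike-slab prior this gives
    a Bernoulli inclusion draw followed by a normal slab draw
    (mean ``v * n * beta_tilde / sigma_e^2``,
    variance ``v = 1 / (n / sigma_e^2 + 1 / slab_var)``) or an exact zero.
    Draws after ``burn_in``, thinned by ``thin``, are retained.
    Deterministic given ``seed``.
    """
    if stats.m != ld.m or stats.m != prior.m:
        raise ValueError("summary stats, LD and prior dimensions must match")
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    for r in ld.matrices:
        if np.linalg.eigvalsh(r).min() <= 0:
            raise ValueError("LD matrix is not positive definite; increase epsilon")

    rng = np.random.default_rng(seed)
    m = stats.m
    n = stats.n
    beta = np.zeros(m)
    retained = []

    if prior.h2 == 0.0:
        # prior collapses to the spike: the posterior is a point mass at zero
        n_keep = max(1, (n_iter - burn_in) // thin)
        return PosteriorEffectDraws(
            draws=np.zeros((n_keep, m)),
            burn_in=burn_in,
            thin=thin,
            seed=seed,
            variant_ids=stats.variant_ids,
        )

    slab_var = prior.slab_var
    obs_var = sigma_e2 / n  # sampling variance of the residualized marginal
    post_var = 1.0 / (1.0 / obs_var + 1.0 / slab_var)
    log_prior_odds = np.log(prior.p_causal) - np.log1p(-prior.p_causal) if prior.p_causal < 1 else np.inf
    sqrt_post = np.sqrt(post_var)

    # per-block local state: beta_hat slice, R, running R @ beta
    block_state = []
    for idx, r in zip(ld.blocks, ld.matrices):
        block_state.append(
            {
                "idx": idx,
                "R": r,
                "bh": stats.beta_hat[idx].copy(),
                "rb": r @ beta[idx],
            }
        )

    for it in range(n_iter):
        for st in block_state:
            idx, r, bh, rb = st["idx"], st["R"], st["bh"], st["rb"]
            for jj in range(len(idx)):
                j = idx[jj]
                old = beta[j]
                # residualize: remove every other variant's LD contribution
                beta_tilde = bh[jj] - (rb[jj] - r[jj, jj] * old)
                mean_post = post_var * beta_tilde / obs_var
                if prior.p_causal >= 1.0:
                    new = mean_post + sqrt_post * rng.standard_normal()
                else:
                    log_bf = (
                        0.5 * np.log(post_var / slab_var)
                        + 0.5 * mean_post**2 / post_var
                    )
                    logit_incl = log_prior_odds + log_bf
                    p_incl = 1.0 / (1.0 + np.exp(-logit_incl))
                    if rng.random() < p_incl:
                        new = mean_post + sqrt_post * rng.standard_normal()
                    else:
                        new = 0.0
                if new != old:
                    beta[j] = new
                    rb += r[:, jj] * (new - old)
        if it >= burn_in and (it - burn_in) % thin == 0:
            retained.append(beta.copy())

    return PosteriorEffectDraws(
        draws=np.array(retained),
        burn_in=burn_in,
        thin=thin,
        seed=seed,
        variant_ids=stats.variant_ids,
    )


def posterior_prs_draws(
    genotypes: GenotypeMatrix,
    draws: PosteriorEffectDraws,
    center: np.ndarray | None = None,
    scale: np.ndarray | None = None,
) -> PRSDraws:
    """Score every individual with every retained effect-vector draw.

    Effects live on the standardized-genotype scale, so scoring uses the
    standardized dosages: ``score_i^(d) = sum_j x_std_ij * beta_j^(d)``.
    ``center``/``scale`` override the per-variant standardization (e.g. with
    training-fold statistics when scoring held-out individuals).
    """
    if genotypes.m != draws.draws.shape[1]:
        raise ValueError("genotypes and effect draws are not dimension-matched")
    if center is not None or scale is not None:
        if center is None or scale is None:
            raise ValueError("center and scale must be supplied together")
        x = (genotypes.imputed_dosages() - center) / np.where(scale > 0, scale, 1.0)
    else:
        x = genotypes.standardized()
    scores = x @ draws.draws.T  # (n_individuals, n_draws)
    return PRSDraws(draws=scores, samples=list(genotypes.samples), source="posterior")


def select_prior(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | None = None,
    h2_grid: tuple[float, ...] = (0.05, 0.1, 0.3),
    p_causal_grid: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0),
    val_fraction: float = 0.25,
    n_iter: int = 300,
    burn_in: int = 100,
    seed: int = 0,
) -> SpikeSlabPrior:
    """Pick spike-slab hyperparameters by held-out AUC of the posterior-mean PRS.

    A single stratified train/validation split of the supplied (training)
    data; for each (h2, p_causal) pair the sampler runs on the training part
    and the posterior-mean score is evaluated by AUC on the validation part.
    Ties break toward the sparser, lower-h2 prior (grid order).
    """
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import train_test_split

    y = np.asarray(phenotype, dtype=int)
    idx_train, idx_val = train_test_split(
        np.arange(genotypes.n),
        test_size=val_fraction,
        stratify=y,
        random_state=seed % 2**31,
    )
    g_train = genotypes.subset_samples(idx_train)
    cov_train = covariates.iloc[idx_train] if covariates is not None else None
    stats = marginal_stats(g_train, y[idx_train], cov_train)
    if stats.m != genotypes.m:
        raise ValueError("constant variant within the training split; run QC first")
    ld = ld_matrix(g_train)
    x_train = g_train.imputed_dosages()
    g_val = genotypes.subset_samples(idx_val)

    best: tuple[float, SpikeSlabPrior] | None = None
    sub_seeds = child_seeds(seed, len(h2_grid) * len(p_causal_grid))
    k = 0
    for h2 in h2_grid:
        for p_causal in p_causal_grid:
            prior = SpikeSlabPrior(p_causal=p_causal, h2=h2, m=genotypes.m)
            eff = gibbs_sample_effects(
                stats, ld, prior, n_iter=n_iter, burn_in=burn_in, seed=sub_seeds[k]
            )
            k += 1
            scores = posterior_prs_draws(
                g_val, eff, center=x_train.mean(axis=0), scale=x_train.std(axis=0)
            ).means()
            auc = roc_auc_score(y[idx_val], scores)
            if best is None or auc > best[0]:
                best = (auc, prior)
    return best[1]


def cv_posterior_prs(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | None,
    prior: SpikeSlabPrior,
    k_folds: int = 5,
    n_iter: int = 700,
    burn_in: int = 200,
    thin: int = 1,
    epsilon: float = 0.01,
    seed: int = 0,
) -> PRSDraws:
    """Held-out posterior PRS draws under stratified k-fold training.

    Summary statistics and LD are computed on the training folds only;
    posterior effect draws are sampled there and held-out individuals are
    scored with them, mirroring the train/score separation of the
    cross-validated bootstrap arm.
    """
    y = np.asarray(phenotype, dtype=int)
    n = genotypes.n
    draws_out: np.ndarray | None = None
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed % 2**31)
    fold_seeds = child_seeds(seed, k_folds)
    for f, (train, test) in enumerate(skf.split(np.zeros((n, 1)), y)):
        g_train = genotypes.subset_samples(train)
        cov_train = covariates.iloc[train] if covariates is not None else None
        stats = marginal_stats(g_train, y[train], cov_train)
        if stats.m != genotypes.m:
            raise ValueError("constant variant within a training fold; run QC first")
        ld = ld_matrix(g_train, epsilon=epsilon)
        eff = gibbs_sample_effects(
            stats, ld, prior, n_iter=n_iter, burn_in=burn_in, thin=thin,
            seed=fold_seeds[f],
        )
        g_test = genotypes.subset_samples(test)
        x_train = g_train.imputed_dosages()
        fold_scores = posterior_prs_draws(
            g_test, eff, center=x_train.mean(axis=0), scale=x_train.std(axis=0)
        )
        if draws_out is None:
            draws_out = np.empty((n, fold_scores.n_draws))
        draws_out[test] = fold_scores.draws
    return PRSDraws(draws=draws_out, samples=list(genotypes.samples), source="posterior")
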