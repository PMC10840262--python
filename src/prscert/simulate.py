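"""Synthetic case-control cohort generator with known genetic architecture.

Genotypes are biallelic SNP dosages with block LD: each haplotype is a
thresholded latent Gaussian AR(1) process within blocks (a Gaussian copula),
so genotypes are the sum of two independent haplotypes and sit exactly in
Hardy-Weinberg proportions marginally, while within-block correlation grows
with the copula parameter ``ld_rho``. Causal effects follow a spike-slab
architecture: a variant is causal with probability ``p_causal`` and causal
effects are N(0, h2 / (M * p_causal)) on the standardized-genotype scale, so
the genetic score variance is h2. Disease status is drawn from a logistic
(default) or liability-threshold model on the genetic score plus covariate
effects (age, gender, smoking), and the cohort is subsampled to an exact
case:control count, emulating a consortium case-control design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .containers import GenotypeMatrix

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class VariantSpec:
    """Number, allele-frequency range and LD structure of simulated variants."""

    n_variants: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 1
    ld_rho: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range {self.maf_range} must lie inside (0, 0.5]")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError(f"ld_rho={self.ld_rho} must lie in [0, 1)")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if self.n_variants < 1:
            raise ValueError("n_variants must be positive")


@dataclass
class TrueEffects:
    """Ground-truth per-variant effects on the liability scale."""

    beta_true: np.ndarray
    causal_mask: np.ndarray
    p_causal: float
    h2: float

    def __post_init__(self) -> None:
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        self.causal_mask = np.asarray(self.causal_mask, dtype=bool)
        if self.beta_true.shape != self.causal_mask.shape:
            raise ValueError("beta_true and causal_mask must align")
        if np.any(self.beta_true[~self.causal_mask] != 0.0):
            raise ValueError("non-causal effects must be exactly zero")


@dataclass(frozen=True)
class CovariateModel:
    """Covariate marginals and their log-OR effects on disease risk.

    Marginal defaults mimic a large lung-cancer case-control consortium:
    age ~ N(62.9, 10.6^2) years, 62% male, smoking never/former/current at
    19.3/38.2/42.4%, and pack-years log-normal among ever smokers (median
    ~25). Effect sizes (log-ORs) are generative defaults for testing, not
    epidemiological estimates; all are overridable.
    """

    age_mean: float = 62.9
    age_sd: float = 10.6
    p_male: float = 0.62
    smoking_probs: tuple[float, float, float] = (0.193, 0.382, 0.424)
    packyears_meanlog: float = 3.2
    packyears_sdlog: float = 0.8
    # log-odds-ratio effects on disease
    log_or_age_per_decade: float = 0.15
    log_or_male: float = 0.10
    log_or_former: float = 0.60
    log_or_current: float = 1.00
    log_or_packyear: float = 0.008
    link: str = "logistic"  # "logistic" | "liability"
    base_prevalence: float = 0.55

    def __post_init__(self) -> None:
        if self.link not in ("logistic", "liability"):
            raise ValueError("link must be 'logistic' or 'liability'")
        if abs(sum(self.smoking_probs) - 1.0) > 0.01:
            raise ValueError("smoking_probs must sum to 1")


@dataclass
class Cohort:
    """A simulated case-control cohort with its generative ground truth."""

    genotypes: GenotypeMatrix
    phenotype: np.ndarray  # 0/1 per individual
    covariates: pd.DataFrame  # age, gender, smoking_status, pack_years
    true_prs: np.ndarray

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=int)
        if np.isnan(self.phenotype).any() if self.phenotype.dtype.kind == "f" else False:
            raise ValueError("phenotype may not be missing")
        never = self.covariates["smoking_status"] == "never"
        if (self.covariates.loc[never, "pack_years"] != 0).any():
            raise ValueError("never smokers must have zero pack-years")

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return int((1 - self.phenotype).sum())


def _variant_table(rng: np.random.Generator, spec: VariantSpec, mafs: np.ndarray) -> pd.DataFrame:
    """Synthetic variant metadata: ids, positions, random distinct alleles."""
    m = spec.n_variants
    eff = rng.integers(0, 4, size=m)
    shift = rng.integers(1, 4, size=m)
    oth = (eff + shift) % 4
    return pd.DataFrame(
        {
            "id": [f"rs{100000 + j}" for j in range(m)],
            "chrom": "1",
            "pos": 1000 * (np.arange(m) + 1),
            "effect_allele": [_BASES[i] for i in eff],
            "other_allele": [_BASES[i] for i in oth],
            "maf": mafs,
            "block": np.arange(m) // spec.ld_block_size,
        }
    )


def simulate_genotypes(n: int, spec: VariantSpec, seed: int) -> GenotypeMatrix:
    """Simulate HWE genotype dosages with block-AR(1) copula LD.

    Two independent latent haplotype fields z ~ AR(1)(ld_rho) per block are
    thresholded at the normal quantile of each variant's allele frequency;
    the effect-allele dosage is the sum of the two indicator haplotypes, so
    each variant is marginally in exact Hardy-Weinberg proportions.

    Deterministic given ``seed``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    m = spec.n_variants
    mafs = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=m)
    thresholds = ndtri(mafs)

    haplotypes = np.empty((2, n, m))
    for h in range(2):
        z = rng.standard_normal((n, m))
        if spec.ld_rho > 0 and spec.ld_block_size > 1:
            rho = spec.ld_rho
            scale = np.sqrt(1.0 - rho * rho)
            for j in range(1, m):
                if j % spec.ld_block_size != 0:  # stays inside the block
                    z[:, j] = rho * z[:, j - 1] + scale * z[:, j]
        haplotypes[h] = z < thresholds
    dosages = haplotypes.sum(axis=0)

    variants = _variant_table(rng, spec, mafs)
    samples = [f"ind{i:06d}" for i in range(n)]
    return GenotypeMatrix(dosages=dosages, variants=variants, samples=samples)


def simulate_effects(m: int, p_causal: float, h2: float, seed: int) -> TrueEffects:
    """Draw spike-slab ground-truth effects on the standardized-genotype scale.

    Each variant is causal independently with probability ``p_causal``;
    causal effects are N(0, h2 / (m * p_causal)) so that the genetic score on
    standardized genotypes has variance ~= h2.
    """
    if not 0.0 <= p_causal <= 1.0:
        raise ValueError("p_causal must lie in [0, 1]")
    if not 0.0 <= h2 < 1.0:
        raise ValueError("h2 must lie in [0, 1)")
    if p_causal == 0.0 and h2 > 0.0:
        raise ValueError("p_causal=0 with h2>0 is unrealizable heritability")
    rng = np.random.default_rng(seed)
    mask = rng.random(m) < p_causal
    beta = np.zeros(m)
    if h2 > 0:
        slab_sd = np.sqrt(h2 / (m * p_causal))
        beta[mask] = rng.normal(0.0, slab_sd, size=int(mask.sum()))
    else:
        mask = np.zeros(m, dtype=bool)
    return TrueEffects(beta_true=beta, causal_mask=mask, p_causal=p_causal, h2=h2)


def true_prs(genotypes: GenotypeMatrix, effects: TrueEffects) -> np.ndarray:
    """Ground-truth genetic score: standardized dosages times true effects.

    Standardization uses the generating allele frequencies stored by the
    simulator (``variants['maf']``) when available.
    """
    if genotypes.m != effects.beta_true.shape[0]:
        raise ValueError("genotypes and effects are not dimension-matched")
    freqs = genotypes.variants["maf"].to_numpy() if "maf" in genotypes.variants else None
    return genotypes.standardized(freqs) @ effects.beta_true


def _draw_covariates(rng: np.random.Generator, n: int, model: CovariateModel) -> pd.DataFrame:
    age = rng.normal(model.age_mean, model.age_sd, size=n)
    gender = (rng.random(n) < model.p_male).astype(int)  # 1 = male
    probs = np.asarray(model.smoking_probs, dtype=float)
    probs = probs / probs.sum()
    smoking = rng.choice(np.array(["never", "former", "current"]), size=n, p=probs)
    pack_years = np.zeros(n)
    ever = smoking != "never"
    pack_years[ever] = rng.lognormal(
        model.packyears_meanlog, model.packyears_sdlog, size=int(ever.sum())
    )
    return pd.DataFrame(
        {"age": age, "gender": gender, "smoking_status": smoking, "pack_years": pack_years}
    )


def _linear_predictor(cov: pd.DataFrame, model: CovariateModel) -> np.ndarray:
    eta = model.log_or_age_per_decade * (cov["age"].to_numpy() - model.age_mean) / 10.0
    eta = eta + model.log_or_male * cov["gender"].to_numpy()
    smoking = cov["smoking_status"].to_numpy()
    eta = eta + model.log_or_former * (smoking == "former")
    eta = eta + model.log_or_current * (smoking == "current")
    eta = eta + model.log_or_packyear * cov["pack_years"].to_numpy()
    return eta


def simulate_cohort(
    genotypes: GenotypeMatrix,
    effects: TrueEffects,
    covariate_model: CovariateModel | None = None,
    case_control: tuple[int, int] = (1717, 1289),
    seed: int = 0,
) -> Cohort:
    """Draw disease status for a source pool and subsample an exact case:control design.

    Disease probability follows the configured link on (true genetic score +
    covariate linear predictor), with the intercept calibrated so the pool
    prevalence matches ``covariate_model.base_prevalence``. The returned
    cohort has exactly the requested case and control counts; if the pool
    yields too few of either, the error suggests a larger source pool.
    """
    model = covariate_model or CovariateModel()
    n_cases_req, n_controls_req = case_control
    if n_cases_req < 1 or n_controls_req < 1:
        raise ValueError("requested case and control counts must be positive")
    if genotypes.m != effects.beta_true.shape[0]:
        raise ValueError("genotypes and effects are not dimension-matched")

    rng = np.random.default_rng(seed)
    n_pool = genotypes.n
    cov = _draw_covariates(rng, n_pool, model)
    g = true_prs(genotypes, effects)
    eta = g + _linear_predictor(cov, model)

    if model.link == "logistic":
        # calibrate the intercept so the pool prevalence hits base_prevalence
        intercept = np.log(model.base_prevalence / (1 - model.base_prevalence)) - eta.mean()
        prob = expit(intercept + eta)
        status = (rng.random(n_pool) < prob).astype(int)
    else:  # liability threshold
        liability = eta + rng.standard_normal(n_pool)
        cutoff = np.quantile(liability, 1.0 - model.base_prevalence)
        status = (liability > cutoff).astype(int)

    case_idx = np.flatnonzero(status == 1)
    control_idx = np.flatnonzero(status == 0)
    if len(case_idx) < n_cases_req or len(control_idx) < n_controls_req:
        raise ValueError(
            f"source pool of {n_pool} yielded {len(case_idx)} cases and "
            f"{len(control_idx)} controls; requested ({n_cases_req}, "
            f"{n_controls_req}) — simulate a larger source population "
            "(e.g. increase the pool multiplier)"
        )
    keep = np.concatenate(
        [
            rng.permutation(case_idx)[:n_cases_req],
            rng.permutation(control_idx)[:n_controls_req],
        ]
    )
    keep = rng.permutation(keep)  # shuffle case/control order

    return Cohort(
        genotypes=genotypes.subset_samples(keep),
        phenotype=status[keep],
        covariates=cov.iloc[keep].reset_index(drop=True),
        true_prs=g[keep],
    )


def simulate_study(
    n_cases: int,
    n_controls: int,
    spec: VariantSpec,
    p_causal: float,
    h2: float,
    covariate_model: CovariateModel | None = None,
    pool_multiplier: float = 2.5,
    seed: int = 0,
) -> tuple[Cohort, TrueEffects]:
    """Convenience wrapper: pool genotypes -> effects -> exact-design cohort."""
    ss = np.random.SeedSequence(seed)
    s_geno, s_eff, s_cohort = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))
    n_pool = int(np.ceil((n_cases + n_controls) * pool_multiplier))
    genotypes = simulate_genotypes(n_pool, spec, seed=s_geno)
    effects = simulate_effects(spec.n_variants, p_causal, h2, seed=s_eff)
    cohort = simulate_cohort(
        genotypes, effects, covariate_model, (n_cases, n_controls), seed=s_cohort
    )
    return cohort, effects
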