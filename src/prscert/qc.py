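"""Variant-level quality control and principal-component covariates.

Filters mirror standard pre-PRS QC on imputed case-control data: genotype
call rate > 95%, minor allele frequency > 1%, and an exact Hardy-Weinberg
equilibrium test with p > 1e-10 evaluated in controls. Population structure
is captured by the top principal components of the standardized dosage
matrix (10 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import GenotypeMatrix


@dataclass(frozen=True)
class QCConfig:
    min_call_rate: float = 0.95
    min_maf: float = 0.01
    hwe_p_floor: float = 1e-10
    hwe_in_controls_only: bool = True

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "hwe_p_floor"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} must lie in (0, 1)")


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value from genotype counts.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts that are no more probable than the observed one
    (the exact conditional test; plain p, not mid-p). Monomorphic variants
    return 1.0.
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n < 1:
        raise ValueError("at least one genotyped individual is required")
    # work with the rarer allele
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0

    # feasible heterozygote counts share the parity of the rare-allele count
    het_min = n_rare % 2
    het_max = min(n_rare, 2 * n - n_rare)
    hets = np.arange(het_min, het_max + 1, 2)
    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    # log P(het | n, n_rare) up to a shared constant
    logp = (
        hets * np.log(2.0)
        - gammaln(rare_hom + 1)
        - gammaln(hets + 1)
        - gammaln(common_hom + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[np.nonzero(hets == n_Aa)[0][0]]
    return float(min(1.0, prob[prob <= obs * (1.0 + 1e-12)].sum()))


def _genotype_counts(dosage_col: np.ndarray) -> tuple[int, int, int]:
    """Hard genotype counts from (possibly fractional) dosages."""
    d = dosage_col[~np.isnan(dosage_col)]
    hard = np.clip(np.rint(d), 0, 2).astype(int)
    return (
        int((hard == 2).sum()),  # effect-allele homozygotes
        int((hard == 1).sum()),
        int((hard == 0).sum()),
    )


def qc_filter(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray | None = None,
    config: QCConfig = QCConfig(),
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply call-rate, MAF and HWE filters; return kept variants and a report.

    The report carries, per variant, the call rate, MAF, HWE p-value (in
    controls when ``hwe_in_controls_only``) and the failure reasons. An
    all-fail outcome is allowed (empty matrix, with the report explaining
    why), not an error.
    """
    if config.hwe_in_controls_only:
        if phenotype is None:
            raise ValueError("phenotype is required when hwe_in_controls_only=True")
        hwe_rows = np.asarray(phenotype) == 0
    else:
        hwe_rows = np.ones(genotypes.n, dtype=bool)

    d = genotypes.dosages
    call_rate = 1.0 - np.isnan(d).mean(axis=0)
    af = genotypes.effect_allele_freq()
    maf = np.minimum(af, 1.0 - af)
    hwe_p = np.array(
        [hwe_exact_test(*_genotype_counts(d[hwe_rows, j])) for j in range(genotypes.m)]
    )

    pass_call = call_rate > config.min_call_rate
    pass_maf = maf > config.min_maf
    pass_hwe = hwe_p > config.hwe_p_floor
    keep = pass_call & pass_maf & pass_hwe

    reasons = []
    for ok_c, ok_m, ok_h in zip(pass_call, pass_maf, pass_hwe):
        r = []
        if not ok_c:
            r.append("call_rate")
        if not ok_m:
            r.append("maf")
        if not ok_h:
            r.append("hwe")
        reasons.append(";".join(r) if r else ".")

    report = pd.DataFrame(
        {
            "id": genotypes.variants["id"],
            "call_rate": call_rate,
            "maf": maf,
            "hwe_p": hwe_p,
            "pass_call_rate": pass_call,
            "pass_maf": pass_maf,
            "pass_hwe": pass_hwe,
            "pass": keep,
            "fail_reason": reasons,
        }
    )
    return genotypes.subset_variants(np.flatnonzero(keep)), report


def compute_pcs(genotypes: GenotypeMatrix, k: int = 10) -> pd.DataFrame:
    """Top-k principal components of the standardized dosage matrix.

    Missing dosages are mean-imputed per variant before standardization.
    Components are ordered by decreasing explained variance, mutually
    orthogonal, and sign-fixed so the largest-magnitude variant loading of
    each component is positive. Returns a DataFrame ``PC1..PCk`` indexed by
    sample, with per-component explained variance fractions in
    ``df.attrs['explained_variance_ratio']``.
    """
    max_k = min(genotypes.n - 1, genotypes.m)
    if not 1 <= k <= max_k:
        raise ValueError(f"k={k} must lie in [1, min(n-1, M)] = [1, {max_k}]")
    x = genotypes.standardized()
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :k] * s[:k]
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            scores[:, j] = -scores[:, j]
            vt[j] = -vt[j]
    df = pd.DataFrame(
        scores, index=genotypes.samples, columns=[f"PC{i + 1}" for i in range(k)]
    )
    total_var = (s**2).sum()
    df.attrs["explained_variance_ratio"] = (s[:k] ** 2) / total_var if total_var > 0 else s[:k] * 0
    return df
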