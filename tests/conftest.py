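"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import prscert as pc


@pytest.fixture(scope="session")
def small_cohort():
    """Moderate cohort with real signal: 60 variants in LD blocks, h2=0.3."""
    spec = pc.VariantSpec(n_variants=60, ld_block_size=5, ld_rho=0.6)
    cohort, effects = pc.simulate_study(500, 400, spec, p_causal=0.2, h2=0.3, seed=42)
    return cohort, effects


@pytest.fixture(scope="session")
def null_cohort():
    """No genetic or covariate signal: every association is noise."""
    model = pc.CovariateModel(
        log_or_age_per_decade=0.0,
        log_or_male=0.0,
        log_or_former=0.0,
        log_or_current=0.0,
        log_or_packyear=0.0,
    )
    spec = pc.VariantSpec(n_variants=50, ld_block_size=1, ld_rho=0.0)
    cohort, effects = pc.simulate_study(
        2000, 2000, spec, p_causal=0.5, h2=0.0, covariate_model=model, seed=43
    )
    return cohort, effects


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def toy_genotypes(dosages: np.ndarray, alleles: list[tuple[str, str]] | None = None):
    """Hand-built GenotypeMatrix for micro-tests."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if alleles is None:
        alleles = [("A", "G")] * m
    variants = pd.DataFrame(
        {
            "id": [f"v{j}" for j in range(m)],
            "chrom": "1",
            "pos": np.arange(1, m + 1) * 100,
            "effect_allele": [a for a, _ in alleles],
            "other_allele": [b for _, b in alleles],
        }
    )
    return pc.GenotypeMatrix(
        dosages=dosages, variants=variants, samples=[f"s{i}" for i in range(n)]
    )
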