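"""Core in-memory containers shared across the pipeline.

A :class:`GenotypeMatrix` (individuals x variants effect-allele dosages with
variant metadata) is the scoring substrate for every PRS flavour, and a
:class:`PRSDraws` holds the per-individual *distribution* of scores — bootstrap
replicates or posterior samples — from which means, standard deviations and
empirical p-level intervals are derived.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["id", "chrom", "pos", "effect_allele", "other_allele"]


@dataclass
class GenotypeMatrix:
    """Effect-allele dosage matrix with per-variant metadata.

    Parameters
    ----------
    dosages
        ``(n_individuals, n_variants)`` float array of effect-allele copies
        in ``[0, 2]`` (fractional for imputed data); ``NaN`` marks missing.
    variants
        One row per variant; must carry at least ``id``, ``effect_allele``
        and ``other_allele``. Optional columns used downstream: ``maf`` (the
        generating allele frequency, kept by the simulator), ``block`` (LD
        block label) and ``chrom``/``pos``.
    samples
        Individual identifiers, in row order.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (individuals x variants) array")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError(
                f"{self.dosages.shape[1]} dosage columns but "
                f"{len(self.variants)} variant rows"
            )
        if self.dosages.shape[0] != len(self.samples):
            raise ValueError("sample list length does not match dosage rows")
        for col in ("id", "effect_allele", "other_allele"):
            if col not in self.variants.columns:
                raise ValueError(f"variants table lacks required column {col!r}")
        if self.variants["id"].duplicated().any():
            raise ValueError("variant identifiers must be unique")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def effect_allele_freq(self) -> np.ndarray:
        """Observed effect-allele frequency per variant (missing excluded)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def imputed_dosages(self) -> np.ndarray:
        """Dosages with missing entries mean-imputed per variant."""
        out = self.dosages.copy()
        if np.isnan(out).any():
            col_mean = np.nanmean(out, axis=0)
            idx = np.where(np.isnan(out))
            out[idx] = col_mean[idx[1]]
        return out

    def standardized(self, freqs: np.ndarray | None = None) -> np.ndarray:
        """Per-variant standardized dosages.

        With ``freqs`` given (e.g. the simulator's generating MAF), uses the
        population convention mean ``2f`` and s.d. ``sqrt(2 f (1-f))``;
        otherwise the empirical column mean and s.d. Missing entries are
        mean-imputed (hence exactly zero after centering).
        """
        x = self.imputed_dosages()
        if freqs is not None:
            freqs = np.asarray(freqs, dtype=float)
            mu = 2.0 * freqs
            sd = np.sqrt(2.0 * freqs * (1.0 - freqs))
        else:
            mu = x.mean(axis=0)
            sd = x.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return (x - mu) / sd

    def subset_variants(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            variants=self.variants.iloc[index].reset_index(drop=True),
            samples=list(self.samples),
        )

    def subset_samples(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[index, :],
            variants=self.variants.copy(),
            samples=[self.samples[i] for i in index],
        )

    def variant_indexer(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.variants["id"])}


def summarize_draws(
    draws: np.ndarray, p: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Mean, s.d. and empirical p-level interval of score draws.

    The interval is the empirical ``(1-p)/2`` and ``(1+p)/2`` quantiles with
    the linear-interpolation convention; ``p = 0`` degenerates to the median
    and ``p = 1`` to ``(min, max)``.

    Parameters
    ----------
    draws
        ``(n_individuals, n_draws)`` (or 1-D for a single individual).
    p
        Confidence/credible level in ``[0, 1]``.

    Returns
    -------
    mean, sd, lower, upper : arrays of length ``n_individuals``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"confidence/credible level p={p} outside [0, 1]")
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    if draws.shape[1] < 1:
        raise ValueError("at least one draw is required")
    mean = draws.mean(axis=1)
    sd = draws.std(axis=1, ddof=1) if draws.shape[1] > 1 else np.zeros(draws.shape[0])
    lo_q, hi_q = (1.0 - p) / 2.0, (1.0 + p) / 2.0
    lower = np.quantile(draws, lo_q, axis=1, method="linear")
    upper = np.quantile(draws, hi_q, axis=1, method="linear")
    return mean, sd, lower, upper


@dataclass
class PRSDraws:
    """Per-individual PRS distribution (bootstrap replicates or posterior samples)."""

    draws: np.ndarray  # (n_individuals, n_draws)
    samples: list[str]
    source: str = "bootstrap"  # "bootstrap" | "posterior" | "fixed"

    def __post_init__(self) -> None:
        self.draws = np.atleast_2d(np.asarray(self.draws, dtype=float))
        if self.draws.shape[0] != len(self.samples):
            raise ValueError("draws rows do not match sample list")
        if not np.isfinite(self.draws).all():
            raise ValueError("draws must be finite")

    @property
    def n(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def means(self) -> np.ndarray:
        return self.draws.mean(axis=1)

    def medians(self) -> np.ndarray:
        return np.median(self.draws, axis=1)

    def summarize(self, p: float = 0.95) -> pd.DataFrame:
        """Per-individual mean, s.d. and p-level interval as a table."""
        mean, sd, lower, upper = summarize_draws(self.draws, p)
        return pd.DataFrame(
            {
                "sample_id": self.samples,
                "mean": mean,
                "sd": sd,
                "ci_lower": lower,
                "ci_upper": upper,
            }
        )

    def zscored(self) -> "PRSDraws":
        """Draws rescaled so the per-individual means have zero mean, unit s.d.

        The same affine map is applied to every draw, so ranks, intervals and
        classifications are preserved; useful to compare uncertainty across
        estimators whose raw scales differ.
        """
        m = self.means()
        mu, sd = m.mean(), m.std(ddof=1)
        if sd == 0:
            raise ValueError("cannot z-score a degenerate score distribution")
        return replace(self, draws=(self.draws - mu) / sd)


@dataclass(frozen=True)
class ThresholdSpec:
    """A population percentile threshold with its confidence/credible level.

    ``t`` is the population percentile in (0, 100); ``side`` says whether the
    certain region lies above (``"upper"``) or below (``"lower"``) it; ``p``
    is the interval level used for the certainty rule.
    """

    t: float
    side: str = "upper"
    p: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 < self.t < 100.0:
            raise ValueError(f"percentile t={self.t} must lie strictly inside (0, 100)")
        if self.side not in ("upper", "lower"):
            raise ValueError("side must be 'upper' or 'lower'")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"level p={self.p} outside [0, 1]")
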