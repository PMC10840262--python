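"""Certainty-aware risk stratification from individual PRS distributions.

The classification rule: fix a population percentile threshold ``t`` (taken
over the distribution of per-individual PRS *means*) and an interval level
``p``. An individual is *certainly high* genetic risk when their entire
p-level interval lies above the upper threshold, *certainly low* when it
lies entirely below the lower threshold, and *uncertain* when the interval
covers a threshold. The module also reports decile certainty (whole interval
inside one decile of the mean distribution), percentile-rank distributions
of the draws, cross-estimator concordance tables, and the certainty
proportion as a function of ``p``.

Conventions, fixed because interval endpoints feed hard decisions:
empirical percentiles use linear interpolation between order statistics
(shared with the interval construction); "above"/"below" a threshold is
strict, so a tie at the threshold is uncertain; deciles are left-closed /
right-open on means, top decile right-closed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import PRSDraws, ThresholdSpec, summarize_draws

LABELS = ("certainly_low", "uncertain", "certainly_high")


def population_threshold(means: np.ndarray, t: float) -> float:
    """Empirical t-th percentile of the per-individual PRS means."""
    means = np.asarray(means, dtype=float)
    if means.size < 2:
        raise ValueError("at least two individuals are required")
    return float(np.percentile(means, t, method="linear"))


@dataclass
class RiskClassification:
    """Per-individual certainty labels plus the thresholds that produced them."""

    table: pd.DataFrame  # sample_id, label, mean_label
    threshold_low: float
    threshold_high: float
    p: float
    estimator: str = ""

    def counts(self) -> pd.Series:
        return self.table["label"].value_counts().reindex(LABELS, fill_value=0)


def classify_certainty(
    draws: PRSDraws,
    spec_low: ThresholdSpec,
    spec_high: ThresholdSpec,
    point: str = "mean",
) -> RiskClassification:
    """Classify individuals as certainly high / certainly low / uncertain.

    ``spec_low`` and ``spec_high`` must share the interval level ``p``.
    Alongside the interval-based label, a point-estimate label (``mean`` or
    ``median`` of the draws vs the same thresholds; ``high``/``low``/
    ``middle``) is emitted for comparison.
    """
    if spec_low.p != spec_high.p:
        raise ValueError(
            f"threshold specs disagree on the interval level: {spec_low.p} vs {spec_high.p}"
        )
    if spec_low.side != "lower" or spec_high.side != "upper":
        raise ValueError("expected spec_low.side='lower' and spec_high.side='upper'")
    p = spec_low.p
    means = draws.means()
    thr_low = population_threshold(means, spec_low.t)
    thr_high = population_threshold(means, spec_high.t)

    _, _, lower, upper = summarize_draws(draws.draws, p)
    label = np.where(
        lower > thr_high,
        "certainly_high",
        np.where(upper < thr_low, "certainly_low", "uncertain"),
    )

    pt = means if point == "mean" else draws.medians()
    mean_label = np.where(pt > thr_high, "high", np.where(pt < thr_low, "low", "middle"))

    table = pd.DataFrame(
        {"sample_id": draws.samples, "label": label, "mean_label": mean_label}
    )
    return RiskClassification(
        table=table,
        threshold_low=thr_low,
        threshold_high=thr_high,
        p=p,
        estimator=draws.source,
    )


def decile_assignment(means: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Decile index (0..9) per individual and the 11 decile boundary values.

    Boundaries are empirical percentiles 0,10,...,100 of the means; deciles
    are left-closed/right-open with the top decile right-closed.
    """
    means = np.asarray(means, dtype=float)
    bounds = np.percentile(means, np.arange(0, 101, 10), method="linear")
    decile = np.clip(np.searchsorted(bounds[1:-1], means, side="right"), 0, 9)
    return decile, bounds


def decile_certainty(draws: PRSDraws, p: float = 0.95) -> pd.DataFrame:
    """Individuals whose whole p-level interval sits inside their mean's decile.

    The lowest decile requires interval upper < the 10th-percentile bound,
    the highest requires interval lower > the 90th-percentile bound, and
    interior deciles require containment on both sides. Returns one row per
    decile: size, number certain, and the decile bounds.
    """
    if draws.n < 10:
        raise ValueError("decile certainty needs at least 10 individuals")
    means = draws.means()
    decile, bounds = decile_assignment(means)
    _, _, lower, upper = summarize_draws(draws.draws, p)

    certain = np.zeros(draws.n, dtype=bool)
    low = decile == 0
    high = decile == 9
    mid = ~(low | high)
    certain[low] = upper[low] < bounds[1]
    certain[high] = lower[high] > bounds[9]
    certain[mid] = (lower[mid] >= bounds[decile[mid]]) & (
        upper[mid] <= bounds[decile[mid] + 1]
    )

    rows = []
    for d in range(10):
        members = decile == d
        rows.append(
            {
                "decile": d + 1,
                "lower_bound": bounds[d],
                "upper_bound": bounds[d + 1],
                "n": int(members.sum()),
                "n_certain": int(certain[members].sum()),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["certain_mask"] = certain
    out.attrs["decile_assignment"] = decile
    return out


def _percentile_ranks(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Midrank percentile of each value against the reference distribution.

    rank = 100 * (count(reference < v) + 0.5 * count(reference == v)) / N.
    """
    ref = np.sort(np.asarray(reference, dtype=float))
    below = np.searchsorted(ref, values, side="left")
    upto = np.searchsorted(ref, values, side="right")
    return 100.0 * (below + 0.5 * (upto - below)) / ref.size


def rank_distribution(
    draws: PRSDraws, reference: str = "means"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percentile-rank distribution of each individual's draws.

    Every draw is ranked against the population reference distribution —
    the per-individual PRS means by default (``reference='pooled'`` ranks
    against all draws pooled instead). Returns a per-individual table
    (mean/min/max rank, decile of the mean) and a per-decile summary
    (mean of mean ranks, min and max rank observed in the decile).
    """
    means = draws.means()
    ref = means if reference == "means" else draws.draws.ravel()
    ranks = _percentile_ranks(draws.draws.ravel(), ref).reshape(draws.draws.shape)
    decile, _ = decile_assignment(means)
    per_ind = pd.DataFrame(
        {
            "sample_id": draws.samples,
            "decile": decile + 1,
            "mean_rank": ranks.mean(axis=1),
            "min_rank": ranks.min(axis=1),
            "max_rank": ranks.max(axis=1),
        }
    )
    per_decile = (
        per_ind.groupby("decile")
        .agg(
            n=("sample_id", "size"),
            mean_rank=("mean_rank", "mean"),
            min_rank=("min_rank", "min"),
            max_rank=("max_rank", "max"),
        )
        .reset_index()
    )
    return per_ind, per_decile


def concordance(
    means_a: np.ndarray | PRSDraws,
    means_b: np.ndarray | PRSDraws,
    thresholds: list[float] = (60, 70, 80, 90, 95),
    labels: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Overlap of individuals classified above each percentile threshold by two estimators.

    For each threshold t, counts individuals whose PRS mean strictly exceeds
    the t-th percentile under *both* estimators; the percentage is taken
    relative to the nominal above-threshold group size N * (100 - t) / 100.
    """
    a = means_a.means() if isinstance(means_a, PRSDraws) else np.asarray(means_a, float)
    b = means_b.means() if isinstance(means_b, PRSDraws) else np.asarray(means_b, float)
    if a.shape != b.shape:
        raise ValueError("the two estimators must cover the same cohort")
    n = a.size
    rows = []
    for t in thresholds:
        above_a = a > population_threshold(a, t)
        above_b = b > population_threshold(b, t)
        count = int((above_a & above_b).sum())
        expected = n * (100.0 - t) / 100.0
        rows.append(
            {
                "threshold": t,
                "estimators": f"{labels[0]} vs {labels[1]}",
                "n_overlap": count,
                "pct_overlap": 100.0 * count / expected,
            }
        )
    return pd.DataFrame(rows)


def certainty_curve(
    draws: PRSDraws,
    spec: ThresholdSpec,
    p_grid: np.ndarray | list[float],
) -> pd.DataFrame:
    """Proportion of individuals certain beyond the threshold, per interval level.

    For each p in the grid the intervals are recomputed and the certain
    proportion measured; by the nesting of empirical quantile intervals the
    curve is monotone non-increasing in p.
    """
    p_grid = np.asarray(p_grid, dtype=float)
    if np.any((p_grid < 0) | (p_grid > 1)):
        raise ValueError("p_grid values must lie in [0, 1]")
    means = draws.means()
    thr = population_threshold(means, spec.t)
    rows = []
    for p in p_grid:
        _, _, lower, upper = summarize_draws(draws.draws, p)
        if spec.side == "upper":
            certain = lower > thr
        else:
            certain = upper < thr
        rows.append({"p": p, "proportion_certain": certain.mean()})
    return pd.DataFrame(rows)
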