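"""Certainty classification, decile certainty, ranks, concordance, sensitivity."""

import numpy as np
import pytest

import prscert as pc


def draws_from_means(means, width=0.0, n_draws=1, seed=0):
    """PRSDraws with controlled per-individual spread around given means."""
    means = np.asarray(means, dtype=float)
    rng = np.random.default_rng(seed)
    if width == 0.0:
        draws = np.tile(means[:, None], (1, n_draws))
    else:
        draws = means[:, None] + rng.normal(0, width, (means.size, n_draws))
    return pc.PRSDraws(draws=draws, samples=[f"s{i}" for i in range(means.size)])


@pytest.fixture(scope="module")
def noisy_draws():
    rng = np.random.default_rng(31)
    means = rng.normal(0, 1, 400)
    draws = means[:, None] + rng.normal(0, 0.4, (400, 200))
    return pc.PRSDraws(draws=draws, samples=[f"s{i}" for i in range(400)])


class TestPopulationThreshold:
    def test_interpolated_percentile(self):
        means = np.arange(1, 101, dtype=float)
        assert pc.population_threshold(means, 90) == pytest.approx(90.1)

    def test_median_at_fifty(self, rng):
        means = rng.normal(size=501)
        assert pc.population_threshold(means, 50) == pytest.approx(np.median(means))

    def test_constant_means(self):
        assert pc.population_threshold(np.full(20, 3.3), 77) == pytest.approx(3.3)


class TestClassifyCertainty:
    def test_strict_dominance_rule(self):
        # 100 individuals spread 1..100; individual intervals are tight except two
        means = np.arange(1.0, 101.0)
        draws = draws_from_means(means, n_draws=3)
        # make the top individual clearly above the 90th-percentile threshold
        cls = pc.classify_certainty(
            draws,
            pc.ThresholdSpec(10, "lower", p=0.95),
            pc.ThresholdSpec(90, "upper", p=0.95),
        )
        thr_high = cls.threshold_high
        labels = cls.table["label"].to_numpy()
        assert (labels[means > thr_high] == "certainly_high").all()
        assert (labels[means < cls.threshold_low] == "certainly_low").all()
        # an interval covering the threshold is uncertain
        straddle = draws.draws.copy()
        straddle[95] = [thr_high - 0.5, thr_high + 0.5, thr_high]
        cls2 = pc.classify_certainty(
            pc.PRSDraws(draws=straddle, samples=draws.samples),
            pc.ThresholdSpec(10, "lower", p=0.95),
            pc.ThresholdSpec(90, "upper", p=0.95),
        )
        assert cls2.table.loc[95, "label"] == "uncertain"

    def test_degenerate_level_reproduces_point_classification(self, noisy_draws):
        cls = pc.classify_certainty(
            noisy_draws,
            pc.ThresholdSpec(10, "lower", p=0.0),
            pc.ThresholdSpec(90, "upper", p=0.0),
            point="median",
        )
        mapping = {"high": "certainly_high", "low": "certainly_low", "middle": "uncertain"}
        expected = cls.table["mean_label"].map(mapping)
        assert (cls.table["label"] == expected).all()

    def test_mismatched_levels_rejected(self, noisy_draws):
        with pytest.raises(ValueError, match="level"):
            pc.classify_certainty(
                noisy_draws,
                pc.ThresholdSpec(10, "lower", p=0.9),
                pc.ThresholdSpec(90, "upper", p=0.95),
            )

    def test_labels_partition_cohort(self, noisy_draws):
        cls = pc.classify_certainty(
            noisy_draws,
            pc.ThresholdSpec(10, "lower", p=0.95),
            pc.ThresholdSpec(90, "upper", p=0.95),
        )
        assert cls.counts().sum() == noisy_draws.n

    def test_invariant_under_increasing_affine_transform(self, noisy_draws):
        """Rescaling all draws (hence thresholds) jointly preserves certainty sets."""
        cls = pc.classify_certainty(
            noisy_draws,
            pc.ThresholdSpec(10, "lower", p=0.9),
            pc.ThresholdSpec(90, "upper", p=0.9),
        )
        transformed = pc.PRSDraws(
            draws=2.5 * noisy_draws.draws + 1.0, samples=noisy_draws.samples
        )
        cls_t = pc.classify_certainty(
            transformed,
            pc.ThresholdSpec(10, "lower", p=0.9),
            pc.ThresholdSpec(90, "upper", p=0.9),
        )
        assert (cls.table["label"] == cls_t.table["label"]).all()


class TestDecileCertainty:
    def test_zero_width_intervals_fill_every_decile(self, rng):
        means = rng.normal(size=200)
        draws = draws_from_means(means)
        table = pc.decile_certainty(draws, p=0.95)
        assert (table["n_certain"] == table["n"]).all()
        assert table["n"].sum() == 200

    def test_dominating_width_leaves_no_certain_individuals(self, rng):
        means = rng.normal(size=100)
        span = means.max() - means.min()
        draws = draws_from_means(means, width=5 * span, n_draws=100, seed=1)
        table = pc.decile_certainty(draws, p=0.95)
        assert (table["n_certain"] == 0).all()

    def test_equal_decile_sizes_with_distinct_means(self):
        rng = np.random.default_rng(32)
        means = rng.normal(size=30060)
        draws = draws_from_means(means)
        table = pc.decile_certainty(draws, p=0.95)
        assert (table["n"] == 3006).all()

    def test_certain_counts_bounded_by_decile_sizes(self, noisy_draws):
        table = pc.decile_certainty(noisy_draws, p=0.9)
        assert (table["n_certain"] <= table["n"]).all()
        assert table["n_certain"].sum() <= noisy_draws.n


class TestRankDistribution:
    def test_rank_matches_brute_force_midrank(self, rng):
        means = rng.normal(size=50)
        draws = means[:, None] + rng.normal(0, 0.3, (50, 7))
        prs = pc.PRSDraws(draws=draws, samples=[f"s{i}" for i in range(50)])
        per_ind, _ = pc.rank_distribution(prs)
        ref = prs.means()
        for i in range(50):
            ranks = []
            for d in range(7):
                v = draws[i, d]
                below = sum(1 for r in ref if r < v)
                ties = sum(1 for r in ref if r == v)
                ranks.append(100.0 * (below + 0.5 * ties) / 50)
            assert per_ind.loc[i, "mean_rank"] == pytest.approx(np.mean(ranks))
            assert per_ind.loc[i, "min_rank"] == pytest.approx(min(ranks))
            assert per_ind.loc[i, "max_rank"] == pytest.approx(max(ranks))

    def test_zero_width_draws_collapse_rank_ranges(self, rng):
        means = rng.normal(size=100)
        prs = draws_from_means(means, n_draws=5)
        per_ind, per_decile = pc.rank_distribution(prs)
        assert np.allclose(per_ind["min_rank"], per_ind["max_rank"])
        assert len(per_decile) == 10

    def test_far_apart_individuals_rank_at_extremes(self):
        prs = pc.PRSDraws(
            draws=np.array([[-10.0, -10.1], [10.0, 10.1]]), samples=["a", "b"]
        )
        per_ind, _ = pc.rank_distribution(prs)
        assert per_ind.loc[0, "max_rank"] <= 50
        assert per_ind.loc[1, "min_rank"] >= 50
        assert per_ind.loc[0, "mean_rank"] < per_ind.loc[1, "mean_rank"]

    def test_ranks_bounded(self, noisy_draws):
        per_ind, _ = pc.rank_distribution(noisy_draws)
        assert (per_ind["min_rank"] >= 0).all() and (per_ind["max_rank"] <= 100).all()
        assert (per_ind["min_rank"] <= per_ind["mean_rank"]).all()
        assert (per_ind["mean_rank"] <= per_ind["max_rank"]).all()


class TestConcordance:
    def test_identical_estimators_fully_concordant(self, rng):
        means = rng.normal(size=1000)
        table = pc.concordance(means, means)
        assert np.allclose(table["pct_overlap"], 100.0)

    def test_anticorrelated_estimators_do_not_overlap(self):
        means = np.arange(1000, dtype=float)
        table = pc.concordance(means, -means, thresholds=[90])
        assert table["n_overlap"][0] == 0

    def test_percentage_uses_nominal_group_size(self):
        # 2470 of the nominal 3006-strong top decile at N=30,060 is 82%
        n = 30060
        rng = np.random.default_rng(33)
        a = rng.normal(size=n)
        table = pc.concordance(a, a, thresholds=[90])
        assert table["n_overlap"][0] == 3006
        assert table["pct_overlap"][0] == pytest.approx(100.0)


class TestCertaintyCurve:
    def test_monotone_non_increasing_in_p(self, noisy_draws):
        grid = np.linspace(0, 1, 21)
        curve = pc.certainty_curve(
            noisy_draws, pc.ThresholdSpec(90, "upper", p=0.95), grid
        )
        assert np.all(np.diff(curve["proportion_certain"]) <= 1e-12)

    def test_degenerate_level_recovers_group_fraction(self, rng):
        means = rng.normal(size=2000)
        prs = draws_from_means(means, n_draws=11)
        curve = pc.certainty_curve(prs, pc.ThresholdSpec(90, "upper", p=0.95), [0.0])
        assert curve["proportion_certain"][0] == pytest.approx(0.10, abs=0.01)

    def test_full_level_with_covering_draws_gives_zero(self, rng):
        means = rng.normal(size=200)
        span = means.max() - means.min()
        prs = draws_from_means(means, width=10 * span, n_draws=50, seed=2)
        curve = pc.certainty_curve(prs, pc.ThresholdSpec(90, "upper", p=0.95), [1.0])
        assert curve["proportion_certain"][0] == 0.0
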