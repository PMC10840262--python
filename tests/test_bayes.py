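"""Spike-slab Gibbs sampler: summary stats, LD, conjugate oracle, recovery."""

import numpy as np
import pytest
from scipy.special import expit

import prscert as pc
from tests.conftest import toy_genotypes


class TestMarginalStats:
    def test_matches_brute_force_inner_product(self, small_cohort):
        cohort, _ = small_cohort
        g = cohort.genotypes.subset_variants(np.arange(10))
        stats = pc.marginal_stats(g, cohort.phenotype, cohort.covariates)
        # independent recomputation: residualize, standardize, loop
        from prscert._utils import design_matrix

        y = cohort.phenotype.astype(float)
        c = np.hstack([np.ones((g.n, 1)), design_matrix(cohort.covariates)])
        y = y - c @ np.linalg.lstsq(c, y, rcond=None)[0]
        y = y / y.std()
        x = g.imputed_dosages()
        x = (x - x.mean(0)) / x.std(0)
        for j in range(g.m):
            brute = sum(x[i, j] * y[i] for i in range(g.n)) / g.n
            assert stats.beta_hat[j] == pytest.approx(brute, abs=1e-10)

    def test_null_phenotype_z_scores_calibrated(self):
        g = pc.simulate_genotypes(
            2000, pc.VariantSpec(n_variants=500, maf_range=(0.1, 0.5)), seed=21
        )
        rng = np.random.default_rng(22)
        y = rng.integers(0, 2, g.n)
        stats = pc.marginal_stats(g, y)
        frac = np.mean(np.abs(stats.beta_hat / stats.se) > 1.96)
        assert 0.02 <= frac <= 0.09

    def test_causal_variant_sign_recovered(self):
        rng = np.random.default_rng(23)
        g = pc.simulate_genotypes(
            3000, pc.VariantSpec(n_variants=3, maf_range=(0.3, 0.5)), seed=23
        )
        eta = 0.6 * g.dosages[:, 0]
        y = (rng.random(g.n) < expit(eta - eta.mean())).astype(int)
        stats = pc.marginal_stats(g, y)
        assert stats.beta_hat[0] > 0
        assert abs(stats.beta_hat[0]) > 3 * stats.se[0]

    def test_constant_variant_dropped_with_warning(self):
        dosages = np.column_stack([np.ones(20), np.arange(20) % 3])
        g = toy_genotypes(dosages.astype(float))
        y = np.arange(20) % 2
        with pytest.warns(UserWarning, match="constant"):
            stats = pc.marginal_stats(g, y)
        assert stats.m == 1


class TestLDMatrix:
    def test_independent_variants_near_zero_offdiagonal(self):
        g = pc.simulate_genotypes(
            2000, pc.VariantSpec(n_variants=10, ld_rho=0.0), seed=24
        )
        ld = pc.ld_matrix(g, blocks=[np.arange(10)])
        off = ld.matrices[0] - np.diag(np.diag(ld.matrices[0]))
        assert np.abs(off).max() < 0.1

    def test_duplicated_column_perfectly_correlated(self):
        col = np.array([0.0, 1.0, 2.0, 1.0, 0.0, 2.0] * 5)
        g = toy_genotypes(np.column_stack([col, col]))
        ld = pc.ld_matrix(g, blocks=[np.arange(2)], epsilon=0.05)
        assert ld.matrices[0][0, 1] == pytest.approx(1.0)

    def test_singular_block_without_ridge_is_error(self):
        col = np.array([0.0, 1.0, 2.0, 1.0] * 5)
        g = toy_genotypes(np.column_stack([col, col]))
        with pytest.raises(ValueError, match="epsilon"):
            pc.ld_matrix(g, blocks=[np.arange(2)], epsilon=0.0)

    def test_ar1_block_correlation_matches_measured(self):
        spec = pc.VariantSpec(n_variants=10, ld_block_size=5, ld_rho=0.8)
        g = pc.simulate_genotypes(3000, spec, seed=25)
        ld = pc.ld_matrix(g)
        measured = np.corrcoef(g.standardized(), rowvar=False)
        for b, idx in enumerate(ld.blocks):
            for k in range(len(idx) - 1):
                assert ld.matrices[b][k, k + 1] == pytest.approx(
                    measured[idx[k], idx[k + 1]], abs=0.1
                )

    def test_blocks_must_partition(self):
        g = toy_genotypes(np.zeros((4, 3)) + np.arange(3) % 3)
        with pytest.raises(ValueError, match="partition"):
            pc.ld_matrix(g, blocks=[np.array([0, 1])])


def identity_ld(m: int, epsilon: float = 0.0) -> pc.LDMatrix:
    return pc.LDMatrix(
        blocks=[np.array([j]) for j in range(m)],
        matrices=[np.array([[1.0 + epsilon]]) for _ in range(m)],
        epsilon=epsilon,
    )


class TestGibbsSampler:
    def test_matches_conjugate_shrinkage_closed_form(self):
        """Identity LD, p_causal=1: each coordinate is conjugate normal-normal."""
        m, n = 50, 2000
        h2 = 0.3
        rng = np.random.default_rng(26)
        beta_hat = rng.normal(0, np.sqrt(h2 / m + 1 / n), size=m)
        stats = pc.SummaryStats(beta_hat=beta_hat, se=np.full(m, 1 / np.sqrt(n)), n=n)
        prior = pc.SpikeSlabPrior(p_causal=1.0, h2=h2, m=m)
        draws = pc.gibbs_sample_effects(
            stats, identity_ld(m), prior, n_iter=700, burn_in=200, seed=27
        )
        sigma_b2 = h2 / m
        shrink = n * sigma_b2 / (n * sigma_b2 + 1.0)
        expected_mean = beta_hat * shrink
        post_var = 1.0 / (n + 1.0 / sigma_b2)
        mc_se = np.sqrt(post_var / draws.draws.shape[0])
        err = np.abs(draws.draws.mean(axis=0) - expected_mean)
        assert np.all(err <= 3.0 * mc_se)
        # posterior spread also matches the conjugate variance on average
        assert draws.draws.var(axis=0).mean() == pytest.approx(post_var, rel=0.2)

    def test_prior_collapse_at_zero_heritability(self):
        m = 10
        stats = pc.SummaryStats(
            beta_hat=np.full(m, 0.1), se=np.full(m, 0.02), n=1000
        )
        prior = pc.SpikeSlabPrior(p_causal=0.5, h2=0.0, m=m)
        draws = pc.gibbs_sample_effects(stats, identity_ld(m), prior, seed=1)
        assert np.all(draws.draws == 0.0)

    def test_null_stats_rarely_included_sparse_prior(self):
        """With beta_hat identically 0 the inclusion rate follows the analytic value."""
        m, n = 200, 2000
        p_causal, h2 = 0.01, 0.1
        stats = pc.SummaryStats(
            beta_hat=np.zeros(m), se=np.full(m, 1 / np.sqrt(n)), n=n
        )
        prior = pc.SpikeSlabPrior(p_causal=p_causal, h2=h2, m=m)
        draws = pc.gibbs_sample_effects(
            stats, identity_ld(m), prior, n_iter=400, burn_in=100, seed=28
        )
        slab_var = h2 / (m * p_causal)
        post_var = 1.0 / (n + 1.0 / slab_var)
        log_odds = np.log(p_causal / (1 - p_causal)) + 0.5 * np.log(post_var / slab_var)
        analytic = 1.0 / (1.0 + np.exp(-log_odds))
        inclusion = np.mean(draws.draws != 0.0)
        assert inclusion == pytest.approx(analytic, rel=0.5, abs=0.005)
        assert np.abs(draws.draws).mean() < np.sqrt(slab_var)

    def test_deterministic_given_seed(self):
        stats = pc.SummaryStats(beta_hat=np.full(5, 0.05), se=np.full(5, 0.02), n=1000)
        prior = pc.SpikeSlabPrior(p_causal=0.5, h2=0.2, m=5)
        a = pc.gibbs_sample_effects(stats, identity_ld(5), prior, n_iter=50, burn_in=10, seed=3)
        b = pc.gibbs_sample_effects(stats, identity_ld(5), prior, n_iter=50, burn_in=10, seed=3)
        assert np.array_equal(a.draws, b.draws)

    def test_shrinkage_improves_effect_recovery(self):
        """Posterior means beat raw marginals, and posterior-mean PRS tracks truth."""
        spec = pc.VariantSpec(n_variants=500, ld_block_size=5, ld_rho=0.5)
        cohort, effects = pc.simulate_study(2284, 1716, spec, 0.05, 0.3, seed=29)
        g = cohort.genotypes
        stats = pc.marginal_stats(g, cohort.phenotype, cohort.covariates)
        ld = pc.ld_matrix(g)
        prior = pc.SpikeSlabPrior(p_causal=0.05, h2=0.3, m=g.m)
        draws = pc.gibbs_sample_effects(stats, ld, prior, n_iter=400, burn_in=150, seed=30)
        post_mean = draws.draws.mean(axis=0)
        r_post = np.corrcoef(post_mean, effects.beta_true)[0, 1]
        r_marg = np.corrcoef(stats.beta_hat, effects.beta_true)[0, 1]
        assert r_post > r_marg
        prs = pc.posterior_prs_draws(g, draws)
        assert np.corrcoef(prs.means(), cohort.true_prs)[0, 1] > 0.4


class TestSelectPrior:
    def test_returns_grid_member_and_is_deterministic(self, small_cohort):
        cohort, _ = small_cohort
        grid_h2, grid_p = (0.1, 0.3), (0.1, 1.0)
        a = pc.select_prior(
            cohort.genotypes, cohort.phenotype, cohort.covariates,
            h2_grid=grid_h2, p_causal_grid=grid_p,
            n_iter=120, burn_in=40, seed=9,
        )
        b = pc.select_prior(
            cohort.genotypes, cohort.phenotype, cohort.covariates,
            h2_grid=grid_h2, p_causal_grid=grid_p,
            n_iter=120, burn_in=40, seed=9,
        )
        assert (a.h2, a.p_causal) == (b.h2, b.p_causal)
        assert a.h2 in grid_h2 and a.p_causal in grid_p
        assert a.m == cohort.genotypes.m


class TestPosteriorPRSDraws:
    def test_single_draw_is_degenerate(self):
        g = toy_genotypes(np.array([[0.0, 2.0], [1.0, 1.0]]))
        eff = pc.PosteriorEffectDraws(draws=np.array([[0.1, -0.2]]), burn_in=0, thin=1, seed=0)
        prs = pc.posterior_prs_draws(g, eff)
        assert np.all(prs.summarize(0.95)["sd"] == 0.0)

    def test_equal_effect_draws_give_zero_width_intervals(self):
        g = toy_genotypes(np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]]))
        eff = pc.PosteriorEffectDraws(
            draws=np.tile([[0.3, 0.1]], (20, 1)), burn_in=0, thin=1, seed=0
        )
        summ = pc.posterior_prs_draws(g, eff).summarize(0.95)
        assert np.allclose(summ["ci_upper"] - summ["ci_lower"], 0.0)

    def test_matches_double_loop(self, rng):
        dosages = rng.integers(0, 3, (10, 5)).astype(float)
        g = toy_genotypes(dosages)
        eff_draws = rng.normal(0, 0.1, (20, 5))
        eff = pc.PosteriorEffectDraws(draws=eff_draws, burn_in=0, thin=1, seed=0)
        prs = pc.posterior_prs_draws(g, eff)
        x = g.standardized()
        brute = np.array(
            [
                [sum(x[i, j] * eff_draws[d, j] for j in range(5)) for d in range(20)]
                for i in range(10)
            ]
        )
        assert np.allclose(prs.draws, brute, atol=1e-12)
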