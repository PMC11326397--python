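"""Gibbs sampler: conditionals, bookkeeping, oracle agreement, pruning, annotations."""

import numpy as np
import pytest

from gwfm.ldmatrix import build_pseudo_data, eigendecompose_block, empirical_correlation
from gwfm.pipeline import blocks_from_genotypes
from gwfm.sampler import (
    AnnotationSet,
    ConfigError,
    GibbsModel,
    McmcConfig,
    MixtureSpec,
    auto_prune_components,
    exact_posterior_small,
    gibbs_sweep,
    run_mcmc,
    snp_component_probs,
)


def _toy_block(b_std, n, frac=1.0):
    m = len(b_std)
    return build_pseudo_data(np.asarray(b_std, float), n, eigendecompose_block(np.eye(m), frac))


class TestSnpComponentProbs:
    def test_all_null_prior_forces_null(self):
        spec = MixtureSpec.sbayesc()
        cond = snp_component_probs(2.0, 1000, 1.0, 0.01, np.array([1.0, 0.0]), spec)
        np.testing.assert_allclose(cond.comp_prob, [1.0, 0.0])

    def test_r_zero_favors_null_for_small_gamma(self):
        spec = MixtureSpec.sbayesrc()
        pi = np.full(5, 0.2)
        cond = snp_component_probs(0.0, 10_000, 1.0, 0.1, pi, spec)
        assert cond.comp_prob.sum() == pytest.approx(1.0)
        # with no signal the null dominates every non-null component
        assert cond.comp_prob[0] == max(cond.comp_prob)
        # r = 0 kills the exp term: weights decrease with component variance
        assert np.all(np.diff(cond.comp_prob[1:]) < 0)

    def test_single_snp_closed_form_oracle(self):
        """K=2, m=1: membership probability equals the exact Bernoulli posterior."""
        n, pi, sb2, se2 = 5000.0, 0.2, 1e-3, 1.0
        b_std = 0.015
        r = n * b_std
        spec = MixtureSpec.sbayesc()
        cond = snp_component_probs(r, n, se2, sb2, np.array([1 - pi, pi]), spec)
        # direct Bayes: w ~ N(0, se2) under null, N(0, se2 + n*sb2) under slab
        # (w = sqrt(n) b_std for a single SNP with unit LD)
        w = np.sqrt(n) * b_std
        from scipy.stats import norm

        l0 = norm.pdf(w, 0, np.sqrt(se2))
        l1 = norm.pdf(w, 0, np.sqrt(se2 + n * sb2))
        post = pi * l1 / (pi * l1 + (1 - pi) * l0)
        assert cond.comp_prob[1] == pytest.approx(post, abs=1e-10)

    def test_nan_input_rejected(self):
        with pytest.raises(ValueError):
            snp_component_probs(np.nan, 100, 1.0, 0.1, np.array([0.9, 0.1]), MixtureSpec.sbayesc())


class TestGibbsSweep:
    def test_residual_bookkeeping_identity(self, rng):
        """Incrementally maintained residuals equal the from-scratch recomputation."""
        n, m = 2000, 30
        X = rng.standard_normal((n, m)) + 0.5 * rng.standard_normal((n, 1))
        y = X[:, 5] * 0.1 + rng.standard_normal(n)
        Xs = (X - X.mean(0)) / X.std(0)
        ys = (y - y.mean()) / y.std()
        b_std = Xs.T @ ys / n
        bases, blocks = blocks_from_genotypes(X, np.zeros(m), b_std, n, 0.999)
        model = GibbsModel(blocks, MixtureSpec.sbayesc(), McmcConfig(n_iter=100, burn_in=10, seed=0))
        for _ in range(5):
            gibbs_sweep(model)
        fresh = model.state.recompute_residuals(blocks, model.offsets)
        for a, b in zip(model.state.residuals, fresh):
            np.testing.assert_allclose(a, b, atol=1e-8)

    def test_no_signal_stays_mostly_null(self):
        blocks = [_toy_block(np.zeros(20), 5000)]
        cfg = McmcConfig(n_iter=200, burn_in=50, seed=4, update_pi=False, update_sigma=False,
                         init_pi=np.array([0.9, 0.1]), init_sigma_g2=1e-3)
        _, summary = run_mcmc(blocks, MixtureSpec.sbayesc(), cfg)
        # with w = 0 exactly, the posterior null mass exceeds the prior's
        assert summary.pip.mean() < 0.1

    def test_label_conservation(self, small_fit):
        """Every retained draw assigns each SNP to exactly one component."""
        nn = small_fit.samples.nonnull
        assert nn.shape[1] == len(small_fit.summary.pip)
        assert nn.dtype == bool


class TestExactPosteriorSmall:
    def test_null_data_pip_below_prior(self):
        pip = exact_posterior_small(np.zeros(1), np.eye(1), 10_000, 0.1, 1e-3, 1.0)
        assert pip[0] < 0.1

    def test_perfect_ld_symmetry(self):
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        b = np.array([0.05, 0.05])
        pip = exact_posterior_small(b, R, 5000, 0.05, 1e-3, 1.0)
        assert pip[0] == pytest.approx(pip[1], abs=1e-12)

    def test_refuses_large_m(self):
        with pytest.raises(ValueError):
            exact_posterior_small(np.zeros(13), np.eye(13), 100, 0.1, 1e-3, 1.0)


class TestMcmcAgainstEnumeration:
    def test_three_snp_system_matches_brute_force(self):
        """MCMC PIPs agree with exhaustive configuration enumeration (m=3, 50k draws)."""
        rng = np.random.default_rng(7)
        n = 5000
        R = np.array([[1.0, 0.6, 0.3], [0.6, 1.0, 0.5], [0.3, 0.5, 1.0]])
        L = np.linalg.cholesky(R)
        beta_true = np.array([0.02, 0.0, 0.0])
        b_std = R @ beta_true + L @ rng.standard_normal(3) / np.sqrt(n)
        pi, sb2, se2 = 0.1, 4e-4, 1.0
        exact = exact_posterior_small(b_std, R, n, pi, sb2, se2)
        pdat = build_pseudo_data(b_std, n, eigendecompose_block(R, 1.0))
        cfg = McmcConfig(
            n_iter=55_000, burn_in=5_000, thin=50, seed=3,
            update_pi=False, update_sigma=False,
            init_pi=np.array([1 - pi, pi]), init_sigma_g2=sb2, init_sigma_e2=se2,
        )
        _, summary = run_mcmc([pdat], MixtureSpec.sbayesc(), cfg)
        np.testing.assert_allclose(summary.pip, exact, atol=0.02)

    def test_duplicated_snp_pair_splits_posterior(self):
        """With r^2 = 1 and one strong signal, draws put one of the pair in, rarely both."""
        rng = np.random.default_rng(2)
        n = 10_000
        x = rng.binomial(2, 0.3, n).astype(float)
        xs = (x - x.mean()) / x.std()
        y = xs * np.sqrt(0.01) + rng.normal(0, 1, n)
        ys = (y - y.mean()) / y.std()
        b1 = float(xs @ ys / n)
        b_std = np.array([b1, b1])
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        pdat = build_pseudo_data(b_std, n, eigendecompose_block(R, 0.995))
        cfg = McmcConfig(n_iter=4_000, burn_in=1_000, thin=1, seed=5,
                         update_pi=False, update_sigma=False,
                         init_pi=np.array([0.99, 0.01]), init_sigma_g2=0.01)
        samples, summary = run_mcmc([pdat], MixtureSpec.sbayesc(), cfg)
        n_in = samples.nonnull.sum(axis=1)
        assert np.mean(n_in == 1) > 0.8  # exactly one of the pair
        assert np.mean(n_in == 2) < 0.1  # rarely both
        assert summary.pip.sum() == pytest.approx(1.0, abs=0.1)

    def test_determinism(self):
        b_std = np.array([0.02, -0.01, 0.0, 0.005])
        pdat = _toy_block(b_std, 2000)
        cfg = McmcConfig(n_iter=500, burn_in=100, seed=42)
        s1, p1 = run_mcmc([pdat], MixtureSpec.sbayesc(), cfg)
        s2, p2 = run_mcmc([pdat], MixtureSpec.sbayesc(), cfg)
        np.testing.assert_array_equal(s1.beta, s2.beta)
        np.testing.assert_array_equal(p1.pip, p2.pip)


class TestAutoPrune:
    def test_small_component_removed(self):
        spec = MixtureSpec.sbayesrc()
        shares = np.array([0.004, 0.010, 0.30, 0.50])
        new, removed = auto_prune_components(shares, spec)
        assert removed
        np.testing.assert_allclose(new.gammas, [0.0, 1e-4, 1e-3, 1e-2])

    def test_exactly_half_retained(self):
        spec = MixtureSpec.sbayesrc()
        shares = np.array([0.005, 0.010, 0.30, 0.50])
        _, removed = auto_prune_components(shares, spec)
        assert not removed

    def test_comparable_shares_unchanged(self):
        spec = MixtureSpec.sbayesrc()
        _, removed = auto_prune_components(np.array([0.1, 0.12, 0.1, 0.1]), spec)
        assert not removed

    def test_cannot_prune_below_two(self):
        spec = MixtureSpec.sbayesc()
        new, removed = auto_prune_components(np.array([1e-9]), spec)
        assert not removed and new.K == 2

    def test_pruning_in_chain_restarts_burnin(self):
        """A chain on null data prunes surplus components and still yields draws."""
        blocks = [_toy_block(np.zeros(50), 5000)]
        cfg = McmcConfig(n_iter=2_000, burn_in=400, seed=1, prune_check_every=200,
                         auto_prune=True)
        samples, summary = run_mcmc(blocks, MixtureSpec.sbayesrc(), cfg)
        assert samples.n_draws > 0
        assert summary.gammas[0] == 0.0
        assert len(summary.gammas) <= 5


class TestAnnotations:
    def test_zero_alpha_gives_uniform_priors(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((100, 3))
        ann = AnnotationSet(A, ["a", "b", "c"])
        blocks = [_toy_block(np.zeros(100), 2000)]
        model = GibbsModel(blocks, MixtureSpec.sbayesrc(),
                           McmcConfig(n_iter=10, burn_in=1, seed=0), ann)
        log_pi = model.state.log_pi_snp
        # alpha initialized at zero: identical membership priors for every SNP
        assert np.allclose(log_pi, log_pi[0][None, :])
        np.testing.assert_allclose(np.exp(log_pi).sum(axis=1), 1.0, atol=1e-10)

    def test_probit_monotonicity(self):
        """Raising an annotation with positive effect never lowers non-null prior mass."""
        from gwfm.sampler import _stick_break_log_pi

        a_vals = np.linspace(-2, 2, 9)
        mu = np.array([0.2, -0.5])
        alpha = np.array([[0.8, 0.1]])
        eta = mu[None, :] + a_vals[:, None] @ alpha
        log_pi = _stick_break_log_pi(eta)
        nonnull = 1.0 - np.exp(log_pi[:, 0])
        assert np.all(np.diff(nonnull) >= -1e-12)
        np.testing.assert_allclose(np.exp(log_pi).sum(axis=1), 1.0, atol=1e-12)

    def test_enrichment_recovery(self):
        """A binary annotation enriched for causals gets a positive fitted effect."""
        rng = np.random.default_rng(8)
        m, n = 1200, 6000
        annot = (rng.random(m) < 0.25).astype(float)
        causal = np.flatnonzero(annot)[:40]  # causals only inside the annotation
        beta = np.zeros(m)
        beta[causal] = rng.normal(0, np.sqrt(0.4 / 40), 40)
        b_std = beta + rng.standard_normal(m) / np.sqrt(n)
        blocks = [
            build_pseudo_data(b_std[i : i + 100], n, eigendecompose_block(np.eye(100), 1.0))
            for i in range(0, m, 100)
        ]
        ann = AnnotationSet(annot[:, None], ["enriched"])
        # auto-pruning removes surplus small components whose noise-absorbing
        # SNPs would otherwise dilute the enrichment signal
        cfg = McmcConfig(n_iter=3_000, burn_in=1_000, thin=5, seed=9, auto_prune=True)
        samples, _ = run_mcmc(blocks, MixtureSpec.sbayesrc(), cfg, ann)
        alpha_first_stage = samples.annot_alpha[:, 0, 0]
        assert np.mean(alpha_first_stage > 0) >= 0.95


def test_config_validation():
    with pytest.raises(ConfigError):
        McmcConfig(n_iter=100, burn_in=100)
    with pytest.raises(ConfigError):
        McmcConfig(thin=0)
    with pytest.raises(ConfigError):
        MixtureSpec(np.array([0.1, 1.0]))
    with pytest.raises(ConfigError):
        MixtureSpec(np.array([0.0, 1.0, 0.5]))
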