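"""Metropolis-within-Gibbs sampler: full conditionals, bookkeeping, diagnostics."""

import numpy as np
import pytest
from scipy.special import expit, logit

from latentgwas.model import ChainState, ModelConfig, marginal_log_likelihood
from latentgwas.sampler import (BlockGram, ChainTrace, SamplerConfig,
                                geweke_diagnostic, gibbs_update_gamma,
                                gibbs_update_theta, initial_state,
                                mh_update_xi, run_block_sampler, update_alpha)
from conftest import make_gene_map


@pytest.fixture
def tiny_block():
    rng = np.random.default_rng(21)
    n, p = 10, 3
    Z = rng.standard_normal((n, p))
    V = np.ones((n, 1))
    y = 1.2 * Z[:, 0] + rng.standard_normal(n)
    return {"y": y, "V": V, "Z": Z, "gene_map": make_gene_map(p, [[0, 1], [2]]),
            "config": ModelConfig(tau2=1.0, sigma2=1.0)}


def test_block_gram_matches_direct_likelihood(tiny_block):
    """The cached Gram-matrix route equals from-scratch dense evaluation."""
    tb = tiny_block
    gram = BlockGram(tb["y"], tb["V"], tb["Z"], tb["config"])
    rng = np.random.default_rng(0)
    for _ in range(8):
        theta = rng.integers(0, 2, 3)
        direct = marginal_log_likelihood(tb["y"], tb["V"], tb["Z"], theta,
                                         tb["config"], method="dense")
        assert gram.loglik(theta) == pytest.approx(direct, abs=1e-6)


def test_theta_first_site_matches_analytic_full_conditional(tiny_block):
    """Monte-Carlo frequency of the first updated site equals its analytic odds."""
    tb = tiny_block
    gram = BlockGram(tb["y"], tb["V"], tb["Z"], tb["config"])
    state = ChainState(theta=np.array([0, 1, 0]), gamma=np.array([1, 0]),
                       xi0=-2.5, xi1=1.0, alpha=0.2)
    # analytic full conditional of theta_0 given the start state
    from latentgwas.model import theta_prior_probs
    pj = theta_prior_probs(state.xi0, state.xi1, state.gamma, tb["gene_map"])[0]
    l1 = gram.loglik(np.array([1, 1, 0]))
    l0 = gram.loglik(np.array([0, 1, 0]))
    p_analytic = expit(logit(pj) + l1 - l0)
    n_rep = 4000
    rng = np.random.default_rng(99)
    hits = 0
    for _ in range(n_rep):
        new, _ = gibbs_update_theta(state.copy(), tb["y"], tb["V"], tb["Z"],
                                    tb["gene_map"], tb["config"], rng, gram=gram)
        hits += int(new.theta[0])
    se = np.sqrt(p_analytic * (1 - p_analytic) / n_rep)
    assert hits / n_rep == pytest.approx(p_analytic, abs=4 * se)


def test_theta_update_with_zero_column_follows_prior(tiny_block):
    """A SNP carrying no signal (all-zero Z column) is drawn from its prior."""
    tb = tiny_block
    Z = np.zeros((10, 1))
    gm = make_gene_map(1, [[0]])
    state = ChainState(theta=np.array([0]), gamma=np.array([1]),
                       xi0=-1.0, xi1=1.0, alpha=0.5)
    prior = expit(-1.0 + 1.0)
    rng = np.random.default_rng(5)
    hits = sum(int(gibbs_update_theta(state.copy(), tb["y"], tb["V"], Z, gm,
                                      tb["config"], rng)[0].theta[0])
               for _ in range(4000))
    se = np.sqrt(prior * (1 - prior) / 4000)
    assert hits / 4000 == pytest.approx(prior, abs=4 * se)


class TestGammaUpdate:
    def test_empty_gene_and_zero_boost_draw_from_alpha(self):
        cfg = ModelConfig(tau2=1.0)
        gm = make_gene_map(2, [[0, 1], []])
        state = ChainState(theta=np.array([1, 0]), gamma=np.array([0, 0]),
                           xi0=-3.0, xi1=0.0, alpha=0.3)  # xi1=0: boost disabled
        rng = np.random.default_rng(17)
        hits = np.zeros(2)
        n_rep = 4000
        for _ in range(n_rep):
            hits += gibbs_update_gamma(state.copy(), gm, cfg, rng).gamma
        se = np.sqrt(0.3 * 0.7 / n_rep)
        np.testing.assert_allclose(hits / n_rep, 0.3, atol=4 * se)

    def test_single_covered_associated_snp_odds(self):
        # odds(gamma=1) = [alpha/(1-alpha)] * p(theta=1|gamma=1)/p(theta=1|gamma=0)
        cfg = ModelConfig(tau2=1.0)
        gm = make_gene_map(1, [[0]])
        state = ChainState(theta=np.array([1]), gamma=np.array([0]),
                           xi0=-4.0, xi1=2.0, alpha=0.5)
        odds = expit(-2.0) / expit(-6.0)
        p_expected = odds / (1 + odds)
        rng = np.random.default_rng(23)
        n_rep = 4000
        hits = sum(int(gibbs_update_gamma(state.copy(), gm, cfg, rng).gamma[0])
                   for _ in range(n_rep))
        se = np.sqrt(p_expected * (1 - p_expected) / n_rep)
        assert hits / n_rep == pytest.approx(p_expected, abs=4 * se)


class TestXiUpdate:
    def test_proposals_outside_support_always_rejected(self):
        cfg = ModelConfig(tau2=1.0)
        gm = make_gene_map(1, [[0]])
        state = ChainState(theta=np.array([0]), gamma=np.array([0]),
                           xi0=-4.0, xi1=2.5, alpha=0.1)
        scfg = SamplerConfig(n_sweeps=2, burn_in=0, xi_proposal_sd=(1e9, 1e9))
        rng = np.random.default_rng(31)
        for _ in range(50):
            new, acc = mh_update_xi(state, gm, cfg, scfg, rng)
            assert (new.xi0, new.xi1) == (state.xi0, state.xi1)
            assert acc == (False, False)

    def test_stationary_density_matches_quadrature(self):
        """With theta all zero and xi1 pinned, the xi0 chain's histogram matches
        the normalised density prod_j (1 - logit^-1(xi0)) on (-6, -2)."""
        p = 30
        cfg = ModelConfig(tau2=1.0)
        gm = make_gene_map(p, [])
        state = ChainState(theta=np.zeros(p, dtype=np.int8),
                           gamma=np.zeros(0, dtype=np.int8),
                           xi0=-4.0, xi1=2.0, alpha=0.1)
        scfg = SamplerConfig(n_sweeps=2, burn_in=0, xi_proposal_sd=(0.6, 1e-12))
        rng = np.random.default_rng(41)
        xs = []
        for _ in range(30_000):
            state, _ = mh_update_xi(state, gm, cfg, scfg, rng)
            xs.append(state.xi0)
        xs = np.asarray(xs[2000:])
        grid = np.linspace(-6, -2, 200)
        dens = (1 - expit(grid)) ** p
        dens /= np.trapezoid(dens, grid)
        # compare chain CDF with quadrature CDF at a few quantile points
        cdf = np.cumsum(dens)
        cdf /= cdf[-1]
        for qp in (0.25, 0.5, 0.75):
            x_chain = np.quantile(xs, qp)
            x_exact = grid[np.searchsorted(cdf, qp)]
            assert x_chain == pytest.approx(x_exact, abs=0.15)


class TestAlphaUpdate:
    def test_conjugate_posterior_moments(self):
        cfg = ModelConfig(tau2=1.0, alpha_beta_params=(0.75, 49.25))
        G = 336
        state = ChainState(theta=np.zeros(1, dtype=np.int8),
                           gamma=np.zeros(G, dtype=np.int8),
                           xi0=-4.0, xi1=2.0, alpha=0.05)
        scfg = SamplerConfig(n_sweeps=2, burn_in=0, alpha_update="conjugate")
        rng = np.random.default_rng(51)
        draws = np.array([update_alpha(state, cfg, scfg, rng).alpha
                          for _ in range(20_000)])
        # Beta(0.75, 385.25): mean a/(a+b)
        mean = 0.75 / (0.75 + 385.25)
        assert draws.mean() == pytest.approx(mean, rel=0.05)

    def test_mh_mode_targets_same_law_as_conjugate(self):
        cfg = ModelConfig(tau2=1.0, alpha_beta_params=(2.0, 8.0))
        state = ChainState(theta=np.zeros(1, dtype=np.int8),
                           gamma=np.array([1, 0, 1, 1, 0]),
                           xi0=-4.0, xi1=2.0, alpha=0.3)
        rng = np.random.default_rng(61)
        conj = SamplerConfig(n_sweeps=2, burn_in=0, alpha_update="conjugate")
        mean_conj = np.mean([update_alpha(state, cfg, conj, rng).alpha
                             for _ in range(10_000)])
        mh = SamplerConfig(n_sweeps=2, burn_in=0, alpha_update="mh")
        cur = state
        xs = []
        for _ in range(30_000):
            cur = update_alpha(cur, cfg, mh, rng)
            xs.append(cur.alpha)
        assert np.mean(xs[3000:]) == pytest.approx(mean_conj, abs=0.01)


class TestRunBlockSampler:
    def test_kept_sweep_bookkeeping(self, tiny_block):
        tb = tiny_block
        scfg = SamplerConfig(n_sweeps=10, burn_in=0, thin=1, seed=1)
        tr = run_block_sampler(tb["y"], tb["V"], tb["Z"], tb["gene_map"],
                               tb["config"], scfg)
        assert tr.n_kept == 10
        assert tr.theta_samples.shape == (10, 3)
        assert tr.gamma_samples.shape == (10, 2)
        scfg2 = SamplerConfig(n_sweeps=25, burn_in=5, thin=3, seed=1)
        tr2 = run_block_sampler(tb["y"], tb["V"], tb["Z"], tb["gene_map"],
                                tb["config"], scfg2)
        assert tr2.n_kept == (25 - 5) // 3

    def test_identical_seed_bit_identical_trace(self, tiny_block):
        tb = tiny_block
        scfg = SamplerConfig(n_sweeps=60, burn_in=10, seed=7)
        tr1 = run_block_sampler(tb["y"], tb["V"], tb["Z"], tb["gene_map"],
                                tb["config"], scfg)
        tr2 = run_block_sampler(tb["y"], tb["V"], tb["Z"], tb["gene_map"],
                                tb["config"], scfg)
        np.testing.assert_array_equal(tr1.theta_samples, tr2.theta_samples)
        np.testing.assert_array_equal(tr1.gamma_samples, tr2.gamma_samples)
        np.testing.assert_array_equal(tr1.hyper_samples, tr2.hyper_samples)
        np.testing.assert_array_equal(tr1.log_post, tr2.log_post)
        assert tr1.accept_rates == tr2.accept_rates

    def test_initial_state_midpoints_and_prior_mean(self, tiny_block):
        st = initial_state(3, 2, tiny_block["config"], SamplerConfig())
        assert (st.theta == 0).all() and (st.gamma == 0).all()
        assert st.xi0 == -4.0 and st.xi1 == 2.5
        assert st.alpha == pytest.approx(0.015)


class TestGeweke:
    @staticmethod
    def _trace_from_series(x):
        n = len(x)
        return ChainTrace(theta_samples=np.zeros((n, 1), dtype=np.int8),
                          gamma_samples=np.zeros((n, 1), dtype=np.int8),
                          hyper_samples=np.column_stack([x, x, x]),
                          log_post=np.zeros(n), accept_rates=(0.3, 0.3))

    def test_stationary_chain_passes(self):
        rng = np.random.default_rng(71)
        z = geweke_diagnostic(self._trace_from_series(rng.standard_normal(2000)))
        assert np.all(np.abs(z[:3]) < 3)

    def test_trending_chain_flagged(self):
        z = geweke_diagnostic(self._trace_from_series(np.linspace(0, 5, 2000)
                                                      + 0.01 * np.sin(np.arange(2000))))
        assert np.all(np.abs(z[:3]) > 3)

    def test_constant_chain_defined_as_zero(self):
        z = geweke_diagnostic(self._trace_from_series(np.ones(500)))
        np.testing.assert_array_equal(z, 0.0)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            geweke_diagnostic(self._trace_from_series(np.ones(50)))
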