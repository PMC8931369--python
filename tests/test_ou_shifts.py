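"""Multiregime OU likelihood, priors, the RJ-MCMC sampler and its
diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from allogrades import ou_shifts as ou
from allogrades.phylo import bm_covariance, paint_regimes
from allogrades.synthdata import (
    planted_shift_scenario,
    simulate_grade_dataset,
    simulate_tree,
)


def _series(tree, vals):
    return pd.Series(vals, index=tree.tip_labels)


def _make_chain(**arrays):
    n = len(next(iter(arrays.values())))
    base = dict(
        alpha=np.ones(n), sigma2=np.ones(n), n_shifts=np.zeros(n),
        theta_root=np.zeros(n), beta_root=np.zeros(n),
        logpost=np.zeros(n), shift_states=[{} for _ in range(n)],
        n_iter=n, thin=1, burn_in=0.0, seed=0,
    )
    base.update(arrays)
    return ou.PosteriorChain(**base)


class TestLikelihood:
    def test_bm_limit_single_regime(self):
        tree = simulate_tree(16, 1)
        p0 = paint_regimes(tree, [])
        ds = simulate_grade_dataset(tree, p0, [7.0], [0.5], 0.2, seed=2)
        x, y = ds.traits.log_body_mass, ds.traits.log_neurons
        pars = ou.OUAllometryParams(1e-8, 0.001, [7.0], [0.5])
        ll = ou.ou_regression_loglik(x, y, tree, p0, pars)
        V = 0.001 * bm_covariance(tree)
        mu = 7.0 + 0.5 * np.asarray(x.loc[tree.tip_labels])
        ref = stats.multivariate_normal.logpdf(
            np.asarray(y.loc[tree.tip_labels]), mu, V
        )
        assert abs(ll - ref) / abs(ref) < 1e-5

    def test_three_taxon_dense_mvn_oracle(self, three_taxon):
        from allogrades.phylo import ou_covariance, ou_weight_matrix

        t = three_taxon
        b = next(bb for bb in t.branch_ids if t.children[bb])
        p = paint_regimes(t, [b])
        x = _series(t, [1.0, 2.0, 3.0])
        y = _series(t, [7.4, 8.1, 8.0])
        pars = ou.OUAllometryParams(0.7, 0.2, [7.0, 7.5], [0.4, 0.55])
        ll = ou.ou_regression_loglik(x, y, t, p, pars)
        W = ou_weight_matrix(t, p, 0.7)
        mu = W @ pars.theta + x.to_numpy() * (W @ pars.beta)
        V = ou_covariance(t, 0.7, 0.2)
        ref = stats.multivariate_normal.logpdf(y.to_numpy(), mu, V)
        assert ll == pytest.approx(ref, abs=1e-8)

    def test_true_params_beat_perturbed(self):
        tree = simulate_tree(64, 3)
        p0 = paint_regimes(tree, [])
        a, sd = 2.0 / 300, 0.15
        wins = 0
        for i in range(30):
            ds = simulate_grade_dataset(
                tree, p0, [7.0], [0.5], 0.0, seed=100 + i,
                residual_mode="ou", alpha=a, sigma2=2 * a * sd**2,
            )
            x, y = ds.traits.log_body_mass, ds.traits.log_neurons
            true = ou.OUAllometryParams(a, 2 * a * sd**2, [7.0], [0.5])
            pert = ou.OUAllometryParams(
                a, 2 * a * sd**2, [7.0 + 2 * sd], [0.5]
            )
            wins += ou.ou_regression_loglik(x, y, tree, p0, true) > \
                ou.ou_regression_loglik(x, y, tree, p0, pert)
        assert wins >= 27

    def test_dimension_mismatch(self, three_taxon):
        p0 = paint_regimes(three_taxon, [])
        pars = ou.OUAllometryParams(0.1, 0.1, [1.0, 2.0], [0.1, 0.2])
        with pytest.raises(ValueError):
            ou.ou_regression_loglik(
                _series(three_taxon, [1, 2, 3]),
                _series(three_taxon, [1, 2, 3]),
                three_taxon, p0, pars,
            )


class TestPriors:
    def test_poisson_mean_and_truncation_arithmetic(self):
        pr = ou.PriorSpec()
        assert pr.poisson_mean(500) == pytest.approx(10.0)
        assert pr.max_shifts(500) == 100

    def test_half_cauchy_closed_form(self):
        # density at the scale parameter: 2 / (pi * s * 2) = 1 / (pi * s)
        assert ou._halfcauchy_logpdf(0.1, 0.1) == pytest.approx(
            math.log(1.0 / (0.1 * math.pi))
        )
        assert ou._halfcauchy_logpdf(-1.0, 0.1) == -np.inf

    def test_zero_shift_location_term_vanishes(self, tree20):
        p0 = paint_regimes(tree20, [])
        pr = ou.PriorSpec(theta_mu=7, theta_sd=1, beta_mu=0.5)
        pars = ou.OUAllometryParams(0.1, 0.1, [7.0], [0.5])
        lp = ou.log_prior(pars, p0, pr)
        manual = (
            ou._trunc_poisson_logpmf(
                0, pr.poisson_mean(tree20.n_branches),
                pr.max_shifts(tree20.n_branches))
            + ou._halfcauchy_logpdf(0.1, 0.1) * 2
            + stats.norm.logpdf(7.0, 7, 1)
            + stats.norm.logpdf(0.5, 0.5, 0.3)
        )
        assert lp == pytest.approx(manual, abs=1e-10)

    def test_shift_count_above_bound_rejected(self, tree20):
        pr = ou.PriorSpec(shift_max_fraction=0.05)  # bound: 1 shift
        shifts = list(tree20.branch_ids[:3])
        p = paint_regimes(tree20, shifts)
        pars = ou.OUAllometryParams(0.1, 0.1, [0.0] * 4, [0.0] * 4)
        assert ou.log_prior(pars, p, pr) == -np.inf


class TestSampler:
    def test_prior_only_recovers_truncated_poisson(self):
        """Flat likelihood: the sampled shift count must match the
        truncated Poisson prior (detailed-balance smoke test)."""
        tree = simulate_tree(32, 5)
        pr = ou.PriorSpec(theta_mu=0, theta_sd=1, beta_mu=0, beta_sd=0.3)
        chains = ou.rjmcmc_run(
            _series(tree, np.zeros(32)), _series(tree, np.zeros(32)),
            tree, priors=pr, n_iter=600_000, thin=60, n_chains=1,
            burn_in_fraction=0.2, seed=9, prior_only=True,
        )
        counts = chains[0].trace("n_shifts").astype(int)
        B = tree.n_branches
        mmax = pr.max_shifts(B)
        pmf = stats.poisson.pmf(np.arange(mmax + 1), pr.poisson_mean(B))
        pmf /= pmf.sum()
        # bin the tail so expected counts stay >= 5
        edges = [0, 1, 2, 3, 4]
        obs = np.array(
            [np.sum(counts == e) for e in edges]
            + [np.sum(counts > edges[-1])]
        )
        exp = np.array(
            [pmf[e] for e in edges] + [pmf[edges[-1] + 1:].sum()]
        ) * len(counts)
        chi2 = ((obs - exp) ** 2 / exp).sum()
        p = stats.chi2.sf(chi2, len(obs) - 1)
        assert p > 0.01

    def test_seeded_runs_bit_identical(self):
        ds = planted_shift_scenario(32, seed=3)
        x, y = ds.traits.log_body_mass, ds.traits.log_neurons
        a = ou.rjmcmc_run(x, y, ds.tree, n_iter=4000, thin=10,
                          n_chains=2, seed=77)
        b = ou.rjmcmc_run(x, y, ds.tree, n_iter=4000, thin=10,
                          n_chains=2, seed=77)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.alpha, cb.alpha)
            assert np.array_equal(ca.logpost, cb.logpost)
            assert ca.shift_states == cb.shift_states

    def test_birth_then_death_restores_logpost(self):
        tr = simulate_tree(24, seed=4)
        ds = simulate_grade_dataset(
            tr, paint_regimes(tr, []), [7.0], [0.5], 0.15, seed=5
        )
        x, y = ds.traits.log_body_mass, ds.traits.log_neurons
        pr = ou.PriorSpec.from_data(tr, x, y)
        smp = ou._OUSampler(
            tr, np.asarray(x.loc[tr.tip_labels]),
            np.asarray(y.loc[tr.tip_labels]), pr,
            np.random.default_rng(0),
        )
        smp.sig2 = 0.01
        smp.set_alpha(0.02)
        smp.theta0, smp.beta0 = pr.theta_mu, pr.beta_mu
        smp.set_painting({})
        lp0 = smp.logpost()
        smp.set_painting({5: (7.7, 0.6)})  # birth
        smp.set_painting({})  # matching death
        assert smp.logpost() == pytest.approx(lp0, abs=1e-10)

    def test_sampler_caches_match_public_functions(self):
        from allogrades.phylo import ou_weight_matrix

        tree = simulate_tree(48, 8)
        rng = np.random.default_rng(1)
        x = _series(tree, rng.normal(2, 1, 48))
        y = _series(tree, rng.normal(7, 1, 48))
        pr = ou.PriorSpec(theta_mu=7, theta_sd=1.5, beta_mu=0.5)
        smp = ou._OUSampler(
            tree, x.to_numpy(), y.to_numpy(), pr, rng
        )
        smp.sig2 = 0.004
        smp.set_alpha(0.015)
        for shifts in ({}, {7: (7.5, 0.6)}, {7: (7.5, 0.6), 9: (8.0, 0.7)}):
            smp.theta0, smp.beta0 = 7.0, 0.5
            smp.set_painting(dict(shifts))
            pub = paint_regimes(tree, sorted(shifts))
            assert np.array_equal(smp.reg, pub.branch_regime)
            assert np.allclose(
                smp.W, ou_weight_matrix(tree, pub, 0.015), atol=1e-12
            )
            th, be = smp.theta_beta_vectors()
            pars = ou.OUAllometryParams(0.015, 0.004, th, be)
            assert smp.loglik() == pytest.approx(
                ou.ou_regression_loglik(x, y, tree, pub, pars), abs=1e-6
            )
            assert smp.logprior() == pytest.approx(
                ou.log_prior(pars, pub, pr), abs=1e-8
            )

    def test_planted_shifts_recovered(self):
        ds = planted_shift_scenario(64, seed=6)
        x, y = ds.traits.log_body_mass, ds.traits.log_neurons
        chains = ou.rjmcmc_run(x, y, ds.tree, n_iter=40_000, thin=100,
                               n_chains=4, seed=11)
        s = ou.summarize_shifts(chains, ds.tree)
        b1, b2 = ds.painting.shifts
        assert s.pp[b1] > 0.7 and s.pp[b2] > 0.7
        fp = [
            int(b) for b in ds.tree.branch_ids
            if len(ds.tree.clade_tip_ids(b)) >= 4
            and s.pp[b] > 0.7 and b not in (b1, b2)
        ]
        assert fp == []
        assert set(s.accepted) == {b1, b2}

    def test_no_shift_data_gives_no_acceptances(self):
        tree = simulate_tree(64, 13)
        p0 = paint_regimes(tree, [])
        a, sd = 2.0 / 300, 0.15
        ds = simulate_grade_dataset(
            tree, p0, [7.0], [0.5], 0.0, seed=14,
            residual_mode="ou", alpha=a, sigma2=2 * a * sd**2,
        )
        x, y = ds.traits.log_body_mass, ds.traits.log_neurons
        chains = ou.rjmcmc_run(x, y, tree, n_iter=40_000, thin=100,
                               n_chains=4, seed=15)
        s = ou.summarize_shifts(chains, tree)
        assert s.accepted == []

    def test_rejects_invalid_settings(self, tree20):
        x = _series(tree20, np.zeros(20))
        with pytest.raises(ValueError):
            ou.rjmcmc_run(x, x, tree20, n_chains=1)
        with pytest.raises(ValueError):
            ou.rjmcmc_run(x, x, tree20, n_iter=0, prior_only=True,
                          n_chains=1)


class TestDiagnostics:
    def test_rhat_identical_chains(self):
        tr = np.random.default_rng(0).normal(size=1000)
        chains = [_make_chain(alpha=tr.copy()), _make_chain(alpha=tr.copy())]
        assert ou.gelman_rhat(chains, "alpha") == pytest.approx(1.0,
                                                               abs=1e-3)

    def test_rhat_same_stationary_normal(self):
        rng = np.random.default_rng(1)
        chains = [
            _make_chain(alpha=rng.normal(size=10_000)) for _ in range(2)
        ]
        assert ou.gelman_rhat(chains, "alpha") < 1.05

    def test_rhat_separated_chains(self):
        rng = np.random.default_rng(2)
        chains = [
            _make_chain(alpha=rng.normal(0, 1, 2000)),
            _make_chain(alpha=rng.normal(5, 1, 2000)),
        ]
        assert ou.gelman_rhat(chains, "alpha") > 1.5

    def test_rhat_single_chain_error(self):
        with pytest.raises(ValueError):
            ou.gelman_rhat([_make_chain(alpha=np.zeros(10))], "alpha")

    def test_ess_iid(self):
        z = np.random.default_rng(3).normal(size=10_000)
        assert ou.effective_sample_size(z) == pytest.approx(10_000,
                                                            rel=0.10)

    def test_ess_ar1(self):
        rho, n = 0.9, 50_000
        rng = np.random.default_rng(4)
        z = np.empty(n)
        z[0] = rng.normal()
        eps = rng.normal(size=n) * np.sqrt(1 - rho**2)
        for i in range(1, n):
            z[i] = rho * z[i - 1] + eps[i]
        expected = n * (1 - rho) / (1 + rho)
        assert ou.effective_sample_size(z) == pytest.approx(expected,
                                                            rel=0.20)

    def test_ess_alternating_capped(self):
        z = np.tile([1.0, -1.0], 50)
        assert ou.effective_sample_size(z) == len(z)

    def test_ess_constant_trace(self):
        assert ou.effective_sample_size(np.ones(50)) == 50


class TestSummarize:
    def test_pp_counts_and_filters(self, tree20):
        # fabricate chains: a shift on a big clade in all samples, one on
        # a 1-tip clade in 95% of samples
        big = max(
            tree20.branch_ids,
            key=lambda b: len(tree20.clade_tip_ids(b))
            if tree20.parent[b] != 0 else 0,
        )
        tiny = next(
            b for b in tree20.branch_ids if not tree20.children[b]
        )
        n = 100
        states = [
            {big: (8.0, 0.6), tiny: (9.0, 0.7)} if i < 95
            else {big: (8.0, 0.6)}
            for i in range(n)
        ]
        rng = np.random.default_rng(5)
        chains = [
            _make_chain(
                alpha=rng.normal(1, 0.01, n),
                sigma2=rng.normal(1, 0.01, n),
                n_shifts=np.full(n, 2.0),
                shift_states=list(states),
            )
            for _ in range(2)
        ]
        s = ou.summarize_shifts(chains, tree20)
        assert s.pp[big] == 1.0
        assert s.pp[tiny] == pytest.approx(0.95)
        assert big in s.accepted
        assert tiny not in s.accepted  # clade-size filter
        assert s.regime_params[big]["theta"] == pytest.approx(8.0)

    def test_grade_labels_partition(self, tree64):
        b = next(
            bb for bb in tree64.branch_ids
            if len(tree64.clade_tip_ids(bb)) >= 6
            and tree64.parent[bb] != 0
        )
        n = 10
        chains = [
            _make_chain(
                alpha=np.random.default_rng(6).normal(1, 0.01, n),
                shift_states=[{b: (8.0, 0.6)}] * n,
                n_shifts=np.ones(n),
            )
            for _ in range(2)
        ]
        s = ou.summarize_shifts(chains, tree64)
        labels = s.grade_labels(tree64)
        clade = set(tree64.label[u] for u in tree64.clade_tip_ids(b))
        assert set(labels.index) == set(tree64.tip_labels)
        assert all(
            (labels[sp] == f"shift_{b}") == (sp in clade)
            for sp in labels.index
        )
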