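"""Sampler: moves, known-target calibration, hyper updates, diagnostics."""

import numpy as np
import pytest

from blastdm.demcmc import (HierarchicalFit, HyperParams, SamplerConfig,
                            crossover_step, diagnostics, init_chains,
                            migration_step, sample, update_hyper)


class TestInit:
    def test_distinct_finite_states(self, rng):
        logpost = lambda x: float(-0.5 * x @ x)
        states, logps = init_chains(logpost, lambda r: r.normal(0, 2, 8),
                                    24, rng)
        assert states.shape == (24, 8)
        assert np.all(np.isfinite(logps))
        assert len({tuple(s) for s in states}) == 24

    def test_determinism(self):
        logpost = lambda x: float(-0.5 * x @ x)
        s1, _ = init_chains(logpost, lambda r: r.normal(0, 2, 3), 6,
                            np.random.default_rng(3))
        s2, _ = init_chains(logpost, lambda r: r.normal(0, 2, 3), 6,
                            np.random.default_rng(3))
        np.testing.assert_array_equal(s1, s2)

    def test_impossible_start_raises(self, rng):
        with pytest.raises(RuntimeError):
            init_chains(lambda x: -np.inf, lambda r: r.normal(size=2),
                        3, rng, max_retries=10)


class TestMoves:
    def test_zero_gamma_zero_eps_keeps_states(self, rng):
        logpost = lambda x: float(-0.5 * x @ x)
        states, logps = init_chains(logpost, lambda r: r.normal(0, 1, 2),
                                    6, rng)
        before = states.copy()
        n_acc = crossover_step(states, logps, logpost, 0.0, 0.0, rng)
        assert n_acc == 6  # identical proposals always accepted
        np.testing.assert_array_equal(states, before)

    def test_migration_prob_zero_is_identity(self, rng):
        states = rng.normal(size=(5, 2))
        logps = rng.normal(size=5)
        b1, b2 = states.copy(), logps.copy()
        assert migration_step(states, logps, 0.0, rng) == 0
        np.testing.assert_array_equal(states, b1)
        np.testing.assert_array_equal(logps, b2)

    def test_migration_identical_states_is_noop_up_to_bookkeeping(self, rng):
        states = np.tile(np.array([1.0, 2.0]), (4, 1))
        logps = np.full(4, -1.0)
        migration_step(states, logps, 1.0, rng)
        np.testing.assert_array_equal(states, np.tile([1.0, 2.0], (4, 1)))

    def test_multimodal_mixture_visits_both_modes(self):
        # well-separated equal modes; the default move mix (crossover with
        # occasional gamma = 1 jumps plus mild migration) must keep finding
        # and holding both modes within budget
        def logpost(x):
            return float(np.logaddexp(-0.5 * ((x[0] + 5) / 0.3) ** 2,
                                      -0.5 * ((x[0] - 5) / 0.3) ** 2))

        hits = 0
        for s in range(8):
            cfg = SamplerConfig(n_chains=8, n_burn=200, n_keep=800,
                                migration_prob=0.05, gamma1_prob=0.3,
                                seed=100 + s)
            d = sample(logpost, 1, lambda r: r.normal(0, 6, 1), cfg)
            x = d.draws.ravel()
            hits += (x < 0).any() and (x > 0).any()
        assert hits >= 6

    def test_migration_rescues_outlier_chain(self):
        # one chain starts absurdly far out; migration lets it adopt a good
        # state instead of random-walking back, cutting recovery time
        target = lambda x: float(-0.5 * x @ x)

        def recovery_iters(mig_prob, seed):
            rng = np.random.default_rng(seed)
            states = rng.normal(0, 1, (8, 1))
            states[0] = 50.0
            logps = np.array([target(s) for s in states])
            for it in range(2000):
                crossover_step(states, logps, target, 1.68, 0.001, rng, 0.1)
                migration_step(states, logps, mig_prob, rng)
                if logps.min() > -5:
                    return it
            return 2000

        without = np.mean([recovery_iters(0.0, 40 + s) for s in range(15)])
        with_mig = np.mean([recovery_iters(0.1, 40 + s) for s in range(15)])
        assert with_mig < without


class TestCalibration:
    def test_standard_normal_2d(self):
        logpost = lambda x: float(-0.5 * x @ x)
        cfg = SamplerConfig(n_chains=8, n_burn=500, n_keep=2500, seed=21)
        d = sample(logpost, 2, lambda r: r.normal(0, 3, 2), cfg)
        x = d.draws.reshape(-1, 2)
        assert np.abs(x.mean(axis=0)).max() < 0.05
        assert np.abs(np.cov(x.T) - np.eye(2)).max() < 0.1

    def test_correlated_normal_beats_independent_walk(self):
        rho = 0.95
        icov = np.linalg.inv(np.array([[1, rho], [rho, 1]]))
        logpost = lambda x: float(-0.5 * x @ icov @ x)
        cfg = SamplerConfig(n_chains=8, n_burn=500, n_keep=1250, seed=22)
        d = sample(logpost, 2, lambda r: r.normal(0, 3, 2), cfg)
        x = d.draws.reshape(-1, 2)
        cov_err_de = np.abs(np.cov(x.T) - np.array([[1, rho], [rho, 1]])).max()
        assert np.abs(x.mean(axis=0)).max() < 0.08
        assert cov_err_de < 0.12

        # equal-budget naive independent random-walk Metropolis
        rng = np.random.default_rng(22)
        n_total = 8 * 1750
        cur = rng.normal(0, 3, 2)
        lp = logpost(cur)
        keep = []
        for i in range(n_total):
            prop = cur + rng.normal(0, 0.1, 2)  # untuned isotropic steps
            lpp = logpost(prop)
            if lpp - lp > np.log(rng.random() + 1e-300):
                cur, lp = prop, lpp
            if i >= 8 * 500:
                keep.append(cur.copy())
        xw = np.array(keep)
        cov_err_walk = np.abs(np.cov(xw.T)
                              - np.array([[1, rho], [rho, 1]])).max()
        assert cov_err_de < cov_err_walk


class TestUpdateHyper:
    def test_degenerate_individuals_concentrate_location(self, rng):
        thetas = np.full((30, 1), 2.5)
        hp = HyperParams(("p",), np.array([0.0]), np.array([1.0]))
        mus, sigmas = [], []
        for _ in range(300):
            hp = update_hyper(thetas, hp, [(0.0, 10.0)], [1.0], rng)
            mus.append(hp.mu[0])
            sigmas.append(hp.sigma[0])
        assert np.mean(mus[100:]) == pytest.approx(2.5, abs=0.05)
        assert np.median(sigmas[100:]) < 0.2

    def test_conjugate_location_matches_closed_form(self, rng):
        # fixed sigma: mu draws follow the exact normal-normal posterior
        sigma = 1.5
        thetas = rng.normal(1.0, sigma, size=(25, 1))
        m0, t0 = 0.0, 2.0
        prec = 25 / sigma**2 + 1 / t0**2
        mu_post = (thetas.sum() / sigma**2 + m0 / t0**2) / prec
        hp = HyperParams(("p",), np.array([0.0]), np.array([sigma]))
        draws = []
        for _ in range(4000):
            new = update_hyper(thetas, hp, [(m0, t0)], [1.0], rng, n_mh=0)
            draws.append(new.mu[0])
        draws = np.array(draws)
        assert draws.mean() == pytest.approx(mu_post, abs=0.02)
        assert draws.std() == pytest.approx(prec**-0.5, rel=0.1)


class TestHierarchicalNormal:
    def _fit(self, seed, P=12, mu_true=1.0, sig_g=0.8, s_obs=0.5,
             n_keep=400):
        rng = np.random.default_rng(seed)
        th = rng.normal(mu_true, sig_g, P)
        y = rng.normal(th, s_obs)
        loglik = lambda i, t, s: float(-0.5 * ((y[i] - t[0]) / s_obs) ** 2)
        fit = HierarchicalFit(
            loglik=loglik, n_participants=P, param_names=("theta",),
            mu_prior=[(0.0, 10.0)], sigma_scale=[2.0],
            config=SamplerConfig(n_chains=6, n_burn=300, n_keep=n_keep,
                                 seed=seed),
            noisy=False, fixed_sigma=[sig_g], theta_init_scale=[3.0])
        d = fit.run()
        prec = P / (s_obs**2 + sig_g**2) + 1 / 10.0**2
        mu_cf = y.sum() / (s_obs**2 + sig_g**2) / prec
        sd_cf = prec**-0.5
        return d.mu[:, :, 0], mu_cf, sd_cf

    def test_location_posterior_matches_closed_form(self):
        mu_draws, mu_cf, sd_cf = self._fit(31)
        assert mu_draws.mean() == pytest.approx(mu_cf, abs=0.1 * sd_cf * 3)
        assert mu_draws.std() == pytest.approx(sd_cf, rel=0.2)

    def test_credible_interval_coverage(self):
        hits = 0
        n_rep = 25
        for r in range(n_rep):
            mu_draws, mu_cf, sd_cf = self._fit(500 + r, n_keep=250)
            lo, hi = np.percentile(mu_draws, [2.5, 97.5])
            # truth here is the generating mu = 1.0
            hits += lo <= 1.0 <= hi
        # nominal 95%: at least 20 of 25 by binomial slack
        assert hits >= 20

    def test_resample_every_iteration_policy_also_converges(self):
        # noisy likelihood with per-iteration re-evaluation of the current
        # state; the location posterior must still land on the closed form
        rng_data = np.random.default_rng(71)
        P, s_obs, sig_g = 10, 0.5, 0.8
        th = rng_data.normal(1.0, sig_g, P)
        y = rng_data.normal(th, s_obs)

        def noisy_loglik(i, t, seed):
            noise = np.random.default_rng(seed).normal(0, 0.3)
            return float(-0.5 * ((y[i] - t[0]) / s_obs) ** 2 + noise)

        fit = HierarchicalFit(
            loglik=noisy_loglik, n_participants=P, param_names=("theta",),
            mu_prior=[(0.0, 10.0)], sigma_scale=[2.0],
            config=SamplerConfig(n_chains=6, n_burn=300, n_keep=300,
                                 resample="every_iteration", seed=72),
            noisy=True, fixed_sigma=[sig_g], theta_init_scale=[2.0])
        mu_draws = fit.run().mu[:, :, 0]
        prec = P / (s_obs**2 + sig_g**2) + 1 / 100.0
        mu_cf = y.sum() / (s_obs**2 + sig_g**2) / prec
        assert mu_draws.mean() == pytest.approx(mu_cf, abs=0.2)

    def test_support_never_violated_with_guarded_likelihood(self):
        # -inf outside theta > 0 must keep every retained draw positive
        rng = np.random.default_rng(7)
        y = rng.normal(1.0, 0.3, 6)

        def loglik(i, t, s):
            if t[0] <= 0:
                return -np.inf
            return float(-0.5 * ((y[i] - t[0]) / 0.3) ** 2)

        fit = HierarchicalFit(
            loglik=loglik, n_participants=6, param_names=("theta",),
            mu_prior=[(1.0, 5.0)], sigma_scale=[1.0],
            config=SamplerConfig(n_chains=5, n_burn=100, n_keep=200, seed=8),
            noisy=False, theta_init_scale=[0.5])
        d = fit.run()
        assert (d.theta > 0).all()


class TestDiagnostics:
    def test_iid_chains_rhat_near_one(self, rng):
        x = rng.normal(size=(4, 500))
        r, ess = diagnostics(x)
        assert r == pytest.approx(1.0, abs=0.02)
        assert ess > 1000

    def test_offset_chain_detected(self, rng):
        x = rng.normal(size=(4, 500))
        x[0] += 10
        r, _ = diagnostics(x)
        assert r > 1.5

    def test_ar1_ess_fraction(self, rng):
        # AR(1) with phi = 0.5: ESS/N = (1-phi)/(1+phi) = 1/3
        phi, n = 0.5, 20000
        x = np.empty((4, n))
        for c in range(4):
            e = rng.standard_normal(n)
            x[c, 0] = e[0]
            for t in range(1, n):
                x[c, t] = phi * x[c, t - 1] + e[t] * np.sqrt(1 - phi**2)
        _, ess = diagnostics(x)
        assert ess / (4 * n) == pytest.approx(1 / 3, rel=0.2)

    def test_too_few_draws_error(self, rng):
        with pytest.raises(ValueError):
            diagnostics(rng.normal(size=(1, 500)))
        with pytest.raises(ValueError):
            diagnostics(rng.normal(size=(4, 20)))
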