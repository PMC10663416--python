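"""Fitting engine: PIRLS, LAML, dispersion, tri-exponential regression.

External oracles: closed-form Poisson MLEs, statsmodels GLM (unpenalized),
a brute-force penalized-likelihood optimizer, and scipy log-pmfs.
"""

import numpy as np
import pytest
from scipy import optimize, stats

from aifcount import (Family, TriExpParams, family_loglik, pirls_solve,
                      reml_optimize, estimate_negbin_dispersion, model_aic,
                      nls_poisson_fit, curve_strip_init, tps_design)
from aifcount.engine import (FitError, linear_block, triexp_logf,
                             laml_criterion, gaussian_reml_fit)


class TestFamily:
    def test_poisson_loglik_matches_scipy(self):
        y = np.array([0.0, 3, 7, 12])
        mu = np.array([1.0, 2.5, 8.0, 11.0])
        assert family_loglik(Family("poisson"), y, mu) == pytest.approx(
            stats.poisson.logpmf(y, mu).sum())

    def test_negbin_loglik_matches_scipy(self):
        y = np.array([0.0, 3, 7, 120])
        mu = np.array([1.0, 2.5, 8.0, 100.0])
        psi = 0.4
        r = 1 / psi
        assert family_loglik(Family("negbin", psi), y, mu) == pytest.approx(
            stats.nbinom.logpmf(y, r, r / (r + mu)).sum())

    def test_negbin_small_psi_converges_to_poisson(self):
        y = np.array([2.0, 5, 9])
        mu = np.array([3.0, 4.0, 10.0])
        ll_p = family_loglik(Family("poisson"), y, mu)
        ll_nb = family_loglik(Family("negbin", 1e-9), y, mu)
        assert ll_nb == pytest.approx(ll_p, abs=1e-6)

    def test_rvs_moments(self):
        rng = np.random.default_rng(7)
        mu = np.full(100_000, 40.0)
        y = Family("negbin", 0.3).rvs(mu, rng)
        assert np.mean(y) == pytest.approx(40.0, rel=0.02)
        assert np.var(y) == pytest.approx(40 + 0.3 * 1600, rel=0.05)

    def test_variance_function(self):
        mu = np.array([2.0, 10.0])
        np.testing.assert_allclose(Family("negbin", 0.5).variance(mu),
                                   mu + 0.5 * mu ** 2)
        np.testing.assert_allclose(Family("poisson").variance(mu), mu)


class TestPirlsClosedForm:
    def test_intercept_only_poisson(self):
        y = np.array([1.0, 3, 5, 7])
        block = linear_block(np.ones((4, 1)))
        fit = pirls_solve([block], y, np.zeros(4), Family("poisson"),
                          np.zeros(1))
        assert fit.coef[0] == pytest.approx(np.log(4.0), abs=1e-9)

    def test_intercept_with_offsets(self):
        y = np.array([2.0, 4, 9])
        tau = np.array([1.0, 2.0, 2.0])
        block = linear_block(np.ones((3, 1)))
        fit = pirls_solve([block], y, np.log(tau), Family("poisson"),
                          np.zeros(1))
        # MLE: exp(beta) = sum(y) / sum(tau) = 3
        assert fit.coef[0] == pytest.approx(np.log(3.0), abs=1e-9)

    def test_matches_statsmodels_glm(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=n),
                             rng.uniform(-1, 1, n)])
        off = np.log(rng.uniform(0.5, 2.0, n))
        eta = X @ np.array([1.0, 0.4, -0.7]) + off
        y = rng.poisson(np.exp(eta)).astype(float)
        fit = pirls_solve([linear_block(X)], y, off, Family("poisson"),
                          np.zeros(1))
        ref = sm.GLM(y, X, family=sm.families.Poisson(), offset=off).fit()
        np.testing.assert_allclose(fit.coef, ref.params, atol=1e-6)
        np.testing.assert_allclose(np.diag(fit.cov_coef),
                                   np.diag(ref.cov_params()), rtol=1e-4)

    def test_matches_statsmodels_negbin(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(6)
        n = 300
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        mu = np.exp(X @ np.array([2.0, 0.5]))
        psi = 0.4
        y = Family("negbin", psi).rvs(mu, rng).astype(float)
        fit = pirls_solve([linear_block(X)], y, np.zeros(n),
                          Family("negbin", psi), np.zeros(1))
        ref = sm.GLM(y, X,
                     family=sm.families.NegativeBinomial(alpha=psi)).fit()
        np.testing.assert_allclose(fit.coef, ref.params, atol=1e-5)


class TestPenalizedOracle:
    def test_matches_brute_force_penalized_optimizer(self):
        rng = np.random.default_rng(9)
        n = 60
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.poisson(np.exp(0.5 + 0.3 * X[:, 1])).astype(float)
        S = np.array([[0.0, 0.0], [0.0, 1.0]])
        sp = 3.7
        from aifcount.bases import BasisBlock
        block = BasisBlock(design=X, penalty=S, nullspace_dim=1,
                           kind="toy")
        fit = pirls_solve([block], y, np.zeros(n), Family("poisson"),
                          np.array([sp]))

        def npll(beta):
            mu = np.exp(X @ beta)
            return -(family_loglik(Family("poisson"), y, mu)
                     - 0.5 * sp * beta @ S @ beta)

        brute = optimize.minimize(npll, np.zeros(2), method="Nelder-Mead",
                                  options={"xatol": 1e-10, "fatol": 1e-12,
                                           "maxiter": 10_000})
        np.testing.assert_allclose(fit.coef, brute.x, atol=1e-6)

    def test_edf_interpolates_between_rank_and_dimension(self):
        rng = np.random.default_rng(10)
        x = np.sort(rng.uniform(0, 1, 120))
        y = rng.poisson(np.exp(2 + np.sin(2 * np.pi * x))).astype(float)
        block = tps_design(x, k=10)
        lo = pirls_solve([block], y, np.zeros(x.size), Family("poisson"),
                         np.array([1e-6]))
        hi = pirls_solve([block], y, np.zeros(x.size), Family("poisson"),
                         np.array([1e8]))
        assert lo.edf == pytest.approx(10.0, abs=0.2)
        assert hi.edf == pytest.approx(2.0, abs=0.2)  # null space {1, x}

    def test_nonconvergence_raises_fit_error(self):
        # complete separation analogue: infinite MLE drift
        y = np.array([0.0, 0.0, 5.0, 5.0])
        X = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        fit_err = False
        try:
            fit = pirls_solve([linear_block(X)], y, np.zeros(4),
                              Family("poisson"), np.zeros(1), max_iter=25)
            # if it converged, the zero-group coefficient must be huge
            fit_err = fit.coef[0] < -10
        except FitError:
            fit_err = True
        assert fit_err


class TestLamlAndReml:
    def test_laml_blockwise_logdet_scales_with_sp(self):
        rng = np.random.default_rng(12)
        x = np.sort(rng.uniform(0, 1, 80))
        y = rng.poisson(np.exp(2 - x)).astype(float)
        blocks = [tps_design(x, k=8)]
        vals = []
        for sp in (1e-8, 1e-4, 1e0):
            fit = pirls_solve(blocks, y, np.zeros(x.size),
                              Family("poisson"), np.array([sp]))
            vals.append(laml_criterion(fit, blocks, np.array([sp]),
                                       Family("poisson")))
        # as sp -> 0 the log|S|+ term drives the criterion to -infinity,
        # so it must increase strictly over these decades
        assert vals[0] < vals[1] < vals[2]
        assert vals[1] - vals[0] > 1.0

    def test_laml_insensitive_to_other_blocks_scale(self):
        # the penalized log|S|+ of one block must not be swallowed by a
        # much larger smoothing parameter on another block
        rng = np.random.default_rng(13)
        x = np.sort(rng.uniform(0, 1, 100))
        g = np.where(np.arange(100) % 2 == 0, "a", "b")
        from aifcount import factor_smooth_design
        blocks = [tps_design(x, k=8), factor_smooth_design(x, g, k=4)]
        y = rng.poisson(np.exp(2 - x)).astype(float)

        def lam_at(sp_g):
            sp = np.array([sp_g, 1e12])
            fit = pirls_solve(blocks, y, np.zeros(x.size),
                              Family("poisson"), sp)
            return laml_criterion(fit, blocks, sp, Family("poisson"))

        assert abs(lam_at(1e-6) - lam_at(1e-2)) > 1.0

    def test_reml_smooths_noise_but_tracks_signal(self):
        rng = np.random.default_rng(14)
        x = np.sort(rng.uniform(0, 1, 250))
        f = 3.0 + np.sin(2 * np.pi * x)
        y = rng.poisson(np.exp(f)).astype(float)
        fit = reml_optimize([tps_design(x, k=12)], y, np.zeros(x.size),
                            Family("poisson"))
        assert 3.0 < fit.edf < 12.0
        err = np.abs(np.log(fit.mu) - f)
        assert np.median(err) < 0.1

    def test_reml_constant_truth_yields_small_edf(self):
        rng = np.random.default_rng(15)
        x = np.sort(rng.uniform(0, 1, 250))
        y = rng.poisson(np.exp(3.0) * np.ones(x.size)).astype(float)
        fit = reml_optimize([tps_design(x, k=12)], y, np.zeros(x.size),
                            Family("poisson"))
        assert fit.edf < 3.5


class TestDispersionEstimate:
    def test_profile_recovers_psi(self):
        rng = np.random.default_rng(16)
        n = 800
        mu = np.exp(rng.uniform(2, 6, n))
        y = Family("negbin", 0.25).rvs(mu, rng).astype(float)
        X = np.ones((n, 1))
        off = np.log(mu)

        def fit_fn(psi):
            return pirls_solve([linear_block(X)], y, off,
                               Family("negbin", psi), np.zeros(1))

        est = estimate_negbin_dispersion(fit_fn)
        assert est.psi == pytest.approx(0.25, rel=0.25)
        assert not est.effectively_poisson
        # the profiled dispersion adds one effective degree of freedom
        assert est.fit.edf == pytest.approx(est.fit.edf_coef + 1.0)

    def test_poisson_data_flagged_as_boundary(self):
        rng = np.random.default_rng(17)
        n = 500
        mu = np.exp(rng.uniform(2, 5, n))
        y = rng.poisson(mu).astype(float)

        def fit_fn(psi):
            return pirls_solve([linear_block(np.ones((n, 1)))], y,
                               np.log(mu), Family("negbin", psi),
                               np.zeros(1))

        est = estimate_negbin_dispersion(fit_fn)
        assert est.psi < 1e-6
        assert est.effectively_poisson

    def test_model_aic(self):
        y = np.array([1.0, 3, 5, 7])
        fit = pirls_solve([linear_block(np.ones((4, 1)))], y, np.zeros(4),
                          Family("poisson"), np.zeros(1))
        assert model_aic(fit) == pytest.approx(
            -2 * fit.log_likelihood + 2 * fit.edf)


class TestTriExp:
    def test_params_sorted_and_callable(self):
        p = TriExpParams.from_arrays([100, 4000, 800], [0.03, 3.0, 0.3])
        assert p.gamma[0] > p.gamma[1] > p.gamma[2]
        val = p(1.0)
        assert val == pytest.approx(4000 * np.exp(-3) + 800 * np.exp(-0.3)
                                    + 100 * np.exp(-0.03))

    def test_logf_gradient_matches_finite_differences(self):
        t = np.array([0.5, 2.0, 10.0, 60.0])
        p = np.log(np.array([4000.0, 800, 150, 3.0, 0.3, 0.03]))
        logf, G = triexp_logf(t, p)
        eps = 1e-7
        for j in range(6):
            pp = p.copy()
            pp[j] += eps
            fd = (triexp_logf(t, pp)[0] - logf) / eps
            np.testing.assert_allclose(G[:, j], fd, atol=1e-5)

    def test_curve_strip_on_noiseless_curve(self):
        truth = TriExpParams(A=(4000.0, 800.0, 150.0),
                             gamma=(3.0, 0.3, 0.03))
        t = np.geomspace(0.7, 90, 400)
        init = curve_strip_init(t, truth(t))
        # peeling is only a starting guess; each rate within a factor ~3
        for g_hat, g in zip(init.gamma, truth.gamma):
            assert g / 3.5 < g_hat < g * 3.5

    def test_nls_recovers_noiseless_parameters(self):
        truth = TriExpParams(A=(4000.0, 800.0, 150.0),
                             gamma=(3.0, 0.3, 0.03))
        t = np.geomspace(0.7, 90, 300)
        tau = np.full(t.size, 5.0)
        y = truth(t) * tau  # expected counts, no noise
        start = curve_strip_init(t, y / tau)
        fit = nls_poisson_fit(lambda tt, p: triexp_logf(tt, p)[0],
                              lambda tt, p: triexp_logf(tt, p)[1],
                              start, y, t, np.log(tau))
        est = TriExpParams.from_log_params(fit.coef[:6])
        np.testing.assert_allclose(est.A, truth.A, rtol=1e-4)
        np.testing.assert_allclose(est.gamma, truth.gamma, rtol=1e-4)


class TestGaussianReml:
    def test_interpolates_smooth_signal(self):
        rng = np.random.default_rng(20)
        x = np.sort(rng.uniform(0, 1, 150))
        f = 1.0 + 0.5 * np.cos(2 * np.pi * x)
        y = f + rng.normal(0, 0.05, x.size)
        fit = gaussian_reml_fit([tps_design(x, k=10)], y)
        assert np.median(np.abs(fit.mu - f)) < 0.05
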