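"""Skew-t density, sampler and EM estimation."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from skewsort.skewt import (EMConfig, SkewTMixtureModel, SkewTMixtureResults,
                            fit_em, observed_loglik, sample_skewt,
                            skewt_logpdf)


class TestDensity:
    def test_zero_skewness_equals_student_t(self, rng):
        Y = rng.normal(size=(60, 3)) * 2
        mu = np.array([0.3, -0.2, 1.0])
        A = rng.normal(size=(3, 3))
        Sigma = A @ A.T + 3 * np.eye(3)
        lp = skewt_logpdf(Y, mu, Sigma, np.zeros(3), v=5.0)
        ref = stats.multivariate_t(loc=mu, shape=Sigma, df=5.0).logpdf(Y)
        assert np.abs(lp - ref).max() < 1e-10

    def test_univariate_density_integrates_to_one(self):
        def f(y):
            return float(np.exp(skewt_logpdf(
                np.array([[y]]), np.zeros(1), np.eye(1), np.array([2.0]), 5.0))[0])
        val, err = quad(f, -60, 60, limit=300)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_large_dof_limit_is_skew_normal(self, rng):
        # oracle: direct evaluation of the skew-normal density
        # 2 phi_p(x|mu,Sigma) Phi(lam' Sigma^{-1/2} (x-mu))
        p = 3
        mu = np.array([0.5, -1.0, 0.2])
        A = rng.normal(size=(p, p))
        Sigma = A @ A.T + 2 * np.eye(p)
        lam = np.array([2.0, -1.0, 0.5])
        Y = stats.multivariate_normal(mean=mu, cov=Sigma).rvs(100,
                                                              random_state=7)
        w, V = np.linalg.eigh(Sigma)
        inv_sqrt = (V / np.sqrt(w)) @ V.T
        sn = (np.log(2.0)
              + stats.multivariate_normal(mean=mu, cov=Sigma).logpdf(Y)
              + stats.norm.logcdf((Y - mu) @ (inv_sqrt @ lam)))
        st = skewt_logpdf(Y, mu, Sigma, lam, v=1e6)
        assert np.abs((st - sn) / sn).max() < 1e-4

    def test_finite_for_extreme_points(self):
        y = np.array([[1e3, -1e3]])
        lp = skewt_logpdf(y, np.zeros(2), np.eye(2), np.array([5.0, -5.0]), 4.0)
        assert np.isfinite(lp).all()


class TestSampler:
    def test_same_seed_gives_identical_draws(self):
        a = sample_skewt(100, np.zeros(2), np.eye(2), np.array([2.0, 0]), 6, seed=5)
        b = sample_skewt(100, np.zeros(2), np.eye(2), np.array([2.0, 0]), 6, seed=5)
        assert np.array_equal(a, b)

    def test_gaussian_limit_mean(self):
        mu = np.array([1.0, -2.0, 0.5])
        X = sample_skewt(40_000, mu, np.eye(3), np.zeros(3), v=1e6, seed=3)
        assert np.abs(X.mean(axis=0) - mu).max() < 4 / np.sqrt(40_000) * 3

    def test_histogram_matches_density(self):
        """Total-variation distance between sampled and analytic density."""
        lam = np.array([2.0])
        X = sample_skewt(100_000, np.zeros(1), np.eye(1), lam, 5.0, seed=9)[:, 0]
        lo, hi = np.quantile(X, [0.001, 0.999])
        bins = np.linspace(lo, hi, 51)
        hist, _ = np.histogram(X, bins=bins)
        p_emp = hist / X.size
        centers = 0.5 * (bins[1:] + bins[:-1])
        dens = np.exp(skewt_logpdf(centers[:, None], np.zeros(1), np.eye(1),
                                   lam, 5.0))
        p_th = dens * np.diff(bins)
        tv = 0.5 * np.abs(p_emp - p_th).sum()
        assert tv < 0.02


class TestObservedLoglik:
    def test_single_component_reduces_to_sum(self, rng):
        X = rng.normal(size=(20, 2))
        res = _results(pi=[1.0], mu=[[0, 0]], lam=[[1.0, 0]], v=5.0)
        direct = skewt_logpdf(X, np.zeros(2), np.eye(2), np.array([1.0, 0]),
                              5.0).sum()
        assert observed_loglik(X, res) == pytest.approx(direct, abs=1e-10)

    def test_duplicate_components_collapse(self, rng):
        X = rng.normal(size=(15, 2))
        one = _results(pi=[1.0], mu=[[0.5, 0]], lam=[[0.5, 1]], v=7.0)
        two = _results(pi=[0.5, 0.5], mu=[[0.5, 0]] * 2, lam=[[0.5, 1]] * 2,
                       v=7.0)
        assert observed_loglik(X, two) == pytest.approx(
            observed_loglik(X, one), abs=1e-10)

    def test_matches_naive_summation(self, rng):
        X = rng.normal(size=(5, 2))
        res = _results(pi=[0.3, 0.7], mu=[[0, 0], [2, 1]],
                       lam=[[1, 0], [0, -1]], v=4.0)
        naive = 0.0
        for x in X:
            s = 0.0
            for j in range(2):
                s += res.pi[j] * float(np.exp(skewt_logpdf(
                    x[None, :], res.mu[j], res.Sigma[j], res.lam[j], res.v))[0])
            naive += np.log(s)
        assert observed_loglik(X, res) == pytest.approx(naive, abs=1e-10)


def _results(pi, mu, lam, v, Sigma=None):
    pi = np.asarray(pi, float)
    mu = np.asarray(mu, float)
    lam = np.asarray(lam, float)
    g, p = mu.shape
    if Sigma is None:
        Sigma = np.tile(np.eye(p), (g, 1, 1))
    return SkewTMixtureResults(pi=pi, mu=mu, Sigma=np.asarray(Sigma, float),
                               lam=lam, v=v, loglik_trace=np.array([0.0]),
                               converged=True, n_iter=1, n_obs=1)


class TestFit:
    def test_gaussian_data_single_component(self, rng):
        X = rng.normal(loc=[2.0, -1.0], size=(2000, 2))
        init = {"pi": [1.0], "mu": [X.mean(axis=0)], "Sigma": [np.cov(X.T)],
                "lam": [[0.0, 0.0]], "v": 10.0}
        res = fit_em(X, 1, init=init, seed=0)
        assert np.abs(res.mu[0] - X.mean(axis=0)).max() < 0.1
        assert np.linalg.norm(res.lam[0]) < 0.5

    def test_two_component_parameter_recovery(self):
        lam = np.array([3.0, 0.0])
        X1 = sample_skewt(2000, np.zeros(2), np.eye(2), lam, 6.0, seed=2)
        X2 = sample_skewt(2000, np.array([6.0, 0.0]), np.eye(2), lam, 6.0,
                          seed=3)
        X = np.vstack([X1, X2])
        res = fit_em(X, 2, seed=0)
        order = np.argsort(res.mu[:, 0])
        mu_err = np.abs(res.mu[order] -
                        np.array([[0, 0], [6, 0.0]])).max()
        assert mu_err < 0.15
        assert np.abs(res.pi - 0.5).max() < 0.05
        assert np.all(res.lam[:, 0] > 0)  # sign of the skewness recovered

    def test_loglik_trace_is_monotone(self, rng):
        X = np.vstack([rng.normal(size=(300, 2)),
                       rng.normal(loc=[4, 0], size=(300, 2))])
        res = fit_em(X, 2, seed=1)
        d = np.diff(res.loglik_trace)
        assert (d >= -1e-8 * np.maximum(1.0, np.abs(res.loglik_trace[:-1]))).all()

    def test_responsibilities_rows_sum_to_one(self, rng):
        X = rng.normal(size=(200, 2))
        res = fit_em(X, 2, seed=1, cfg=EMConfig(max_iter=20))
        assert np.abs(res.resp.sum(axis=1) - 1.0).max() < 1e-10

    def test_translation_equivariance(self, rng):
        X = rng.normal(size=(600, 2)) * [1.0, 2.0]
        shift = np.array([10.0, -5.0])
        cfg = EMConfig(max_iter=60)
        r0 = fit_em(X, 1, seed=0, cfg=cfg)
        r1 = fit_em(X + shift, 1, seed=0, cfg=cfg)
        assert np.abs(r1.mu[0] - (r0.mu[0] + shift)).max() < 1e-6
        assert np.abs(r1.Sigma - r0.Sigma).max() < 1e-6
        assert np.abs(r1.lam - r0.lam).max() < 1e-5

    def test_lambda_clamped_matches_independent_t_mixture_em(self, rng):
        """Skewness clamped to zero reproduces a plain t-mixture fit.

        Oracle: a from-scratch EM for a two-component multivariate-t
        mixture with fixed dof, run from the same initial parameters.
        """
        X = np.vstack([rng.standard_t(6, size=(400, 2)) * 0.7,
                       rng.standard_t(6, size=(400, 2)) * 0.7 + [5, 0]])
        v = 6.0
        init = {"pi": [0.5, 0.5], "mu": [[0.5, 0.0], [4.5, 0.5]],
                "Sigma": [np.eye(2), np.eye(2)],
                "lam": [[0.0, 0.0], [0.0, 0.0]], "v": v}

        # independent naive t-mixture EM
        pi = np.array(init["pi"], float)
        mu = np.array(init["mu"], float)
        Sig = np.array(init["Sigma"], float)
        p = 2
        for _ in range(400):
            dens = np.stack([stats.multivariate_t(mu[j], Sig[j], df=v).pdf(X)
                             for j in range(2)], axis=1)
            w = dens * pi
            z = w / w.sum(axis=1, keepdims=True)
            for j in range(2):
                R = X - mu[j]
                d = np.einsum("ij,jk,ik->i", R, np.linalg.inv(Sig[j]), R)
                u = (v + p) / (v + d)
                zu = z[:, j] * u
                mu[j] = zu @ X / zu.sum()
                R = X - mu[j]
                Sig[j] = (R * zu[:, None]).T @ R / z[:, j].sum()
            pi = z.mean(axis=0)

        cfg = EMConfig(max_iter=400, v_update_every=10**6,  # dof held at init
                       loglik_tol=None, l_em=1e-6)
        res = fit_em(X, 2, init=init, cfg=cfg, fix_skew_zero=True)
        order = np.argsort(res.mu[:, 0])
        oracle_order = np.argsort(mu[:, 0])
        assert np.abs(res.mu[order] - mu[oracle_order]).max() < 0.02
        assert np.abs(res.pi[order] - pi[oracle_order]).max() < 0.01
        assert np.abs(res.Sigma[order] - Sig[oracle_order]).max() < 0.05
        assert np.abs(res.lam).max() == 0.0

    def test_serialization_roundtrip(self, rng):
        X = rng.normal(size=(200, 2))
        res = fit_em(X, 1, seed=0, cfg=EMConfig(max_iter=15))
        back = SkewTMixtureResults.from_json(res.to_json())
        assert back.g == res.g and back.v == pytest.approx(res.v)
        assert np.allclose(back.mu, res.mu)
        assert np.allclose(back.Sigma, res.Sigma)

    def test_summary_mentions_fit_quality(self, rng):
        X = rng.normal(size=(150, 2))
        res = fit_em(X, 1, seed=0, cfg=EMConfig(max_iter=10))
        text = res.summary()
        assert "log-likelihood" in text and "components: 1" in text
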