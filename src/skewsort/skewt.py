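"""Finite mixtures of multivariate skew-t distributions, fitted by EM.

The skew-t density used here is

    ST_p(y | mu, Sigma, lam, v)
        = 2 t_p(y | mu, Sigma, v)
          * T( sqrt((v+p)/(v+d)) lam' Sigma^{-1/2} (y-mu) | v+p )

with ``d`` the Mahalanobis form ``(y-mu)' Sigma^{-1} (y-mu)``,
``Sigma^{-1/2}`` the symmetric inverse square root, ``t_p`` the p-variate
Student-t density and ``T`` the univariate Student-t CDF.  It arises from
the scale-mixture construction ``Y = mu + U^{-1/2} Z`` with
``U ~ Gamma(v/2, v/2)`` and ``Z`` skew-normal; heavy tails absorb outliers,
the skewness vector absorbs asymmetric clusters (e.g. amplitude truncation
of near-threshold units).

Estimation follows the skew-normal/independent EM scheme: internally each
component is carried in the (Delta, Gamma) parameterisation

    Delta = Sigma^{1/2} delta,  delta = lam / sqrt(1 + lam'lam),
    Gamma = Sigma - Delta Delta',

under which the conditional expectations of the latent scale U and the
latent truncated-normal skewing variable have closed forms and the M-step
updates are closed-form weighted least squares.  The shared degrees of
freedom ``v`` are updated by bounded one-dimensional maximisation of the
observed log-likelihood, so the observed log-likelihood is monotone
non-decreasing over iterations.

The public surface is statsmodels-like: :class:`SkewTMixtureModel` wraps
the data, ``fit`` returns :class:`SkewTMixtureResults` with estimates,
diagnostics, ``summary()``, prediction and simulation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import optimize
from scipy.special import betainc, gammaln, logsumexp

logger = logging.getLogger(__name__)

_LOG2PI = math.log(2.0 * math.pi)


def _t_logcdf(x: np.ndarray, df: float) -> np.ndarray:
    """Log CDF of the standard Student-t, vectorised.

    Uses the regularised incomplete beta representation
    ``T(x|v) = 1 - I_z(v/2, 1/2)/2`` with ``z = v/(v + x^2)`` for ``x >= 0``
    (mirrored for ``x < 0``).  The polynomial tails of the t distribution
    keep the beta term representable far into the tail, so no asymptotic
    branch is needed.
    """
    x = np.asarray(x, float)
    z = df / (df + x * x)
    tail = 0.5 * betainc(df / 2.0, 0.5, z)   # P(T > |x|)
    with np.errstate(divide="ignore"):
        neg = np.log(tail)
    pos = np.log1p(-tail)
    return np.where(x < 0, neg, pos)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class SkewTComponent:
    """One mixture component: location, dispersion, skewness, weight."""

    mu: np.ndarray
    Sigma: np.ndarray
    lam: np.ndarray
    pi_j: float


@dataclass
class EMConfig:
    """EM controls.

    l_em : stop when the largest absolute parameter change (over pi, mu,
        Sigma, lam and v) drops below this.
    v_bounds : search interval for the shared degrees of freedom (kept
        above 2 so component covariances stay finite).
    reg_eps : ridge scale (times trace/p) applied to a dispersion matrix
        whose condition number exceeds 1e10.
    criterion : 'abs' (default) or 'rel' parameter-change stopping rule.
    v_update_every : iterations between degrees-of-freedom updates (the
        1-D search is the most expensive step and v moves slowly).
    loglik_tol : additional stop on the relative observed log-likelihood
        improvement per iteration (the likelihood plateaus long before
        weakly identified parameters stop drifting, so a parameter-only
        rule can spin on a ridge); None disables it.
    """

    l_em: float = 1e-3
    max_iter: int = 500
    v_bounds: tuple[float, float] = (2.1, 100.0)
    reg_eps: float = 1e-6
    seed: int | None = None
    criterion: str = "abs"
    v_update_every: int = 5
    loglik_tol: float | None = 1e-5

    def validate(self) -> None:
        if self.l_em <= 0:
            raise ValueError("l_em must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.criterion not in ("abs", "rel"):
            raise ValueError("criterion must be 'abs' or 'rel'")


# ---------------------------------------------------------------------------
# linear-algebra helpers
# ---------------------------------------------------------------------------

def _sym_eig(Sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Sigma = 0.5 * (Sigma + Sigma.T)
    w, V = np.linalg.eigh(Sigma)
    return w, V


def _regularize(Sigma: np.ndarray, reg_eps: float) -> np.ndarray:
    """Ridge a dispersion matrix if it is near-singular."""
    p = Sigma.shape[0]
    w, V = _sym_eig(Sigma)
    if w[-1] <= 0:
        raise np.linalg.LinAlgError("dispersion matrix not positive definite")
    if w[0] <= 0 or w[-1] / max(w[0], 1e-300) > 1e10:
        ridge = reg_eps * np.trace(Sigma) / p
        Sigma = Sigma + ridge * np.eye(p)
    return 0.5 * (Sigma + Sigma.T)


def _inv_sqrt_logdet(Sigma: np.ndarray) -> tuple[np.ndarray, float]:
    """Symmetric inverse square root and log-determinant."""
    w, V = _sym_eig(Sigma)
    if w[0] <= 0:
        raise np.linalg.LinAlgError("dispersion matrix not positive definite")
    inv_sqrt = (V / np.sqrt(w)) @ V.T
    return inv_sqrt, float(np.log(w).sum())


def _lam_to_delta(lam: np.ndarray, Sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(Delta, Gamma) from (lam, Sigma)."""
    lam = np.asarray(lam, float)
    delta = lam / math.sqrt(1.0 + float(lam @ lam))
    w, V = _sym_eig(Sigma)
    sqrt_S = (V * np.sqrt(np.maximum(w, 0))) @ V.T
    Delta = sqrt_S @ delta
    Gamma = Sigma - np.outer(Delta, Delta)
    return Delta, Gamma


def _delta_to_lam(Delta: np.ndarray, Gamma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(lam, Sigma) from (Delta, Gamma)."""
    Sigma = Gamma + np.outer(Delta, Delta)
    inv_sqrt, _ = _inv_sqrt_logdet(Sigma)
    delta_S = inv_sqrt @ Delta          # = Sigma^{-1/2} Delta
    s2 = 1.0 - float(delta_S @ delta_S)
    s2 = max(s2, 1e-10)
    lam = delta_S / math.sqrt(s2)
    return lam, Sigma


# ---------------------------------------------------------------------------
# densities and sampling
# ---------------------------------------------------------------------------

def _mvt_logpdf(X: np.ndarray, mu: np.ndarray, inv_sqrt: np.ndarray,
                logdet: float, v: float) -> tuple[np.ndarray, np.ndarray]:
    """p-variate Student-t log-density and Mahalanobis distances."""
    X = np.atleast_2d(X)
    p = X.shape[1]
    Z = (X - mu) @ inv_sqrt
    d = np.einsum("ij,ij->i", Z, Z)
    lp = (gammaln((v + p) / 2.0) - gammaln(v / 2.0)
          - 0.5 * p * math.log(v * math.pi) - 0.5 * logdet
          - 0.5 * (v + p) * np.log1p(d / v))
    return lp, d


def skewt_logpdf(y: np.ndarray, mu: np.ndarray, Sigma: np.ndarray,
                 lam: np.ndarray, v: float) -> np.ndarray:
    """Log-density of the multivariate skew-t at one or more points.

    With ``lam = 0`` this is exactly the p-variate Student-t log-density
    (the CDF factor equals 1/2 and cancels the leading 2).
    """
    y = np.atleast_2d(np.asarray(y, float))
    mu = np.asarray(mu, float)
    Sigma = np.atleast_2d(np.asarray(Sigma, float))
    lam = np.asarray(lam, float)
    if v <= 0:
        raise ValueError("v must be > 0")
    p = y.shape[1]
    inv_sqrt, logdet = _inv_sqrt_logdet(Sigma)
    lt, d = _mvt_logpdf(y, mu, inv_sqrt, logdet, v)
    A = (y - mu) @ (inv_sqrt @ lam)
    arg = A * np.sqrt((v + p) / (v + d))
    return math.log(2.0) + lt + _t_logcdf(arg, v + p)


def sample_skewt(n: int, mu: np.ndarray, Sigma: np.ndarray, lam: np.ndarray,
                 v: float, seed=None) -> np.ndarray:
    """Draw from the skew-t via its scale-mixture representation.

    ``Y = mu + U^{-1/2} (Delta |t0| + Gamma^{1/2} z)`` with
    ``U ~ Gamma(v/2, v/2)``, ``t0 ~ N(0,1)``, ``z ~ N(0, I)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    mu = np.asarray(mu, float)
    p = mu.size
    Delta, Gamma = _lam_to_delta(np.asarray(lam, float), np.atleast_2d(Sigma))
    w, V = _sym_eig(Gamma)
    Gh = (V * np.sqrt(np.maximum(w, 0))) @ V.T
    u = rng.gamma(shape=v / 2.0, scale=2.0 / v, size=n)
    t0 = np.abs(rng.standard_normal(n))
    z = rng.standard_normal((n, p))
    Y = mu + (t0[:, None] * Delta + z @ Gh) / np.sqrt(u)[:, None]
    return Y


# ---------------------------------------------------------------------------
# Results object
# ---------------------------------------------------------------------------

@dataclass
class SkewTMixtureResults:
    """Fitted mixture: estimates, diagnostics and prediction methods."""

    pi: np.ndarray            # (g,)
    mu: np.ndarray            # (g, p)
    Sigma: np.ndarray         # (g, p, p)
    lam: np.ndarray           # (g, p)
    v: float
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    n_obs: int
    resp: np.ndarray | None = None   # (n, g) responsibilities on training data
    events: list[str] = field(default_factory=list)

    @property
    def g(self) -> int:
        return int(self.pi.size)

    @property
    def p(self) -> int:
        return int(self.mu.shape[1])

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    @property
    def n_parameters(self) -> int:
        p = self.p
        per_comp = p + p + p * (p + 1) // 2   # mu, lam, Sigma
        return self.g * per_comp + (self.g - 1) + 1

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_parameters * math.log(self.n_obs)

    @property
    def components(self) -> list[SkewTComponent]:
        return [SkewTComponent(self.mu[j], self.Sigma[j], self.lam[j],
                               float(self.pi[j])) for j in range(self.g)]

    # -- densities ---------------------------------------------------------
    def component_logpdf(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        out = np.empty((X.shape[0], self.g))
        for j in range(self.g):
            out[:, j] = skewt_logpdf(X, self.mu[j], self.Sigma[j],
                                     self.lam[j], self.v)
        return out

    def logpdf(self, X: np.ndarray) -> np.ndarray:
        lp = self.component_logpdf(X) + np.log(self.pi)[None, :]
        return logsumexp(lp, axis=1)

    def score(self, X: np.ndarray) -> float:
        """Observed-data log-likelihood of ``X`` under the fitted mixture."""
        return float(self.logpdf(X).sum())

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        lp = self.component_logpdf(X) + np.log(self.pi)[None, :]
        return np.exp(lp - logsumexp(lp, axis=1, keepdims=True))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """MAP component labels; ties break toward the smaller index."""
        return np.argmax(self.predict_proba(X), axis=1)

    def sample(self, n: int, seed=None) -> tuple[np.ndarray, np.ndarray]:
        rng = np.random.default_rng(seed)
        counts = rng.multinomial(n, self.pi)
        chunks, labels = [], []
        for j, c in enumerate(counts):
            if c:
                chunks.append(sample_skewt(c, self.mu[j], self.Sigma[j],
                                           self.lam[j], self.v, seed=rng))
                labels.append(np.full(c, j))
        X = np.vstack(chunks)
        y = np.concatenate(labels)
        order = rng.permutation(n)
        return X[order], y[order]

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Skew-t mixture results",
            "=" * 58,
            f"components: {self.g}    dims: {self.p}    n_obs: {self.n_obs}",
            f"log-likelihood: {self.loglik:.3f}    BIC: {self.bic:.3f}",
            f"dof (v): {self.v:.3f}    iterations: {self.n_iter}"
            f"    converged: {self.converged}",
            "-" * 58,
        ]
        for j in range(self.g):
            lines.append(
                f"comp {j}: pi={self.pi[j]:.4f}  "
                f"mu={np.array2string(self.mu[j], precision=3)}  "
                f"lam={np.array2string(self.lam[j], precision=3)}"
            )
        if self.events:
            lines.append("-" * 58)
            lines.extend(f"note: {e}" for e in self.events)
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "g": self.g, "v": self.v,
            "components": [{
                "pi": float(self.pi[j]),
                "mu": self.mu[j].tolist(),
                "Sigma": self.Sigma[j].tolist(),
                "lam": self.lam[j].tolist(),
            } for j in range(self.g)],
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "n_obs": self.n_obs,
        })
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text: str) -> "SkewTMixtureResults":
        d = json.loads(text)
        comps = d["components"]
        return cls(
            pi=np.array([c["pi"] for c in comps]),
            mu=np.array([c["mu"] for c in comps]),
            Sigma=np.array([c["Sigma"] for c in comps]),
            lam=np.array([c["lam"] for c in comps]),
            v=float(d["v"]),
            loglik_trace=np.array([d["loglik"]]),
            converged=bool(d["converged"]),
            n_iter=int(d["n_iter"]),
            n_obs=int(d["n_obs"]),
        )


def observed_loglik(X: np.ndarray, results: SkewTMixtureResults) -> float:
    """Sum over points of the log mixture density (log-sum-exp stabilised)."""
    return results.score(X)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class SkewTMixtureModel:
    """A g-component multivariate skew-t mixture to be fitted to data.

    Parameters
    ----------
    X : (n, p) array
        Observations (e.g. PCA scores of spike waveforms).
    n_components : int
        Number of mixture components ``g``.
    fix_skew_zero : bool
        Clamp every skewness vector to zero; the fit is then a mixture of
        multivariate Student-t distributions (the symmetric baseline).
    config : EMConfig
        Stopping rule, bounds and regularisation.
    """

    def __init__(self, X: np.ndarray, n_components: int, *,
                 fix_skew_zero: bool = False, config: EMConfig | None = None):
        self.X = np.atleast_2d(np.asarray(X, float))
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        self.n, self.p = self.X.shape
        self.g = int(n_components)
        if self.g < 1:
            raise ValueError("n_components must be >= 1")
        if self.n <= self.g * (self.p + 1):
            raise ValueError("need n > g*(p+1) observations")
        self.fix_skew_zero = bool(fix_skew_zero)
        self.config = config or EMConfig()
        self.config.validate()

    # -- initialisation ----------------------------------------------------
    def _default_init(self, seed=None) -> dict:
        from .select import init_from_fcm  # local import avoids a cycle
        return init_from_fcm(self.X, self.g, seed=seed)

    @staticmethod
    def _check_init(init: dict, g: int, p: int) -> dict:
        need = {"pi", "mu", "Sigma", "lam", "v"}
        missing = need - set(init)
        if missing:
            raise ValueError(f"init missing {sorted(missing)}")
        out = {
            "pi": np.asarray(init["pi"], float).reshape(g),
            "mu": np.asarray(init["mu"], float).reshape(g, p),
            "Sigma": np.asarray(init["Sigma"], float).reshape(g, p, p),
            "lam": np.asarray(init["lam"], float).reshape(g, p),
            "v": float(init["v"]),
        }
        out["pi"] = out["pi"] / out["pi"].sum()
        return out

    # -- E step ------------------------------------------------------------
    def _geometry(self, mu, Sigma, lam):
        """Per-component quantities independent of v.

        Returns ``logdet`` (g,), Mahalanobis distances ``d`` (n, g) and the
        skewing linear forms ``A = lam' Sigma^{-1/2} (x - mu)`` (n, g).
        """
        X, n, g = self.X, self.n, len(mu)
        logdet = np.empty(g)
        d = np.empty((n, g))
        A = np.empty((n, g))
        for j in range(g):
            inv_sqrt, ld = _inv_sqrt_logdet(Sigma[j])
            Z = (X - mu[j]) @ inv_sqrt
            logdet[j] = ld
            d[:, j] = np.einsum("ij,ij->i", Z, Z)
            A[:, j] = Z @ lam[j]
        return logdet, d, A

    def _logf_from_geometry(self, logdet, d, A, v):
        """Component log-densities (n, g) from cached geometry."""
        p = self.p
        lt = (gammaln((v + p) / 2.0) - gammaln(v / 2.0)
              - 0.5 * p * math.log(v * math.pi) - 0.5 * logdet[None, :]
              - 0.5 * (v + p) * np.log1p(d / v))
        arg = A * np.sqrt((v + p) / (v + d))
        return math.log(2.0) + lt + _t_logcdf(arg, v + p)

    def _estep(self, pi, mu, Sigma, lam, v, geometry=None):
        """Responsibilities and latent moments.

        Returns ``z`` (n, g) responsibilities, the conditional expectations
        ``e1 = E[U|y,j]``, ``e2 = E[U T|y,j]``, ``e3 = E[U T^2|y,j]`` of the
        latent Gamma scale U and truncated-normal skewing variable T, and the
        observed log-likelihood at the current parameters.
        """
        p = self.p
        logdet, d, A = geometry if geometry is not None else \
            self._geometry(mu, Sigma, lam)
        alpha = (v + p) / 2.0
        beta = (v + d) / 2.0
        M = A * np.sqrt((v + p) / (v + d))
        logT = _t_logcdf(M, v + p)
        lt = (gammaln(alpha) - gammaln(v / 2.0)
              - 0.5 * p * math.log(v * math.pi) - 0.5 * logdet[None, :]
              - 0.5 * (v + p) * np.log1p(d / v))
        logf = math.log(2.0) + lt + logT
        logw = logf + np.log(pi)[None, :]
        norm = logsumexp(logw, axis=1, keepdims=True)
        z = np.exp(logw - norm)

        # latent moments are only consumed with weight z in the M step, so
        # skip the expensive t-CDF where the responsibility is negligible
        active = z > 1e-10
        logT2 = np.zeros_like(logT)
        arg2 = A * np.sqrt((v + p + 2.0) / (v + d))
        logT2[active] = _t_logcdf(arg2[active], v + p + 2.0)
        e1 = (alpha / beta) * np.exp(logT2 - logT)
        logW = (-0.5 * _LOG2PI + gammaln(alpha + 0.5) - gammaln(alpha)
                + alpha * np.log(beta) - (alpha + 0.5) * np.log(beta + 0.5 * A**2)
                - logT)
        W = np.exp(logW)
        s2 = 1.0 / (1.0 + np.einsum("jk,jk->j", lam, lam))  # (g,)
        s_T = np.sqrt(s2)
        m_T = s_T[None, :] * A
        e2 = m_T * e1 + s_T[None, :] * W
        e3 = m_T**2 * e1 + s2[None, :] + m_T * s_T[None, :] * W
        e1[~active] = 1.0
        e2[~active] = 0.0
        e3[~active] = 1.0
        return z, e1, e2, e3, float(norm.sum())

    # -- v profile likelihood ----------------------------------------------
    def _loglik_cached(self, pi, logdet, d, A, v) -> float:
        logf = self._logf_from_geometry(logdet, d, A, v)
        return float(logsumexp(logf + np.log(pi)[None, :], axis=1).sum())

    def _update_v(self, pi, geometry, v) -> tuple[float, float]:
        """Bounded 1-D maximisation of the observed log-likelihood over v.

        Works on the cached geometry (distances and skew forms do not depend
        on v), and never returns a worse v than the current one.  Returns
        (v_new, loglik at v_new).
        """
        lo, hi = self.config.v_bounds
        logdet, d, A = geometry
        # warm bracket around the current v: v moves slowly between updates
        blo = max(lo, v / 1.8)
        bhi = min(hi, v * 1.8)
        res = optimize.minimize_scalar(
            lambda u: -self._loglik_cached(pi, logdet, d, A, u),
            bounds=(blo, bhi), method="bounded",
            options={"xatol": 5e-2},
        )
        cur = self._loglik_cached(pi, logdet, d, A, v)
        if res.success and -res.fun > cur:
            return float(res.x), float(-res.fun)
        return float(v), cur

    # -- fit ---------------------------------------------------------------
    def fit(self, init: dict | None = None, seed=None) -> SkewTMixtureResults:
        """Run EM from ``init`` (or a fuzzy-c-means start) to convergence.

        Components whose weight collapses below 1/n or whose dispersion
        cannot be kept positive definite are removed and the fit continues
        with one fewer component (recorded in ``results.events``).
        """
        cfg = self.config
        if init is None:
            init = self._default_init(seed=seed if seed is not None else cfg.seed)
        init = self._check_init(init, self.g, self.p)
        pi = init["pi"].copy()
        mu = init["mu"].copy()
        Sigma = np.array([_regularize(S, cfg.reg_eps) for S in init["Sigma"]])
        lam = init["lam"].copy()
        if self.fix_skew_zero:
            lam = np.zeros_like(lam)
        v = float(init["v"])

        events: list[str] = []
        trace: list[float] = []
        converged = False
        it = 0
        X = self.X
        geometry = self._geometry(mu, Sigma, lam)
        while it < cfg.max_iter:
            it += 1
            old = (pi.copy(), mu.copy(), Sigma.copy(), lam.copy(), v)

            z, e1, e2, e3, ll = self._estep(pi, mu, Sigma, lam, v,
                                            geometry=geometry)
            if (cfg.loglik_tol is not None and trace
                    and ll - trace[-1] < cfg.loglik_tol * abs(trace[-1])):
                trace.append(ll)
                converged = True
                break
            trace.append(ll)

            # component collapse check (on responsibilities)
            sz = z.sum(axis=0)
            weak = np.flatnonzero(sz < 1.0)
            if weak.size and len(pi) > 1:
                j = int(weak[0])
                events.append(f"removed collapsed component {j} (iter {it})")
                logger.warning("EM: %s", events[-1])
                keep = np.arange(len(pi)) != j
                pi, mu, Sigma, lam = pi[keep], mu[keep], Sigma[keep], lam[keep]
                pi = pi / pi.sum()
                trace.pop()  # value referred to the pre-collapse model
                geometry = self._geometry(mu, Sigma, lam)
                continue

            # M step (Delta/Gamma parameterisation per component)
            g = len(pi)
            new_mu = np.empty_like(mu)
            new_Sigma = np.empty_like(Sigma)
            new_lam = np.empty_like(lam)
            drop: list[int] = []
            Deltas = np.empty_like(mu)
            for j in range(g):
                Delta_j, _ = _lam_to_delta(lam[j], Sigma[j])
                zj, e1j, e2j, e3j = z[:, j], e1[:, j], e2[:, j], e3[:, j]
                sz_j = zj.sum()
                mu_j = ((zj * e1j) @ X - (zj @ e2j) * Delta_j) / (zj @ e1j)
                R = X - mu_j
                if self.fix_skew_zero:
                    Delta_new = np.zeros(self.p)
                else:
                    Delta_new = ((zj * e2j) @ R) / (zj @ e3j)
                S1 = (R * (zj * e1j)[:, None]).T @ R
                S2 = np.outer((zj * e2j) @ R, Delta_new)
                S3 = (zj @ e3j) * np.outer(Delta_new, Delta_new)
                Gamma_j = (S1 - S2 - S2.T + S3) / sz_j
                Gamma_j = 0.5 * (Gamma_j + Gamma_j.T)
                try:
                    Gamma_j = _regularize(Gamma_j, cfg.reg_eps)
                    lam_j, Sigma_j = _delta_to_lam(Delta_new, Gamma_j)
                    Sigma_j = _regularize(Sigma_j, cfg.reg_eps)
                except np.linalg.LinAlgError:
                    drop.append(j)
                    continue
                new_mu[j] = mu_j
                new_Sigma[j] = Sigma_j
                new_lam[j] = lam_j if not self.fix_skew_zero else np.zeros(self.p)
                Deltas[j] = Delta_new
            new_pi = sz / self.n

            if drop:
                keep = np.array([j for j in range(g) if j not in drop])
                events.append(f"removed singular component(s) {drop} (iter {it})")
                logger.warning("EM: %s", events[-1])
                pi = new_pi[keep] / new_pi[keep].sum()
                mu, Sigma, lam = new_mu[keep], new_Sigma[keep], new_lam[keep]
                geometry = self._geometry(mu, Sigma, lam)
                continue

            pi, mu, Sigma, lam = new_pi, new_mu, new_Sigma, new_lam
            geometry = self._geometry(mu, Sigma, lam)
            if it % cfg.v_update_every == 0:
                v, _ = self._update_v(pi, geometry, v)

            # stop when the largest parameter change falls below l_em
            if old[0].size == pi.size:
                diffs = [np.abs(old[0] - pi).max(),
                         np.abs(old[1] - mu).max(),
                         np.abs(old[2] - Sigma).max(),
                         np.abs(old[3] - lam).max(),
                         abs(old[4] - v)]
                change = max(diffs)
                if cfg.criterion == "rel":
                    scale = max(1.0, np.abs(old[1]).max(), np.abs(old[2]).max())
                    change = change / scale
                if change < cfg.l_em:
                    converged = True
                    break

        # final log-likelihood at the returned parameters
        trace.append(self._loglik_cached(pi, *self._geometry(mu, Sigma, lam), v))
        resp = self._responsibilities(pi, mu, Sigma, lam, v)
        return SkewTMixtureResults(
            pi=pi, mu=mu, Sigma=Sigma, lam=lam, v=v,
            loglik_trace=np.asarray(trace), converged=converged, n_iter=it,
            n_obs=self.n, resp=resp, events=events,
        )

    def _responsibilities(self, pi, mu, Sigma, lam, v) -> np.ndarray:
        lp = np.empty((self.n, len(pi)))
        for j in range(len(pi)):
            lp[:, j] = skewt_logpdf(self.X, mu[j], Sigma[j], lam[j], v)
        lw = lp + np.log(pi)[None, :]
        return np.exp(lw - logsumexp(lw, axis=1, keepdims=True))


def fit_em(X: np.ndarray, g: int, init: dict | None = None,
           cfg: EMConfig | None = None, *, fix_skew_zero: bool = False,
           seed=None) -> SkewTMixtureResults:
    """Functional wrapper: fit a g-component skew-t mixture to ``X``."""
    model = SkewTMixtureModel(X, g, fix_skew_zero=fix_skew_zero, config=cfg)
    return model.fit(init=init, seed=seed)
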