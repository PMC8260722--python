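"""Automatic choice of the number of mixture components.

The search fits the mixture once at ``g_max`` (seeded by fuzzy c-means) and
walks backwards to ``g_min``, initialising each fit by deleting the
lowest-weight component of the previous one.  Each examined ``g`` receives a
selection score ``L_g``; the returned order maximises it.

The default score is BIC (reported negated so larger is better): the raw
observed likelihood never decreases with g, and the entropy-penalised
complete-data variant collapses to one component whenever clusters overlap
appreciably, so BIC is the one of the three that selects interior orders on
realistic data; all three are available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .fcm import fuzzy_c_means, fuzzy_c_means_restarts
from .skewt import EMConfig, SkewTMixtureModel, SkewTMixtureResults

logger = logging.getLogger(__name__)


@dataclass
class SearchConfig:
    """Backward-search controls.

    score : 'bic' (negated BIC, so larger is better; default), 'loglik'
        (raw observed log-likelihood; monotone in g, so it degenerates to
        g_max) or 'complete' (observed loglik minus assignment entropy; very
        conservative on overlapping clusters).
    early_stop : stop descending once the score of the last fit drops below
        the best seen so far (off by default).
    max_fit_points : if set, each EM runs on a seeded random subsample of
        at most this many points (labels and posteriors are still computed
        for every point); caps the cost on long recordings.
    """

    g_min: int = 1
    g_max: int = 9
    early_stop: bool = False
    score: str = "bic"
    v_init: float = 10.0
    fix_skew_zero: bool = False
    max_fit_points: int | None = None

    def validate(self) -> None:
        if not (1 <= self.g_min <= self.g_max):
            raise ValueError("need 1 <= g_min <= g_max")
        if self.score not in ("complete", "loglik", "bic"):
            raise ValueError("score must be 'complete', 'loglik' or 'bic'")
        if self.max_fit_points is not None and self.max_fit_points < 10:
            raise ValueError("max_fit_points too small")


@dataclass
class SearchResult:
    """Outcome of the backward search over g."""

    models: dict[int, SkewTMixtureResults]
    L_g: dict[int, float]
    g_opt: int
    labels: np.ndarray
    posteriors: np.ndarray

    @property
    def best(self) -> SkewTMixtureResults:
        return self.models[self.g_opt]


def moments_from_partition(X: np.ndarray, U: np.ndarray, centers: np.ndarray,
                           v_init: float = 10.0) -> dict:
    """Mixture start values from a (possibly fuzzy) partition.

    Per component j: the dispersion is the membership-weighted scatter
    ``sum_i U_ij (x_i - mu_j)(x_i - mu_j)' / sum_i U_ij``; the skewness
    start is the element-wise sign of the membership-weighted third central
    moment (entries in {-1, 0, +1}, sign(0) = 0); the weight is the
    normalised membership mass.  With a binary U the dispersion is exactly
    the per-cluster maximum-likelihood covariance.
    """
    X = np.atleast_2d(np.asarray(X, float))
    U = np.atleast_2d(np.asarray(U, float))
    centers = np.atleast_2d(np.asarray(centers, float))
    n, p = X.shape
    g = centers.shape[0]
    pi = U.sum(axis=0) / n
    Sigma = np.empty((g, p, p))
    lam = np.empty((g, p))
    for j in range(g):
        R = X - centers[j]
        w = U[:, j]
        Sigma[j] = (R * w[:, None]).T @ R / w.sum()
        # keep the start positive definite even for degenerate partitions
        tr = np.trace(Sigma[j]) / p
        Sigma[j] += max(tr, 1e-12) * 1e-8 * np.eye(p)
        lam[j] = np.sign(np.round(w @ (R**3), 12))
    return {"pi": pi, "mu": centers.copy(), "Sigma": Sigma, "lam": lam,
            "v": float(v_init)}


def init_from_fcm(X: np.ndarray, g: int, seed=None, v_init: float = 10.0,
                  n_init: int = 3) -> dict:
    """Moment-style initial parameters from a fuzzy c-means partition.

    Runs a few seeded FCM restarts and initialises from the best objective.
    """
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    if n <= g:
        raise ValueError("need n > g")
    res = fuzzy_c_means_restarts(X, g, n_init=n_init, seed=seed)
    return moments_from_partition(X, res.U, res.centers, v_init=v_init)


def prune_component(results: SkewTMixtureResults) -> dict:
    """Initial parameters with the lowest-weight component removed.

    Ties on the minimum weight remove the smallest index; remaining weights
    are renormalised; the fitted degrees of freedom carry forward.
    """
    if results.g < 2:
        raise ValueError("cannot prune a single-component model")
    j = int(np.argmin(results.pi))
    keep = np.arange(results.g) != j
    pi = results.pi[keep]
    return {
        "pi": pi / pi.sum(),
        "mu": results.mu[keep],
        "Sigma": results.Sigma[keep],
        "lam": results.lam[keep],
        "v": results.v,
    }


def _assignment_entropy(resp: np.ndarray) -> float:
    z = np.clip(resp, 1e-300, 1.0)
    return float(-(resp * np.log(z)).sum())


def _score(results: SkewTMixtureResults, kind: str) -> float:
    if kind == "loglik":
        return results.loglik
    if kind == "bic":
        return -results.bic
    # expected complete-data log-likelihood over assignments:
    # loglik - H(assignments | data)
    return results.loglik - _assignment_entropy(results.resp)


def backward_search(
    X: np.ndarray,
    cfg: SearchConfig | None = None,
    em: EMConfig | None = None,
    seed=None,
) -> SearchResult:
    """Fit at g_max, prune backwards to g_min, pick the score-maximising g.

    ``g_max`` is lowered automatically (and logged) when the sample is too
    small for the requested order.  Identical data and seeds give identical
    results.
    """
    cfg = cfg or SearchConfig()
    cfg.validate()
    em = em or EMConfig()
    X_all = np.atleast_2d(np.asarray(X, float))
    X = X_all
    if cfg.max_fit_points is not None and X_all.shape[0] > cfg.max_fit_points:
        rng = np.random.default_rng(seed)
        sub = rng.choice(X_all.shape[0], cfg.max_fit_points, replace=False)
        X = X_all[np.sort(sub)]
    n, p = X.shape

    g_max = cfg.g_max
    while g_max > cfg.g_min and n <= g_max * (p + 1):
        g_max -= 1
    if g_max != cfg.g_max:
        logger.warning("backward_search: g_max lowered to %d for n=%d, p=%d",
                       g_max, n, p)
    if n <= g_max * (p + 1):
        raise ValueError("too few observations for the requested search range")

    models: dict[int, SkewTMixtureResults] = {}
    scores: dict[int, float] = {}
    errors: dict[int, str] = {}
    init = init_from_fcm(X, g_max, seed=seed, v_init=cfg.v_init)
    g = g_max
    while g >= cfg.g_min:
        model = SkewTMixtureModel(X, g, fix_skew_zero=cfg.fix_skew_zero,
                                  config=em)
        try:
            res = model.fit(init=init)
        except Exception as exc:  # pragma: no cover - defensive per-g record
            errors[g] = str(exc)
            logger.warning("backward_search: fit at g=%d failed: %s", g, exc)
            if g == cfg.g_min:
                break
            g -= 1
            init = init_from_fcm(X, g, seed=seed, v_init=cfg.v_init)
            continue
        g_fit = res.g  # collapse inside EM may return fewer components
        models[g_fit] = res
        scores[g_fit] = _score(res, cfg.score)
        if g_fit <= cfg.g_min:
            break
        # optional early termination: while descending in g, a drop in the
        # score relative to the best already seen ends the sweep
        if cfg.early_stop and scores[g_fit] < max(scores.values()):
            break
        init = prune_component(res)
        g = g_fit - 1
    if not models:
        raise RuntimeError(f"all fits failed: {errors}")

    g_opt = max(sorted(scores), key=lambda k: scores[k])
    best = models[g_opt]
    posteriors = best.predict_proba(X_all)
    labels = np.argmax(posteriors, axis=1)
    return SearchResult(models=models, L_g=scores, g_opt=g_opt,
                        labels=labels, posteriors=posteriors)


def assign_labels(results: SkewTMixtureResults, X: np.ndarray) -> np.ndarray:
    """MAP cluster index per point; ties break toward the smaller index."""
    return results.predict(X)
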