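"""Fuzzy c-means clustering, used to seed the mixture EM at g = g_max."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class FCMResult:
    centers: np.ndarray   # (g, p)
    U: np.ndarray         # (n, g) fuzzy partition, rows sum to 1
    n_iter: int
    converged: bool
    objective: float = float("inf")


def fuzzy_c_means(
    X: np.ndarray,
    g: int,
    *,
    fuzzifier: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int | None = None,
) -> FCMResult:
    """Standard fuzzy c-means with random-row center initialisation.

    Alternates membership and center updates until the relative improvement
    of the FCM objective drops below ``tol`` (centers and memberships can
    creep along flat directions long after the objective has settled, so
    the objective is the robust stopping quantity).  On non-convergence the
    caller may retry with a different seed.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if g < 1 or n <= g:
        raise ValueError("need n > g >= 1")
    rng = np.random.default_rng(seed)
    centers = X[rng.choice(n, size=g, replace=False)]
    m = float(fuzzifier)
    if m <= 1:
        raise ValueError("fuzzifier must be > 1")
    converged = False
    it = 0
    J_prev = np.inf
    for it in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-300)
        inv = d2 ** (-1.0 / (m - 1.0))
        U = inv / inv.sum(axis=1, keepdims=True)
        Um = U**m
        centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
        J = float((Um * d2).sum())
        if abs(J_prev - J) < tol * max(abs(J), 1e-300):
            converged = True
            break
        J_prev = J
    return FCMResult(centers=centers, U=U, n_iter=it, converged=converged,
                     objective=J)


def fuzzy_c_means_restarts(X: np.ndarray, g: int, n_init: int = 3,
                           seed=None, **kwargs) -> FCMResult:
    """Best-of-``n_init`` seeded FCM runs (lowest objective wins).

    FCM is sensitive to its random center draw; a few cheap restarts make
    the downstream mixture initialisation markedly more reproducible.
    """
    ss = np.random.SeedSequence(seed)
    best: FCMResult | None = None
    for child in ss.spawn(max(1, n_init)):
        res = fuzzy_c_means(X, g, seed=int(child.generate_state(1)[0] % (2**31)),
                            **kwargs)
        if res.converged and (best is None or res.objective < best.objective):
            best = res
    if best is None:
        raise RuntimeError("fuzzy c-means failed to converge in every restart")
    return best
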