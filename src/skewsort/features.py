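"""Adaptive PCA feature extraction.

Waveforms are projected onto the smallest number of principal components
that explains a target fraction (default 95%) of the variance, capped so
the clustering stage is not hit by the curse of dimensionality.  Covariance
(not correlation) PCA: waveform rows arrive already in noise-sigma units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detect import WaveformSet


class DegenerateInputError(ValueError):
    """Input carries no usable variance (or too few rows)."""


@dataclass
class PCAConfig:
    var_target: float = 0.95
    n_pca_max: int = 15
    center: bool = True

    def validate(self) -> None:
        if not (0 < self.var_target <= 1):
            raise ValueError("var_target must be in (0, 1]")
        if self.n_pca_max < 1:
            raise ValueError("n_pca_max must be >= 1")


@dataclass
class FeatureMatrix:
    """PCA scores plus the full eigen-spectrum they were cut from."""

    X: np.ndarray
    eigenvalues: np.ndarray
    n_c: int

    @property
    def explained(self) -> np.ndarray:
        """Cumulative explained-variance ratio over all components."""
        tot = self.eigenvalues.sum()
        return np.cumsum(self.eigenvalues) / tot


def select_num_components(eigenvalues: np.ndarray, cfg: PCAConfig | None = None) -> int:
    """Smallest n_c whose leading eigenvalues reach ``var_target``, capped.

    ``sum(lambda_1..lambda_nc) / sum(lambda) >= var_target``; if that n_c
    exceeds ``n_pca_max`` the cap wins.
    """
    cfg = cfg or PCAConfig()
    cfg.validate()
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size == 0 or np.any(lam < -1e-12 * max(1.0, abs(lam).max())):
        raise ValueError("eigenvalues must be nonnegative")
    if np.any(np.diff(lam) > 1e-9 * max(1.0, lam.max())):
        raise ValueError("eigenvalues must be sorted descending")
    total = lam.sum()
    if total <= 0:
        raise DegenerateInputError("all-zero eigenvalues")
    ratio = np.cumsum(lam) / total
    n_c = int(np.searchsorted(ratio, cfg.var_target - 1e-12) + 1)
    return min(n_c, cfg.n_pca_max, lam.size)


def extract_features(ws: WaveformSet | np.ndarray, cfg: PCAConfig | None = None) -> FeatureMatrix:
    """Mean-centered PCA scores of the waveform matrix.

    Deterministic up to nothing: each component's sign is fixed so the
    largest-magnitude loading entry is positive, so repeated runs agree
    exactly.
    """
    cfg = cfg or PCAConfig()
    cfg.validate()
    W = ws.W if isinstance(ws, WaveformSet) else np.asarray(ws, dtype=float)
    n, T = W.shape
    if n < 2 or T < 2:
        raise DegenerateInputError("need at least 2 waveforms of length >= 2")
    Wc = W - W.mean(axis=0) if cfg.center else W.copy()
    # eigendecomposition of the sample covariance via SVD for stability
    U, s, Vt = np.linalg.svd(Wc, full_matrices=False)
    lam = s**2 / (n - 1)
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    n_c = select_num_components(lam, cfg)
    X = Wc @ Vt[:n_c].T
    return FeatureMatrix(X=X, eigenvalues=lam, n_c=n_c)
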