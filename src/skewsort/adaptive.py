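"""Adaptive post-detection cleanup: statistical filtering and multi-point alignment.

Two independent stages applied to a detected waveform matrix:

* **Statistical filtering** removes windows whose per-row mean or standard
  deviation (in noise-sigma units) is abnormal — noise or artifact windows
  masquerading as spikes.
* **Multi-point alignment** groups waveforms by whether their maximum or
  minimum dominates, finds data-driven aligning points as the largest peaks
  of a spline-smoothed histogram of extremum positions, and shifts each
  waveform (integer samples, at most ``m_shift``) so its extremum lands on
  the nearest aligning point.  Several aligning points preserve genuine
  latency differences between units that a single-point alignment would
  erase.  Afterwards the tails that are not valid under every applied shift
  are trimmed so the matrix stays rectangular.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .detect import WaveformSet


@dataclass
class StatFilterConfig:
    """Thresholds for the mean/std waveform test (noise-sigma units)."""

    thr_mean: float = 1.0
    thr_std: float = 3.0
    normalize_by_sigma: bool = True

    def validate(self) -> None:
        if self.thr_mean <= 0 or self.thr_std <= 0:
            raise ValueError("thresholds must be > 0")


@dataclass
class AlignmentConfig:
    """Multi-point alignment parameters.

    m_peak : number of aligning points per group (largest smoothed-histogram
        peaks).  With ``m_peak`` equal to the window length the stage is the
        identity.
    m_shift : maximum allowed integer shift in samples (0.25 ms at 40 kHz
        for the default 10).
    spline_smoothing : penalty of the cubic smoothing spline fitted to the
        unit-bin histogram of extremum indices.
    """

    m_peak: int = 3
    m_shift: int = 10
    spline_smoothing: float = 0.5

    def validate(self) -> None:
        if self.m_peak < 1:
            raise ValueError("m_peak must be >= 1")
        if self.m_shift < 0:
            raise ValueError("m_shift must be >= 0")


@dataclass
class FilterReport:
    """Audit record of a statistical-filtering pass."""

    kept_idx: np.ndarray
    removed_idx: np.ndarray
    row_mean: np.ndarray
    row_std: np.ndarray

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "kept_idx": self.kept_idx.tolist(),
            "removed_idx": self.removed_idx.tolist(),
            "row_mean": np.round(self.row_mean, 6).tolist(),
            "row_std": np.round(self.row_std, 6).tolist(),
        })
        if path is not None:
            Path(path).write_text(payload)
        return payload


def statistical_filter(
    ws: WaveformSet, cfg: StatFilterConfig | None = None
) -> tuple[WaveformSet, FilterReport]:
    """Remove rows with abnormal mean or standard deviation.

    A row is removed iff ``|mean| > thr_mean`` or ``std > thr_std``, both
    computed on the row divided by ``sigma_n`` (a pure-noise window then has
    mean ~0 and std ~1, so the default thresholds 1 and 3 are meaningful).
    Surviving rows are untouched and keep their order.
    """
    cfg = cfg or StatFilterConfig()
    cfg.validate()
    if ws.n == 0:
        empty = np.empty(0, dtype=int)
        return ws, FilterReport(empty, empty, np.empty(0), np.empty(0))
    if cfg.normalize_by_sigma:
        if not ws.sigma_n > 0:
            raise ValueError("sigma_n must be > 0 for normalized filtering")
        R = ws.W / ws.sigma_n
    else:
        R = ws.W
    row_mean = R.mean(axis=1)
    row_std = R.std(axis=1)
    bad = (np.abs(row_mean) > cfg.thr_mean) | (row_std > cfg.thr_std)
    kept = np.flatnonzero(~bad)
    removed = np.flatnonzero(bad)
    return ws.take(kept), FilterReport(kept, removed, row_mean, row_std)


def _group_masks(ws: WaveformSet) -> tuple[np.ndarray, np.ndarray]:
    """Split rows by dominant extremum: group MAX has |min| < |max|."""
    gmax = ws.a_min < ws.a_max
    return gmax, ~gmax


def _histogram_peaks(idx: np.ndarray, T: int, cfg: AlignmentConfig) -> np.ndarray:
    """Aligning points: largest local maxima of the smoothed index histogram.

    Unit bins over [0, T); cubic smoothing spline with penalty
    ``spline_smoothing``; peaks ranked by smoothed height, ties broken
    toward the smaller index; returns at most ``m_peak`` points (ascending).
    """
    if idx.size == 0:
        return np.empty(0, dtype=int)
    hist = np.bincount(idx, minlength=T).astype(float)
    if cfg.m_peak >= T:
        # extreme case: every occupied bin is an aligning point, so the
        # alignment stage degenerates to the identity
        return np.flatnonzero(hist)
    x = np.arange(T, dtype=float)
    if np.count_nonzero(hist) == 1 or T < 4:
        return np.array([int(np.argmax(hist))])
    y = make_smoothing_spline(x, hist, lam=cfg.spline_smoothing)(x)
    left = np.concatenate([[-np.inf], y[:-1]])
    right = np.concatenate([y[1:], [-np.inf]])
    is_peak = (y > left) & (y >= right)
    peaks = np.flatnonzero(is_peak)
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(y))])
    order = np.lexsort((peaks, -y[peaks]))  # height desc, then smaller index
    chosen = peaks[order[: cfg.m_peak]]
    return np.sort(chosen)


def find_alignment_points(
    ws: WaveformSet, cfg: AlignmentConfig | None = None
) -> dict[str, np.ndarray]:
    """Aligning points per group ('max' uses idx_max, 'min' uses idx_min)."""
    cfg = cfg or AlignmentConfig()
    cfg.validate()
    gmax, gmin = _group_masks(ws)
    return {
        "max": _histogram_peaks(ws.idx_max[gmax], ws.T, cfg),
        "min": _histogram_peaks(ws.idx_min[gmin], ws.T, cfg),
    }


def _shifts_for_group(ext_idx: np.ndarray, points: np.ndarray, m_shift: int) -> np.ndarray:
    """Per-row shift moving the extremum onto the nearest aligning point.

    Ties between equidistant points go to the earlier point; rows farther
    than ``m_shift`` from every point stay unshifted.
    """
    if ext_idx.size == 0 or points.size == 0:
        return np.zeros(ext_idx.size, dtype=int)
    dist = np.abs(points[None, :] - ext_idx[:, None])
    nearest = np.argmin(dist, axis=1)  # argmin takes first minimum: earlier point
    shift = points[nearest] - ext_idx
    shift[np.abs(shift) > m_shift] = 0
    return shift


def align_waveforms(
    ws: WaveformSet,
    points: dict[str, np.ndarray],
    cfg: AlignmentConfig | None = None,
) -> WaveformSet:
    """Shift rows onto their aligning points and trim invalid tails.

    Shifting is pure index slicing (no interpolation, no wrap-around): a
    shift ``s`` moves row content right by ``s`` columns.  The matrix is
    then trimmed to the column range valid under every applied shift (at
    most ``m_shift`` columns per side), and event indices are corrected by
    ``-s`` so aligned times stay physical.
    """
    cfg = cfg or AlignmentConfig()
    cfg.validate()
    if ws.n == 0:
        return ws
    gmax, gmin = _group_masks(ws)
    shifts = np.zeros(ws.n, dtype=int)
    shifts[gmax] = _shifts_for_group(ws.idx_max[gmax], points["max"], cfg.m_shift)
    shifts[gmin] = _shifts_for_group(ws.idx_min[gmin], points["min"], cfg.m_shift)

    lo = int(max(0, shifts.max()))
    hi = int(ws.T + min(0, shifts.min()))
    width = hi - lo
    rows = np.arange(ws.n)[:, None]
    cols = np.arange(lo, hi)[None, :] - shifts[:, None]
    Wt = ws.W[rows, cols]
    new_events = ws.event_indices - shifts
    out = WaveformSet(Wt, new_events, ws.fs, ws.pre - lo, ws.sigma_n)
    return out


def align_extremum(ws: WaveformSet, column: int | None = None) -> WaveformSet:
    """Single-point (extremum) alignment: every row's minimum to one column.

    The classic alignment used by threshold-based sorters; serves as the
    baseline against which multi-point alignment is compared.  The target
    column defaults to the current extraction column ``pre``.
    """
    if ws.n == 0:
        return ws
    column = ws.pre if column is None else column
    shifts = column - ws.idx_min
    lo = int(max(0, shifts.max()))
    hi = int(ws.T + min(0, shifts.min()))
    rows = np.arange(ws.n)[:, None]
    cols = np.arange(lo, hi)[None, :] - shifts[:, None]
    return WaveformSet(ws.W[rows, cols], ws.event_indices - shifts, ws.fs,
                       ws.pre - lo, ws.sigma_n)


def adaptive_detect(
    ws: WaveformSet,
    sf: StatFilterConfig | None = None,
    ac: AlignmentConfig | None = None,
    *,
    do_filter: bool = True,
    do_align: bool = True,
) -> tuple[WaveformSet, FilterReport]:
    """Statistical filtering followed by multi-point alignment.

    Either stage can be disabled; with both off the input is returned
    unchanged (the plain-detection baseline).  Works on any waveform/event
    list, including detections produced by external detectors.
    """
    report = FilterReport(np.arange(ws.n), np.empty(0, dtype=int),
                          np.empty(0), np.empty(0))
    if do_filter:
        ws, report = statistical_filter(ws, sf)
    if do_align and ws.n > 0:
        points = find_alignment_points(ws, ac)
        ws = align_waveforms(ws, points, ac)
    return ws, report
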