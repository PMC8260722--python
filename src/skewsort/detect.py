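"""Threshold detection of spikes and waveform extraction.

An event requires ``m_d + 1`` successive samples below ``-t_s`` (a single
sub-threshold sample is too easily produced by noise); the event index is
then snapped to the first local minimum after the crossing, where a local
minimum has no smaller value within a 1 ms look-ahead.  A fixed window of
0.5 ms before / 1 ms after the event index is cut out per spike.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .preprocess import NoiseModel, RecordingSignal

logger = logging.getLogger(__name__)


@dataclass
class DetectionConfig:
    """Threshold-detection parameters.

    c_t : threshold multiplier on the noise std (threshold = c_t * sigma_n).
    m_d : extra successive samples that must stay below threshold
          (m_d + 1 samples in total; ~0.05 ms at 40 kHz for the default 2).
    localmin_window_s : look-ahead defining a local minimum (1 ms).
    pre_s, post_s : extraction window around the event index.
    polarity : 'negative' detects troughs (default); 'positive' mirrors the
          rule on the sign-flipped signal.
    """

    c_t: float = 3.0
    m_d: int = 2
    localmin_window_s: float = 1e-3
    pre_s: float = 0.5e-3
    post_s: float = 1e-3
    polarity: str = "negative"

    def validate(self) -> None:
        if self.c_t <= 0:
            raise ValueError("c_t must be > 0")
        if self.m_d < 0:
            raise ValueError("m_d must be >= 0")
        if min(self.localmin_window_s, self.pre_s, self.post_s) <= 0:
            raise ValueError("windows must be > 0")
        if self.polarity not in ("negative", "positive"):
            raise ValueError("polarity must be 'negative' or 'positive'")

    def window_samples(self, fs: float) -> tuple[int, int]:
        return int(round(self.pre_s * fs)), int(round(self.post_s * fs))


@dataclass
class SpikeEvents:
    """Detected event indices (sample index of the aligned minimum)."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.size > 1 and not np.all(np.diff(self.indices) > 0):
            raise ValueError("event indices must be strictly increasing")

    @property
    def times_s(self) -> np.ndarray:
        return self.indices / self.fs

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclass
class WaveformSet:
    """Matrix of spike snippets plus per-row extremum metadata.

    W : (n, T) waveform matrix, one spike per row.
    event_indices : sample index in the source signal of each row's
        alignment column (column ``pre`` before any tail trimming).
    pre : alignment column (the event index sits at ``W[:, pre]`` on
        extraction; alignment may move extrema onto other columns).
    sigma_n : noise std used for normalisation downstream.
    """

    W: np.ndarray
    event_indices: np.ndarray
    fs: float
    pre: int
    sigma_n: float = 1.0

    def __post_init__(self) -> None:
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        self.event_indices = np.asarray(self.event_indices, dtype=np.int64)
        if self.W.shape[0] != self.event_indices.size:
            raise ValueError("one event index per waveform row required")

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def T(self) -> int:
        return self.W.shape[1]

    @property
    def times_s(self) -> np.ndarray:
        return self.event_indices / self.fs

    # extremum metadata, recomputed on demand so it stays consistent after
    # filtering / alignment / trimming
    @property
    def idx_min(self) -> np.ndarray:
        return np.argmin(self.W, axis=1)

    @property
    def idx_max(self) -> np.ndarray:
        return np.argmax(self.W, axis=1)

    @property
    def a_min(self) -> np.ndarray:
        return np.abs(self.W.min(axis=1))

    @property
    def a_max(self) -> np.ndarray:
        return np.abs(self.W.max(axis=1))

    def take(self, rows: np.ndarray) -> "WaveformSet":
        return WaveformSet(self.W[rows], self.event_indices[rows], self.fs,
                           self.pre, self.sigma_n)


def _forward_min(x: np.ndarray, w: int) -> np.ndarray:
    """fmin[j] = min(x[j+1], ..., x[j+w]) with +inf past the end."""
    n = x.size
    pad = np.concatenate([x, np.full(w, np.inf)])
    win = sliding_window_view(pad, w)  # win[k] = pad[k : k+w]
    return win[1 : n + 1].min(axis=1)


def detect_spikes(
    filtered: RecordingSignal,
    noise: NoiseModel,
    cfg: DetectionConfig | None = None,
    threshold: float | None = None,
) -> SpikeEvents:
    """Detect spike events on a filtered trace.

    A trigger occurs at the first sample ``m_s`` with
    ``x[m_s + m_i] < -t_s`` for all ``m_i`` in ``{0..m_d}`` (strict
    inequality; ties at exactly ``-t_s`` do not trigger).  The event index
    is the first local minimum at or after ``m_s`` (no smaller value within
    the 1 ms look-ahead).  Duplicate triggers snapping to the same minimum
    are merged, and events too close to either edge for the extraction
    window are dropped.
    """
    cfg = cfg or DetectionConfig()
    cfg.validate()
    x = filtered.samples
    if cfg.polarity == "positive":
        x = -x
    t_s = noise.threshold if threshold is None else threshold
    if t_s <= 0:
        return SpikeEvents(np.empty(0, dtype=np.int64), filtered.fs)

    n = x.size
    fs = filtered.fs
    below = x < -t_s
    m_d = cfg.m_d
    if m_d > 0:
        # run[j] True iff below[j..j+m_d] all True
        pad = np.concatenate([below, np.zeros(m_d, dtype=bool)])
        run = sliding_window_view(pad, m_d + 1).all(axis=1)[:n]
    else:
        run = below

    # trigger = first sample of a below-threshold excursion that also
    # satisfies the consecutive-sample rule somewhere inside the excursion:
    # the paper's m_s is the first threshold crossing; the event is accepted
    # if the run condition holds at m_s.
    first_cross = below & ~np.concatenate([[False], below[:-1]])
    triggers = np.flatnonzero(first_cross & run)
    if triggers.size == 0:
        return SpikeEvents(np.empty(0, dtype=np.int64), fs)

    w = int(round(cfg.localmin_window_s * fs))
    is_locmin = x <= _forward_min(x, w)
    locmin_idx = np.flatnonzero(is_locmin)
    pos = np.searchsorted(locmin_idx, triggers, side="left")
    pos = pos[pos < locmin_idx.size]  # trigger with no local minimum after it
    events = locmin_idx[pos]

    events = np.unique(events)  # merge duplicate snaps, sort
    pre, post = cfg.window_samples(fs)
    in_bounds = (events >= pre) & (events + post < n)
    dropped = int(np.sum(~in_bounds))
    if dropped:
        logger.info("detect_spikes: dropped %d edge events", dropped)
    return SpikeEvents(events[in_bounds], fs)


def extract_waveforms(
    filtered: RecordingSignal,
    events: SpikeEvents,
    cfg: DetectionConfig | None = None,
    sigma_n: float = 1.0,
) -> WaveformSet:
    """Cut fixed windows around event indices.

    Each row spans ``round(pre_s*fs)`` samples before to ``round(post_s*fs)``
    samples after the event index inclusive (T = pre + post + 1; 61 at
    40 kHz with the defaults).  Events too close to an edge are dropped
    (count logged).
    """
    cfg = cfg or DetectionConfig()
    pre, post = cfg.window_samples(filtered.fs)
    x = filtered.samples
    idx = events.indices
    ok = (idx >= pre) & (idx + post < x.size)
    if not np.all(ok):
        logger.info("extract_waveforms: dropped %d edge events", int(np.sum(~ok)))
        idx = idx[ok]
    T = pre + post + 1
    if idx.size == 0:
        return WaveformSet(np.empty((0, T)), idx, filtered.fs, pre, sigma_n)
    offsets = np.arange(-pre, post + 1)
    W = x[idx[:, None] + offsets[None, :]]
    return WaveformSet(W, idx, filtered.fs, pre, sigma_n)
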