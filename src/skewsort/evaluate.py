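"""Detection and clustering metrics, the sorting index, and the Bayes reference.

Detection is scored by one-to-one matching of detected to true spike times
within a 1 ms tolerance.  Clustering is scored by dominant-neuron accuracy
and purity on the matched spikes.  The overall sorting index (SSI) is a
normalised mutual information between true and predicted labelings in which
false alarms form one hypothetical true cluster and missed spikes are
randomly assigned to existing predicted clusters (averaged over repeats),
so misses, false alarms and clustering errors all reduce a single score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class GroundTruth:
    """True spike times and neuron identities (plus simulator metadata)."""

    spike_times_s: np.ndarray     # all spikes, sorted
    neuron_ids: np.ndarray        # parallel to spike_times_s
    templates: np.ndarray | None = None   # (n_neurons, T_t), trough-aligned
    template_trough: int | None = None    # trough column within the template
    noise_std: float | None = None
    fs: float | None = None

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, float)
        self.neuron_ids = np.asarray(self.neuron_ids, int)
        order = np.argsort(self.spike_times_s, kind="stable")
        self.spike_times_s = self.spike_times_s[order]
        self.neuron_ids = self.neuron_ids[order]

    @property
    def n_neurons(self) -> int:
        return int(self.neuron_ids.max()) + 1 if self.neuron_ids.size else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.spike_times_s,
                             "neuron_id": self.neuron_ids})


@dataclass
class DetectionMatch:
    """One-to-one matching between detected and true spikes."""

    tp: int
    fp: int
    fn: int
    matched_detected: np.ndarray   # indices into the detected list
    matched_true: np.ndarray       # indices into the true list


def match_spike_times(detected_s: np.ndarray, true_s: np.ndarray,
                      tol_s: float = 1e-3) -> DetectionMatch:
    """Greedy one-to-one matching by ascending time difference.

    Candidate pairs within ``tol_s`` are taken smallest |dt| first; each
    detected and each true spike matches at most once.  Unmatched detected
    spikes are false positives, unmatched true spikes false negatives.
    """
    det = np.asarray(detected_s, float)
    tru = np.asarray(true_s, float)
    if np.any(np.diff(det) < 0) or np.any(np.diff(tru) < 0):
        raise ValueError("inputs must be sorted")
    pairs_d, pairs_t, dts = [], [], []
    lo = np.searchsorted(tru, det - tol_s, side="left")
    hi = np.searchsorted(tru, det + tol_s, side="right")
    for i, (a, b) in enumerate(zip(lo, hi)):
        for j in range(a, b):
            dt = abs(det[i] - tru[j])
            if dt <= tol_s:
                pairs_d.append(i)
                pairs_t.append(j)
                dts.append(dt)
    md, mt = [], []
    if dts:
        order = np.argsort(dts, kind="stable")
        used_d = np.zeros(det.size, bool)
        used_t = np.zeros(tru.size, bool)
        for k in order:
            i, j = pairs_d[k], pairs_t[k]
            if not used_d[i] and not used_t[j]:
                used_d[i] = used_t[j] = True
                md.append(i)
                mt.append(j)
    md = np.asarray(md, int)
    mt = np.asarray(mt, int)
    tp = md.size
    return DetectionMatch(tp=tp, fp=det.size - tp, fn=tru.size - tp,
                          matched_detected=md, matched_true=mt)


def detection_metrics(m: DetectionMatch) -> tuple[float, float]:
    """(precision, recall) = (tp/(tp+fp), tp/(tp+fn)); NaN when undefined."""
    if m.tp + m.fp == 0:
        logger.warning("precision undefined (no detections)")
        precision = float("nan")
    else:
        precision = m.tp / (m.tp + m.fp)
    if m.tp + m.fn == 0:
        logger.warning("recall undefined (no true spikes)")
        recall = float("nan")
    else:
        recall = m.tp / (m.tp + m.fn)
    return precision, recall


def _contingency(pred: np.ndarray, true: np.ndarray) -> np.ndarray:
    pred = np.asarray(pred, int)
    true = np.asarray(true, int)
    pc = np.unique(pred)
    tc = np.unique(true)
    table = np.zeros((pc.size, tc.size), dtype=int)
    pi = np.searchsorted(pc, pred)
    ti = np.searchsorted(tc, true)
    np.add.at(table, (pi, ti), 1)
    return table


def clustering_metrics(pred_labels: np.ndarray, true_labels: np.ndarray
                       ) -> tuple[float, float]:
    """Dominant-neuron accuracy and purity on aligned label vectors.

    Accuracy: clusters are processed in descending size (ties toward the
    smaller cluster index); each takes as its label the most frequent true
    neuron not yet assigned to another cluster; accuracy is the fraction of
    spikes whose cluster label matches their true neuron.  Purity is the
    normalised sum of per-cluster maximum overlaps.
    """
    pred = np.asarray(pred_labels, int)
    true = np.asarray(true_labels, int)
    if pred.size == 0 or pred.size != true.size:
        raise ValueError("need non-empty aligned label vectors")
    table = _contingency(pred, true)
    n = pred.size
    purity = table.max(axis=1).sum() / n

    sizes = table.sum(axis=1)
    order = np.lexsort((np.arange(sizes.size), -sizes))
    assigned: set[int] = set()
    correct = 0
    for c in order:
        counts = table[c].copy()
        for d in assigned:
            counts[d] = -1
        if counts.max() <= 0:
            continue  # nothing left to assign: cluster contributes no hits
        d = int(np.argmax(counts))
        assigned.add(d)
        correct += int(table[c, d])
    return correct / n, float(purity)


def _mutual_info(a: np.ndarray, b: np.ndarray) -> float:
    """Mutual information (nats) of two label vectors."""
    table = _contingency(a, b).astype(float)
    n = table.sum()
    pij = table / n
    pi = pij.sum(axis=1, keepdims=True)
    pj = pij.sum(axis=0, keepdims=True)
    mask = pij > 0
    return float((pij[mask] * np.log(pij[mask] / (pi @ pj)[mask])).sum())


def ssi(true_times_s: np.ndarray, true_labels: np.ndarray,
        pred_times_s: np.ndarray, pred_labels: np.ndarray,
        tol_s: float = 1e-3, reps: int = 20, seed=None) -> float:
    """Spike sorting index: normalised mutual information with penalties.

    Detected spikes are matched one-to-one to true spikes within ``tol_s``.
    The joint label vectors cover matched spikes (true neuron, predicted
    cluster), false alarms (all receive one new hypothetical true cluster
    and keep their predicted cluster) and misses (true neuron, with a
    uniformly random existing predicted cluster, redrawn ``reps`` times and
    averaged).  SSI = I(C, C') / max(H(C), H(C')); note I(C, C) = H(C).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    tt = np.asarray(true_times_s, float)
    tl = np.asarray(true_labels, int)
    pt = np.asarray(pred_times_s, float)
    pl = np.asarray(pred_labels, int)
    if tt.size != tl.size or pt.size != pl.size:
        raise ValueError("times and labels must align")

    m = match_spike_times(pt, tt, tol_s=tol_s)
    matched_true = tl[m.matched_true]
    matched_pred = pl[m.matched_detected]
    fa_mask = np.ones(pt.size, bool)
    fa_mask[m.matched_detected] = False
    fa_pred = pl[fa_mask]
    miss_mask = np.ones(tt.size, bool)
    miss_mask[m.matched_true] = False
    miss_true = tl[miss_mask]

    fa_true_label = int(tl.max()) + 1 if tl.size else 0
    clusters = np.unique(pl) if pl.size else np.array([0])

    C_fixed = np.concatenate([matched_true,
                              np.full(fa_pred.size, fa_true_label),
                              miss_true])
    P_fixed = np.concatenate([matched_pred, fa_pred])

    rng = np.random.default_rng(seed)
    n_draws = reps if miss_true.size else 1
    vals = []
    for _ in range(n_draws):
        miss_pred = rng.choice(clusters, size=miss_true.size)
        C = C_fixed
        Cp = np.concatenate([P_fixed, miss_pred])
        hC = _mutual_info(C, C)
        hCp = _mutual_info(Cp, Cp)
        denom = max(hC, hCp)
        if denom <= 0:
            val = 1.0 if np.array_equal(C, Cp) else 0.0
            logger.warning("ssi: degenerate single-label case -> %s", val)
        else:
            val = _mutual_info(C, Cp) / denom
        vals.append(val)
    return float(np.mean(vals))


def bayes_reference_accuracy(session, pred_times_s: np.ndarray,
                             pred_labels: np.ndarray, tol_s: float = 1e-3
                             ) -> tuple[float, float]:
    """Accuracy of a sorter next to the Bayes-optimal waveform classifier.

    The reference knows the generative model of the synthetic session —
    templates, firing priors and the iid Gaussian noise level — and assigns
    each true-spike waveform ``w`` to ``argmax_k [log prior_k
    - ||w - template_k||^2 / (2 sigma_n^2)]``, which is the optimal rule
    under that noise.  Returns ``(ca_method, ca_bayes)``: the dominant-neuron
    accuracy of the labels under test on matched spikes, and the reference's
    classification accuracy on all true spikes.
    """
    truth: GroundTruth = session.truth
    if truth.templates is None or truth.noise_std is None or truth.fs is None:
        raise ValueError("session lacks generative metadata for the reference")
    x = session.signal.samples
    fs = truth.fs
    templates = np.atleast_2d(truth.templates)
    trough = truth.template_trough
    T_t = templates.shape[1]
    counts = np.bincount(truth.neuron_ids, minlength=templates.shape[0])
    priors = counts / counts.sum()
    log_priors = np.log(np.clip(priors, 1e-12, None))

    idx = np.round(truth.spike_times_s * fs).astype(int)
    start = idx - trough
    ok = (start >= 0) & (start + T_t <= x.size)
    offsets = np.arange(T_t)
    Wn = x[start[ok, None] + offsets[None, :]]
    d2 = ((Wn[:, None, :] - templates[None, :, :]) ** 2).sum(axis=2)
    sigma = max(float(truth.noise_std), 1e-300)
    score = log_priors[None, :] - d2 / (2.0 * sigma**2)
    bayes_pred = np.argmax(score, axis=1)
    ca_bayes = float(np.mean(bayes_pred == truth.neuron_ids[ok]))

    m = match_spike_times(np.asarray(pred_times_s, float), truth.spike_times_s,
                          tol_s=tol_s)
    if m.tp == 0:
        return 0.0, ca_bayes
    acc, _ = clustering_metrics(np.asarray(pred_labels)[m.matched_detected],
                                truth.neuron_ids[m.matched_true])
    return float(acc), ca_bayes


def ca_ca_fit(ca_method: np.ndarray, ca_bayes: np.ndarray) -> tuple[float, float]:
    """OLS line of method accuracy on reference accuracy: (slope, R^2)."""
    x = np.asarray(ca_bayes, float)
    y = np.asarray(ca_method, float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in reference accuracy")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.rvalue**2)


@dataclass
class EvalReport:
    """Bundle of detection + clustering metrics for one session."""

    precision: float
    recall: float
    accuracy: float
    purity: float
    ssi: float
    g_true: int
    g_est: int
    contingency: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {k: (getattr(self, k) if k != "contingency" else None)
                for k in ("precision", "recall", "accuracy", "purity",
                          "ssi", "g_true", "g_est")}


def evaluate_sorting(truth: GroundTruth, pred_times_s: np.ndarray,
                     pred_labels: np.ndarray, tol_s: float = 1e-3,
                     reps: int = 20, seed=None) -> EvalReport:
    """All metrics for one sorted session against its ground truth."""
    pred_times_s = np.asarray(pred_times_s, float)
    pred_labels = np.asarray(pred_labels, int)
    m = match_spike_times(pred_times_s, truth.spike_times_s, tol_s=tol_s)
    precision, recall = detection_metrics(m)
    if m.tp > 0:
        accuracy, purity = clustering_metrics(
            pred_labels[m.matched_detected], truth.neuron_ids[m.matched_true])
        table = _contingency(pred_labels[m.matched_detected],
                             truth.neuron_ids[m.matched_true])
    else:
        accuracy = purity = 0.0
        table = None
    s = ssi(truth.spike_times_s, truth.neuron_ids, pred_times_s, pred_labels,
            tol_s=tol_s, reps=reps, seed=seed)
    return EvalReport(precision=precision, recall=recall, accuracy=accuracy,
                      purity=purity, ssi=s, g_true=truth.n_neurons,
                      g_est=int(np.unique(pred_labels).size) if pred_labels.size else 0,
                      contingency=table)
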