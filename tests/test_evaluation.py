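"""Detection/clustering metrics, sorting index and the Bayes reference."""

import itertools

import numpy as np
import pytest

from skewsort.evaluate import (GroundTruth, bayes_reference_accuracy,
                               ca_ca_fit, clustering_metrics,
                               detection_metrics, evaluate_sorting,
                               match_spike_times, ssi)
from skewsort.simulate import SessionConfig, generate_session


def _exhaustive_best_matching(det, tru, tol):
    """Oracle: maximum one-to-one matching by brute force (tiny inputs)."""
    best = 0
    pairs = [(i, j) for i in range(len(det)) for j in range(len(tru))
             if abs(det[i] - tru[j]) <= tol]
    for r in range(len(pairs), 0, -1):
        for combo in itertools.combinations(pairs, r):
            ds = [p[0] for p in combo]
            ts = [p[1] for p in combo]
            if len(set(ds)) == r and len(set(ts)) == r:
                return r
    return best


class TestMatching:
    def test_identical_lists_match_perfectly(self):
        t = np.array([0.1, 0.5, 0.9])
        m = match_spike_times(t, t)
        assert (m.tp, m.fp, m.fn) == (3, 0, 0)

    def test_within_tolerance_counts_as_hit(self):
        m = match_spike_times(np.array([0.1004]), np.array([0.1]))
        assert m.tp == 1 and m.fp == 0

    def test_one_to_one_rule_on_duplicates(self):
        m = match_spike_times(np.array([0.0998, 0.1003]), np.array([0.1]))
        assert m.tp == 1 and m.fp == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_greedy_matches_exhaustive_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        det = np.sort(rng.uniform(0, 0.02, size=5))
        tru = np.sort(rng.uniform(0, 0.02, size=4))
        m = match_spike_times(det, tru)
        assert m.tp == _exhaustive_best_matching(det, tru, 1e-3)


class TestDetectionMetrics:
    def test_precision_worked_case(self):
        from skewsort.evaluate import DetectionMatch
        e = np.empty(0, int)
        m = DetectionMatch(tp=8, fp=2, fn=0, matched_detected=e, matched_true=e)
        assert detection_metrics(m)[0] == pytest.approx(0.8)

    def test_recall_worked_case(self):
        from skewsort.evaluate import DetectionMatch
        e = np.empty(0, int)
        m = DetectionMatch(tp=8, fp=0, fn=2, matched_detected=e, matched_true=e)
        assert detection_metrics(m)[1] == pytest.approx(0.8)

    def test_perfect_detection(self):
        m = match_spike_times(np.array([0.1, 0.2]), np.array([0.1, 0.2]))
        assert detection_metrics(m) == (1.0, 1.0)

    def test_empty_denominators_are_nan(self):
        m = match_spike_times(np.empty(0), np.empty(0))
        p, r = detection_metrics(m)
        assert np.isnan(p) and np.isnan(r)


class TestClusteringMetrics:
    def test_perfect_clustering(self):
        y = np.array([0, 0, 1, 1, 2])
        assert clustering_metrics(y, y) == (1.0, 1.0)

    def test_hand_case_metrics_agree(self):
        # clusters {A:9, B:1} and {A:1, B:4}
        pred = np.array([0] * 10 + [1] * 5)
        true = np.array(["A"] * 9 + ["B"] + ["A"] + ["B"] * 4)
        true = (true == "B").astype(int)
        acc, pur = clustering_metrics(pred, true)
        assert pur == pytest.approx(13 / 15)
        assert acc == pytest.approx(13 / 15)

    def test_hand_case_metrics_differ(self):
        # clusters {A:9, B:1} and {A:3, B:2}: the second cluster's dominant
        # neuron A is taken, so it is forced onto B
        pred = np.array([0] * 10 + [1] * 5)
        true = np.array([0] * 9 + [1] + [0] * 3 + [1] * 2)
        acc, pur = clustering_metrics(pred, true)
        assert pur == pytest.approx(12 / 15)
        assert acc == pytest.approx(11 / 15)

    def test_both_one_iff_permutation_table(self):
        pred = np.array([1, 1, 0, 0, 2, 2])
        true = np.array([2, 2, 1, 1, 0, 0])
        assert clustering_metrics(pred, true) == (1.0, 1.0)
        pred2 = np.array([1, 1, 0, 0, 2, 0])
        acc, pur = clustering_metrics(pred2, true)
        assert acc < 1.0 and pur < 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            clustering_metrics(np.empty(0), np.empty(0))


class TestSSI:
    def test_perfect_sorting_scores_one(self):
        t = np.linspace(0, 1, 40)
        lab = np.tile([0, 1, 2, 3], 10)
        assert ssi(t, lab, t, lab, seed=0) == pytest.approx(1.0)

    def test_shuffled_labels_score_near_zero(self, rng):
        n = 10_000
        t = np.sort(rng.uniform(0, 100, size=n))
        lab = np.tile([0, 1, 2, 3], n // 4)
        assert ssi(t, lab, t, rng.permutation(lab), seed=0) < 0.01

    def test_small_worked_case_matches_enumeration(self):
        """12 true spikes, 1 miss, 1 false alarm, hand-built contingency.

        The miss draws a uniformly random predicted cluster; enumerating
        both possible draws and averaging the resulting NMI values gives
        the expected SSI exactly.
        """
        true_t = np.arange(12) * 0.01
        true_lab = np.array([0] * 6 + [1] * 6)
        # detections: true spikes except the last (miss), plus a false alarm
        pred_t = np.concatenate([true_t[:11], [0.5]])
        pred_lab = np.array([0] * 6 + [1] * 5 + [0])

        def nmi(a, b):
            from skewsort.evaluate import _mutual_info
            return _mutual_info(a, b) / max(_mutual_info(a, a),
                                            _mutual_info(b, b))

        vals = []
        for miss_label in (0, 1):
            C = np.concatenate([true_lab[:11], [2], [true_lab[11]]])
            Cp = np.concatenate([pred_lab[:11], [pred_lab[11]], [miss_label]])
            vals.append(nmi(C, Cp))
        expected = np.mean(vals)
        got = ssi(true_t, true_lab, pred_t, pred_lab, reps=4000, seed=1)
        assert got == pytest.approx(expected, abs=0.01)

    def test_extra_false_alarms_decrease_ssi(self, rng):
        n = 2000
        t = np.sort(rng.uniform(0, 50, size=n))
        lab = np.tile([0, 1], n // 2)
        base = ssi(t, lab, t, lab, seed=0)
        fa = np.sort(np.concatenate([t, rng.uniform(51, 60, size=200)]))
        fa_lab = np.concatenate([lab, rng.integers(0, 2, size=200)])
        order = np.argsort(np.concatenate([t, rng.uniform(51, 60, size=0)]))
        pred_t = np.concatenate([t, np.linspace(51, 60, 200)])
        pred_lab = np.concatenate([lab, rng.integers(0, 2, size=200)])
        worse = ssi(t, lab, pred_t, pred_lab, seed=0)
        assert worse < base == pytest.approx(1.0)

    def test_bounded_in_unit_interval(self, rng):
        t = np.sort(rng.uniform(0, 10, size=500))
        lab = rng.integers(0, 3, size=500)
        pt = np.sort(rng.uniform(0, 10, size=450))
        pl = rng.integers(0, 4, size=450)
        val = ssi(t, lab, pt, pl, seed=2)
        assert 0.0 <= val <= 1.0


class TestBayesReference:
    def test_zero_noise_is_perfect(self):
        # low rate: overlapping spikes (outside the single-spike model) are
        # rare, so the noiseless reference is essentially exact
        s = generate_session(SessionConfig(duration_s=20, snr_db=80,
                                           rate_hz=3.0, seed=3))
        _, ca_b = bayes_reference_accuracy(s, s.truth.spike_times_s,
                                           s.truth.neuron_ids)
        assert ca_b > 0.97

    def test_equal_templates_fall_to_chance(self):
        s = generate_session(SessionConfig(duration_s=5, snr_db=15, seed=3))
        s.truth.templates = np.tile(s.truth.templates[:1], (4, 1))
        _, ca_b = bayes_reference_accuracy(s, s.truth.spike_times_s,
                                           s.truth.neuron_ids)
        counts = np.bincount(s.truth.neuron_ids)
        chance = counts.max() / counts.sum()
        assert ca_b == pytest.approx(chance, abs=1e-9)

    def test_beats_alternative_waveform_classifiers(self):
        """Optimality: no rival classifier on the same windows does better."""
        s = generate_session(SessionConfig(duration_s=20, snr_db=9, seed=5))
        truth = s.truth
        _, ca_b = bayes_reference_accuracy(s, truth.spike_times_s,
                                           truth.neuron_ids)
        x = s.signal.samples
        T_t = truth.templates.shape[1]
        idx = np.round(truth.spike_times_s * truth.fs).astype(int)
        start = idx - truth.template_trough
        ok = (start >= 0) & (start + T_t <= x.size)
        W = x[start[ok, None] + np.arange(T_t)[None, :]]
        y = truth.neuron_ids[ok]
        rivals = []
        # (a) peak-amplitude nearest template
        peaks = np.abs(W.min(axis=1))
        t_peaks = np.abs(truth.templates.min(axis=1))
        rivals.append(np.abs(peaks[:, None] - t_peaks[None, :]).argmin(1))
        # (b) correlation (ignores amplitude)
        Wn = W / np.linalg.norm(W, axis=1, keepdims=True)
        Tn = truth.templates / np.linalg.norm(truth.templates, axis=1,
                                              keepdims=True)
        rivals.append((Wn @ Tn.T).argmax(1))
        # (c) unscaled distance on the first half of the window only
        half = T_t // 2
        rivals.append(((W[:, :half, None] -
                        truth.templates.T[None, :half, :]) ** 2
                       ).sum(1).argmin(1))
        for r in rivals:
            assert ca_b >= (r == y).mean() - 0.01

    def test_missing_metadata_is_an_error(self):
        truth = GroundTruth(np.array([0.1]), np.array([0]))

        class Shim:
            pass

        shim = Shim()
        shim.truth = truth
        shim.signal = None
        with pytest.raises(ValueError):
            bayes_reference_accuracy(shim, np.array([0.1]), np.array([0]))


class TestCACAFit:
    def test_exact_line_has_unit_r_squared(self):
        x = np.array([0.2, 0.5, 0.8, 0.9])
        slope, r2 = ca_ca_fit(0.7 * x + 0.1, x)
        assert slope == pytest.approx(0.7)
        assert r2 == pytest.approx(1.0)

    def test_identity_line_slope_one(self):
        x = np.array([0.1, 0.4, 0.6, 0.95])
        slope, r2 = ca_ca_fit(x, x)
        assert slope == pytest.approx(1.0)

    def test_matches_closed_form_ols(self, rng):
        x = rng.uniform(0.3, 1.0, size=20)
        y = 0.9 * x + rng.normal(scale=0.03, size=20)
        slope, r2 = ca_ca_fit(y, x)
        xc, yc = x - x.mean(), y - y.mean()
        slope_o = (xc @ yc) / (xc @ xc)
        r2_o = (xc @ yc) ** 2 / ((xc @ xc) * (yc @ yc))
        assert slope == pytest.approx(slope_o, abs=1e-12)
        assert r2 == pytest.approx(r2_o, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ca_ca_fit(np.array([0.5, 0.6]), np.array([0.5, 0.6]))
        with pytest.raises(ValueError):
            ca_ca_fit(np.array([0.5, 0.6, 0.7]), np.array([0.5, 0.5, 0.5]))
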