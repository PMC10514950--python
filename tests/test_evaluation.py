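"""Metrics, ROC/AUC, bootstrap CIs and paired comparisons against oracles."""

import numpy as np
import pytest

from cytoseg.core import BinaryMask, ConfusionCounts, MetricSet, ProbabilityMap, TaskType
from cytoseg.evaluation import (CIResult, EvalConfig, bootstrap_ci,
                                compute_metrics, confusion_counts,
                                evaluate_micro, paired_bootstrap_test, roc_auc,
                                round_half_away, summarize_report)

T = TaskType.NUCLEUS


def _bm(a, task=T):
    return BinaryMask(task, np.asarray(a, dtype=np.uint8))


def _loop_counts(pred, truth):
    """Brute-force per-pixel oracle."""
    tp = fp = tn = fn = 0
    for p, t in zip(np.asarray(pred).ravel(), np.asarray(truth).ravel()):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


class TestConfusionCounts:
    def test_enumerable_example(self):
        c = confusion_counts(_bm([[1, 0], [1, 1]]), _bm([[1, 1], [0, 1]]))
        assert (c.tp, c.fn, c.fp, c.tn) == (2, 1, 1, 0)

    def test_identity_prediction(self):
        m = _bm([[1, 0], [0, 1]])
        c = confusion_counts(m, m)
        assert c.fp == 0 and c.fn == 0 and c.total == 4

    @pytest.mark.parametrize("seed", range(10))
    def test_random_instances_match_pixel_loop(self, seed):
        r = np.random.default_rng(seed)
        pred, truth = r.integers(0, 2, (2, 16, 16))
        assert confusion_counts(_bm(pred), _bm(truth)) == _loop_counts(pred, truth)

    def test_shape_and_task_mismatch(self):
        with pytest.raises(ValueError):
            confusion_counts(_bm(np.zeros((2, 2))), _bm(np.zeros((3, 3))))
        with pytest.raises(ValueError):
            confusion_counts(_bm(np.zeros((2, 2))),
                             _bm(np.zeros((2, 2)), task=TaskType.CYTOPLASM))


class TestComputeMetrics:
    def test_closed_form_example(self):
        ms = compute_metrics(ConfusionCounts(tp=2, fp=1, fn=1, tn=6))
        assert ms.dice == pytest.approx(2 / 3, abs=1e-4)
        assert ms.sensitivity == pytest.approx(2 / 3, abs=1e-4)
        assert ms.specificity == pytest.approx(6 / 7, abs=1e-4)

    def test_perfect_prediction(self):
        ms = compute_metrics(ConfusionCounts(tp=5, tn=10))
        assert ms == MetricSet(1.0, 1.0, 1.0)

    def test_vacuous_truth_conventions(self):
        ms = compute_metrics(ConfusionCounts(tn=9))
        assert ms.dice == 1.0 and ms.sensitivity == 1.0
        assert ms.specificity == 1.0
        ms2 = compute_metrics(ConfusionCounts(tp=4))  # no negatives at all
        assert ms2.specificity == 1.0

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts())

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_on_random_rasters(self, seed):
        r = np.random.default_rng(100 + seed)
        pred, truth = r.integers(0, 2, (2, 32, 32))
        c = _loop_counts(pred, truth)
        ms = compute_metrics(confusion_counts(_bm(pred), _bm(truth)))
        assert ms.dice == pytest.approx(2 * c.tp / (2 * c.tp + c.fp + c.fn))
        assert ms.sensitivity == pytest.approx(c.tp / (c.tp + c.fn))
        assert ms.specificity == pytest.approx(c.tn / (c.tn + c.fp))


class TestMicroAveraging:
    def test_additivity_over_images(self, rng):
        preds = [_bm(rng.integers(0, 2, (8, 8))) for _ in range(3)]
        truths = [_bm(rng.integers(0, 2, (8, 8))) for _ in range(3)]
        total, ms = evaluate_micro(preds, truths)
        by_hand = ConfusionCounts()
        for p, t in zip(preds, truths):
            by_hand = by_hand + confusion_counts(p, t)
        assert total == by_hand
        assert ms == compute_metrics(by_hand)

    def test_duplication_leaves_metrics_unchanged(self, rng):
        preds = [_bm(rng.integers(0, 2, (8, 8)))]
        truths = [_bm(rng.integers(0, 2, (8, 8)))]
        _, once = evaluate_micro(preds, truths)
        _, twice = evaluate_micro(preds * 2, truths * 2)
        assert once == twice

    def test_single_image_reduces_to_compute_metrics(self, rng):
        p = _bm(rng.integers(0, 2, (8, 8)))
        t = _bm(rng.integers(0, 2, (8, 8)))
        _, ms = evaluate_micro([p], [t])
        assert ms == compute_metrics(confusion_counts(p, t))

    def test_grouping_invariance(self, rng):
        """Micro metrics ignore how pixels are partitioned into images."""
        pred = rng.integers(0, 2, (4, 6, 6))
        truth = rng.integers(0, 2, (4, 6, 6))
        _, grouped = evaluate_micro([_bm(p) for p in pred], [_bm(t) for t in truth])
        _, pooled = evaluate_micro([_bm(pred.reshape(12, 12))],
                                   [_bm(truth.reshape(12, 12))])
        assert grouped == pooled

    def test_misaligned_lists(self):
        with pytest.raises(ValueError):
            evaluate_micro([_bm(np.zeros((2, 2)))], [])


def _brute_force_auc(scores, labels):
    pos = scores[labels.astype(bool)]
    neg = scores[~labels.astype(bool)]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def _run(self, scores, labels):
        pm = [ProbabilityMap(T, np.asarray(scores, float).reshape(1, -1))]
        tm = [_bm(np.asarray(labels).reshape(1, -1))]
        return roc_auc(pm, tm)

    def test_small_instance_matches_pair_enumeration(self):
        _, _, auc = self._run([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0])
        assert auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        _, _, auc = self._run([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_ties_half(self):
        _, _, auc = self._run([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert auc == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_rank_auc_equals_trapezoid_and_brute_force(self, seed):
        from sklearn.metrics import auc as sk_auc
        r = np.random.default_rng(seed)
        scores = np.round(r.random(60), 2)  # coarse grid forces ties
        labels = r.integers(0, 2, 60)
        if labels.all() or not labels.any():
            labels[0] = 1 - labels[0]
        fpr, tpr, auc = self._run(scores, labels)
        assert auc == pytest.approx(_brute_force_auc(scores, labels), abs=1e-12)
        assert auc == pytest.approx(sk_auc(fpr, tpr), abs=1e-9)

    def test_degenerate_truth_rejected(self):
        with pytest.raises(ValueError):
            self._run([0.1, 0.9], [1, 1])

    def test_subsampling_is_seeded(self):
        r = np.random.default_rng(0)
        scores = r.random(5000)
        labels = r.integers(0, 2, 5000)
        cfg = EvalConfig(max_roc_pixels=1000, seed=9)
        pm = [ProbabilityMap(T, scores.reshape(50, 100))]
        tm = [_bm(labels.reshape(50, 100))]
        assert roc_auc(pm, tm, cfg)[2] == roc_auc(pm, tm, cfg)[2]


class TestBootstrapCI:
    def test_perfect_prediction_degenerate_interval(self):
        ci = bootstrap_ci(ConfusionCounts(tp=40, tn=60), "dice", EvalConfig(seed=0))
        assert ci == CIResult(1.0, 1.0, 1.0)

    def test_same_seed_identical(self):
        c = ConfusionCounts(tp=30, fp=10, fn=5, tn=55)
        a = bootstrap_ci(c, "dice", EvalConfig(seed=4))
        b = bootstrap_ci(c, "dice", EvalConfig(seed=4))
        assert a == b

    def test_multinomial_equals_naive_pixel_resampling(self):
        """N=10 pixels: resample indices naively, feed the same draws through
        the multinomial path, and recompute each replicate by brute force."""
        pixels = np.array([0, 0, 0, 1, 1, 2, 2, 3, 3, 3])  # tp,fp,fn,tn codes
        counts = ConfusionCounts(tp=3, fp=2, fn=2, tn=3)
        B = 64
        r = np.random.default_rng(5)
        rep_counts = np.zeros((B, 4), dtype=np.int64)
        brute = np.zeros(B)
        for b in range(B):
            draw = pixels[r.integers(0, 10, size=10)]
            for cat in range(4):
                rep_counts[b, cat] = (draw == cat).sum()
            tp, fp, fn = (draw == 0).sum(), (draw == 1).sum(), (draw == 2).sum()
            brute[b] = 1.0 if 2 * tp + fp + fn == 0 else 2 * tp / (2 * tp + fp + fn)
        ci = bootstrap_ci(counts, "dice", EvalConfig(B=B, seed=0),
                          replicate_counts=rep_counts)
        lo, hi = np.quantile(brute, [0.025, 0.975])
        assert ci.lo == pytest.approx(lo) and ci.hi == pytest.approx(hi)

    def test_interval_width_shrinks_with_n(self):
        cfg = EvalConfig(seed=7)
        widths = []
        for n in (10**3, 10**5):
            # fixed 10% error rate, half fp half fn, 30% prevalence
            c = ConfusionCounts(tp=int(0.25 * n), fp=int(0.05 * n),
                                fn=int(0.05 * n), tn=int(0.65 * n))
            ci = bootstrap_ci(c, "dice", cfg)
            widths.append(ci.hi - ci.lo)
        assert widths[1] < widths[0] / 3

    def test_point_estimate_inside_interval(self):
        r = np.random.default_rng(11)
        inside = 0
        trials = 100
        for i in range(trials):
            raw = r.integers(1, 200, 4)
            c = ConfusionCounts(*map(int, raw))
            metric = ("dice", "sensitivity", "specificity")[i % 3]
            ci = bootstrap_ci(c, metric, EvalConfig(seed=i))
            inside += ci.lo - 1e-12 <= ci.point <= ci.hi + 1e-12
        assert inside >= 95

    def test_unknown_metric_and_empty_counts(self):
        with pytest.raises(ValueError):
            bootstrap_ci(ConfusionCounts(tp=1), "accuracy")
        with pytest.raises(ValueError):
            bootstrap_ci(ConfusionCounts(), "dice")


class TestPairedBootstrap:
    def test_identical_predictors_p_one(self):
        counts = [ConfusionCounts(tp=20, fp=5, fn=5, tn=70) for _ in range(4)]
        p = paired_bootstrap_test(counts, list(counts), "dice", EvalConfig(seed=0))
        assert p == 1.0

    def test_perfect_vs_poor_hits_floor(self):
        a = [ConfusionCounts(tp=500, tn=500) for _ in range(5)]
        b = [ConfusionCounts(tp=50, fp=450, fn=450, tn=50) for _ in range(5)]
        p = paired_bootstrap_test(a, b, "dice", EvalConfig(B=500, seed=0))
        assert p == pytest.approx(1 / 500)

    def test_clearly_better_predictor_significant(self):
        """A dominates B by a wide Dice margin on 50 images -> p < 0.05."""
        r = np.random.default_rng(3)
        n = 4096
        a, b = [], []
        for _ in range(50):
            pos = int(r.integers(200, 400))
            fn_a, fp_a = int(r.integers(0, 20)), int(r.integers(0, 20))
            fn_b, fp_b = int(r.integers(100, 180)), int(r.integers(100, 200))
            a.append(ConfusionCounts(tp=pos - fn_a, fp=fp_a, fn=fn_a,
                                     tn=n - pos - fp_a))
            b.append(ConfusionCounts(tp=pos - fn_b, fp=fp_b, fn=fn_b,
                                     tn=n - pos - fp_b))
        p = paired_bootstrap_test(a, b, "dice", EvalConfig(seed=1))
        assert p < 0.05

    def test_misaligned_inputs(self):
        c = [ConfusionCounts(tp=1, tn=1)]
        with pytest.raises(ValueError):
            paired_bootstrap_test(c, c * 2, "dice")
        with pytest.raises(ValueError):
            paired_bootstrap_test(c, [ConfusionCounts(tp=3, tn=4)], "dice")


class TestReport:
    # per-model test-set metrics of the four transfer-learned base models
    NUCLEUS_DICE = (0.7411, 0.7506, 0.8055, 0.7731)
    NUCLEUS_SENS = (0.9431, 0.9566, 0.9481, 0.9653)
    NUCLEUS_SPEC = (0.9951, 0.9952, 0.9967, 0.9957)

    def _report(self, dice, sens, spec):
        per_model = [(f"m{i}", MetricSet(d, s, p))
                     for i, (d, s, p) in enumerate(zip(dice, sens, spec))]
        return summarize_report(per_model)

    def test_average_row_recomputes_reference_cells(self):
        rep = self._report(self.NUCLEUS_DICE, self.NUCLEUS_SENS, self.NUCLEUS_SPEC)
        assert round_half_away(rep.average.dice) == 0.7676
        assert round_half_away(rep.average.sensitivity) == 0.9533
        assert round_half_away(rep.average.specificity) == 0.9957

    def test_single_model_average_is_itself(self):
        rep = self._report((0.8,), (0.9,), (0.95,))
        assert rep.average == MetricSet(0.8, 0.9, 0.95)

    def test_round_half_away_from_zero(self):
        assert round_half_away(0.95205) == 0.9521
        assert round_half_away(0.982975) == 0.9830
        assert round_half_away(0.00005) == 0.0001

    def test_dataframe_layout(self):
        rep = summarize_report([("a", MetricSet(0.9, 0.8, 0.7))],
                               ensemble=MetricSet(0.92, 0.81, 0.72),
                               cis={"dice": CIResult(0.92, 0.91, 0.93)})
        df = rep.to_dataframe()
        assert list(df["model"]) == ["a", "Average value", "Ensemble model"]
        assert df.iloc[2]["dice_ci"] == "0.9100-0.9300"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_report([])
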