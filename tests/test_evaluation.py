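import math

import numpy as np
import pytest

from m6aloco.evaluation import (
    ConfusionCounts,
    EvaluationError,
    MetricsReport,
    aggregate,
    auc_roc,
    confidence_interval,
    confusion,
    evaluate_predictions,
    metrics_from_confusion,
    tsne_view,
)


def brute_force_metrics(c: ConfusionCounts):
    """Independent re-coding of the standard confusion-matrix formulas."""
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    total = tp + tn + fp + fn
    acc = (tn + tp) / total
    sens = tp / (tp + fn) if tp + fn else None
    spec = tn / (fp + tn) if fp + tn else None
    denom = math.sqrt((tn + fp) * (tn + fn) * (tp + fp) * (tp + fn)) if (
        (tn + fp) and (tn + fn) and (tp + fp) and (tp + fn)
    ) else 0
    mcc = (tp * tn - fp * fn) / denom if denom else None
    return acc, sens, spec, mcc


def brute_force_auc(y, s):
    """Exhaustive pairwise comparison of positive vs negative scores."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect(self):
        c = confusion([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2], 0.5)
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 0, 0)

    def test_inverted(self):
        c = confusion([1, 0], [0.4, 0.6], 0.5)
        assert (c.tp, c.tn, c.fp, c.fn) == (0, 0, 1, 1)

    def test_tie_counts_as_positive(self):
        c = confusion([1, 0], [0.5, 0.5], 0.5)
        assert c.tp == 1 and c.fp == 1

    def test_errors(self):
        with pytest.raises(EvaluationError):
            confusion([1], [0.5, 0.5])
        with pytest.raises(EvaluationError):
            confusion([], [])


class TestMetricsFromConfusion:
    def test_perfect_classifier(self):
        rep = metrics_from_confusion(ConfusionCounts(5, 5, 0, 0))
        assert rep.accuracy == 1.0 and rep.mcc == 1.0

    def test_worked_confusion_against_oracle(self):
        c = ConfusionCounts(tp=3, fn=1, tn=2, fp=2)
        rep = metrics_from_confusion(c)
        assert rep.accuracy == pytest.approx(0.625)
        assert rep.sensitivity == pytest.approx(0.75)
        assert rep.specificity == pytest.approx(0.5)
        acc, sens, spec, mcc = brute_force_metrics(c)
        assert rep.mcc == pytest.approx(mcc)

    def test_no_predicted_positives_mcc_undefined(self):
        rep = metrics_from_confusion(ConfusionCounts(tp=0, fp=0, tn=3, fn=2))
        assert rep.mcc is None
        assert "mcc" in rep.undefined

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_random_confusions(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(100):
            c = ConfusionCounts(*(int(x) for x in rng.integers(0, 20, 4)))
            if c.total == 0:
                continue
            rep = metrics_from_confusion(c)
            acc, sens, spec, mcc = brute_force_metrics(c)
            assert rep.accuracy == pytest.approx(acc)
            for got, want in [(rep.sensitivity, sens), (rep.specificity, spec), (rep.mcc, mcc)]:
                if want is None:
                    assert got is None
                else:
                    assert got == pytest.approx(want)


class TestAucRoc:
    def test_perfect_separation(self):
        assert auc_roc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_half(self):
        assert auc_roc([0, 1, 0, 1], [0.5] * 4) == 0.5

    def test_six_point_vs_pairwise_oracle(self):
        y = [1, 0, 1, 0, 1, 0]
        s = [0.9, 0.8, 0.8, 0.3, 0.2, 0.1]
        assert auc_roc(y, s) == pytest.approx(brute_force_auc(y, s))

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_random_scores(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(100):
            n = int(rng.integers(4, 15))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            s = np.round(rng.random(n), 1)  # coarse grid to exercise ties
            assert auc_roc(y, s) == pytest.approx(brute_force_auc(y, s))

    def test_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 200)
        s = rng.random(200)
        assert auc_roc(y, s) == pytest.approx(roc_auc_score(y, s))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 50)
        s = rng.random(50)
        assert auc_roc(y, s) == pytest.approx(auc_roc(y, np.exp(3 * s)))

    def test_negated_scores_complement(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 50)
        s = rng.random(50)
        assert auc_roc(y, -s) == pytest.approx(1 - auc_roc(y, s))

    def test_single_class_undefined(self):
        with pytest.raises(EvaluationError):
            auc_roc([1, 1], [0.2, 0.4])


class TestLabelSwapLaws:
    @pytest.mark.parametrize("seed", range(3))
    def test_swap_laws(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, 80)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        s = rng.random(80)
        rep = evaluate_predictions(y, s)
        # relabel classes and flip scores around the 0.5 threshold
        swapped = evaluate_predictions(1 - y, 1 - s + 1e-12)
        assert swapped.accuracy == pytest.approx(rep.accuracy, abs=1e-9)
        assert swapped.sensitivity == pytest.approx(rep.specificity)
        assert swapped.specificity == pytest.approx(rep.sensitivity)
        assert swapped.mcc == pytest.approx(rep.mcc, abs=1e-9)


class TestConfidenceInterval:
    def test_constant_series_zero_width(self):
        lo, hi = confidence_interval([0.7, 0.7, 0.7])
        assert hi - lo == pytest.approx(0.0, abs=1e-12)
        assert lo == pytest.approx(0.7)

    def test_two_values_hand_computed(self):
        # mu = 0.85, s = sd([0.8, 0.9], ddof=1), half-width z * s / sqrt(2)
        lo, hi = confidence_interval([0.8, 0.9], level=0.95)
        s = np.std([0.8, 0.9], ddof=1)
        half = 1.959963985 * s / np.sqrt(2)
        assert lo == pytest.approx(0.85 - half)
        assert hi == pytest.approx(0.85 + half)

    def test_bootstrap_reproducible(self):
        vals = [0.7, 0.8, 0.75, 0.9, 0.82]
        a = confidence_interval(vals, method="bootstrap", seed=11)
        b = confidence_interval(vals, method="bootstrap", seed=11)
        assert a == b

    def test_degenerate_input(self):
        with pytest.raises(EvaluationError):
            confidence_interval([0.5])


class TestAggregate:
    def test_mean_across_chromosome_reports(self):
        reports = [
            MetricsReport(accuracy=a, n=10, scope=f"chr{i}")
            for i, a in enumerate([0.8, 0.9, 1.0], 1)
        ]
        agg = aggregate(reports, by="chromosome")
        assert agg.accuracy == pytest.approx(0.9)
        assert "accuracy" in agg.ci

    def test_undefined_excluded_and_disclosed(self):
        reports = [
            MetricsReport(accuracy=0.8, sensitivity=0.7, n=5),
            MetricsReport(accuracy=0.9, sensitivity=None, n=5, undefined={"sensitivity": "x"}),
        ]
        agg = aggregate(reports)
        assert agg.sensitivity == pytest.approx(0.7)
        assert "sensitivity_excluded" in agg.undefined

    def test_single_report_degenerate(self):
        agg = aggregate([MetricsReport(accuracy=0.5, n=4)])
        assert agg.accuracy == 0.5 and "accuracy" not in agg.ci


class TestTsneView:
    def test_separated_clusters_and_determinism(self, tmp_path):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.3, size=(100, 10))
        b = rng.normal(4, 0.3, size=(100, 10))
        X = np.vstack([a, b])
        y = np.array([0] * 100 + [1] * 100)
        c1 = tsne_view(X, y, seed=4, perplexity=20, out_prefix=tmp_path / "t")
        c2 = tsne_view(X, y, seed=4, perplexity=20)
        assert np.allclose(c1, c2)
        assert (tmp_path / "t.csv").exists() and (tmp_path / "t.png").exists()
        from sklearn.metrics import silhouette_score

        assert silhouette_score(c1, y) > 0.5

    def test_too_few_points(self):
        with pytest.raises(EvaluationError):
            tsne_view(np.zeros((10, 3)), np.zeros(10), perplexity=30)
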