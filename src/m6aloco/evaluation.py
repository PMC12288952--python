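"""Classification metrics, confidence intervals, aggregation, and t-SNE views.

The metric suite is the standard binary-classification panel: accuracy,
sensitivity (recall on positives), specificity (recall on negatives),
Matthews correlation coefficient, and AUC-ROC.  AUC is computed as the
tie-corrected Mann-Whitney rank statistic, which equals the trapezoidal
area under the ROC curve.  Confidence intervals use the normal
approximation mu +/- z * sigma / sqrt(n) with the sample (n-1) standard
deviation, or optionally a seeded percentile bootstrap.

Degenerate quantities (zero denominators, single-class inputs) are reported
as ``None`` with an explicit reason — never silently coerced to 0 — and
aggregation excludes them while disclosing how many were excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "mcc", "auc_roc")


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Point metrics, optional per-metric CIs, and provenance of the scope.

    A metric that cannot be computed is ``None`` with the reason recorded in
    ``undefined``; ``ci`` maps metric name to (lower, upper).
    """

    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    mcc: float | None = None
    auc_roc: float | None = None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    undefined: dict[str, str] = field(default_factory=dict)
    n: int = 0
    scope: str = ""

    def metric(self, name: str) -> float | None:
        return getattr(self, name)

    def to_dict(self) -> dict:
        d = {m: self.metric(m) for m in METRIC_NAMES}
        d.update(
            {f"{m}_ci_low": self.ci[m][0] for m in self.ci},
            **{f"{m}_ci_high": self.ci[m][1] for m in self.ci},
        )
        d["n"] = self.n
        d["scope"] = self.scope
        return d


def confusion(y_true, y_prob, threshold: float = 0.5) -> ConfusionCounts:
    """Tally the confusion matrix; a probability exactly at the threshold
    counts as a positive call (documented tie rule)."""
    y_true = np.asarray(y_true)
    y_prob = np.asarray(y_prob)
    if y_true.shape != y_prob.shape:
        raise EvaluationError(f"length mismatch: {y_true.shape} vs {y_prob.shape}")
    if y_true.size == 0:
        raise EvaluationError("empty input")
    if not 0 < threshold < 1:
        raise EvaluationError(f"threshold must be in (0,1), got {threshold}")
    pred = y_prob >= threshold
    pos = y_true == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def metrics_from_confusion(c: ConfusionCounts, scope: str = "") -> MetricsReport:
    """Accuracy, sensitivity, specificity and MCC from confusion counts;
    zero-denominator cases flow to the undefined channel with a reason."""
    rep = MetricsReport(n=c.total, scope=scope)
    if c.total == 0:
        rep.undefined["accuracy"] = "no evaluated records"
        return rep
    rep.accuracy = (c.tp + c.tn) / c.total
    if c.tp + c.fn > 0:
        rep.sensitivity = c.tp / (c.tp + c.fn)
    else:
        rep.undefined["sensitivity"] = "no positive records (TP+FN=0)"
    if c.tn + c.fp > 0:
        rep.specificity = c.tn / (c.tn + c.fp)
    else:
        rep.undefined["specificity"] = "no negative records (TN+FP=0)"
    denom = (c.tn + c.fp) * (c.tn + c.fn) * (c.tp + c.fp) * (c.tp + c.fn)
    if denom > 0:
        rep.mcc = (c.tp * c.tn - c.fp * c.fn) / np.sqrt(denom)
    else:
        rep.undefined["mcc"] = "zero MCC denominator (a confusion margin is empty)"
    return rep


def auc_roc(y_true, y_prob) -> float:
    """Tie-corrected Mann-Whitney AUC: the probability that a random
    positive outscores a random negative, ties counted half."""
    y_true = np.asarray(y_true)
    y_prob = np.asarray(y_prob, dtype=np.float64)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError(
            f"AUC undefined: both classes required (n_pos={n_pos}, n_neg={n_neg})"
        )
    ranks = stats.rankdata(y_prob)  # average ranks handle ties
    rank_sum_pos = float(np.sum(ranks[y_true == 1]))
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def confidence_interval(
    values,
    level: float = 0.95,
    method: str = "normal",
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """CI over a series of repeated evaluations.

    ``normal``: mu +/- z * s / sqrt(n) with the (n-1)-denominator sample
    standard deviation; ``bootstrap``: seeded percentile bootstrap of the
    mean.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise EvaluationError(f"confidence interval needs >=2 values, got {v.size}")
    if not 0 < level < 1:
        raise EvaluationError(f"level must be in (0,1), got {level}")
    mu = float(v.mean())
    if method == "normal":
        z = stats.norm.ppf((1 + level) / 2)
        half = z * v.std(ddof=1) / np.sqrt(v.size)
        return (mu - half, mu + half)
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        means = rng.choice(v, size=(n_boot, v.size), replace=True).mean(axis=1)
        lo, hi = np.quantile(means, [(1 - level) / 2, (1 + level) / 2])
        return (float(lo), float(hi))
    raise EvaluationError(f"unknown CI method {method!r}")


def evaluate_predictions(y_true, y_prob, threshold: float = 0.5, scope: str = "") -> MetricsReport:
    """Full metric panel for one prediction set."""
    rep = metrics_from_confusion(confusion(y_true, y_prob, threshold), scope=scope)
    try:
        rep.auc_roc = auc_roc(y_true, y_prob)
    except EvaluationError as e:
        rep.undefined["auc_roc"] = str(e)
    return rep


def aggregate(reports: list[MetricsReport], by: str = "cv_fold", level: float = 0.95) -> MetricsReport:
    """Unweighted mean of each defined metric across reports, with a
    cross-report CI; undefined entries excluded and their count disclosed."""
    if not reports:
        raise EvaluationError("nothing to aggregate")
    out = MetricsReport(n=sum(r.n for r in reports), scope=f"mean over {len(reports)} {by}s")
    for m in METRIC_NAMES:
        vals = [r.metric(m) for r in reports if r.metric(m) is not None]
        excluded = len(reports) - len(vals)
        if not vals:
            out.undefined[m] = f"all {len(reports)} reports undefined"
            continue
        setattr(out, m, float(np.mean(vals)))
        if excluded:
            out.undefined[f"{m}_excluded"] = f"{excluded} undefined report(s) excluded"
        if len(vals) >= 2:
            out.ci[m] = confidence_interval(vals, level=level)
    return out


def reports_to_csv(reports: list[MetricsReport], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame([r.to_dict() for r in reports]).to_csv(path, index=False)


def roc_points(y_true, y_prob):
    """(fpr, tpr, thresholds) arrays for plotting the ROC curve."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(y_true, y_prob)
    return fpr, tpr, thr


def tsne_view(
    embeddings: np.ndarray,
    labels,
    seed: int = 0,
    perplexity: float = 30.0,
    out_prefix: str | Path | None = None,
):
    """Seeded 2-D t-SNE of an embedding matrix, colored by class label.

    Returns the (n, 2) coordinates; when ``out_prefix`` is given also
    writes ``<prefix>.csv`` and ``<prefix>.png``.
    """
    import logging

    from sklearn.manifold import TSNE

    X = np.asarray(embeddings, dtype=np.float64)
    y = np.asarray(labels)
    if X.shape[0] < 3 * perplexity:
        raise EvaluationError(
            f"t-SNE needs >= 3*perplexity={3 * perplexity:.0f} points, got {X.shape[0]}"
        )
    if len(np.unique(y)) < 2:
        logging.getLogger(__name__).warning("t-SNE input carries a single class")
    coords = TSNE(
        n_components=2, random_state=seed, perplexity=perplexity, init="pca"
    ).fit_transform(X)
    if out_prefix is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        import pandas as pd

        prefix = Path(out_prefix)
        pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1], "label": y}).to_csv(
            prefix.with_suffix(".csv"), index=False
        )
        fig, ax = plt.subplots(figsize=(5, 5))
        for lab, color in ((0, "tab:blue"), (1, "tab:red")):
            m = y == lab
            ax.scatter(coords[m, 0], coords[m, 1], s=8, alpha=0.6, c=color, label=str(lab))
        ax.legend(title="label")
        ax.set_xlabel("t-SNE 1")
        ax.set_ylabel("t-SNE 2")
        fig.tight_layout()
        fig.savefig(prefix.with_suffix(".png"), dpi=120)
        plt.close(fig)
    return coords
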