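"""Imbalance-aware performance evaluation.

Primary metrics are sensitivity, specificity, MCC and rank AUC; secondary
metrics are PPV, NPV, Brier score, accuracy and support-weighted F1.
Uncertainty is quantified with percentile bootstrap confidence intervals
(row resampling, default 1000 replicates).  Two reference analyses frame
the numbers: the incidence-only null model (predict everyone positive —
the recall ceiling and precision floor under the observed incidence) and a
three-way report on test / original train / resampled train splits that
makes memorization of resampling artifacts visible.

Zero-denominator conventions: MCC is 0 whenever any factor of its
denominator is 0 (so the null model scores exactly 0), and PPV/NPV with no
predicted positives/negatives report 0 with an ``undefined`` flag rather
than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .modeling import ThresholdPolicy, classify

__all__ = [
    "ConfusionCounts",
    "BootstrapConfig",
    "MetricReport",
    "confusion",
    "metrics_from_confusion",
    "auc_rank",
    "brier_score",
    "evaluate_scores",
    "bootstrap_ci",
    "null_model_report",
    "threshold_sweep",
    "overfit_report",
]

PRIMARY_METRICS = ("sensitivity", "specificity", "auc", "mcc")
ALL_METRICS = (
    "sensitivity",
    "specificity",
    "auc",
    "mcc",
    "ppv",
    "npv",
    "brier",
    "accuracy",
    "weighted_f1",
)
#: metrics undefined on single-class bootstrap replicates
CLASS_CONDITIONAL = ("sensitivity", "specificity", "auc", "ppv", "npv")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _check_binary(labels, predictions) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.shape != p.shape:
        raise ValueError("labels and predictions differ in length")
    if y.size == 0:
        raise ValueError("empty input")
    return y, p


def confusion(labels, predictions) -> ConfusionCounts:
    y, p = _check_binary(labels, predictions)
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def metrics_from_confusion(c: ConfusionCounts) -> dict[str, float]:
    """Decision metrics from a confusion table.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), defined as
    0 when any denominator factor vanishes.  weighted_f1 is the
    class-support-weighted mean of the per-class F1 scores.
    """
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    sens = _safe_div(tp, tp + fn)
    spec = _safe_div(tn, tn + fp)
    ppv = _safe_div(tp, tp + fp)
    npv = _safe_div(tn, tn + fn)
    acc = _safe_div(tp + tn, c.n)
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(den) if den else 0.0
    f1_pos = _safe_div(2 * ppv * sens, ppv + sens)
    npv_neg_prec, neg_rec = npv, spec
    f1_neg = _safe_div(2 * npv_neg_prec * neg_rec, npv_neg_prec + neg_rec)
    n_pos, n_neg = tp + fn, tn + fp
    wf1 = _safe_div(n_pos * f1_pos + n_neg * f1_neg, c.n)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ppv,
        "npv": npv,
        "accuracy": acc,
        "mcc": float(mcc),
        "weighted_f1": wf1,
    }


def auc_rank(labels, scores) -> float:
    """Rank (Mann-Whitney) AUC; ties contribute 1/2."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes")
    r = rankdata(s)
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def brier_score(labels, scores) -> float:
    y = np.asarray(labels, dtype=float)
    s = np.asarray(scores, dtype=float)
    return float(np.mean((s - y) ** 2))


def evaluate_scores(labels, scores, policy: ThresholdPolicy) -> dict[str, float]:
    """Point estimates of every metric at one threshold."""
    preds = classify(scores, policy)
    out = metrics_from_confusion(confusion(labels, preds))
    y = np.asarray(labels, dtype=int)
    out["auc"] = auc_rank(labels, scores) if 0 < y.sum() < y.size else float("nan")
    out["brier"] = brier_score(labels, scores)
    return out


@dataclass(frozen=True)
class BootstrapConfig:
    n_reps: int = 1000
    ci_level: float = 0.95
    seed: int = 0
    stratified: bool = False

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass
class MetricReport:
    """Per-metric point estimates with percentile bootstrap CIs."""

    metrics: dict[str, dict[str, float]]  # name -> {point, ci_low, ci_high}
    threshold: float
    split: str = ""
    bootstrap: BootstrapConfig | None = None
    skipped_replicates: int = 0
    flags: dict[str, str] = field(default_factory=dict)

    def point(self, name: str) -> float:
        return self.metrics[name]["point"]

    def ci(self, name: str) -> tuple[float, float]:
        m = self.metrics[name]
        return m["ci_low"], m["ci_high"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.metrics).T[["point", "ci_low", "ci_high"]]


def bootstrap_ci(
    labels,
    scores,
    policy: ThresholdPolicy,
    config: BootstrapConfig | None = None,
    metrics: tuple[str, ...] = ALL_METRICS,
    split: str = "",
) -> MetricReport:
    """Percentile bootstrap CIs by row resampling with replacement.

    Replicates missing a class are skipped for class-conditional metrics
    (the skip count is reported); an optional class-stratified resampling
    mode avoids them entirely.
    """
    config = config or BootstrapConfig()
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 rows to bootstrap")
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both classes required in the observed data")
    rng = np.random.default_rng(config.seed)
    n = y.size
    point = evaluate_scores(y, s, policy)
    preds = classify(s, policy)

    if config.stratified:
        pos, neg = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
        idx = np.concatenate(
            [
                rng.choice(pos, size=(config.n_reps, pos.size), replace=True),
                rng.choice(neg, size=(config.n_reps, neg.size), replace=True),
            ],
            axis=1,
        )
    else:
        idx = rng.integers(0, n, size=(config.n_reps, n))

    yb, pb = y[idx], preds[idx]
    tp = ((yb == 1) & (pb == 1)).sum(axis=1).astype(float)
    fp = ((yb == 0) & (pb == 1)).sum(axis=1).astype(float)
    tn = ((yb == 0) & (pb == 0)).sum(axis=1).astype(float)
    fn = ((yb == 1) & (pb == 0)).sum(axis=1).astype(float)
    single_class = (tp + fn == 0) | (tn + fp == 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        reps: dict[str, np.ndarray] = {}
        if "sensitivity" in metrics:
            reps["sensitivity"] = tp / (tp + fn)
        if "specificity" in metrics:
            reps["specificity"] = tn / (tn + fp)
        if "ppv" in metrics:
            d = tp + fp
            reps["ppv"] = np.where(d > 0, tp / np.where(d > 0, d, 1), 0.0)
        if "npv" in metrics:
            d = tn + fn
            reps["npv"] = np.where(d > 0, tn / np.where(d > 0, d, 1), 0.0)
        if "accuracy" in metrics:
            reps["accuracy"] = (tp + tn) / n if not config.stratified else (tp + tn) / idx.shape[1]
        if "mcc" in metrics:
            den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            reps["mcc"] = np.where(den > 0, (tp * tn - fp * fn) / np.sqrt(np.where(den > 0, den, 1)), 0.0)
        if "weighted_f1" in metrics:
            f1p = np.where(2 * tp + fp + fn > 0, 2 * tp / np.maximum(2 * tp + fp + fn, 1), 0.0)
            f1n = np.where(2 * tn + fp + fn > 0, 2 * tn / np.maximum(2 * tn + fp + fn, 1), 0.0)
            reps["weighted_f1"] = ((tp + fn) * f1p + (tn + fp) * f1n) / idx.shape[1]
        if "brier" in metrics:
            reps["brier"] = ((s[idx] - yb) ** 2).mean(axis=1)
        if "auc" in metrics:
            aucs = np.full(config.n_reps, np.nan)
            for r in range(config.n_reps):
                if not single_class[r]:
                    aucs[r] = auc_rank(yb[r], s[idx[r]])
            reps["auc"] = aucs

    alpha = (1 - config.ci_level) / 2
    out: dict[str, dict[str, float]] = {}
    for name in metrics:
        vals = reps[name]
        if name in CLASS_CONDITIONAL:
            vals = vals[~single_class]
        vals = vals[~np.isnan(vals)]
        lo, hi = (
            (float(np.percentile(vals, 100 * alpha)), float(np.percentile(vals, 100 * (1 - alpha))))
            if vals.size
            else (float("nan"), float("nan"))
        )
        out[name] = {"point": point[name], "ci_low": lo, "ci_high": hi}
    return MetricReport(
        metrics=out,
        threshold=policy.threshold,
        split=split,
        bootstrap=config,
        skipped_replicates=int(single_class.sum()),
    )


def null_model_report(labels, split: str = "test") -> MetricReport:
    """Evaluate the incidence-only null model (everyone predicted positive).

    By construction: sensitivity 1, specificity 0, MCC 0, AUC 1/2 (constant
    scores — all pairs tie), PPV = prevalence, NPV undefined (flagged).
    """
    y = np.asarray(labels, dtype=int)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("null-model report requires both classes")
    prevalence = y.mean()
    scores = np.full(y.size, 0.5)
    policy = ThresholdPolicy(0.5, origin="fixed")
    vals = evaluate_scores(y, scores, policy)
    metrics = {k: {"point": v, "ci_low": v, "ci_high": v} for k, v in vals.items()}
    report = MetricReport(metrics=metrics, threshold=policy.threshold, split=split)
    report.flags["npv"] = "undefined: no predicted negatives"
    report.flags["prevalence"] = f"{prevalence:.6g}"
    return report


def threshold_sweep(labels, scores, grid) -> pd.DataFrame:
    """Metric series across a strictly increasing threshold grid.

    Sensitivity is non-increasing and specificity non-decreasing in the
    threshold (each increase can only de-flag positives).
    """
    grid = tuple(grid)
    if not all(0 < t < 1 for t in grid):
        raise ValueError("thresholds must lie in (0, 1)")
    if not all(a < b for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be strictly increasing")
    rows = []
    for t in grid:
        vals = evaluate_scores(labels, scores, ThresholdPolicy(t))
        rows.append({"threshold": t, **vals})
    return pd.DataFrame(rows)


def overfit_report(
    model,
    splits: dict,
    policy: ThresholdPolicy,
    config: BootstrapConfig | None = None,
    correction=None,
) -> dict[str, MetricReport | None]:
    """Side-by-side evaluation on test / original train / resampled train.

    A memorizing model shows near-perfect resampled-train metrics that
    collapse on the imbalanced test split; a well-regularized one is flat
    across the three.  Missing splits are reported as absent (None).
    """
    out: dict[str, MetricReport | None] = {}
    for name in ("test", "train_original", "train_resampled"):
        table = splits.get(name)
        if table is None:
            out[name] = None
            continue
        scores = model.predict_proba(table)
        if correction is not None:
            scores = correction(scores)
        out[name] = bootstrap_ci(table.y, scores, policy, config, split=name)
    return out
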