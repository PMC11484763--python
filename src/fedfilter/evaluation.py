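"""Per-client and macro evaluation metrics, and gradient feature importance.

AUROC is the rank statistic with tie mid-ranks and AUPRC the step-wise
precision–recall integral (both via scikit-learn).  Threshold-dependent
metrics (sensitivity, specificity, PPV, NPV) are computed from the
confusion matrix at either a fixed threshold or the Youden-J-optimal
threshold chosen on a validation split.  Metrics that are undefined on a
single-class sample are reported as NaN and excluded from macro means —
never fabricated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve

from .compose import input_gradients

METRIC_NAMES = ("auroc", "auprc", "sensitivity", "specificity", "ppv", "npv")

__all__ = [
    "METRIC_NAMES",
    "MetricsReport",
    "ImportanceReport",
    "youden_threshold",
    "compute_metrics",
    "feature_importance",
]


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximising sensitivity + specificity - 1 on the given data."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        return 0.5
    fpr, tpr, thr = roc_curve(labels, scores)
    j = tpr - fpr
    best = int(np.argmax(j))
    t = float(thr[best])
    return min(t, 1.0)  # roc_curve's leading threshold can exceed 1


def _binary_metrics(scores: np.ndarray, labels: np.ndarray, threshold: float) -> dict:
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=np.float64)
    out = {m: float("nan") for m in METRIC_NAMES}
    classes = np.unique(labels)
    if len(classes) == 2:
        out["auroc"] = float(roc_auc_score(labels, scores))
        out["auprc"] = float(average_precision_score(labels, scores))
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    if tp + fn > 0:
        out["sensitivity"] = tp / (tp + fn)
    if tn + fp > 0:
        out["specificity"] = tn / (tn + fp)
    if tp + fp > 0:
        out["ppv"] = tp / (tp + fp)
    if tn + fn > 0:
        out["npv"] = tn / (tn + fn)
    return out


def compute_metrics(scores: np.ndarray, labels: np.ndarray,
                    threshold_policy: str = "fixed", threshold: float = 0.5,
                    val_scores: np.ndarray | None = None,
                    val_labels: np.ndarray | None = None) -> dict:
    """One evaluation row: AUROC/AUPRC plus confusion metrics at a threshold.

    ``threshold_policy`` is ``"fixed"`` (use ``threshold``) or ``"youden"``
    (maximise Youden's J on the validation scores; falls back to the fixed
    threshold when no validation data is supplied).  Multilabel inputs
    (2-d scores/labels) are macro-averaged over labels, per-label
    thresholds, skipping labels undefined on the sample.
    """
    if threshold_policy not in ("fixed", "youden"):
        raise ValueError(f"unknown threshold policy {threshold_policy!r}")
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError(f"scores shape {scores.shape} != labels shape {labels.shape}")
    if scores.ndim == 1:
        t = threshold
        if threshold_policy == "youden" and val_scores is not None:
            t = youden_threshold(np.asarray(val_scores), np.asarray(val_labels))
        return _binary_metrics(scores, labels, t)
    # multilabel: macro over labels
    rows = []
    for j in range(scores.shape[1]):
        t = threshold
        if threshold_policy == "youden" and val_scores is not None:
            t = youden_threshold(np.asarray(val_scores)[:, j], np.asarray(val_labels)[:, j])
        rows.append(_binary_metrics(scores[:, j], labels[:, j], t))
    out = {}
    for m in METRIC_NAMES:
        vals = [r[m] for r in rows if np.isfinite(r[m])]
        out[m] = float(np.mean(vals)) if vals else float("nan")
    return out


@dataclass
class MetricsReport:
    """Per-client metric table with unweighted macro summaries.

    ``per_client`` averages each client's metrics over runs; ``per_run``
    keeps every (run, client) row.  ``macro_mean``/``macro_sd`` are the
    unweighted mean and standard deviation across clients of the per-client
    run means, skipping NaNs with a logged count.
    """

    scenario: str
    method: str
    per_run: pd.DataFrame              # columns: run, client, <metrics>
    n_runs: int = 1
    n_undefined: int = 0

    @property
    def per_client(self) -> pd.DataFrame:
        return self.per_run.groupby("client")[list(METRIC_NAMES)].mean()

    @property
    def macro_mean(self) -> dict:
        pc = self.per_client
        return {m: float(np.nanmean(pc[m])) for m in METRIC_NAMES}

    @property
    def macro_sd(self) -> dict:
        pc = self.per_client
        return {m: float(np.nanstd(pc[m], ddof=0)) for m in METRIC_NAMES}

    def run_macro(self, metric: str = "auroc") -> np.ndarray:
        """Per-run macro value: unweighted mean over clients within each run."""
        g = self.per_run.groupby("run")[metric].mean()
        return g.to_numpy()

    def to_frame(self) -> pd.DataFrame:
        df = self.per_client.copy()
        df.loc["macro_mean"] = pd.Series(self.macro_mean)
        df.loc["macro_sd"] = pd.Series(self.macro_sd)
        return df


@dataclass
class ImportanceReport:
    """Mean absolute input gradient per native feature of one client."""

    client_id: str
    feature_names: list[str]
    values: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature": self.feature_names, "importance": self.values})


def feature_importance(theta, spec, X: np.ndarray, h=None, stack=None,
                       adjacency=None, feature_names: list[str] | None = None,
                       client_id: str = "") -> ImportanceReport:
    """Gradient-based feature importance on a sample set.

    Mean over samples (and output labels) of |d p / d x|, reported in the
    client's native feature order.  Time-series gradients are additionally
    averaged over time steps.
    """
    X = np.asarray(X, dtype=np.float64)
    n_labels = spec.output_dim
    acc = np.zeros(X.shape[-1])
    for j in range(n_labels):
        g = input_gradients(theta, spec, X, h=h, stack=stack,
                            adjacency=adjacency, label=j)
        a = np.abs(g)
        while a.ndim > 1:
            a = a.mean(axis=0)
        acc += a
    acc /= n_labels
    names = feature_names if feature_names is not None else [
        f"x{i}" for i in range(X.shape[-1])]
    if len(names) != X.shape[-1]:
        raise ValueError("feature_names length must match the feature dimension")
    return ImportanceReport(client_id=client_id, feature_names=list(names), values=acc)
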