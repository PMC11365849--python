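"""Classification metrics and cross-fold aggregation.

AUROC is the probability that a random anomalous volume outranks a random
normal one (ties count one half); AUPRC is average precision (step-wise, no
interpolation); F1 is taken on the anomalous class. Fold means are reported
with Student-t 95% confidence intervals, the conventional choice for k-fold
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score

POSITIVE_LABEL = 1  # anomalous


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    return scores, labels


def auroc(scores, labels) -> float:
    scores, labels = _validate(scores, labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(labels, scores))


def auprc(scores, labels) -> float:
    scores, labels = _validate(scores, labels)
    if not np.any(labels == POSITIVE_LABEL):
        raise ValueError("AUPRC needs at least one positive")
    return float(average_precision_score(labels, scores))


def f1(predictions, labels) -> float:
    predictions, labels = _validate(predictions, labels)
    return float(f1_score(labels, predictions, pos_label=POSITIVE_LABEL,
                          zero_division=0))


def aggregate_ci(values, level: float = 0.95) -> tuple[float, float, float]:
    """(mean, ci_low, ci_high) with a Student-t interval over fold values."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two values to aggregate")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    tq = float(stats.t.ppf(0.5 + level / 2.0, df=values.size - 1))
    half = tq * sd / np.sqrt(values.size)
    return mean, mean - half, mean + half


@dataclass
class MetricsReport:
    """Per-fold metric triplets plus their aggregated mean and 95% CI."""

    per_fold: list[dict] = field(default_factory=list)
    config_fingerprint: str = ""
    ci_level: float = 0.95

    def add_fold(self, auroc_value: float, auprc_value: float, f1_value: float) -> None:
        self.per_fold.append({"auroc": auroc_value, "auprc": auprc_value,
                              "f1": f1_value})

    def summary(self) -> dict:
        out = {"n_folds": len(self.per_fold), "ci_level": self.ci_level,
               "ci_method": "student_t",
               "config_fingerprint": self.config_fingerprint}
        for metric in ("auroc", "auprc", "f1"):
            values = [fold[metric] for fold in self.per_fold]
            if len(values) >= 2:
                mean, lo, hi = aggregate_ci(values, self.ci_level)
            else:
                mean, lo, hi = float(values[0]), float(values[0]), float(values[0])
            out[metric] = {"mean": mean, "ci_low": lo, "ci_high": hi,
                           "per_fold": values}
        return out
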