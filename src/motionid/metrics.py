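"""Per-target classification metrics and cross-target median/IQR summaries.

One-vs-rest authentication is evaluated per target user with precision,
recall, F1 and accuracy on the positive (target) class, then summarized
across targets with the median and interquartile range (25th and 75th
percentile, linear interpolation between order statistics) because the
metrics are bounded at 1 and not normally distributed across children.

Zero-division conventions: precision, recall and F1 are defined as 0 when
their denominators vanish, matching the degenerate F1 = 0 outcomes reported
for cross-position and far-proximity conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["METRIC_NAMES", "MetricsSet", "MetricsSummary", "compute_metrics", "summarize"]

METRIC_NAMES = ("precision", "recall", "f1", "accuracy")


@dataclass(frozen=True)
class MetricsSet:
    true_positives: int
    false_positives: int
    true_negatives: int
    false_negatives: int
    precision: float
    recall: float
    f1: float
    accuracy: float

    @classmethod
    def from_counts(cls, tp: int, fp: int, tn: int, fn: int) -> "MetricsSet":
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = (
            2.0 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        accuracy = (tp + tn) / (tp + fp + tn + fn)
        return cls(
            true_positives=int(tp),
            false_positives=int(fp),
            true_negatives=int(tn),
            false_negatives=int(fn),
            precision=float(precision),
            recall=float(recall),
            f1=float(f1),
            accuracy=float(accuracy),
        )

    @property
    def total(self) -> int:
        return (
            self.true_positives
            + self.false_positives
            + self.true_negatives
            + self.false_negatives
        )

    def to_dict(self) -> dict:
        return asdict(self)


def compute_metrics(truth, decisions) -> MetricsSet:
    """Confusion counts and the four metrics for one target's test windows."""
    t = np.asarray(truth).astype(bool)
    d = np.asarray(decisions).astype(bool)
    if t.shape != d.shape or t.ndim != 1:
        raise ValueError("truth and decisions must be 1-D and the same length")
    if len(t) < 1:
        raise ValueError("metrics need at least one observation")
    tp = int(np.sum(t & d))
    fp = int(np.sum(~t & d))
    tn = int(np.sum(~t & ~d))
    fn = int(np.sum(t & ~d))
    return MetricsSet.from_counts(tp, fp, tn, fn)


@dataclass(frozen=True)
class MetricsSummary:
    """Per-target metric sets plus their median and quartiles per metric."""

    per_target: tuple[MetricsSet, ...]
    median: dict[str, float]
    q25: dict[str, float]
    q75: dict[str, float]

    @property
    def n_targets(self) -> int:
        return len(self.per_target)

    def to_dict(self) -> dict:
        return {
            "n_targets": self.n_targets,
            "median": self.median,
            "q25": self.q25,
            "q75": self.q75,
            "per_target": [m.to_dict() for m in self.per_target],
        }


def summarize(metrics_list: list[MetricsSet]) -> MetricsSummary:
    """Median and 25th/75th percentiles of each metric across targets."""
    if not metrics_list:
        raise ValueError("cannot summarize an empty metrics list")
    median, q25, q75 = {}, {}, {}
    for name in METRIC_NAMES:
        values = np.array([getattr(m, name) for m in metrics_list], dtype=float)
        lo, mid, hi = np.percentile(values, [25.0, 50.0, 75.0])
        median[name], q25[name], q75[name] = float(mid), float(lo), float(hi)
    return MetricsSummary(
        per_target=tuple(metrics_list), median=median, q25=q25, q75=q75
    )
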