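"""Classifier performance metrics, the 85% acceptance gate, and agreement.

Performance is summarized by four binary-classification metrics —
sensitivity/recall, specificity, precision/PPV, and overall accuracy — and
a deployment gate requiring every one of them to reach a minimum threshold
(default 85%). Inter-rater agreement between two annotators is reported as
simple percent agreement, with Cohen's kappa available as an extra.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

from sklearn.metrics import cohen_kappa_score


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(
        cls,
        gold: Sequence[str],
        predicted: Sequence[str],
        positive_label: str = "positive",
    ) -> "ConfusionCounts":
        if len(gold) != len(predicted):
            raise ValueError(
                f"label lists differ in length ({len(gold)} vs {len(predicted)})"
            )
        tp = fp = tn = fn = 0
        for g, p in zip(gold, predicted):
            if g == positive_label:
                if p == positive_label:
                    tp += 1
                else:
                    fn += 1
            else:
                if p == positive_label:
                    fp += 1
                else:
                    tn += 1
        return cls(tp, fp, tn, fn)


@dataclass(frozen=True)
class Metrics:
    """The four gate metrics; a metric is None when its denominator is 0."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    accuracy: Optional[float]

    def as_tuple(self) -> tuple:
        return (self.sensitivity, self.specificity, self.ppv, self.accuracy)


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def metrics(c: ConfusionCounts) -> Metrics:
    """sensitivity=tp/(tp+fn), specificity=tn/(tn+fp), ppv=tp/(tp+fp),
    accuracy=(tp+tn)/total; undefined metrics come back as None."""
    if c.total == 0:
        raise ValueError("cannot compute metrics on an empty confusion matrix")
    return Metrics(
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        ppv=_ratio(c.tp, c.tp + c.fp),
        accuracy=_ratio(c.tp + c.tn, c.total),
    )


METRIC_NAMES = ("sensitivity", "specificity", "ppv", "accuracy")


def gate_report(
    m: Union[Metrics, Iterable[Optional[float]]], threshold: float = 0.85
) -> tuple[bool, list[str]]:
    """Gate outcome plus the reasons any metric failed it."""
    values = m.as_tuple() if isinstance(m, Metrics) else tuple(m)
    if len(values) != 4:
        raise ValueError("expected the four gate metrics")
    reasons = []
    for name, v in zip(METRIC_NAMES, values):
        if v is None:
            reasons.append(f"{name} is undefined")
        elif v < threshold:
            reasons.append(f"{name}={v:.3f} < {threshold}")
    return (not reasons, reasons)


def performance_gate(
    m: Union[Metrics, Iterable[Optional[float]]], threshold: float = 0.85
) -> bool:
    """True iff all four metrics are defined and >= ``threshold``."""
    ok, _ = gate_report(m, threshold)
    return ok


def percent_agreement(labels_a: Sequence, labels_b: Sequence) -> float:
    """100 x fraction of positions where the two annotators agree."""
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"annotation lists differ in length ({len(labels_a)} vs {len(labels_b)})"
        )
    if not labels_a:
        raise ValueError("cannot compute agreement on empty annotations")
    matches = sum(a == b for a, b in zip(labels_a, labels_b))
    return 100.0 * matches / len(labels_a)


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement, offered alongside percent agreement."""
    if len(labels_a) != len(labels_b):
        raise ValueError("annotation lists differ in length")
    return float(cohen_kappa_score(list(labels_a), list(labels_b)))
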