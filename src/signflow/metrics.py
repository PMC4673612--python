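"""Micro instance-level and macro bag-level performance metrics.

Two levels of evaluation are needed because each protein pair is scored
twice. Micro metrics treat every orientation instance as an independent
binary classification (label +1 = verified direction, -1 = its reverse):
confusion matrix, per-label specificity/sensitivity/MCC, overall accuracy,
MCC, F1 and ROC-AUC on the raw decision values. The macro metric works at
the bag level: a verified pair counts as correct only when the fused call
names exactly the verified orientation — a bidirectional, undetermined or
reversed call scores zero. macro_accuracy is the fraction of verified,
encodable pairs called correctly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionMatrix",
    "LabelMetrics",
    "MetricsReport",
    "confusion",
    "per_label_metrics",
    "overall_metrics",
    "roc_auc",
    "macro_accuracy",
    "build_report",
]

LABEL_ORDER: Tuple[int, int] = (1, -1)


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts: m[i][j] = instances of true label i predicted as label j.

    Rows/columns follow ``label_order`` (+1 first, then -1).
    """

    m: np.ndarray
    label_order: Tuple[int, int] = LABEL_ORDER

    @property
    def total(self) -> int:
        return int(self.m.sum())


@dataclass(frozen=True)
class LabelMetrics:
    """One-vs-rest specificity, sensitivity and MCC for a single label."""

    sp: float
    se: float
    mcc: float
    degenerate: bool = False  # some denominator was zero; affected metric reported as 0


def confusion(y_true: Sequence[int], scores: Sequence[float], threshold: float = 0.0) -> ConfusionMatrix:
    """Tally a confusion matrix; predicted label is +1 iff score >= threshold."""
    y_true = np.asarray(y_true, dtype=np.int64)
    scores = np.asarray(scores, dtype=np.float64)
    if y_true.shape != scores.shape:
        raise ValueError(f"labels/scores length mismatch: {y_true.shape} vs {scores.shape}")
    if y_true.size == 0:
        raise ValueError("no scored instances")
    if not set(np.unique(y_true).tolist()) <= {-1, 1}:
        raise ValueError("labels must be in {-1, +1}")
    y_pred = np.where(scores >= threshold, 1, -1)
    m = np.zeros((2, 2), dtype=np.int64)
    for i, true_label in enumerate(LABEL_ORDER):
        for j, pred_label in enumerate(LABEL_ORDER):
            m[i, j] = int(np.sum((y_true == true_label) & (y_pred == pred_label)))
    return ConfusionMatrix(m=m)


def _safe_div(num: float, den: float) -> Tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def per_label_metrics(cm: ConfusionMatrix) -> Dict[int, LabelMetrics]:
    """One-vs-rest SP/SE/MCC per label; zero denominators yield 0 with a flag."""
    out: Dict[int, LabelMetrics] = {}
    for i, label in enumerate(cm.label_order):
        tp = float(cm.m[i, i])
        fn = float(cm.m[i].sum() - cm.m[i, i])
        fp = float(cm.m[:, i].sum() - cm.m[i, i])
        tn = float(cm.m.sum() - tp - fn - fp)
        se, d1 = _safe_div(tp, tp + fn)
        sp, d2 = _safe_div(tn, tn + fp)
        mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        mcc, d3 = _safe_div(tp * tn - fp * fn, mcc_den)
        out[label] = LabelMetrics(sp=sp, se=se, mcc=mcc, degenerate=d1 or d2 or d3)
    return out


def overall_metrics(cm: ConfusionMatrix) -> Tuple[float, float, float]:
    """(accuracy, binary MCC, positive-class F1) from the 2x2 matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = float(np.trace(cm.m)) / cm.total
    # label order is (+1, -1): m[0,0]=TP, m[0,1]=FN, m[1,0]=FP, m[1,1]=TN
    tp, fn = float(cm.m[0, 0]), float(cm.m[0, 1])
    fp, tn = float(cm.m[1, 0]), float(cm.m[1, 1])
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc, _ = _safe_div(tp * tn - fp * fn, mcc_den)
    precision, _ = _safe_div(tp, tp + fp)
    recall, _ = _safe_div(tp, tp + fn)
    f1, _ = _safe_div(2 * precision * recall, precision + recall)
    return accuracy, mcc, f1


def roc_auc(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Mann-Whitney AUC of the decision values; requires both classes present."""
    y_true = np.asarray(y_true, dtype=np.int64)
    scores = np.asarray(scores, dtype=np.float64)
    if len(set(np.unique(y_true).tolist())) < 2:
        raise ValueError("ROC-AUC undefined: only one class present")
    return float(roc_auc_score(y_true, scores))


def macro_accuracy(bags: Sequence) -> float:
    """Fraction of verified bags whose fused call names exactly the true direction."""
    bags = list(bags)
    if not bags:
        raise ValueError("macro_accuracy over an empty bag set")
    hits = 0
    for bag in bags:
        correct = bag.call_correct
        if correct is None:
            raise ValueError(f"bag ({bag.a}, {bag.b}) lacks a call or a verified direction")
        hits += int(correct)
    return hits / len(bags)


@dataclass
class MetricsReport:
    """Joint micro/macro evaluation summary for one experiment."""

    confusion: ConfusionMatrix
    per_label: Dict[int, LabelMetrics]
    accuracy: float
    mcc: float
    f1: float
    auc: float
    macro_accuracy: Optional[float]
    call_counts: Dict[str, int] = field(default_factory=dict)
    n_pairs: int = 0
    n_instances: int = 0
    n_dropped_null: int = 0
    epsilon: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.m.tolist(),
            "label_order": list(self.confusion.label_order),
            "per_label": {
                str(label): {"SP": lm.sp, "SE": lm.se, "MCC": lm.mcc, "degenerate": lm.degenerate}
                for label, lm in self.per_label.items()
            },
            "accuracy": self.accuracy,
            "MCC": self.mcc,
            "F1": self.f1,
            "ROC_AUC": self.auc,
            "macro_accuracy": self.macro_accuracy,
            "call_counts": dict(self.call_counts),
            "n_pairs": self.n_pairs,
            "n_instances": self.n_instances,
            "n_dropped_null": self.n_dropped_null,
            "epsilon": self.epsilon,
        }

    def write_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def write_tsv(self, path) -> None:
        """Flat two-column metric table (metric name, value)."""
        rows: List[Tuple[str, str]] = []
        for label, lm in self.per_label.items():
            tag = "pos" if label == 1 else "neg"
            rows += [(f"SP_{tag}", f"{lm.sp:.4f}"), (f"SE_{tag}", f"{lm.se:.4f}"), (f"MCC_{tag}", f"{lm.mcc:.4f}")]
        rows += [
            ("accuracy", f"{self.accuracy:.4f}"),
            ("MCC", f"{self.mcc:.4f}"),
            ("F1", f"{self.f1:.4f}"),
            ("ROC_AUC", f"{self.auc:.4f}"),
        ]
        if self.macro_accuracy is not None:
            rows.append(("macro_accuracy", f"{self.macro_accuracy:.4f}"))
        for token, count in sorted(self.call_counts.items()):
            rows.append((f"calls[{token}]", str(count)))
        rows += [
            ("n_pairs", str(self.n_pairs)),
            ("n_instances", str(self.n_instances)),
            ("n_dropped_null", str(self.n_dropped_null)),
        ]
        if self.epsilon is not None:
            rows.append(("epsilon", f"{self.epsilon:g}"))
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#metric\tvalue\n")
            for name, value in rows:
                fh.write(f"{name}\t{value}\n")

    def format_table(self) -> str:
        """Human-readable summary printed by the CLI."""
        lines = [
            f"{'label':<6}{'SP':>8}{'SE':>8}{'MCC':>8}",
        ]
        for label, lm in self.per_label.items():
            tag = "+1" if label == 1 else "-1"
            lines.append(f"{tag:<6}{lm.sp:>8.4f}{lm.se:>8.4f}{lm.mcc:>8.4f}")
        lines.append(
            f"accuracy={self.accuracy:.4f}  MCC={self.mcc:.4f}  F1={self.f1:.4f}  ROC-AUC={self.auc:.4f}"
        )
        if self.macro_accuracy is not None:
            lines.append(f"macro_accuracy={self.macro_accuracy:.4f} over {self.n_pairs} pairs")
        if self.call_counts:
            counts = ", ".join(f"{tok}: {cnt}" for tok, cnt in sorted(self.call_counts.items()))
            lines.append(f"calls: {counts}")
        if self.epsilon is not None:
            lines.append(f"epsilon={self.epsilon:g}")
        return "\n".join(lines)


def build_report(
    y_true: Sequence[int],
    scores: Sequence[float],
    bags: Optional[Sequence] = None,
    n_dropped_null: int = 0,
    epsilon: Optional[float] = None,
) -> MetricsReport:
    """Assemble the full micro + macro report from pooled scores and fused bags."""
    cm = confusion(y_true, scores)
    accuracy, mcc, f1 = overall_metrics(cm)
    report = MetricsReport(
        confusion=cm,
        per_label=per_label_metrics(cm),
        accuracy=accuracy,
        mcc=mcc,
        f1=f1,
        auc=roc_auc(y_true, scores),
        macro_accuracy=None,
        n_instances=len(list(y_true)),
        n_dropped_null=n_dropped_null,
        epsilon=epsilon,
    )
    if bags is not None:
        bags = list(bags)
        report.macro_accuracy = macro_accuracy(bags)
        report.n_pairs = len(bags)
        counts: Dict[str, int] = {}
        for bag in bags:
            counts[bag.call.token] = counts.get(bag.call.token, 0) + 1
        report.call_counts = counts
    return report
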