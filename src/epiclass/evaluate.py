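"""Binary-classification evaluation: confusion matrix, the five headline
rates, ROC/AUC, and the two-classifier comparison report.

Positive class = epileptic (label 1).  Rates use the standard orientation
sensitivity = TP/(TP+FN) and specificity = TN/(TN+FP); precision is
TP/(TP+FP) and F1 the harmonic mean of precision and recall.  Cells with
a zero denominator are reported as NaN (undefined), never raised.
"""

from __future__ import annotations

import csv
import json
import math
import os
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import ContractError, DegenerateInputError, EvaluationError

METRIC_COLUMNS = ["Sensitivity", "Specificity", "Accuracy", "Precision",
                  "F1_Score", "AUC"]


@dataclass
class ConfusionMatrix:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray


@dataclass
class MetricsReport:
    """One comparison-table row; rates are percentages, AUC in [0, 1]."""

    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    f1: float
    auc: float = math.nan
    n_test: int = 0
    evaluation_mode: str = "test_set"
    classifier: str = ""

    def as_row(self) -> dict[str, float]:
        return {"Sensitivity": self.sensitivity, "Specificity": self.specificity,
                "Accuracy": self.accuracy, "Precision": self.precision,
                "F1_Score": self.f1, "AUC": self.auc}


def confusion(labels, predictions) -> ConfusionMatrix:
    """Count the four outcome cells; positive = label 1."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(predictions).astype(int)
    if y.shape != p.shape:
        raise ContractError(f"length mismatch: {y.shape} vs {p.shape}")
    return ConfusionMatrix(
        TP=int(np.sum((y == 1) & (p == 1))),
        FP=int(np.sum((y == 0) & (p == 1))),
        FN=int(np.sum((y == 1) & (p == 0))),
        TN=int(np.sum((y == 0) & (p == 0))),
    )


def _rate(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else math.nan


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """The five rates as percentages (AUC is attached separately)."""
    if cm.total == 0:
        raise DegenerateInputError("empty confusion matrix")
    sens = _rate(cm.TP, cm.TP + cm.FN)
    spec = _rate(cm.TN, cm.TN + cm.FP)
    acc = _rate(cm.TP + cm.TN, cm.total)
    prec = _rate(cm.TP, cm.TP + cm.FP)
    if math.isnan(prec) or math.isnan(sens) or (prec + sens) == 0:
        f1 = math.nan
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    return MetricsReport(sensitivity=sens, specificity=spec, accuracy=acc,
                         precision=prec, f1=f1, n_test=cm.total)


def roc_auc(scores, labels) -> tuple[ROCCurve, float]:
    """Threshold-swept ROC and trapezoid AUC.

    Tied scores collapse to a single operating point, which makes the
    trapezoid integral equal to the tie-averaged Mann-Whitney statistic.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ContractError("scores and labels differ in length")
    if not np.all(np.isfinite(s)):
        raise EvaluationError("scores must be finite")
    if len(np.unique(y)) < 2:
        raise EvaluationError("ROC needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thr, tpr=tpr, fpr=fpr), auc


def evaluate_predictions(labels, predictions, scores,
                         evaluation_mode: str = "test_set",
                         classifier: str = "") -> MetricsReport:
    """Full report: confusion-matrix rates plus AUC from the scores."""
    report = metrics(confusion(labels, predictions))
    _, report.auc = roc_auc(scores, labels)
    report.evaluation_mode = evaluation_mode
    report.classifier = classifier
    return report


def compare_report(report_svm: MetricsReport, report_gbdt: MetricsReport,
                   out_dir, make_chart: bool = True) -> dict:
    """Write the two-row comparison table (CSV), a machine-readable JSON,
    and a grouped bar chart over the six criteria."""
    for rep in (report_svm, report_gbdt):
        if rep.n_test == 0:
            raise ContractError("incomplete report: n_test is 0")
        if math.isnan(rep.auc):
            raise ContractError("incomplete report: AUC missing")
    os.makedirs(out_dir, exist_ok=True)
    rows = {"SVM": report_svm.as_row(), "GBDT": report_gbdt.as_row()}

    csv_path = os.path.join(out_dir, "comparison.csv")
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["Classifier"] + METRIC_COLUMNS)
        for name, row in rows.items():
            writer.writerow([name] + [f"{row[c]:.6f}" for c in METRIC_COLUMNS])

    payload = {"SVM": asdict(report_svm), "GBDT": asdict(report_gbdt)}
    json_path = os.path.join(out_dir, "comparison.json")
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")

    if make_chart:
        _bar_chart(rows, os.path.join(out_dir, "comparison.png"))
    return payload


def _bar_chart(rows: dict[str, dict[str, float]], path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.arange(len(METRIC_COLUMNS))
    width = 0.38
    fig, ax = plt.subplots(figsize=(8, 4))
    for k, (name, row) in enumerate(rows.items()):
        vals = [row[c] / 100.0 if c != "AUC" else row[c] for c in METRIC_COLUMNS]
        ax.bar(x + (k - 0.5) * width, vals, width, label=name)
    ax.set_xticks(x, METRIC_COLUMNS, rotation=20)
    ax.set_ylabel("value (rates as fractions)")
    ax.set_ylim(0, 1.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
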