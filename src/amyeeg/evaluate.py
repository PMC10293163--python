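"""Scoring: confusion matrices, sensitivity/specificity/accuracy, ROC/AUC,
diagnosis-subgroup reports and group-difference topographic tables.

Percentages are reported to one decimal with round-half-up, the convention
used in clinical performance tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

from amyeeg.montage import CHANNELS


def _pct(x: float | None) -> float | None:
    """Fraction -> percentage, one decimal, round-half-up (e.g. 0.75 -> 75.0)."""
    if x is None:
        return None
    return float(Decimal(repr(x * 100.0)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; the positive class is amyloid-positive."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Confusion counts from aligned binary label/prediction vectors."""
    y_true = np.asarray(y_true).astype(bool)
    y_pred = np.asarray(y_pred).astype(bool)
    if y_true.size == 0:
        raise ValueError("cannot build a confusion matrix from empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be equal length")
    return ConfusionMatrix(
        tp=int(np.sum(y_pred & y_true)),
        fp=int(np.sum(y_pred & ~y_true)),
        fn=int(np.sum(~y_pred & y_true)),
        tn=int(np.sum(~y_pred & ~y_true)),
    )


@dataclass
class MetricReport:
    """Sensitivity/specificity/accuracy as fractions and rounded percentages.

    A metric whose denominator is zero is reported as ``None`` (undefined),
    never as 0.
    """

    cm: ConfusionMatrix
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    auc: float | None = None
    roc_points: list[tuple[float, float]] | None = None

    @property
    def sensitivity_pct(self) -> float | None:
        return _pct(self.sensitivity)

    @property
    def specificity_pct(self) -> float | None:
        return _pct(self.specificity)

    @property
    def accuracy_pct(self) -> float | None:
        return _pct(self.accuracy)

    def as_dict(self) -> dict:
        return {
            "tp": self.cm.tp, "fp": self.cm.fp, "fn": self.cm.fn, "tn": self.cm.tn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "accuracy_pct": self.accuracy_pct,
            "auc": self.auc,
        }


def metrics(cm: ConfusionMatrix) -> MetricReport:
    """Sensitivity = tp/(tp+fn), specificity = tn/(tn+fp), accuracy = (tp+tn)/total."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    sens = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else None
    spec = cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp else None
    acc = (cm.tp + cm.tn) / cm.total
    return MetricReport(cm=cm, sensitivity=sens, specificity=spec, accuracy=acc)


def roc_auc(scores, labels) -> tuple[list[tuple[float, float]], float]:
    """ROC points (fpr, tpr) by sweeping every distinct score, and trapezoid AUC.

    Tied scores step simultaneously.  Raises on single-class labels.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if np.unique(labels).size < 2:
        raise ValueError("ROC needs both classes present")
    from sklearn.metrics import auc as sk_auc
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist())), float(sk_auc(fpr, tpr))


def subgroup_report(
    y_true,
    y_pred,
    diagnosis,
    scores=None,
) -> dict[str, MetricReport]:
    """Metrics overall and within each diagnosis subgroup.

    Keys: ``SCD+MCI`` (all subjects) plus one per diagnosis present.
    Subgroup confusion counts sum elementwise to the combined counts.
    """
    y_true = np.asarray(y_true).astype(bool)
    y_pred = np.asarray(y_pred).astype(bool)
    diagnosis = np.asarray(diagnosis)
    if diagnosis.shape != y_true.shape:
        raise ValueError("diagnosis must be given for every subject")
    out: dict[str, MetricReport] = {}
    overall = metrics(confusion(y_true, y_pred))
    if scores is not None and np.unique(y_true).size == 2:
        overall.roc_points, overall.auc = roc_auc(scores, y_true)
    out["SCD+MCI"] = overall
    for diag in sorted(set(diagnosis.tolist())):
        m = diagnosis == diag
        if not m.any():
            continue
        rep = metrics(confusion(y_true[m], y_pred[m]))
        if scores is not None and np.unique(y_true[m]).size == 2:
            rep.roc_points, rep.auc = roc_auc(np.asarray(scores)[m], y_true[m])
        out[diag] = rep
    return out


GROUPINGS = (
    "amyloid_within_SCD",
    "amyloid_within_MCI",
    "diagnosis_within_POS",
    "amyloid_overall",
)


def group_topomap_table(
    features: pd.DataFrame,
    profiles: pd.DataFrame,
    grouping: str = "amyloid_overall",
    bands: tuple[str, ...] = ("delta", "theta", "alpha1", "alpha2", "beta1", "beta2", "beta3", "gamma"),
) -> pd.DataFrame:
    """Channel x band group-mean relative-power differences (numeric topomap).

    For the chosen contrast, returns one row per (channel, band) with the
    two group means, their difference (group A minus group B), the Welch t
    statistic and its p-value.  Group A is the amyloid-positive (or MCI)
    group so positive theta differences match the expected pathology sign.
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"grouping must be one of {GROUPINGS}, got {grouping!r}")
    diag = profiles["diagnosis"]
    amy = profiles["amyloid"]
    if grouping == "amyloid_within_SCD":
        mask_a = (diag == "SCD") & (amy == "POS")
        mask_b = (diag == "SCD") & (amy == "NEG")
        label_a, label_b = "SCD_POS", "SCD_NEG"
    elif grouping == "amyloid_within_MCI":
        mask_a = (diag == "MCI") & (amy == "POS")
        mask_b = (diag == "MCI") & (amy == "NEG")
        label_a, label_b = "MCI_POS", "MCI_NEG"
    elif grouping == "diagnosis_within_POS":
        mask_a = (diag == "MCI") & (amy == "POS")
        mask_b = (diag == "SCD") & (amy == "POS")
        label_a, label_b = "MCI_POS", "SCD_POS"
    else:
        mask_a = amy == "POS"
        mask_b = amy == "NEG"
        label_a, label_b = "POS", "NEG"
    ids_a = profiles.index[mask_a]
    ids_b = profiles.index[mask_b]
    if len(ids_a) < 3 or len(ids_b) < 3:
        raise ValueError(
            f"grouping {grouping}: need >= 3 subjects per group, "
            f"got {len(ids_a)} vs {len(ids_b)}"
        )
    rows = []
    for ch in CHANNELS:
        for band in bands:
            col = f"rp_{ch}_{band}"
            a = features.loc[ids_a, col].to_numpy()
            b = features.loc[ids_b, col].to_numpy()
            t, p = stats.ttest_ind(a, b, equal_var=False)
            rows.append(
                {
                    "channel": ch, "band": band,
                    f"mean_{label_a}": float(a.mean()),
                    f"mean_{label_b}": float(b.mean()),
                    "difference": float(a.mean() - b.mean()),
                    "t": float(t), "p": float(p),
                }
            )
    return pd.DataFrame(rows)
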