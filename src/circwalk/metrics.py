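"""Binary-classification metric suite.

Acc, Pre, Sen (=TPR/recall), Spe, FPR and F1 from the 2x2 confusion
tally, plus the ROC curve and its trapezoidal area.  A metric whose
denominator is zero is reported as ``None`` and flagged, never silently
coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(truth, predicted) -> ConfusionCounts:
    """2x2 tally with positive class = 1."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted must have equal length")
    if not (np.isin(truth, (0, 1)).all() and np.isin(predicted, (0, 1)).all()):
        raise ValueError("labels must be 0/1")
    return ConfusionCounts(
        tp=int(((truth == 1) & (predicted == 1)).sum()),
        fp=int(((truth == 0) & (predicted == 1)).sum()),
        tn=int(((truth == 0) & (predicted == 0)).sum()),
        fn=int(((truth == 1) & (predicted == 0)).sum()),
    )


def compute_metrics(c: ConfusionCounts) -> dict:
    """Acc=(TP+TN)/all, Pre=TP/(TP+FP), Sen=TP/(TP+FN), Spe=TN/(TN+FP),
    FPR=FP/(FP+TN), F1=2*Pre*Sen/(Pre+Sen); undefined metrics are None
    and listed under ``undefined``."""
    if c.total == 0:
        raise ValueError("no samples")
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    out = {
        "Acc": (c.tp + c.tn) / c.total,
        "Pre": ratio(c.tp, c.tp + c.fp, "Pre"),
        "Sen": ratio(c.tp, c.tp + c.fn, "Sen"),
        "Spe": ratio(c.tn, c.tn + c.fp, "Spe"),
        "FPR": ratio(c.fp, c.fp + c.tn, "FPR"),
    }
    if out["Pre"] is None or out["Sen"] is None or (out["Pre"] + out["Sen"]) == 0:
        undefined.append("F1")
        out["F1"] = None
    else:
        out["F1"] = 2 * out["Pre"] * out["Sen"] / (out["Pre"] + out["Sen"])
    out["undefined"] = undefined
    return out


def roc_auc(truth, scores) -> tuple[float, np.ndarray, np.ndarray]:
    """ROC curve by threshold sweep over the distinct scores and its
    trapezoidal area.  With ties this equals the concordance form
    AUC = P(score_pos > score_neg) + 0.5 * P(tie).

    Returns (auc, fpr, tpr).
    """
    truth = np.asarray(truth)
    scores = np.asarray(scores, dtype=float)
    if truth.shape != scores.shape:
        raise ValueError("truth and scores must have equal length")
    if len(np.unique(truth)) < 2:
        raise ValueError("ROC undefined: truth contains a single class")
    fpr, tpr, _ = roc_curve(truth, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, fpr, tpr
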