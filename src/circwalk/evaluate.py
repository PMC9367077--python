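"""Classifier training and 5-fold cross-validated evaluation.

Six classifier families are supported — SVM, logistic regression,
random forest, AdaBoost over random-forest base learners (ABRF),
XGBoost (the pipeline default) and a multilayer perceptron — all behind
one ``ClassifierSpec`` so the identical fold permutation is reused by
every one of them.  Reported values are means over folds, not pooled
predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .metrics import compute_metrics, confusion_counts, roc_auc

CLASSIFIER_NAMES = ("SVM", "LR", "RF", "ABRF", "XGB", "MP")

METRIC_COLUMNS = ("Acc", "F1", "Pre", "Sen", "Spe", "AUC")


@dataclass
class ClassifierSpec:
    """Name plus hyperparameter overrides.  ``probability`` records
    whether the fitted model exposes calibrated probabilities; margin
    classifiers fall back to signed decision values for ROC scoring
    (noted in the report)."""

    name: str = "XGB"
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(f"classifier must be one of {CLASSIFIER_NAMES}")

    @property
    def probability(self) -> bool:
        return self.name != "SVM"

    def build(self, seed: int = 0):
        """Instantiate the scikit-learn / xgboost estimator.  Library
        defaults apply except where pinned here or overridden via
        ``hyperparameters`` (single-threaded, seeded, and for the MLP a
        larger iteration cap so small benchmarks converge)."""
        hp = dict(self.hyperparameters)
        if self.name == "SVM":
            return SVC(random_state=seed, **hp)
        if self.name == "LR":
            hp.setdefault("max_iter", 1000)
            return LogisticRegression(**hp)
        if self.name == "RF":
            return RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
        if self.name == "ABRF":
            base_hp = hp.pop("base", {"n_estimators": 10})
            base = RandomForestClassifier(random_state=seed, n_jobs=1, **base_hp)
            return AdaBoostClassifier(estimator=base, random_state=seed, **hp)
        if self.name == "XGB":
            hp.setdefault("eval_metric", "logloss")
            return XGBClassifier(random_state=seed, n_jobs=1, **hp)
        hp.setdefault("max_iter", 500)
        return MLPClassifier(random_state=seed, **hp)


def association_scores(model, X: np.ndarray) -> np.ndarray:
    """Positive-class score: predict_proba where available, otherwise
    the signed decision value."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


@dataclass
class MetricsReport:
    classifier: str
    per_fold: pd.DataFrame  # one row per fold, METRIC_COLUMNS
    roc_curves: list[tuple[np.ndarray, np.ndarray]]
    notes: list[str] = field(default_factory=list)

    @property
    def means(self) -> dict[str, float]:
        return {m: float(self.per_fold[m].mean()) for m in METRIC_COLUMNS}

    def as_percent(self) -> dict[str, float]:
        return {m: round(100 * v, 2) for m, v in self.means.items()}


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    folds: np.ndarray,
    spec: ClassifierSpec | None = None,
    seed: int = 0,
) -> MetricsReport:
    """Train on four folds, score the fifth, rotate; per-fold metric
    suite plus ROC, then arithmetic means."""
    spec = spec or ClassifierSpec()
    y = np.asarray(y)
    folds = np.asarray(folds)
    if not (len(X) == len(y) == len(folds)):
        raise ValueError("X, y and folds must align")
    notes = []
    if not spec.probability:
        notes.append(f"{spec.name}: ROC computed from decision scores, not probabilities")
    rows = []
    curves = []
    for fold in sorted(np.unique(folds)):
        test = folds == fold
        model = spec.build(seed=seed)
        model.fit(X[~test], y[~test])
        pred = model.predict(X[test])
        scores = association_scores(model, X[test])
        m = compute_metrics(confusion_counts(y[test], pred))
        auc, fpr, tpr = roc_auc(y[test], scores)
        rows.append({k: m[k] for k in ("Acc", "F1", "Pre", "Sen", "Spe")} | {"AUC": auc})
        curves.append((fpr, tpr))
    per_fold = pd.DataFrame(rows, index=sorted(np.unique(folds)))
    return MetricsReport(classifier=spec.name, per_fold=per_fold, roc_curves=curves, notes=notes)


@dataclass
class SweepResult:
    """Mean AUC per (classifier, embedding size) and the per-classifier
    argmax; ties go to the smaller size."""

    table: pd.DataFrame  # index classifier, columns k
    best_k: dict[str, int]
    best_auc: dict[str, float]


def sweep_and_select(
    X_by_k: dict[int, np.ndarray],
    y: np.ndarray,
    folds: np.ndarray,
    specs: list[ClassifierSpec] | None = None,
    seed: int = 0,
) -> SweepResult:
    """Cross-validate every classifier at every embedding size and pick
    each classifier's AUC-optimal size."""
    if not X_by_k:
        raise ValueError("need at least one embedding size")
    specs = specs or [ClassifierSpec(name) for name in CLASSIFIER_NAMES]
    sizes = sorted(X_by_k)
    table = pd.DataFrame(index=[s.name for s in specs], columns=sizes, dtype=float)
    for spec in specs:
        for k in sizes:
            report = cross_validate(X_by_k[k], y, folds, spec, seed=seed)
            table.loc[spec.name, k] = report.means["AUC"]
    best_k, best_auc = {}, {}
    for name in table.index:
        row = table.loc[name]
        best = max(sizes, key=lambda k: (row[k], -k))
        best_k[name] = best
        best_auc[name] = float(row[best])
    return SweepResult(table=table, best_k=best_k, best_auc=best_auc)
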