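"""Cross-validated binary stress classification and its metric report.

Three classifier families are evaluated under stratified 10-fold
cross-validation: a random forest (ensemble size 30–100, per-tree split
budget 500–1000), a cubic-kernel SVM (box constraint 1, kernel scale 1–10),
and an untuned logistic regression. The report carries the pooled
out-of-fold confusion matrix, the per-fold mean accuracy, and per-label
precision/recall/F1:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2·precision·recall / (precision + recall)

:class:`StressExperiment` is the model-object entry point: build it from a
feature table, call :meth:`~StressExperiment.fit`, and read the Table-style
grid off the returned :class:`StressExperimentResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FEATURE_COLUMNS, zscore_standardize
from .selection import SelectionResult, chi_square_rank, pearson_rank

__all__ = [
    "ModelSpec",
    "EvaluationReport",
    "StressExperiment",
    "StressExperimentResults",
    "compute_metrics",
    "crossvalidate",
    "run_paper_experiment",
    "REFERENCE_HYPERPARAMETERS",
]

_FAMILIES = ("random_forest", "svm_cubic", "logistic_regression")

_RANGES = {
    "random_forest": {"n_learners": (30, 100), "max_splits": (500, 1000)},
    "svm_cubic": {"kernel_scale": (1, 10)},
}


@dataclass(frozen=True)
class ModelSpec:
    """One classifier family with its hyperparameters.

    random_forest: ``n_learners`` (ensemble size), ``max_splits`` (maximum
    decision splits per tree, i.e. a depth/size budget). svm_cubic: fixed
    degree-3 polynomial kernel, ``box_constraint`` (regularization C) and
    ``kernel_scale`` s, realized as kernel (x·y / s² + 1)³.
    logistic_regression takes no hyperparameters. With ``enforce_ranges``
    the tunable parameters must lie within the published search ranges.
    """

    family: str
    hyperparameters: Mapping[str, float] = field(default_factory=dict)
    enforce_ranges: bool = True

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        object.__setattr__(self, "hyperparameters", dict(self.hyperparameters))
        if self.enforce_ranges:
            for name, (lo, hi) in _RANGES.get(self.family, {}).items():
                v = self.hyperparameters.get(name)
                if v is not None and not lo <= v <= hi:
                    raise ValueError(
                        f"{self.family}.{name}={v} outside allowed range [{lo}, {hi}]"
                    )

    def make_estimator(self, seed: int | None = None):
        hp = self.hyperparameters
        if self.family == "random_forest":
            n_learners = int(hp.get("n_learners", 50))
            max_splits = int(hp.get("max_splits", 1000))
            return RandomForestClassifier(
                n_estimators=n_learners,
                max_leaf_nodes=max_splits + 1,  # k splits => k+1 leaves
                random_state=seed,
            )
        if self.family == "svm_cubic":
            scale = float(hp.get("kernel_scale", 1.0))
            return SVC(
                kernel="poly",
                degree=3,
                C=float(hp.get("box_constraint", 1.0)),
                gamma=1.0 / scale**2,
                coef0=1.0,
            )
        return LogisticRegression(max_iter=2000)


#: Per-condition hyperparameters reported as best for each feature set.
REFERENCE_HYPERPARAMETERS: dict[str, dict[str, dict[str, float]]] = {
    "all": {
        "random_forest": {"n_learners": 50, "max_splits": 1000},
        "svm_cubic": {"kernel_scale": 7, "box_constraint": 1},
        "logistic_regression": {},
    },
    "chi_square": {
        "random_forest": {"n_learners": 100, "max_splits": 500},
        "svm_cubic": {"kernel_scale": 3, "box_constraint": 1},
        "logistic_regression": {},
    },
    "pearson": {
        "random_forest": {"n_learners": 50, "max_splits": 1000},
        "svm_cubic": {"kernel_scale": 3, "box_constraint": 1},
        "logistic_regression": {},
    },
}


def compute_metrics(confusion: np.ndarray, positive_label: int = 1) -> dict[str, float]:
    """Accuracy, precision, recall and F1 from a 2×2 confusion matrix.

    ``confusion[i, j]`` counts true label i predicted as j (labels 0, 1).
    Undefined ratios (empty denominator) are reported as 0 with a flag.
    """
    cm = np.asarray(confusion, dtype=float)
    if cm.shape != (2, 2) or (cm < 0).any() or cm.sum() == 0:
        raise ValueError("confusion must be a nonnegative 2x2 matrix with total > 0")
    p = positive_label
    q = 1 - p
    tp, fp, fn, tn = cm[p, p], cm[q, p], cm[p, q], cm[q, q]
    metrics: dict[str, float] = {
        "accuracy": (tp + tn) / cm.sum(),
        "precision_undefined": 0.0,
        "recall_undefined": 0.0,
    }
    if tp + fp > 0:
        metrics["precision"] = tp / (tp + fp)
    else:
        metrics["precision"], metrics["precision_undefined"] = 0.0, 1.0
    if tp + fn > 0:
        metrics["recall"] = tp / (tp + fn)
    else:
        metrics["recall"], metrics["recall_undefined"] = 0.0, 1.0
    pr, rc = metrics["precision"], metrics["recall"]
    metrics["f1"] = 2 * pr * rc / (pr + rc) if pr + rc > 0 else 0.0
    return metrics


@dataclass(frozen=True)
class EvaluationReport:
    """Pooled cross-validation outcome of one classifier on one feature set."""

    spec: ModelSpec
    confusion: np.ndarray  # rows: true label 0/1; cols: predicted 0/1
    fold_accuracies: tuple[float, ...]
    fold_assignments: np.ndarray
    seed: int
    feature_columns: tuple[str, ...]

    @property
    def accuracy_pooled(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())

    @property
    def accuracy_fold_mean(self) -> float:
        """Accuracy averaged over the k validation folds."""
        return float(np.mean(self.fold_accuracies))

    def metrics(self, positive_label: int = 1) -> dict[str, float]:
        return compute_metrics(self.confusion, positive_label)


def crossvalidate(
    table: pd.DataFrame,
    spec: ModelSpec,
    k: int = 10,
    seed: int = 0,
    feature_columns: Sequence[str] | None = None,
    standardize: str = "per_fold",
    label_column: str = "label",
) -> EvaluationReport:
    """Stratified k-fold cross-validation of one classifier.

    Out-of-fold predictions are pooled into the confusion matrix; per-fold
    accuracies are kept alongside since the headline accuracy can be quoted
    either way. ``standardize`` is ``"per_fold"`` (z-score fitted inside
    each training fold — leakage-safe default), ``"pooled"`` (fitted once on
    the whole table before splitting, reproducing a standardize-then-CV
    order), or ``"none"``.
    """
    cols = list(feature_columns) if feature_columns is not None else list(FEATURE_COLUMNS)
    if standardize == "pooled":
        table, _ = zscore_standardize(table, columns=tuple(cols))
    elif standardize not in ("per_fold", "none"):
        raise ValueError(f"unknown standardize mode {standardize!r}")
    X = table[cols].to_numpy(dtype=float)
    y = table[label_column].to_numpy(dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("table contains a single class")
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(f"need at least k={k} rows per class for stratified folds")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    confusion = np.zeros((2, 2))
    fold_acc: list[float] = []
    assignment = np.empty(len(y), dtype=int)
    for fold, (train, test) in enumerate(skf.split(X, y)):
        est = spec.make_estimator(seed=seed + fold)
        if standardize == "per_fold":
            est = Pipeline([("scale", StandardScaler()), ("clf", est)])
        est.fit(X[train], y[train])
        pred = est.predict(X[test])
        assignment[test] = fold
        fold_acc.append(float(np.mean(pred == y[test])))
        for t, pr in zip(y[test], pred):
            confusion[t, pr] += 1
    return EvaluationReport(
        spec=spec,
        confusion=confusion,
        fold_accuracies=tuple(fold_acc),
        fold_assignments=assignment,
        seed=seed,
        feature_columns=tuple(cols),
    )


def _default_specs(selection: str) -> dict[str, ModelSpec]:
    return {
        family: ModelSpec(family, hp)
        for family, hp in REFERENCE_HYPERPARAMETERS[selection].items()
    }


class StressExperiment:
    """The full classification experiment over one feature table.

    Evaluates each classifier family on each feature set (all 27 features,
    the chi-square survivors, the Pearson survivors) under stratified
    k-fold cross-validation.

    Parameters
    ----------
    table : DataFrame
        Feature table with the 27 feature columns and a ``label`` column.
    selections : sequence of {"all", "chi_square", "pearson"}
        Feature sets to evaluate.
    k : int
        Number of cross-validation folds.
    standardize : {"per_fold", "pooled", "none"}
        Where the z-score transform is fitted (see :func:`crossvalidate`).
    """

    def __init__(
        self,
        table: pd.DataFrame,
        selections: Sequence[str] = ("all", "chi_square", "pearson"),
        k: int = 10,
        standardize: str = "per_fold",
        specs: Mapping[str, Mapping[str, ModelSpec]] | None = None,
    ) -> None:
        missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"table is missing feature columns: {missing}")
        if "label" not in table.columns:
            raise ValueError("table must have a 'label' column")
        self.table = table
        self.selections = tuple(selections)
        self.k = k
        self.standardize = standardize
        self.specs = (
            {sel: dict(fams) for sel, fams in specs.items()}
            if specs is not None
            else {sel: _default_specs(sel) for sel in self.selections}
        )

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kwargs) -> "StressExperiment":
        return cls(table, **kwargs)

    def _feature_sets(self) -> tuple[dict[str, tuple[str, ...]], dict[str, SelectionResult]]:
        sets: dict[str, tuple[str, ...]] = {}
        results: dict[str, SelectionResult] = {}
        for sel in self.selections:
            if sel == "all":
                sets[sel] = tuple(FEATURE_COLUMNS)
            elif sel == "chi_square":
                results[sel] = chi_square_rank(self.table)
                sets[sel] = results[sel].selected
            elif sel == "pearson":
                results[sel] = pearson_rank(self.table)
                sets[sel] = results[sel].selected
            else:
                raise ValueError(f"unknown selection {sel!r}")
            if not sets[sel]:
                raise ValueError(f"selection {sel!r} retained no features")
        return sets, results

    def fit(self, seed: int = 0) -> "StressExperimentResults":
        """Run every (feature set × classifier) cell and collect the reports."""
        sets, selections = self._feature_sets()
        reports: dict[tuple[str, str], EvaluationReport] = {}
        for sel, cols in sets.items():
            for family, spec in self.specs[sel].items():
                reports[(sel, family)] = crossvalidate(
                    self.table,
                    spec,
                    k=self.k,
                    seed=seed,
                    feature_columns=cols,
                    standardize=self.standardize,
                )
        return StressExperimentResults(
            model=self, reports=reports, selections=selections, seed=seed
        )


@dataclass(frozen=True)
class StressExperimentResults:
    """Metric grid of one fitted :class:`StressExperiment`."""

    model: StressExperiment
    reports: dict[tuple[str, str], EvaluationReport]
    selections: dict[str, SelectionResult]
    seed: int

    def summary(self) -> pd.DataFrame:
        """Long-form metric grid: one row per (feature set, classifier, label)."""
        rows = []
        for (sel, family), rep in self.reports.items():
            for lab in (0, 1):
                m = rep.metrics(positive_label=lab)
                rows.append(
                    {
                        "features": sel,
                        "classifier": family,
                        "n_features": len(rep.feature_columns),
                        "accuracy": rep.accuracy_fold_mean,
                        "label": lab,
                        "precision": m["precision"],
                        "recall": m["recall"],
                        "f1": m["f1"],
                    }
                )
        return pd.DataFrame(rows)

    def confusion_matrices(self) -> dict[tuple[str, str], np.ndarray]:
        return {key: rep.confusion.copy() for key, rep in self.reports.items()}

    def plot_confusion_matrices(self, axes=None):
        """Heatmap grid of the pooled confusion matrices (needs matplotlib)."""
        import matplotlib.pyplot as plt

        keys = list(self.reports)
        if axes is None:
            _, axes = plt.subplots(1, len(keys), figsize=(3 * len(keys), 3))
            axes = np.atleast_1d(axes)
        for ax, key in zip(np.ravel(axes), keys):
            cm = self.reports[key].confusion
            ax.imshow(cm, cmap="Blues")
            for i in range(2):
                for j in range(2):
                    ax.text(j, i, f"{int(cm[i, j])}", ha="center", va="center")
            ax.set_title(f"{key[1]}\n({key[0]})", fontsize=8)
            ax.set_xlabel("predicted")
            ax.set_ylabel("true")
        return axes


def run_paper_experiment(
    table: pd.DataFrame,
    seed: int = 0,
    selections: Sequence[str] = ("all", "chi_square", "pearson"),
    k: int = 10,
    standardize: str = "per_fold",
) -> StressExperimentResults:
    """Convenience wrapper: fit a :class:`StressExperiment` with the published
    per-condition hyperparameters and return its results grid."""
    return StressExperiment(
        table, selections=selections, k=k, standardize=standardize
    ).fit(seed=seed)
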