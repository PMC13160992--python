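"""Classifier benchmarking: tuning, step-1 RFE, LOOCV learning curves.

Each (marker subset x classifier) combination goes through the same protocol:

1. hyperparameter tuning by seeded random search with stratified k-fold CV and
   weighted F1 as criterion (tuned parameters are then held constant);
2. recursive feature elimination with step 1 — one feature dropped per round —
   yielding a full informativeness ranking of the subset;
3. for each panel size k = 1..k_max (top-k of the ranking), leave-one-out
   cross-validation repeated over R replicate seeds, recording mean and SD of
   weighted F1, accuracy, weighted precision, weighted recall, and the
   replicate-averaged confusion matrix;
4. the best panel is the smallest k whose mean weighted F1 attains the curve
   maximum — equal weight to performance and parsimony.

Linear SVC feature importance is the aggregate |coefficient| over its
component binary classifiers; tree ensembles use impurity importances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import loguniform
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_recall_fscore_support,
)
from sklearn.model_selection import LeaveOneOut, ParameterSampler, StratifiedKFold, cross_val_score
from sklearn.svm import LinearSVC

from .extract import FeatureKey, FeatureMatrix, GroupLabels
from .select import SelectionResult

__all__ = [
    "ClassifierSpec",
    "MetricSet",
    "LearningCurve",
    "BenchResult",
    "DEFAULT_SEARCH_SPACES",
    "tune",
    "rfe_rank",
    "loocv_evaluate",
    "compute_metrics",
    "learning_curve",
    "choose_best",
    "run_benchmark",
    "summary_table",
]

DEFAULT_SEARCH_SPACES: dict[str, dict] = {
    "linear_svc": {"C": loguniform(1e-3, 1e3)},
    "random_forest": {
        "n_estimators": list(range(50, 501, 50)),
        "max_depth": list(range(2, 21)),
        "min_samples_leaf": [1, 2, 3, 4, 5],
        "max_features": ["sqrt", "log2", 0.1, 0.25, 0.5, 0.75, 1.0],
    },
    "gradient_boosting": {
        "n_estimators": [50, 100, 200, 300],
        "learning_rate": loguniform(1e-2, 3e-1),
        "max_depth": [2, 3, 4, 5],
        "subsample": [0.5, 0.75, 1.0],
    },
}

_KINDS = ("linear_svc", "random_forest", "gradient_boosting")


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier kind with (possibly tuned) hyperparameters and a seed.

    Balanced class weights are on by default for the SVC and the forest to
    counter group-size imbalance; gradient boosting has no such option.
    The SVC kernel is linear by construction.
    """

    kind: str
    hyperparameters: Mapping = field(default_factory=dict)
    class_weight_balanced: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")

    def build(self, seed: int | None = None):
        """Instantiate the scikit-learn estimator (seed override for replicates)."""
        rs = self.seed if seed is None else seed
        params = dict(self.hyperparameters)
        if self.kind == "linear_svc":
            cw = "balanced" if self.class_weight_balanced else None
            return LinearSVC(class_weight=cw, random_state=rs, max_iter=20000, **params)
        if self.kind == "random_forest":
            cw = "balanced" if self.class_weight_balanced else None
            return RandomForestClassifier(class_weight=cw, random_state=rs, n_jobs=1, **params)
        return GradientBoostingClassifier(random_state=rs, **params)

    def importances(self, fitted) -> np.ndarray:
        if self.kind == "linear_svc":
            return np.abs(fitted.coef_).sum(axis=0)
        return fitted.feature_importances_


@dataclass(frozen=True)
class MetricSet:
    weighted_f1: float
    accuracy: float
    weighted_precision: float
    weighted_recall: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.weighted_f1, self.accuracy, self.weighted_precision, self.weighted_recall)


_METRICS = ("weighted_f1", "accuracy", "weighted_precision", "weighted_recall")


@dataclass
class LearningCurve:
    """Per-k replicate statistics along the RFE ranking (k = 1..k_max)."""

    k_values: list[int]
    means: dict[str, np.ndarray]  # metric -> array over k
    sds: dict[str, np.ndarray]
    features_at_k: list[list[FeatureKey]]  # prefix property: list at k extends k-1
    per_k_confusion: np.ndarray  # (k_max, K, K) replicate-averaged
    mean_confusion: np.ndarray  # (K, K) averaged over replicates and k
    classes: list[str]
    replicates: int


@dataclass
class BenchResult:
    curve: LearningCurve
    best_k: int
    best_features: list[FeatureKey]
    mean_confusion_matrix: np.ndarray
    importances_at_best: dict[FeatureKey, float]
    spec: ClassifierSpec
    selection_method: str


def tune(
    spec: ClassifierSpec,
    matrix: FeatureMatrix,
    labels: GroupLabels,
    iterations: int = 100,
    folds: int = 3,
    search_space: Mapping | None = None,
) -> ClassifierSpec:
    """Choose hyperparameters maximizing stratified-CV weighted F1.

    Seeded random search over the kind's documented space; deterministic given
    ``spec.seed``. Ties keep the earliest-drawn configuration.
    """
    y = labels.vector(matrix.sample_ids)
    counts = np.unique(y, return_counts=True)[1]
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples < {folds} folds; reduce folds"
        )
    space = dict(search_space if search_space is not None else DEFAULT_SEARCH_SPACES[spec.kind])
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed)
    best_params, best_score = {}, -np.inf
    for params in ParameterSampler(space, n_iter=iterations, random_state=spec.seed):
        est = replace(spec, hyperparameters=params).build()
        score = cross_val_score(est, matrix.values, y, cv=cv, scoring="f1_weighted").mean()
        if score > best_score:
            best_params, best_score = params, score
    return replace(spec, hyperparameters=dict(best_params))


def rfe_rank(
    spec: ClassifierSpec,
    matrix: FeatureMatrix,
    labels: GroupLabels,
    step: int = 1,
) -> list[FeatureKey]:
    """Full feature ranking by recursive elimination, best feature first.

    Each round refits on the remaining features and removes the ``step``
    lowest-importance features (ties drop the lower column index). The
    returned order is the reverse elimination order with survivors first.
    """
    if step != 1:
        raise ValueError("only step=1 elimination is supported")
    y = labels.vector(matrix.sample_ids)
    remaining = list(range(matrix.n_features))
    eliminated: list[int] = []
    while len(remaining) > 1:
        est = spec.build()
        est.fit(matrix.values[:, remaining], y)
        worst = int(np.argmin(spec.importances(est)))
        eliminated.append(remaining.pop(worst))
    order = remaining + eliminated[::-1]
    return [matrix.feature_keys[j] for j in order]


def compute_metrics(predictions: Sequence[str], labels: Sequence[str]) -> MetricSet:
    """Support-weighted F1/precision/recall plus accuracy from pooled predictions."""
    y_true = np.asarray(labels)
    y_pred = np.asarray(predictions)
    if y_true.size == 0:
        raise ValueError("empty predictions")
    if y_true.shape != y_pred.shape:
        raise ValueError("predictions and labels differ in length")
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, average="weighted", zero_division=0
    )
    return MetricSet(float(f1), float(accuracy_score(y_true, y_pred)), float(prec), float(rec))


def loocv_evaluate(
    spec: ClassifierSpec,
    matrix: FeatureMatrix,
    labels: GroupLabels,
    replicate_seed: int | None = None,
    on_fit: Callable[[], None] | None = None,
) -> tuple[list[str], MetricSet, np.ndarray]:
    """Leave-one-out CV: exactly n fits, each predicting its held-out sample.

    Returns (predictions in sample order, metrics, K x K confusion matrix with
    rows in ``labels.groups`` order). ``on_fit`` is an instrumentation hook
    invoked once per model fit.
    """
    y = labels.vector(matrix.sample_ids)
    n = matrix.n_samples
    if n < 2:
        raise ValueError("LOOCV needs at least two samples")
    preds: list[str] = [""] * n
    X = matrix.values
    for train, test in LeaveOneOut().split(X):
        est = spec.build(seed=replicate_seed)
        est.fit(X[train], y[train])
        if on_fit is not None:
            on_fit()
        preds[int(test[0])] = str(est.predict(X[test])[0])
    metrics = compute_metrics(preds, y)
    cm = confusion_matrix(y, preds, labels=labels.groups)
    return preds, metrics, cm


def learning_curve(
    spec: ClassifierSpec,
    ranking: Sequence[FeatureKey],
    matrix: FeatureMatrix,
    labels: GroupLabels,
    k_max: int = 30,
    replicates: int = 30,
    base_seed: int = 0,
) -> LearningCurve:
    """LOOCV metrics for panels of the top-k ranked markers, k = 1..k_max.

    Replicate r uses seed ``base_seed + r``; for deterministic classifiers all
    replicates coincide and SDs are exactly zero. Confusion matrices are
    averaged over replicates per k, and additionally over the whole curve.
    """
    if not ranking:
        raise ValueError("empty ranking")
    k_max = min(k_max, len(ranking))
    K = len(labels.groups)
    means = {m: np.zeros(k_max) for m in _METRICS}
    sds = {m: np.zeros(k_max) for m in _METRICS}
    per_k_cm = np.zeros((k_max, K, K))
    features_at_k: list[list[FeatureKey]] = []
    for ki, k in enumerate(range(1, k_max + 1)):
        panel = list(ranking[:k])
        features_at_k.append(panel)
        sub = matrix.restrict(panel)
        vals = {m: [] for m in _METRICS}
        for r in range(replicates):
            _, ms, cm = loocv_evaluate(spec, sub, labels, replicate_seed=base_seed + r)
            for m, v in zip(_METRICS, ms.as_tuple()):
                vals[m].append(v)
            per_k_cm[ki] += cm
        per_k_cm[ki] /= replicates
        for m in _METRICS:
            means[m][ki] = float(np.mean(vals[m]))
            sds[m][ki] = float(np.std(vals[m]))
    return LearningCurve(
        k_values=list(range(1, k_max + 1)),
        means=means,
        sds=sds,
        features_at_k=features_at_k,
        per_k_confusion=per_k_cm,
        mean_confusion=per_k_cm.mean(axis=0),
        classes=list(labels.groups),
        replicates=replicates,
    )


def choose_best(curve: LearningCurve) -> tuple[int, list[FeatureKey]]:
    """Smallest k whose mean weighted F1 equals the curve maximum (exact tie)."""
    f1 = curve.means["weighted_f1"]
    if f1.size == 0:
        raise ValueError("empty curve")
    best_idx = int(np.flatnonzero(f1 == f1.max())[0])
    return curve.k_values[best_idx], curve.features_at_k[best_idx]


def run_benchmark(
    matrix: FeatureMatrix,
    labels: GroupLabels,
    selections: Sequence[SelectionResult],
    classifiers: Sequence[ClassifierSpec],
    *,
    tune_iterations: int = 100,
    tune_folds: int = 3,
    replicates: int = 30,
    k_max: int = 30,
    base_seed: int = 0,
    search_spaces: Mapping[str, Mapping] | None = None,
) -> dict[tuple[str, str], BenchResult]:
    """Evaluate the full (subset x classifier) cross-product.

    Per-combination failures are recorded as ``None`` values, not raised, so a
    degenerate subset cannot sink the whole benchmark.
    """
    if not selections:
        raise ValueError("selections must be non-empty")
    results: dict[tuple[str, str], BenchResult] = {}
    for sel in selections:
        sub = matrix.restrict(sel.features)
        for spec in classifiers:
            key = (sel.method, spec.kind)
            try:
                space = (search_spaces or {}).get(spec.kind)
                tuned = tune(
                    spec, sub, labels,
                    iterations=tune_iterations, folds=tune_folds, search_space=space,
                )
                ranking = rfe_rank(tuned, sub, labels)
                curve = learning_curve(
                    tuned, ranking, sub, labels,
                    k_max=k_max, replicates=replicates, base_seed=base_seed,
                )
                best_k, best_features = choose_best(curve)
                est = tuned.build()
                best_sub = sub.restrict(best_features)
                est.fit(best_sub.values, labels.vector(best_sub.sample_ids))
                imps = dict(zip(best_features, map(float, tuned.importances(est))))
                results[key] = BenchResult(
                    curve=curve,
                    best_k=best_k,
                    best_features=best_features,
                    mean_confusion_matrix=curve.mean_confusion,
                    importances_at_best=imps,
                    spec=tuned,
                    selection_method=sel.method,
                )
            except Exception as exc:  # noqa: BLE001 - per-combination isolation
                results[key] = None
                import logging

                logging.getLogger(__name__).warning("combination %s failed: %s", key, exc)
    return results


def summary_table(results: Mapping[tuple[str, str], BenchResult | None]) -> pd.DataFrame:
    """Benchmark summary: one row per combination, mean +/- SD of each metric at best k."""
    rows = []
    for (method, kind), res in results.items():
        if res is None:
            rows.append({"selection": method, "classifier": kind, "ssrs_incorporated": None})
            continue
        ki = res.curve.k_values.index(res.best_k)
        row = {"selection": method, "classifier": kind, "ssrs_incorporated": res.best_k}
        for m, short in zip(_METRICS, ("f1", "acc", "prec", "rec")):
            row[f"mean_{short}"] = res.curve.means[m][ki]
            row[f"sd_{short}"] = res.curve.sds[m][ki]
        rows.append(row)
    return pd.DataFrame(rows)
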