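"""Four SSR feature-selection strategies over a binary presence matrix.

* **gc_ssr** — group-wise conserved filter: keep a marker iff it is present in
  every sample of at least one origin group. A biology-first rule rather than
  a statistical one; its natural output size conventionally caps the other
  strategies' panels.
* **select_k_best** — top-k by one-way ANOVA F between group label and the
  binary feature.
* **hybrid** — ANOVA prefilter to ``k1``, random-search-tuned random forest,
  then step-1 recursive feature elimination on impurity importances down to
  ``k2``.
* **lasso** — one-vs-rest L1-penalized logistic regression; the inverse
  regularization strength is chosen by leave-one-out CV on weighted F1, and
  markers with any non-zero coefficient are ranked by their largest absolute
  per-class weight.

The objective the lasso minimizes per class, summed one-vs-rest and reported
by :func:`lasso_loss`, is mean multinomial cross-entropy plus an L1 penalty:

    L = -(1/n) sum_i sum_k 1(y_i = k) log p_ik  +  lambda sum_k sum_j |w_kj|
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import loguniform
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.model_selection import ParameterSampler, StratifiedKFold, cross_val_score

from .extract import FeatureKey, FeatureMatrix, GroupLabels

__all__ = [
    "SelectionResult",
    "LassoModel",
    "gc_ssr_select",
    "anova_f_scores",
    "select_k_best",
    "hybrid_select",
    "lasso_fit",
    "predict_proba",
    "lasso_loss",
    "lasso_select",
    "DEFAULT_FOREST_SPACE",
]

#: Random-forest hyperparameter search space for the hybrid strategy.
DEFAULT_FOREST_SPACE: dict = {
    "n_estimators": list(range(50, 501, 50)),
    "max_depth": list(range(2, 21)),
    "min_samples_leaf": [1, 2, 3, 4, 5],
    "max_features": ["sqrt", "log2", 0.1, 0.25, 0.5, 0.75, 1.0],
}


@dataclass
class SelectionResult:
    """An ordered, scored SSR subset produced by one selection strategy."""

    method: str
    features: list[FeatureKey]
    scores: list[float]
    params: dict = field(default_factory=dict)
    group_attribution: dict[FeatureKey, set[str]] | None = None

    def __post_init__(self) -> None:
        if len(self.features) != len(set(self.features)):
            raise ValueError("duplicate features in selection")
        if len(self.scores) != len(self.features):
            raise ValueError("scores not aligned with features")

    def to_json_dict(self) -> dict:
        out = {
            "method": self.method,
            "params": {k: v for k, v in self.params.items() if _jsonable(v)},
            "features": [str(k) for k in self.features],
            "scores": [float(s) for s in self.scores],
        }
        if self.group_attribution is not None:
            out["group_attribution"] = {
                str(k): sorted(v) for k, v in self.group_attribution.items()
            }
        return out

    def to_feature_csv(self, path) -> None:
        """One-column CSV of the ordered feature keys."""
        import pandas as pd

        pd.DataFrame({"feature": [str(k) for k in self.features]}).to_csv(path, index=False)


def _jsonable(v) -> bool:
    return isinstance(v, (str, int, float, bool, list, tuple, type(None)))


def _check_groups(matrix: FeatureMatrix, labels: GroupLabels) -> dict[str, np.ndarray]:
    rows: dict[str, np.ndarray] = {}
    for g in labels.groups:
        idx = np.array([i for i, s in enumerate(matrix.sample_ids) if labels[s] == g])
        if idx.size == 0:
            raise ValueError(f"group {g!r} has no samples in the matrix")
        rows[g] = idx
    return rows


def gc_ssr_select(matrix: FeatureMatrix, labels: GroupLabels) -> SelectionResult:
    """Keep markers present in every sample of at least one origin group.

    The score of a marker is the number of groups it is conserved in; ordering
    is (groups attributed desc, feature key lexicographic). No cap is applied:
    the natural panel size is itself the quantity of interest.
    """
    rows = _check_groups(matrix, labels)
    attribution: dict[FeatureKey, set[str]] = {}
    for j, key in enumerate(matrix.feature_keys):
        col = matrix.values[:, j]
        conserved_in = {g for g, idx in rows.items() if col[idx].all()}
        if conserved_in:
            attribution[key] = conserved_in
    ordered = sorted(attribution, key=lambda k: (-len(attribution[k]), k))
    return SelectionResult(
        method="gc_ssr",
        features=ordered,
        scores=[float(len(attribution[k])) for k in ordered],
        params={"groups": list(labels.groups)},
        group_attribution=attribution,
    )


def anova_f_scores(matrix: FeatureMatrix, labels: GroupLabels) -> np.ndarray:
    """One-way ANOVA F statistic of each feature against the group label.

    F = (between-group SS / (K-1)) / (within-group SS / (n-K)). A feature with
    zero within-group variance but non-zero between-group variance scores
    +inf (perfectly group-determined); a constant feature scores 0.
    """
    rows = _check_groups(matrix, labels)
    if len(labels.groups) < 2:
        raise ValueError("ANOVA requires at least two groups")
    X = matrix.values.astype(float)
    n, K = X.shape[0], len(labels.groups)
    if n < 2:
        raise ValueError("ANOVA requires at least two samples")
    grand = X.mean(axis=0)
    ss_between = np.zeros(X.shape[1])
    ss_within = np.zeros(X.shape[1])
    for idx in rows.values():
        gmean = X[idx].mean(axis=0)
        ss_between += idx.size * (gmean - grand) ** 2
        ss_within += ((X[idx] - gmean) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / (K - 1)) / (ss_within / (n - K))
    F = np.where(ss_within == 0, np.where(ss_between > 0, np.inf, 0.0), F)
    return F


def select_k_best(matrix: FeatureMatrix, labels: GroupLabels, k: int = 30) -> SelectionResult:
    """Top-k features by ANOVA F; +inf sorts first, ties lexicographic by key."""
    if k < 1:
        raise ValueError("k must be >= 1")
    F = anova_f_scores(matrix, labels)
    order = sorted(range(matrix.n_features), key=lambda j: (-F[j], matrix.feature_keys[j]))
    top = order[: min(k, matrix.n_features)]
    return SelectionResult(
        method="select_k_best",
        features=[matrix.feature_keys[j] for j in top],
        scores=[float(F[j]) for j in top],
        params={"k": k},
    )


def _forest_importances(model: RandomForestClassifier) -> np.ndarray:
    return model.feature_importances_


def hybrid_select(
    matrix: FeatureMatrix,
    labels: GroupLabels,
    k1: int = 5000,
    k2: int = 30,
    *,
    search_iterations: int = 150,
    cv_folds: int = 4,
    search_space: Mapping | None = None,
    seed: int = 0,
) -> SelectionResult:
    """ANOVA prefilter to ``k1``, tune a forest, RFE (step 1) down to ``k2``.

    Tuning is a random search (``search_iterations`` draws, stratified
    ``cv_folds``-fold CV, weighted-F1 criterion). Elimination continues past
    ``k2`` internally so the surviving panel is fully ordered (last feature
    standing first).
    """
    if k2 > k1:
        raise ValueError("k2 must be <= k1")
    y = labels.vector(matrix.sample_ids)
    counts = np.unique(y, return_counts=True)[1]
    if counts.min() < cv_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; cannot stratify {cv_folds} folds"
        )
    stage1 = select_k_best(matrix, labels, k=min(k1, matrix.n_features))
    sub = matrix.restrict(stage1.features)

    space = dict(search_space or DEFAULT_FOREST_SPACE)
    best_params, best_score = {}, -np.inf
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for params in ParameterSampler(space, n_iter=search_iterations, random_state=seed):
        model = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
        score = cross_val_score(model, sub.values, y, cv=cv, scoring="f1_weighted").mean()
        if score > best_score:
            best_params, best_score = params, score

    remaining = list(range(sub.n_features))
    eliminated: list[int] = []
    while len(remaining) > 1:
        model = RandomForestClassifier(random_state=seed, n_jobs=1, **best_params)
        model.fit(sub.values[:, remaining], y)
        worst = int(np.argmin(_forest_importances(model)))
        eliminated.append(remaining.pop(worst))
    full_order = remaining + eliminated[::-1]  # best first
    chosen = full_order[: min(k2, sub.n_features)]
    rank_score = {j: float(len(full_order) - r) for r, j in enumerate(full_order)}
    return SelectionResult(
        method="hybrid",
        features=[sub.feature_keys[j] for j in chosen],
        scores=[rank_score[j] for j in chosen],
        params={
            "k1": k1, "k2": k2, "search_iterations": search_iterations,
            "cv_folds": cv_folds, "seed": seed, "best_forest_params": dict(best_params),
            "cv_f1_weighted": float(best_score),
        },
    )


@dataclass
class LassoModel:
    """One-vs-rest L1 logistic model: weights (K x m), intercepts, lambda."""

    weights: np.ndarray
    intercepts: np.ndarray
    lam: float
    classes: list[str]
    feature_keys: list[FeatureKey]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        K, m = self.weights.shape
        if K != len(self.classes) or len(self.intercepts) != K or m != len(self.feature_keys):
            raise ValueError("inconsistent model dimensions")


def lasso_fit(
    matrix: FeatureMatrix,
    labels: GroupLabels,
    c_bounds: tuple[float, float] = (1e-3, 1e3),
    search_iterations: int = 25,
    seed: int = 0,
) -> LassoModel:
    """Fit OvR L1 logistic regression, choosing C by LOOCV weighted F1.

    ``search_iterations`` values of the inverse regularization strength C are
    drawn log-uniformly from ``c_bounds``; each candidate is scored by
    leave-one-out weighted F1 of the normalized OvR probabilities, and the
    model is refit on all data at the best C (ties go to the stronger
    regularization, i.e. smaller C). lambda is reported as 1/C.
    """
    y = labels.vector(matrix.sample_ids)
    n, K = matrix.n_samples, len(labels.groups)
    if n < K + 1:
        raise ValueError("need at least K + 1 samples for LOOCV model selection")
    counts = {g: int((y == g).sum()) for g in labels.groups}
    if min(counts.values()) < 2:
        warnings.warn(
            "a class has a single sample; its LOOCV fold can never be predicted correctly",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    cands = sorted(loguniform(*c_bounds).rvs(size=search_iterations, random_state=rng))

    X = matrix.values.astype(float)
    best_c, best_f1 = None, -np.inf
    for c in cands:
        preds = []
        for i in range(n):
            keep = np.arange(n) != i
            model = _fit_ovr(X[keep], y[keep], labels.groups, c, seed)
            p = _proba(model, X[i : i + 1])
            preds.append(labels.groups[int(np.argmax(p[0]))])
        score = f1_score(y, preds, average="weighted", zero_division=0)
        if score > best_f1:  # candidates ascend, so ties keep the smaller C
            best_c, best_f1 = c, score
    model = _fit_ovr(X, y, labels.groups, best_c, seed)
    model.feature_keys = list(matrix.feature_keys)
    return model


def _fit_ovr(X: np.ndarray, y: np.ndarray, classes: Sequence[str], c: float, seed: int) -> LassoModel:
    K, m = len(classes), X.shape[1]
    W = np.zeros((K, m))
    b = np.zeros(K)
    for k, cls in enumerate(classes):
        y_bin = (y == cls).astype(int)
        if y_bin.min() == y_bin.max():  # class absent from training fold
            b[k] = -50.0 if y_bin.max() == 0 else 50.0
            continue
        clf = LogisticRegression(
            l1_ratio=1.0, C=c, solver="liblinear", random_state=seed, max_iter=1000
        )
        clf.fit(X, y_bin)
        W[k] = clf.coef_[0]
        b[k] = clf.intercept_[0]
    placeholder = [FeatureKey(f"f{j}", "A", 1) for j in range(m)]
    return LassoModel(W, b, 1.0 / c, list(classes), placeholder)


def _proba(model: LassoModel, X: np.ndarray) -> np.ndarray:
    z = X @ model.weights.T + model.intercepts
    s = 1.0 / (1.0 + np.exp(-z))
    return s / s.sum(axis=1, keepdims=True)


def predict_proba(model: LassoModel, matrix: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Normalized one-vs-rest probabilities, one row per sample, summing to 1."""
    X = matrix.values.astype(float) if isinstance(matrix, FeatureMatrix) else np.asarray(matrix, float)
    if X.shape[1] != model.weights.shape[1]:
        raise ValueError(
            f"matrix has {X.shape[1]} features, model expects {model.weights.shape[1]}"
        )
    return _proba(model, X)


def lasso_loss(model: LassoModel, matrix: FeatureMatrix | np.ndarray, labels: GroupLabels | Sequence[str]) -> float:
    """Mean cross-entropy of normalized OvR probabilities plus lambda * ||W||_1."""
    if isinstance(matrix, FeatureMatrix):
        y = labels.vector(matrix.sample_ids) if isinstance(labels, GroupLabels) else np.asarray(labels)
    else:
        y = np.asarray(labels)
    P = np.clip(predict_proba(model, matrix), 1e-15, None)
    idx = {c: k for k, c in enumerate(model.classes)}
    ce = -np.mean([np.log(P[i, idx[yi]]) for i, yi in enumerate(y)])
    return float(ce + model.lam * np.abs(model.weights).sum())


def lasso_select(
    matrix: FeatureMatrix,
    labels: GroupLabels,
    cap: int = 30,
    *,
    c_bounds: tuple[float, float] = (1e-3, 1e3),
    search_iterations: int = 25,
    seed: int = 0,
) -> SelectionResult:
    """Markers with any non-zero lasso coefficient, ranked by max |weight|.

    Truncated at ``cap``; ties broken lexicographically by feature key. An
    all-zero model yields an explicit empty selection with a warning.
    """
    model = lasso_fit(matrix, labels, c_bounds, search_iterations, seed)
    strength = np.abs(model.weights).max(axis=0)
    nonzero = [j for j in range(matrix.n_features) if strength[j] > 0]
    if not nonzero:
        warnings.warn("lasso selected no features (all coefficients zero)", stacklevel=2)
    order = sorted(nonzero, key=lambda j: (-strength[j], matrix.feature_keys[j]))[:cap]
    return SelectionResult(
        method="lasso",
        features=[matrix.feature_keys[j] for j in order],
        scores=[float(strength[j]) for j in order],
        params={
            "cap": cap, "lambda": model.lam, "c": 1.0 / model.lam,
            "search_iterations": search_iterations, "seed": seed,
        },
    )
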