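"""Classification harness: gold split, nested cross-validated grid search,
evaluation, and Shapley feature attribution.

The data flow guards against tuning leakage: the observation table is first
split stratified-by-label into a training partition (2/3) and a gold test
partition (1/3) that is never touched until final evaluation.  Hyperparameters
are chosen by nested cross-validation (grid search in k inner folds, scored
in k outer folds, k = 3 for both); the configuration with the best mean
outer-fold weighted F1 is refit on the full training partition.  Missing
feature values are imputed with training-fold medians inside the model
pipeline, so no statistic ever sees held-out rows.

By default splits are grouped by participant, so no speaker contributes
observations to both sides; ungrouped observation-level splitting is
available behind a flag.

Shapley attribution is computed in-package with a background-sample value
function v(S) = E_z[f(x_S, z_{~S})]: exact coalition enumeration up to 12
features, permutation sampling above.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import (
    GridSearchCV,
    StratifiedGroupKFold,
    StratifiedKFold,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

FAMILIES = ("decision_tree", "random_forest", "gradient_boosting", "svm")

#: the "essential hyperparameters" searched per family
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "decision_tree": {"max_depth": [3, 5, 10, None]},
    "random_forest": {"n_estimators": [100, 300], "max_depth": [5, None]},
    "gradient_boosting": {"n_estimators": [100, 300], "learning_rate": [0.05, 0.1]},
    "svm": {"C": [0.1, 1, 10], "gamma": ["scale", 0.1]},
}


@dataclass
class ObservationTable:
    """Feature rows with labels and a participant group key."""

    X: pd.DataFrame
    y: pd.Series
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.y.isna().any():
            raise ValueError("labels must not be missing")
        if not (len(self.X) == len(self.y) == len(self.groups)):
            raise ValueError("X, y and groups must be aligned")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def subset(self, idx: np.ndarray) -> "ObservationTable":
        return ObservationTable(
            self.X.iloc[idx].reset_index(drop=True),
            self.y.iloc[idx].reset_index(drop=True),
            self.groups.iloc[idx].reset_index(drop=True),
        )


@dataclass
class TunedModel:
    family: str
    estimator: Pipeline
    best_params: dict
    outer_scores: list[float]


@dataclass
class ClassificationReport:
    family: str
    scheme: str
    accuracy: float
    precision: float  # weighted
    recall: float  # weighted
    f1: float  # weighted
    precision_macro: float
    recall_macro: float
    f1_macro: float
    per_class: pd.DataFrame
    confusion: pd.DataFrame
    auc: dict[str, tuple[float, float]] = field(default_factory=dict)

    def summary(self) -> dict[str, float]:
        return {
            "accuracy": round(self.accuracy, 4),
            "precision": round(self.precision, 4),
            "recall": round(self.recall, 4),
            "f1": round(self.f1, 4),
        }


@dataclass
class AttributionReport:
    mean_abs_shap: pd.Series  # indexed by feature, descending
    rank: pd.Series  # 1 = most important
    baseline: float
    phi: np.ndarray | None = None  # per-observation values (binary models)


def make_estimator(family: str, seed: int = 0) -> Pipeline:
    """Median imputation + (for SVM) standardization + the classifier."""
    if family == "decision_tree":
        clf = DecisionTreeClassifier(random_state=seed)
    elif family == "random_forest":
        clf = RandomForestClassifier(random_state=seed)
    elif family == "gradient_boosting":
        clf = GradientBoostingClassifier(random_state=seed)
    elif family == "svm":
        clf = SVC(kernel="rbf", random_state=seed)
    else:
        raise ValueError(f"unknown family {family!r}; allowed: {FAMILIES}")
    steps = [("impute", SimpleImputer(strategy="median"))]
    if family == "svm":
        steps.append(("scale", StandardScaler()))
    steps.append(("clf", clf))
    return Pipeline(steps)


def split_gold(
    table: ObservationTable,
    test_fraction: float = 1 / 3,
    seed: int = 0,
    grouped: bool = True,
) -> tuple[ObservationTable, ObservationTable]:
    """Stratified train / gold-test split; gold rows are never used in tuning.

    With ``grouped=True`` (default) all observations of one participant land
    on the same side.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    counts = table.y.value_counts()
    if (counts < 2).any():
        raise ValueError("need at least 2 observations per class")
    n_splits = max(2, int(round(1 / test_fraction)))
    y = table.y.to_numpy()
    if grouped:
        splitter = StratifiedGroupKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        folds = splitter.split(table.X, y, groups=table.groups.to_numpy())
    else:
        splitter = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        folds = splitter.split(table.X, y)
    train_idx, test_idx = next(iter(folds))
    train, test = table.subset(train_idx), table.subset(test_idx)
    classes = set(table.y.unique())
    if set(train.y.unique()) != classes or set(test.y.unique()) != classes:
        raise ValueError("a class is absent from one side of the split")
    return train, test


def nested_cv_tune(
    train: ObservationTable,
    family: str,
    grid: dict[str, list] | None = None,
    k_outer: int = 3,
    k_inner: int = 3,
    seed: int = 0,
    grouped: bool = True,
) -> TunedModel:
    """Nested CV: grid search in inner folds, scoring in outer folds.

    Each outer fold's inner grid search nominates a configuration; the
    configuration with the best mean outer-fold weighted F1 is refit on the
    whole training table.
    """
    if grid is None:
        grid = DEFAULT_GRIDS[family]
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be non-empty")
    param_grid = {f"clf__{k}": v for k, v in grid.items()}
    y = train.y.to_numpy()
    if grouped and train.groups.nunique() >= k_outer:
        outer = StratifiedGroupKFold(n_splits=k_outer, shuffle=True, random_state=seed)
        outer_folds = outer.split(train.X, y, groups=train.groups.to_numpy())
    else:
        outer = StratifiedKFold(n_splits=k_outer, shuffle=True, random_state=seed)
        outer_folds = outer.split(train.X, y)
    per_config: dict[tuple, list[float]] = {}
    for outer_train, outer_test in outer_folds:
        fold_y = y[outer_train]
        if len(np.unique(fold_y)) < 2:
            raise ValueError("degenerate outer fold with a single class")
        search = GridSearchCV(
            make_estimator(family, seed),
            param_grid,
            scoring="f1_weighted",
            cv=StratifiedKFold(n_splits=k_inner, shuffle=True, random_state=seed),
            n_jobs=None,
        )
        search.fit(train.X.iloc[outer_train], fold_y)
        pred = search.best_estimator_.predict(train.X.iloc[outer_test])
        score = f1_score(y[outer_test], pred, average="weighted", zero_division=0)
        key = tuple(sorted(search.best_params_.items()))
        per_config.setdefault(key, []).append(float(score))
    best_key = max(
        per_config, key=lambda k: (np.mean(per_config[k]), len(per_config[k]))
    )
    best_params = dict(best_key)
    estimator = make_estimator(family, seed)
    estimator.set_params(**best_params)
    estimator.fit(train.X, y)
    outer_scores = [s for scores in per_config.values() for s in scores]
    return TunedModel(
        family=family,
        estimator=estimator,
        best_params={k.removeprefix("clf__"): v for k, v in best_params.items()},
        outer_scores=outer_scores,
    )


def evaluate(
    model: TunedModel,
    test: ObservationTable,
    scheme: str = "binary",
    seed: int = 0,
) -> ClassificationReport:
    """Gold-test metrics.

    ``binary`` and ``multiclass_ovo`` report accuracy / precision / recall /
    F1 (weighted, plus macro).  ``multiclass_ovr`` additionally reports
    per-class one-vs-rest ROC AUC as mean +/- sd over a stratified two-fold
    split of the gold test set, which requires the model to expose class
    probabilities.
    """
    if scheme not in ("binary", "multiclass_ovo", "multiclass_ovr"):
        raise ValueError(f"unknown scheme {scheme!r}")
    y_true = test.y.to_numpy()
    y_pred = model.estimator.predict(test.X)
    labels = sorted(np.unique(y_true))
    per_class = pd.DataFrame(
        {
            "precision": precision_score(
                y_true, y_pred, labels=labels, average=None, zero_division=0
            ),
            "recall": recall_score(
                y_true, y_pred, labels=labels, average=None, zero_division=0
            ),
            "f1": f1_score(y_true, y_pred, labels=labels, average=None, zero_division=0),
        },
        index=labels,
    )
    confusion = pd.DataFrame(
        confusion_matrix(y_true, y_pred, labels=labels), index=labels, columns=labels
    )
    auc: dict[str, tuple[float, float]] = {}
    if scheme == "multiclass_ovr":
        proba = model.estimator.predict_proba(test.X)
        classes = list(model.estimator.classes_)
        fold_auc: dict[str, list[float]] = {c: [] for c in classes}
        splitter = StratifiedKFold(n_splits=2, shuffle=True, random_state=seed)
        for _, fold_idx in splitter.split(test.X, y_true):
            for j, c in enumerate(classes):
                y_bin = (y_true[fold_idx] == c).astype(int)
                if y_bin.min() == y_bin.max():
                    continue
                fold_auc[c].append(roc_auc_score(y_bin, proba[fold_idx, j]))
        auc = {
            c: (float(np.mean(v)), float(np.std(v)))
            for c, v in fold_auc.items()
            if v
        }
    return ClassificationReport(
        family=model.family,
        scheme=scheme,
        accuracy=float(accuracy_score(y_true, y_pred)),
        precision=float(precision_score(y_true, y_pred, average="weighted", zero_division=0)),
        recall=float(recall_score(y_true, y_pred, average="weighted", zero_division=0)),
        f1=float(f1_score(y_true, y_pred, average="weighted", zero_division=0)),
        precision_macro=float(precision_score(y_true, y_pred, average="macro", zero_division=0)),
        recall_macro=float(recall_score(y_true, y_pred, average="macro", zero_division=0)),
        f1_macro=float(f1_score(y_true, y_pred, average="macro", zero_division=0)),
        per_class=per_class,
        confusion=confusion,
        auc=auc,
    )


# -- Shapley attribution ----------------------------------------------------


def _coalition_values(
    value_fn: Callable[[np.ndarray], np.ndarray],
    X: np.ndarray,
    background: np.ndarray,
) -> np.ndarray:
    """v[mask, obs] = mean over background rows z of f(x with S from x, rest from z)."""
    m, n = X.shape
    b = background.shape[0]
    v = np.empty((2**n, m))
    tiled_bg = np.tile(background, (m, 1))
    repeated_X = np.repeat(X, b, axis=0)
    for mask in range(2**n):
        in_s = np.array([(mask >> i) & 1 for i in range(n)], dtype=bool)
        hybrid = np.where(in_s, repeated_X, tiled_bg)
        v[mask] = np.asarray(value_fn(hybrid), dtype=float).reshape(m, b).mean(axis=1)
    return v


def exact_shapley(
    value_fn: Callable[[np.ndarray], np.ndarray],
    X: np.ndarray,
    background: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Exact Shapley values by full coalition enumeration (features <= 12).

    Returns (phi of shape (observations, features), baseline).  Satisfies the
    efficiency axiom exactly: phi.sum(axis=1) = f(x) - baseline.
    """
    m, n = X.shape
    if n > 12:
        raise ValueError("exact mode enumerates coalitions; use <= 12 features")
    if background.shape[0] == 0:
        raise ValueError("background sample must be non-empty")
    from math import factorial

    v = _coalition_values(value_fn, X, background)
    weights = [
        factorial(s) * factorial(n - s - 1) / factorial(n) for s in range(n)
    ]
    phi = np.zeros((m, n))
    for mask in range(2**n):
        size = bin(mask).count("1")
        for i in range(n):
            if not (mask >> i) & 1:
                phi[:, i] += weights[size] * (v[mask | (1 << i)] - v[mask])
    # v[0] is E_z f(z) for every observation: the baseline
    baseline = float(v[0, 0]) if m else float("nan")
    return phi, baseline


def sampled_shapley(
    value_fn: Callable[[np.ndarray], np.ndarray],
    X: np.ndarray,
    background: np.ndarray,
    n_draws: int = 2000,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Monte Carlo Shapley via random feature permutations and background draws."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if background.shape[0] == 0:
        raise ValueError("background sample must be non-empty")
    rng = np.random.default_rng(seed)
    m, n = X.shape
    phi = np.zeros((m, n))
    for _ in range(n_draws):
        perm = rng.permutation(n)
        z = background[rng.integers(background.shape[0])]
        # build the chain z -> ... -> x feature by feature, evaluate in one call
        states = np.empty((n + 1, m, n))
        cur = np.tile(z, (m, 1))
        states[0] = cur
        for step, i in enumerate(perm, start=1):
            cur = cur.copy()
            cur[:, i] = X[:, i]
            states[step] = cur
        out = np.asarray(
            value_fn(states.reshape((n + 1) * m, n)), dtype=float
        ).reshape(n + 1, m)
        for step, i in enumerate(perm, start=1):
            phi[:, i] += out[step] - out[step - 1]
    phi /= n_draws
    baseline = float(np.asarray(value_fn(background), dtype=float).mean())
    return phi, baseline


def _model_value_fns(model: Pipeline) -> dict[str, Callable[[np.ndarray], np.ndarray]]:
    """Per-class model-output value functions.

    Probabilities when the model exposes them (binary: positive class only);
    otherwise decision-function margins (binary: the single margin,
    multiclass: one one-vs-rest margin column per class).
    """
    classes = list(model.classes_)
    try:
        model.predict_proba
        has_proba = True
    except AttributeError:
        has_proba = False
    if has_proba:
        if len(classes) == 2:
            return {str(classes[1]): lambda A: model.predict_proba(A)[:, 1]}
        return {
            str(c): (lambda j: (lambda A: model.predict_proba(A)[:, j]))(j)
            for j, c in enumerate(classes)
        }
    if len(classes) == 2:
        return {str(classes[1]): lambda A: model.decision_function(A)}
    return {
        str(c): (lambda j: (lambda A: model.decision_function(A)[:, j]))(j)
        for j, c in enumerate(classes)
    }


def shapley_attribution(
    model: TunedModel | Pipeline,
    test: ObservationTable | pd.DataFrame,
    background: pd.DataFrame | np.ndarray,
    mode: str = "exact",
    n_draws: int = 2000,
    seed: int = 0,
    value_fn: Callable[[np.ndarray], np.ndarray] | None = None,
) -> AttributionReport:
    """Per-feature mean absolute Shapley value on the gold test set.

    The baseline is the mean model output over the background sample.  With a
    multiclass model the per-class attributions (on each class's probability)
    are averaged.  ``value_fn`` may override the model output, e.g. to
    attribute a margin instead of a probability.
    """
    if mode not in ("exact", "sampled"):
        raise ValueError("mode must be 'exact' or 'sampled'")
    X_df = test.X if isinstance(test, ObservationTable) else test
    feature_names = list(X_df.columns)
    X = X_df.to_numpy(dtype=float)
    bg = np.asarray(background, dtype=float)
    if bg.shape[0] == 0:
        raise ValueError("background sample must be non-empty")
    if value_fn is not None:
        fns = {"output": value_fn}
    else:
        pipeline = model.estimator if isinstance(model, TunedModel) else model

        def _named(fn):
            return lambda A: fn(pd.DataFrame(A, columns=feature_names))

        fns = {k: _named(fn) for k, fn in _model_value_fns(pipeline).items()}
    compute = (
        (lambda f: exact_shapley(f, X, bg))
        if mode == "exact"
        else (lambda f: sampled_shapley(f, X, bg, n_draws=n_draws, seed=seed))
    )
    abs_sum = np.zeros(len(feature_names))
    phi_last, baseline = None, float("nan")
    for fn in fns.values():
        phi, baseline = compute(fn)
        abs_sum += np.abs(phi).mean(axis=0)
        phi_last = phi
    mean_abs = pd.Series(abs_sum / len(fns), index=feature_names).sort_values(
        ascending=False
    )
    rank = pd.Series(
        np.arange(1, len(mean_abs) + 1), index=mean_abs.index, name="rank"
    )
    return AttributionReport(
        mean_abs_shap=mean_abs,
        rank=rank,
        baseline=baseline,
        phi=phi_last if len(fns) == 1 else None,
    )


# -- experiment driver ------------------------------------------------------

FEATURE_SETS = ("llm+indices", "llm_only", "indices_only")
TASKS = ("presence", "subtype")


def select_features(
    feature_table: pd.DataFrame,
    feature_set: str,
    backends: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Project the merged feature table onto one feature combination."""
    surp_cols = [c for c in feature_table.columns if c.startswith("surprisal_")]
    if backends is not None:
        wanted = {f"surprisal_{b}" for b in backends}
        surp_cols = [c for c in surp_cols if c in wanted]
    from .indices import INDEX_NAMES

    idx_cols = [c for c in INDEX_NAMES if c in feature_table.columns]
    if feature_set == "llm+indices":
        cols = surp_cols + idx_cols
    elif feature_set == "llm_only":
        cols = surp_cols
    elif feature_set == "indices_only":
        cols = idx_cols
    else:
        raise ValueError(f"unknown feature set {feature_set!r}; allowed: {FEATURE_SETS}")
    if not cols:
        raise ValueError(f"feature set {feature_set!r} selects no columns")
    return feature_table[cols]


def build_observation_table(
    feature_table: pd.DataFrame,
    task: str,
    feature_set: str = "llm+indices",
    backends: Sequence[str] | None = None,
) -> ObservationTable:
    """Observation table for one task from the merged per-paragraph features.

    ``presence`` labels rows control vs aphasia; ``subtype`` keeps only
    aphasia rows and labels them Broca / Wernicke / Anomic.
    """
    if task == "presence":
        rows = feature_table
        y = rows["group"]
    elif task == "subtype":
        rows = feature_table[feature_table["group"] == "aphasia"]
        y = rows["subtype"]
    else:
        raise ValueError(f"unknown task {task!r}; allowed: {TASKS}")
    X = select_features(rows, feature_set, backends)
    return ObservationTable(
        X=X.reset_index(drop=True),
        y=y.reset_index(drop=True),
        groups=rows["participant_id"].reset_index(drop=True),
    )


def run_experiment(
    feature_table: pd.DataFrame,
    task: str = "presence",
    feature_sets: Sequence[str] = ("llm+indices",),
    families: Sequence[str] = FAMILIES,
    backends: Sequence[str] | None = None,
    grids: dict[str, dict[str, list]] | None = None,
    seed: int = 0,
    grouped: bool = True,
    test_fraction: float = 1 / 3,
    attribution_mode: str | None = "exact",
    attribution_sample: int = 30,
    attribution_draws: int = 300,
) -> dict:
    """One full experiment: one report per (family x feature set), plus
    Shapley attribution of the best family per feature set.

    Returns ``{"reports": {(family, feature_set): ClassificationReport},
    "attributions": {feature_set: AttributionReport}, "models": {...}}``.
    """
    scheme = "binary" if task == "presence" else "multiclass_ovo"
    reports: dict[tuple[str, str], ClassificationReport] = {}
    models: dict[tuple[str, str], TunedModel] = {}
    attributions: dict[str, AttributionReport] = {}
    for feature_set in feature_sets:
        table = build_observation_table(feature_table, task, feature_set, backends)
        train, test = split_gold(table, test_fraction=test_fraction, seed=seed, grouped=grouped)
        for family in families:
            grid = (grids or {}).get(family)
            tuned = nested_cv_tune(train, family, grid=grid, seed=seed, grouped=grouped)
            report = evaluate(tuned, test, scheme=scheme, seed=seed)
            reports[(family, feature_set)] = report
            models[(family, feature_set)] = tuned
            logger.info(
                "%s / %s: gold F1 %.3f (params %s)",
                family, feature_set, report.f1, tuned.best_params,
            )
        if attribution_mode is not None:
            best_family = max(families, key=lambda f: reports[(f, feature_set)].f1)
            tuned = models[(best_family, feature_set)]
            n_features = len(table.feature_names)
            mode = attribution_mode
            if mode == "exact" and n_features > 12:
                mode = "sampled"
            rng = np.random.default_rng(seed)
            bg_idx = rng.choice(len(train.X), size=min(20, len(train.X)), replace=False)
            # attribute a subsample of gold-test rows: mean |phi| ranks are
            # stable and full-set exact/sampled runs scale poorly
            t_idx = rng.choice(
                len(test.X), size=min(attribution_sample, len(test.X)), replace=False
            )
            attributions[feature_set] = shapley_attribution(
                tuned,
                test.X.iloc[t_idx],
                train.X.iloc[bg_idx],
                mode=mode,
                n_draws=attribution_draws,
                seed=seed,
            )
    return {"reports": reports, "attributions": attributions, "models": models}
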