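"""Model families, grid-search cross-validation and evaluation metrics.

Five classifier families are tuned by exhaustive 5-fold grid search:
nu-parameterized support vector classification, a multilayer perceptron,
random forests, extremely randomized trees, and gradient-boosted trees
(XGBoost).  Model selection uses the macro-average sensitivity

    MA = 1/2 * ( TP/(TP+FN) + TN/(TN+FP) ),

the unweighted mean of the two per-class recalls, with RVOT fixed as the
positive class; accuracy breaks ties.  MA weighs both classes equally,
so a degenerate always-one-class classifier scores exactly 0.5 no matter
how imbalanced the cohort is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import NuSVC
from xgboost import XGBClassifier

from .scenarios import FeatureTable

MODEL_FAMILIES = ("svm", "mlp", "random_forest", "extra_trees", "xgboost")

#: Selection-score tolerance below which two grid points count as tied.
_TIE_TOL = 1e-12


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 confusion counts with RVOT fixed as the positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.fn, self.tn, self.fp):
            if v < 0 or int(v) != v:
                raise ValueError("confusion counts must be non-negative integers")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        )

    def to_dict(self) -> dict[str, int]:
        return {"tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp}


def macro_average_sensitivity(cm: ConfusionMatrix) -> float:
    """Unweighted mean of RVOT sensitivity and LVOT sensitivity."""
    if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        raise ValueError("class absent from test set")
    return 0.5 * (cm.tp / (cm.tp + cm.fn) + cm.tn / (cm.tn + cm.fp))


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correct predictions."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return (cm.tp + cm.tn) / cm.total


# ---------------------------------------------------------------------------
# hyperparameter grids


def _frange(start: float, stop: float, step: float) -> list[float]:
    n = int(round((stop - start) / step)) + 1
    return [round(start + i * step, 10) for i in range(n)]


def _product(named: Sequence[tuple[str, Sequence]]) -> Iterator[dict]:
    if not named:
        yield {}
        return
    name, values = named[0]
    for v in values:
        for rest in _product(named[1:]):
            yield {name: v, **rest}


def _svm_grid(nu_values, kernels, gammas, degrees, coef0s) -> Iterator[dict]:
    # degree and coef0 only apply to the polynomial kernel
    for nu in nu_values:
        for kernel in kernels:
            for gamma in gammas:
                if kernel == "poly":
                    for degree in degrees:
                        for coef0 in coef0s:
                            yield {"nu": nu, "kernel": kernel, "gamma": gamma,
                                   "degree": degree, "coef0": coef0}
                else:
                    yield {"nu": nu, "kernel": kernel, "gamma": gamma}


def enumerate_grid(family: str, preset: str = "full") -> Iterator[dict]:
    """Lazily enumerate hyperparameter combinations for one family.

    The "full" preset is the complete tuning grid; "fast" is a
    small sub-grid for desk-scale runs and CI.  Conditional parameters
    (polynomial degree / coef0) are expanded only for the poly kernel.
    """
    if family not in MODEL_FAMILIES:
        raise ValueError(f"unknown model family {family!r}")
    if preset not in ("full", "fast"):
        raise ValueError(f"unknown grid preset {preset!r}")
    if family == "svm":
        if preset == "full":
            yield from _svm_grid([0.4, 0.5, 0.6], ["rbf", "linear", "poly"],
                                 ["scale", "auto"], [1, 2, 3, 4, 5], [0.0, 0.5, 1.0])
        else:
            yield from _svm_grid([0.4, 0.5, 0.6], ["rbf", "linear"], ["scale"], [], [])
    elif family == "mlp":
        if preset == "full":
            yield from _product([
                ("solver", ["lbfgs", "adam"]),
                ("alpha", [1e-4, 1e-5, 1e-6]),
                ("hidden_layer_sizes", [(10,), (50,), (100,)]),
                ("activation", ["identity", "logistic", "tanh", "relu"]),
            ])
        else:
            yield from _product([
                ("solver", ["lbfgs"]),
                ("alpha", [1e-4]),
                ("hidden_layer_sizes", [(10,), (50,)]),
                ("activation", ["relu", "logistic"]),
            ])
    elif family in ("random_forest", "extra_trees"):
        if preset == "full":
            yield from _product([
                ("n_estimators", [100, 200, 300, 400, 500]),
                ("min_samples_split", _frange(0.1, 0.9, 0.1) + [1.0]),
                ("min_samples_leaf", _frange(0.1, 0.9, 0.1) + [1]),
            ])
        else:
            yield from _product([
                ("n_estimators", [100]),
                ("min_samples_split", [2]),
                ("min_samples_leaf", [1, 0.1]),
            ])
    else:  # xgboost
        if preset == "full":
            yield from _product([
                ("max_depth", list(range(1, 11))),
                ("min_child_weight", _frange(1.0, 6.0, 0.5)),
                ("gamma", _frange(0.0, 0.5, 0.1)),
                ("subsample", _frange(0.6, 1.0, 0.01)),
                ("colsample_bytree", _frange(0.6, 1.0, 0.01)),
                ("reg_alpha", [1e-5, 1e-2, 0.1, 1.0, 100.0]),
            ])
        else:
            yield from _product([
                ("max_depth", [2, 4, 6]),
                ("min_child_weight", [1.0]),
                ("gamma", [0.0]),
                ("subsample", [0.8, 1.0]),
                ("colsample_bytree", [1.0]),
                ("reg_alpha", [1e-5]),
            ])


def grid_size(family: str, preset: str = "full") -> int:
    """Number of combinations in a family's grid (computed arithmetically
    for the very large gradient-boosting grid, by enumeration otherwise)."""
    if family == "xgboost" and preset == "full":
        return 10 * 11 * 6 * 41 * 41 * 5
    return sum(1 for _ in enumerate_grid(family, preset))


# ---------------------------------------------------------------------------
# model construction and fitting


def make_model(family: str, params: Mapping, seed: int = 0):
    """Instantiate an unfitted classifier of the given family."""
    params = dict(params)
    if family == "svm":
        return NuSVC(probability=True, random_state=seed, **params)
    if family == "mlp":
        return MLPClassifier(max_iter=1000, random_state=seed, **params)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "extra_trees":
        return ExtraTreesClassifier(random_state=seed, n_jobs=1, **params)
    if family == "xgboost":
        return XGBClassifier(
            n_estimators=100, random_state=seed, n_jobs=1,
            eval_metric="logloss", **params,
        )
    raise ValueError(f"unknown model family {family!r}")


def _fit(model, X: np.ndarray, y: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        # sklearn 1.9 deprecation chatter for SVC(probability=True)
        warnings.simplefilter("ignore", FutureWarning)
        model.fit(X, y)
    return model


def predict_with_model(model, table: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    """Predictions (0/1) and P(RVOT) for every row of ``table``.

    The model must have been fitted on a table with identical feature
    names (checked when the model records them).
    """
    expected = getattr(model, "otva_feature_names_", None)
    if expected is not None and tuple(expected) != tuple(table.feature_names):
        raise ValueError(
            "feature columns at prediction time do not match the fitted model: "
            f"{list(table.feature_names)} vs {list(expected)}"
        )
    preds = np.asarray(model.predict(table.X), dtype=int)
    probs = np.asarray(model.predict_proba(table.X))[:, 1]
    return preds, probs


def fit_predict(
    table_train: FeatureTable,
    table_test: FeatureTable,
    family: str,
    params: Mapping,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, object]:
    """Fit one configuration and predict the test table.

    Returns (predictions, P(RVOT), fitted model).  Train and test tables
    must share their feature columns.
    """
    if table_train.feature_names != table_test.feature_names:
        raise ValueError("train and test tables have different feature columns")
    model = make_model(family, params, seed=seed)
    _fit(model, table_train.X, table_train.y)
    model.otva_feature_names_ = tuple(table_train.feature_names)
    preds, probs = predict_with_model(model, table_test)
    return preds, probs, model


# ---------------------------------------------------------------------------
# cross-validated grid search


@dataclass
class GridSearchResult:
    family: str
    best_params: dict
    best_cv_ma: float
    best_cv_accuracy: float
    fold_ma: list[float]
    fold_accuracy: list[float]
    n_evaluated: int


def grid_search_cv(
    table: FeatureTable,
    family: str,
    grid: Iterable[Mapping] | None = None,
    *,
    preset: str = "full",
    folds: int = 5,
    seed: int = 0,
) -> GridSearchResult:
    """Exhaustive grid search with stratified k-fold cross-validation.

    The selection score is mean CV macro-average sensitivity; ties are
    broken by mean CV accuracy, then by grid order.  Configurations whose
    fit fails (e.g. an infeasible nu) are skipped.
    """
    if grid is None:
        grid = enumerate_grid(family, preset)
    y = table.y
    if len(np.unique(y)) < 2:
        raise ValueError("grid search requires both classes in the training table")
    if min(np.bincount(y)) < folds:
        raise ValueError(
            f"the rarer class has fewer samples than folds={folds}; "
            "every fold must contain both classes"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(table.X, y))

    best: GridSearchResult | None = None
    n_eval = 0
    for params in grid:
        n_eval += 1
        fold_ma, fold_acc = [], []
        try:
            for tr, te in splits:
                model = make_model(family, params, seed=seed)
                _fit(model, table.X[tr], y[tr])
                cm = ConfusionMatrix.from_predictions(y[te], model.predict(table.X[te]))
                fold_ma.append(macro_average_sensitivity(cm))
                fold_acc.append(accuracy(cm))
        except (ValueError, np.linalg.LinAlgError) as err:
            if "class absent" in str(err):
                raise
            continue  # infeasible configuration (e.g. nu out of range)
        mean_ma = float(np.mean(fold_ma))
        mean_acc = float(np.mean(fold_acc))
        better = best is None or mean_ma > best.best_cv_ma + _TIE_TOL or (
            abs(mean_ma - best.best_cv_ma) <= _TIE_TOL
            and mean_acc > best.best_cv_accuracy + _TIE_TOL
        )
        if better:
            best = GridSearchResult(
                family=family, best_params=dict(params), best_cv_ma=mean_ma,
                best_cv_accuracy=mean_acc, fold_ma=fold_ma, fold_accuracy=fold_acc,
                n_evaluated=0,
            )
    if best is None:
        raise ValueError("no grid configuration could be fitted")
    best.n_evaluated = n_eval
    return best


# ---------------------------------------------------------------------------
# evaluation reports


@dataclass
class EvaluationReport:
    """Held-out evaluation of one scenario x family configuration."""

    scenario: str
    family: str
    best_params: dict
    accuracy: float
    macro_sensitivity: float
    confusion: ConfusionMatrix
    cv_fold_ma: list[float] = field(default_factory=list)
    cv_fold_accuracy: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "family": self.family,
            "best_params": self.best_params,
            "accuracy": self.accuracy,
            "macro_sensitivity": self.macro_sensitivity,
            "confusion": self.confusion.to_dict(),
            "cv_fold_ma": self.cv_fold_ma,
            "cv_fold_accuracy": self.cv_fold_accuracy,
        }


def train_and_evaluate(
    table_train: FeatureTable,
    table_test: FeatureTable,
    family: str,
    *,
    scenario: str = "",
    preset: str = "fast",
    folds: int = 5,
    seed: int = 0,
) -> tuple[EvaluationReport, object]:
    """Grid-search on the training table, refit the winner, score held-out."""
    search = grid_search_cv(table_train, family, preset=preset, folds=folds, seed=seed)
    preds, _, model = fit_predict(table_train, table_test, family, search.best_params, seed=seed)
    cm = ConfusionMatrix.from_predictions(table_test.y, preds)
    report = EvaluationReport(
        scenario=scenario, family=family, best_params=search.best_params,
        accuracy=accuracy(cm), macro_sensitivity=macro_average_sensitivity(cm),
        confusion=cm, cv_fold_ma=search.fold_ma, cv_fold_accuracy=search.fold_accuracy,
    )
    return report, model


def best_family_report(
    table_train: FeatureTable,
    table_test: FeatureTable,
    families: Sequence[str] = MODEL_FAMILIES,
    *,
    scenario: str = "",
    preset: str = "fast",
    folds: int = 5,
    seed: int = 0,
) -> tuple[EvaluationReport, object]:
    """Tune every family, pick the winner by CV macro-average sensitivity.

    Family selection happens on the training folds only (mean CV MA, ties
    by mean CV accuracy); the returned report carries the winner's
    held-out metrics.
    """
    candidates = []
    for family in families:
        report, model = train_and_evaluate(
            table_train, table_test, family,
            scenario=scenario, preset=preset, folds=folds, seed=seed,
        )
        cv_ma = float(np.mean(report.cv_fold_ma))
        cv_acc = float(np.mean(report.cv_fold_accuracy))
        candidates.append(((cv_ma, cv_acc), report, model))
    _, report, model = max(candidates, key=lambda c: c[0])
    return report, model


# ---------------------------------------------------------------------------
# experiment C stacking and the redundancy check


def stack_experiment_c(
    a_model,
    a_table: FeatureTable,
    b_table: FeatureTable,
    mode: str,
    extra_decile_features: FeatureTable | None = None,
) -> FeatureTable:
    """Append the A-model output (and optional decile columns) to a B table.

    ``mode`` selects the appended column: "binary" (0/1 prediction) or
    "probability" (P(RVOT)).  Inference uses the fitted model directly;
    nothing is refitted.
    """
    if mode not in ("binary", "probability"):
        raise ValueError(f"mode must be 'binary' or 'probability', got {mode!r}")
    if a_table.patient_ids != b_table.patient_ids:
        raise ValueError("patient sets of the A and B tables do not match")
    preds, probs = predict_with_model(a_model, a_table)
    if mode == "binary":
        out = b_table.with_columns(["a_prediction"], preds.astype(float))
    else:
        out = b_table.with_columns(["a_prob_rvot"], probs)
    if extra_decile_features is not None:
        if extra_decile_features.patient_ids != b_table.patient_ids:
            raise ValueError("patient sets of the extra decile table do not match")
        out = out.with_columns(extra_decile_features.feature_names, extra_decile_features.X)
    return out


_ABLATION_BASE = ("norm_age", "sex", "hta", "v3_amp")
_ABLATION_VPTC = tuple(f"ptc_v{i}" for i in range(1, 7))


def redundancy_ablation(
    b4_train: FeatureTable,
    b4_test: FeatureTable,
    a_pred_train: np.ndarray,
    a_pred_test: np.ndarray,
    family: str = "xgboost",
    *,
    preset: str = "fast",
    seed: int = 0,
) -> "pd.DataFrame":
    """Quantify overlap between the transition vector and the A prediction.

    Evaluates four configurations on the same split — neither feature,
    only the transition vector (vPTC), only the A-model prediction, and
    both — and reports accuracy/MA plus their deltas against "neither".
    """
    import pandas as pd

    def variant(train: FeatureTable, test: FeatureTable, with_vptc: bool, with_pred: bool):
        cols = list(_ABLATION_BASE) + (list(_ABLATION_VPTC) if with_vptc else [])
        tr, te = train.select(cols), test.select(cols)
        if with_pred:
            tr = tr.with_columns(["a_prediction"], np.asarray(a_pred_train, dtype=float))
            te = te.with_columns(["a_prediction"], np.asarray(a_pred_test, dtype=float))
        return tr, te

    rows = []
    for name, with_vptc, with_pred in (
        ("neither", False, False),
        ("vptc_only", True, False),
        ("a_prediction_only", False, True),
        ("both", True, True),
    ):
        tr, te = variant(b4_train, b4_test, with_vptc, with_pred)
        report, _ = train_and_evaluate(tr, te, family, scenario=name, preset=preset, seed=seed)
        rows.append({"configuration": name, "accuracy": report.accuracy,
                     "macro_sensitivity": report.macro_sensitivity})
    df = pd.DataFrame(rows)
    base = df.loc[df.configuration == "neither"].iloc[0]
    df["delta_accuracy"] = df.accuracy - base.accuracy
    df["delta_macro_sensitivity"] = df.macro_sensitivity - base.macro_sensitivity
    return df
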