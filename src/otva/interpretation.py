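"""Feature-relevance analysis: Gini importances and Shapley attributions.

Importances of the 120 decile-voltage features are aggregated per lead
and per 10% QRS section, which is how the influential leads (typically
V1-V4 for the outflow-tract discrimination task) and QRS sections are
identified.  The sign convention for Shapley values follows the binary
target: positive attributions push the prediction toward RVOT, negative
toward LVOT.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from ._treeshap import ensemble_shap_values, sklearn_tree_arrays
from .qrs import LEADS

_TREE_FAMILIES = (RandomForestClassifier, ExtraTreesClassifier, DecisionTreeClassifier,
                  XGBClassifier)

_FEATURE_RE = re.compile(r"^(?P<lead>I|II|III|aVR|aVL|aVF|V[1-6])_s(?P<section>10|[1-9])$")


@dataclass
class RelevanceReport:
    """Per-feature Gini importances plus optional per-sample Shapley values."""

    feature_names: tuple[str, ...]
    gini: np.ndarray
    shap_values: np.ndarray | None = None
    shap_base_value: float | None = None

    def __post_init__(self) -> None:
        self.feature_names = tuple(self.feature_names)
        self.gini = np.asarray(self.gini, dtype=float)
        if self.gini.shape != (len(self.feature_names),):
            raise ValueError("gini importances do not match feature names")
        if np.any(self.gini < 0) or abs(self.gini.sum() - 1.0) > 1e-9:
            raise ValueError("gini importances must be non-negative and sum to 1")
        if self.shap_values is not None:
            self.shap_values = np.asarray(self.shap_values, dtype=float)
            if self.shap_values.shape[1] != len(self.feature_names):
                raise ValueError("shap matrix does not match feature names")

    def mean_abs_shap(self) -> np.ndarray:
        if self.shap_values is None:
            return np.zeros(len(self.feature_names))
        return np.abs(self.shap_values).mean(axis=0)

    def ranked_features(self) -> list[str]:
        return top_k_features(self, len(self.feature_names))

    def to_json(self, path) -> None:
        payload = {
            "feature_names": list(self.feature_names),
            "gini": self.gini.tolist(),
            "mean_abs_shap": self.mean_abs_shap().tolist(),
            "shap_base_value": self.shap_base_value,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def gini_importance(model, feature_names: Sequence[str]) -> np.ndarray:
    """Normalized mean impurity-decrease importance of a tree ensemble.

    Importances are re-normalized to sum to 1; a model with no splits at
    all yields a uniform vector.
    """
    if not isinstance(model, _TREE_FAMILIES):
        raise TypeError(f"Gini importance requires a tree-based model, got {type(model).__name__}")
    m = len(feature_names)
    if isinstance(model, XGBClassifier):
        score = model.get_booster().get_score(importance_type="gain")
        imp = np.zeros(m)
        names = list(feature_names)
        for key, val in score.items():
            idx = names.index(key) if key in names else int(key.lstrip("f"))
            imp[idx] = val
    else:
        imp = np.asarray(model.feature_importances_, dtype=float)
    if imp.shape != (m,):
        raise ValueError("importances do not match the supplied feature names")
    total = imp.sum()
    if total <= 0:
        return np.full(m, 1.0 / m)
    return imp / total


def shap_attribution(model, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-sample signed Shapley attributions plus the base value.

    XGBoost models use their built-in tree-path attribution on the margin
    (log-odds) scale; sklearn forests use the in-package implementation on
    the probability scale.  In both cases base value + row sum equals the
    model output for the positive (RVOT) class.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    expected = getattr(model, "otva_feature_names_", None)
    if expected is not None and X.shape[1] != len(expected):
        raise ValueError(
            f"feature mismatch: model fitted on {len(expected)} features, got {X.shape[1]}"
        )
    if isinstance(model, XGBClassifier):
        from xgboost import DMatrix

        contribs = model.get_booster().predict(DMatrix(X), pred_contribs=True)
        return contribs[:, :-1], float(contribs[0, -1])
    if isinstance(model, (RandomForestClassifier, ExtraTreesClassifier)):
        trees = [sklearn_tree_arrays(est) for est in model.estimators_]
        return ensemble_shap_values(trees, X)
    if isinstance(model, DecisionTreeClassifier):
        return ensemble_shap_values([sklearn_tree_arrays(model)], X)
    raise TypeError(f"Shapley attribution implemented for tree models only, got {type(model).__name__}")


def relevance_report(model, table, *, with_shap: bool = True) -> RelevanceReport:
    """Gini + Shapley relevance of a fitted tree model on a feature table."""
    gini = gini_importance(model, table.feature_names)
    shap_values = base = None
    if with_shap:
        shap_values, base = shap_attribution(model, table.X)
    return RelevanceReport(
        feature_names=table.feature_names, gini=gini,
        shap_values=shap_values, shap_base_value=base,
    )


# ---------------------------------------------------------------------------
# aggregation over leads and QRS sections


def _parse_feature(name: str) -> tuple[str, int]:
    m = _FEATURE_RE.match(name)
    if not m:
        raise ValueError(f"feature name {name!r} does not follow the <lead>_s<section> convention")
    return m.group("lead"), int(m.group("section"))


def aggregate_by_lead_and_section(
    importances: np.ndarray,
    feature_names: Sequence[str],
    mode: str = "lead",
) -> pd.DataFrame | pd.Series:
    """Aggregate per-feature importances of a decile-feature model.

    ``mode="lead"`` sums the 10 section importances of each lead and
    returns a Series indexed by lead; ``mode="lead-section"`` returns the
    full 12 x 10 map as a DataFrame (leads x sections).
    """
    importances = np.asarray(importances, dtype=float)
    if mode not in ("lead", "lead-section"):
        raise ValueError(f"mode must be 'lead' or 'lead-section', got {mode!r}")
    grid = pd.DataFrame(0.0, index=list(LEADS), columns=range(1, 11))
    for name, imp in zip(feature_names, importances, strict=True):
        lead, section = _parse_feature(name)
        grid.loc[lead, section] += imp
    if mode == "lead-section":
        grid.columns = [f"{10*(s-1)}-{10*s}%" for s in range(1, 11)]
        return grid
    return grid.sum(axis=1)


def cumulative_share(lead_shares: pd.Series, leads: Sequence[str]) -> float:
    """Total importance share of a named set of leads."""
    unknown = [l for l in leads if l not in lead_shares.index]
    if unknown:
        raise ValueError(f"unknown leads: {unknown}")
    return float(lead_shares.loc[list(leads)].sum())


def top_k_features(report: RelevanceReport, k: int) -> list[str]:
    """Top-k features by Gini importance.

    Ties are broken by mean absolute Shapley value, then by feature name,
    so the ranking is deterministic across runs.
    """
    m = len(report.feature_names)
    if not (1 <= k <= m):
        raise ValueError(f"k must be in 1..{m}, got {k}")
    mean_abs = report.mean_abs_shap()
    order = sorted(
        range(m),
        key=lambda i: (-report.gini[i], -mean_abs[i], report.feature_names[i]),
    )
    return [report.feature_names[i] for i in order[:k]]
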