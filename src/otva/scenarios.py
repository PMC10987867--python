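"""Per-patient feature tables for the supervised experiment scenarios.

Experiment A uses the 120 decile-voltage features of the PVC QRS.
Experiment B combines clinical covariates (age, sex, hypertension, V3
amplitude) with one of several encodings of the precordial transition:
the clinician-reported lead (PTR), the automatically computed lead (PTC),
its one-hot vector form (vPTC), the PVC-minus-sinus vector (vPTCps), or
the raw per-lead R/S ratios (vPTCVal / vPTCpsVal).  Experiment C stacks
the prediction of a fitted A-scenario model (binary or P(RVOT)) and/or
its top-ranked decile features onto the best B feature block.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import qrs
from .qrs import (
    NO_TRANSITION,
    decile_feature_names,
    extract_pvc_and_preceding_sinus,
)

LVOT = "LVOT"
RVOT = "RVOT"

A_SCENARIOS = ("A.1", "A.2")
B_SCENARIOS = ("B.1", "B.2", "B.3", "B.4", "B.5", "B.6", "B.7")
C_SCENARIOS = ("C.1", "C.2", "C.3", "C.4", "C.5")
ALL_SCENARIOS = A_SCENARIOS + B_SCENARIOS + C_SCENARIOS

#: Number of top-ranked decile features stacked in scenarios C.3-C.5.
DEFAULT_TOP_K = 5


@dataclass(frozen=True)
class ClinicalRecord:
    """Clinical covariates and labels for one patient.

    ``sex`` is encoded male=1 / female=0, ``hypertension`` yes=1.  ``ptr``
    is the clinician-reported precordial transition lead (1..6, or 7 for
    none), optional.  ``soo_specific`` is the consolidated 7-way site of
    origin, optional.
    """

    age: float
    sex: int
    hypertension: int
    soo_binary: str
    ptr: int | None = None
    soo_specific: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.age <= 120):
            raise ValueError(f"age out of range: {self.age}")
        if self.sex not in (0, 1):
            raise ValueError("sex must be encoded male=1 / female=0")
        if self.hypertension not in (0, 1):
            raise ValueError("hypertension must be 0/1")
        if self.soo_binary not in (LVOT, RVOT):
            raise ValueError(f"soo_binary must be LVOT or RVOT, got {self.soo_binary!r}")
        if self.ptr is not None and not (1 <= self.ptr <= NO_TRANSITION):
            raise ValueError(f"ptr must be in 1..7, got {self.ptr}")


@dataclass(frozen=True)
class FeatureTable:
    """Numeric per-patient feature matrix with a binary target (RVOT=1)."""

    patient_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=int)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "patient_ids", tuple(self.patient_ids))
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        if X.shape != (len(self.patient_ids), len(self.feature_names)):
            raise ValueError("feature matrix shape does not match ids/names")
        if not np.isfinite(X).all():
            raise ValueError("feature table contains non-finite values")
        if y.shape != (len(self.patient_ids),):
            raise ValueError("target length does not match ids")

    @property
    def n(self) -> int:
        return len(self.patient_ids)

    def subset(self, ids: Sequence[str]) -> "FeatureTable":
        pos = {p: i for i, p in enumerate(self.patient_ids)}
        rows = [pos[i] for i in ids]
        return FeatureTable(tuple(ids), self.feature_names, self.X[rows], self.y[rows])

    def with_columns(self, names: Sequence[str], values: np.ndarray) -> "FeatureTable":
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if values.shape[0] != self.n:
            values = values.T
        return FeatureTable(
            self.patient_ids,
            self.feature_names + tuple(names),
            np.hstack([self.X, values]),
            self.y,
        )

    def select(self, names: Sequence[str]) -> "FeatureTable":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureTable(self.patient_ids, tuple(names), self.X[:, idx], self.y)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df.insert(0, "patient_id", list(self.patient_ids))
        df["target_rvot"] = self.y
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# elementary encodings


def normalize_age(age: float) -> float:
    """Age divided by 100, matching the dynamic range of the other features."""
    if age < 0:
        raise ValueError(f"negative age: {age}")
    return age / 100.0


def binarize_age(age: float) -> int:
    """Binarized age with the classical strict > 50 years threshold."""
    if age < 0:
        raise ValueError(f"negative age: {age}")
    return int(age > 50)


# ---------------------------------------------------------------------------
# per-patient derived quantities

_VPTC_NAMES = tuple(f"ptc_v{i}" for i in range(1, 7))
_VPTCPS_NAMES = tuple(f"ptcps_v{i}" for i in range(1, 7))
_VPTCVAL_NAMES = tuple(f"rs_pvc_v{i}" for i in range(1, 7))
_VPTCPSVAL_NAMES = _VPTCVAL_NAMES + tuple(f"rs_sinus_v{i}" for i in range(1, 7))


def patient_context(sample) -> dict:
    """Extract all per-patient ECG quantities the scenarios draw from.

    ``sample`` needs ``record``, ``annotations`` and ``clinical`` attributes
    (any cohort sample or equivalent container qualifies).
    """
    sinus_seg, pvc_seg = extract_pvc_and_preceding_sinus(sample.record, sample.annotations)
    pvc_tr = qrs.detect_transition(pvc_seg)
    sinus_tr = qrs.detect_transition(sinus_seg)
    _, vptcps = qrs.combine_pvc_sinus_transition(pvc_tr.index, sinus_tr.index)
    return {
        "deciles": qrs.decile_features(pvc_seg),
        "pvc_transition": pvc_tr.index,
        "sinus_transition": sinus_tr.index,
        "vptc": qrs.transition_vector(pvc_tr.index),
        "vptcps": vptcps,
        "rs_pvc": np.array(pvc_tr.ratios),
        "rs_sinus": np.array(sinus_tr.ratios),
        "v3_amp": qrs.v3_amplitude(pvc_seg),
        "clinical": sample.clinical,
    }


def _clinical_block(ctx: dict, *, binarized: bool) -> tuple[list[str], list[float]]:
    c: ClinicalRecord = ctx["clinical"]
    if binarized:
        return (
            ["bin_age", "sex", "hta", "bin_v3"],
            [binarize_age(c.age), c.sex, c.hypertension,
             qrs.binarize_v3_amplitude(ctx["v3_amp"])],
        )
    return (
        ["norm_age", "sex", "hta", "v3_amp"],
        [normalize_age(c.age), c.sex, c.hypertension, ctx["v3_amp"]],
    )


def _require_ptr(ctx: dict) -> int:
    c: ClinicalRecord = ctx["clinical"]
    if c.ptr is None:
        raise ValueError("scenario requires the clinician-reported transition column 'ptr'")
    return c.ptr


def _b_row(scenario: str, ctx: dict) -> tuple[list[str], list[float]]:
    if scenario == "B.1":
        names, vals = _clinical_block(ctx, binarized=True)
        return names + ["ptr"], vals + [float(_require_ptr(ctx))]
    if scenario == "B.2":
        names, vals = _clinical_block(ctx, binarized=True)
        return names + ["ptc"], vals + [float(ctx["pvc_transition"])]
    if scenario == "B.3":
        names, vals = _clinical_block(ctx, binarized=False)
        return names + ["ptr"], vals + [float(_require_ptr(ctx))]
    names, vals = _clinical_block(ctx, binarized=False)
    if scenario == "B.4":
        return names + list(_VPTC_NAMES), vals + list(ctx["vptc"])
    if scenario == "B.5":
        return names + list(_VPTCPS_NAMES), vals + list(ctx["vptcps"])
    if scenario == "B.6":
        return names + list(_VPTCVAL_NAMES), vals + list(ctx["rs_pvc"])
    if scenario == "B.7":
        return (names + list(_VPTCPSVAL_NAMES),
                vals + list(ctx["rs_pvc"]) + list(ctx["rs_sinus"]))
    raise ValueError(f"unknown B scenario {scenario!r}")


def build_features(
    scenario: str,
    cohort: Sequence,
    *,
    b_scenario: str = "B.4",
    a_model=None,
    a_table: "FeatureTable | None" = None,
    top_decile_features: Sequence[str] | None = None,
    contexts: Sequence[Mapping] | None = None,
) -> FeatureTable:
    """Assemble the feature table for one experiment scenario.

    A.* scenarios yield the 120 decile features of the PVC QRS; B.*
    scenarios the clinical + transition blocks; C.* scenarios stack the
    fitted A-model output (and optionally its top decile features, passed
    as ``top_decile_features``) on the best-B block (``b_scenario``).
    ``contexts`` allows reuse of precomputed :func:`patient_context` dicts.
    """
    if scenario not in ALL_SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if contexts is None:
        contexts = [patient_context(s) for s in cohort]
    ids = tuple(s.patient_id for s in cohort)
    y = np.array([1 if s.clinical.soo_binary == RVOT else 0 for s in cohort])

    if scenario in A_SCENARIOS:
        X = np.vstack([ctx["deciles"] for ctx in contexts])
        return FeatureTable(ids, tuple(decile_feature_names()), X, y)

    if scenario in B_SCENARIOS:
        rows = [_b_row(scenario, ctx) for ctx in contexts]
        names = tuple(rows[0][0])
        X = np.array([vals for _, vals in rows])
        return FeatureTable(ids, names, X, y)

    # C.* scenarios
    from .modeling import predict_with_model  # local import to avoid a cycle

    base = build_features(b_scenario, cohort, contexts=contexts)
    needs_model = scenario in ("C.1", "C.2", "C.4", "C.5")
    if needs_model:
        if a_model is None or a_table is None:
            raise ValueError(f"scenario {scenario} requires a fitted Experiment-A model and its table")
        aligned = a_table.subset(ids)
        preds, probs = predict_with_model(a_model, aligned)
        if scenario in ("C.1", "C.4"):
            base = base.with_columns(["a_prediction"], preds.astype(float))
        else:
            base = base.with_columns(["a_prob_rvot"], probs)
    if scenario in ("C.3", "C.4", "C.5"):
        if top_decile_features is None:
            raise ValueError(f"scenario {scenario} requires the ranked decile feature names")
        if a_table is None:
            raise ValueError(f"scenario {scenario} requires the Experiment-A feature table")
        extra = a_table.subset(ids).select(list(top_decile_features))
        base = base.with_columns(extra.feature_names, extra.X)
    return base


# ---------------------------------------------------------------------------
# stratified splitting


def stratified_split(
    ids: Sequence[str],
    labels: Sequence[str],
    *,
    test_fraction: float = 0.2,
    seed: int = 0,
    databases: Sequence[str] | None = None,
) -> tuple[list[str], list[str]]:
    """Per-database stratified train/test split preserving class fractions.

    Each database is split individually (per-class test count rounded to
    the nearest integer of ``test_fraction`` times the class size) and the
    subsets concatenated, so multi-database cohorts keep their own class
    balance.  Deterministic under ``seed``.
    """
    ids = list(ids)
    labels = list(labels)
    if databases is None:
        databases = ["default"] * len(ids)
    if not (len(ids) == len(labels) == len(databases)):
        raise ValueError("ids, labels and databases must have equal length")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for db in sorted(set(databases)):
        db_idx = [i for i, d in enumerate(databases) if d == db]
        classes = sorted({labels[i] for i in db_idx})
        if len(classes) < 2:
            raise ValueError(f"database {db!r} contains a single class; cannot stratify")
        for cls in classes:
            members = [ids[i] for i in db_idx if labels[i] == cls]
            n_test = int(np.floor(test_fraction * len(members) + 0.5))
            perm = rng.permutation(len(members))
            test.extend(members[j] for j in perm[:n_test])
            train.extend(members[j] for j in perm[n_test:])
    return train, test
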