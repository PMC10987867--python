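"""End-to-end orchestration of the supervised and unsupervised experiments.

An experiment run takes a cohort (synthetic config or on-disk directory),
splits it 80/20 stratified by binary origin, trains every requested
scenario x model-family combination with grid-search cross-validation,
and writes evaluation reports plus a manifest recording the config hash
and seeds.  Experiment C automatically trains the Experiment-A model it
stacks on; Experiment D runs the silhouette-selected Ward clustering.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import scenarios as scen
from .clustering import ClusteringResult, cluster_cohort
from .cohort import SyntheticCohortConfig, generate_cohort, read_cohort
from .interpretation import relevance_report, top_k_features
from .modeling import (
    MODEL_FAMILIES,
    EvaluationReport,
    train_and_evaluate,
)
from .scenarios import DEFAULT_TOP_K, FeatureTable, build_features, patient_context

_TREE_FAMILIES = ("random_forest", "extra_trees", "xgboost")

_DEFAULT_SCENARIOS = {
    "A": scen.A_SCENARIOS,
    "B": scen.B_SCENARIOS,
    "C": scen.C_SCENARIOS,
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of one experiment run (A, B, C or D)."""

    experiment: str
    cohort: SyntheticCohortConfig | str
    scenarios: tuple[str, ...] | None = None
    aux_cohorts: tuple[SyntheticCohortConfig | str, ...] = ()
    families: tuple[str, ...] = MODEL_FAMILIES
    grid_preset: str = "fast"
    seed: int = 0
    test_fraction: float = 0.2
    top_k: int = DEFAULT_TOP_K
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.experiment not in ("A", "B", "C", "D"):
            raise ValueError(f"experiment must be one of A, B, C, D, got {self.experiment!r}")
        unknown = set(self.families) - set(MODEL_FAMILIES)
        if unknown:
            raise ValueError(f"unknown model families: {unknown}")
        if self.scenarios is not None:
            valid = _DEFAULT_SCENARIOS.get(self.experiment, ())
            bad = set(self.scenarios) - set(valid)
            if bad:
                raise ValueError(f"scenarios {bad} not valid for experiment {self.experiment}")
            object.__setattr__(self, "scenarios", tuple(self.scenarios))
        object.__setattr__(self, "aux_cohorts", tuple(self.aux_cohorts))
        object.__setattr__(self, "families", tuple(self.families))

    def to_dict(self) -> dict:
        def coh(c):
            return c.to_dict() if isinstance(c, SyntheticCohortConfig) else str(c)

        return {
            "experiment": self.experiment,
            "cohort": coh(self.cohort),
            "scenarios": list(self.scenarios) if self.scenarios else None,
            "aux_cohorts": [coh(c) for c in self.aux_cohorts],
            "families": list(self.families),
            "grid_preset": self.grid_preset,
            "seed": self.seed,
            "test_fraction": self.test_fraction,
            "top_k": self.top_k,
        }

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_cohort(source: SyntheticCohortConfig | str):
    if isinstance(source, SyntheticCohortConfig):
        return generate_cohort(source)
    return read_cohort(source)


@dataclass
class ExperimentBundle:
    """Everything produced by one experiment run."""

    config: ExperimentConfig
    reports: list[EvaluationReport] = field(default_factory=list)
    models: dict[tuple[str, str], object] = field(default_factory=dict)
    clustering: ClusteringResult | None = None
    relevance: dict[str, object] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def best_report(self) -> EvaluationReport:
        if not self.reports:
            raise ValueError("bundle contains no evaluation reports")
        return max(
            self.reports,
            key=lambda r: (r.macro_sensitivity, r.accuracy),
        )


def compare_reports(reports: Sequence[EvaluationReport]) -> pd.DataFrame:
    """Rank reports by macro-average sensitivity, then accuracy."""
    if not reports:
        raise ValueError("no reports to compare")
    df = pd.DataFrame(
        [
            {
                "scenario": r.scenario,
                "family": r.family,
                "macro_sensitivity": r.macro_sensitivity,
                "accuracy": r.accuracy,
            }
            for r in reports
        ]
    ).sort_values(
        ["macro_sensitivity", "accuracy"], ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def _train_scenarios(
    scenario_ids: Sequence[str],
    tables: Mapping[str, tuple[FeatureTable, FeatureTable]],
    config: ExperimentConfig,
) -> tuple[list[EvaluationReport], dict]:
    reports, models = [], {}
    for sid in scenario_ids:
        train, test = tables[sid]
        for family in config.families:
            report, model = train_and_evaluate(
                train, test, family,
                scenario=sid, preset=config.grid_preset, seed=config.seed,
            )
            reports.append(report)
            models[(sid, family)] = model
    return reports, models


def _run_a(config, cohort, contexts, train_ids, test_ids):
    """Experiment A tables: A.1 primary cohort only, A.2 adds auxiliary
    cohorts to the training rows (reporting stays on the primary test set)."""
    full = build_features("A.1", cohort, contexts=contexts)
    tables = {}
    sids = config.scenarios or _DEFAULT_SCENARIOS["A"]
    if "A.1" in sids:
        tables["A.1"] = (full.subset(train_ids), full.subset(test_ids))
    if "A.2" in sids:
        train = full.subset(train_ids)
        for aux_source in config.aux_cohorts:
            aux = _load_cohort(aux_source)
            aux_table = build_features("A.1", aux)
            prefixed = FeatureTable(
                tuple(f"aux-{len(tables)}-{p}" for p in aux_table.patient_ids),
                aux_table.feature_names, aux_table.X, aux_table.y,
            )
            train = FeatureTable(
                train.patient_ids + prefixed.patient_ids,
                train.feature_names,
                np.vstack([train.X, prefixed.X]),
                np.concatenate([train.y, prefixed.y]),
            )
        tables["A.2"] = (train, full.subset(test_ids))
    return {sid: tables[sid] for sid in sids}, full


def run_experiment(config: ExperimentConfig) -> ExperimentBundle:
    """Run one experiment end to end and (optionally) write its artifacts."""
    cohort = _load_cohort(config.cohort)
    contexts = [patient_context(s) for s in cohort]
    bundle = ExperimentBundle(config=config)

    if config.experiment == "D":
        bundle.clustering = cluster_cohort(cohort, contexts=contexts)
    else:
        ids = [s.patient_id for s in cohort]
        labels = [s.clinical.soo_binary for s in cohort]
        train_ids, test_ids = scen.stratified_split(
            ids, labels, test_fraction=config.test_fraction, seed=config.seed
        )
        if config.experiment == "A":
            tables, _ = _run_a(config, cohort, contexts, train_ids, test_ids)
            bundle.reports, bundle.models = _train_scenarios(tables.keys(), tables, config)
        elif config.experiment == "B":
            sids = config.scenarios or _DEFAULT_SCENARIOS["B"]
            tables = {}
            for sid in sids:
                full = build_features(sid, cohort, contexts=contexts)
                tables[sid] = (full.subset(train_ids), full.subset(test_ids))
            bundle.reports, bundle.models = _train_scenarios(sids, tables, config)
        else:  # C — train A first, rank its features, then stack
            a_config = ExperimentConfig(
                experiment="A", cohort=config.cohort, aux_cohorts=config.aux_cohorts,
                families=config.families, grid_preset=config.grid_preset,
                seed=config.seed, test_fraction=config.test_fraction,
            )
            a_tables, a_full = _run_a(a_config, cohort, contexts, train_ids, test_ids)
            a_reports, a_models = _train_scenarios(a_tables.keys(), a_tables, a_config)
            best_a = max(a_reports, key=lambda r: (r.macro_sensitivity, r.accuracy))
            a_model = a_models[(best_a.scenario, best_a.family)]
            # feature ranking needs a tree model; fall back to the best tree
            # family when the overall best A model is not tree-based
            if best_a.family in _TREE_FAMILIES:
                ranking_model = a_model
            else:
                tree_reports = [r for r in a_reports if r.family in _TREE_FAMILIES]
                best_tree = max(tree_reports, key=lambda r: (r.macro_sensitivity, r.accuracy))
                ranking_model = a_models[(best_tree.scenario, best_tree.family)]
            rel = relevance_report(ranking_model, a_full)
            top_features = top_k_features(rel, config.top_k)
            bundle.relevance["A"] = rel
            bundle.relevance["A_top_features"] = top_features
            bundle.relevance["A_best"] = (best_a.scenario, best_a.family)

            sids = config.scenarios or _DEFAULT_SCENARIOS["C"]
            tables = {}
            for sid in sids:
                full = build_features(
                    sid, cohort, contexts=contexts, a_model=a_model,
                    a_table=a_full, top_decile_features=top_features,
                )
                tables[sid] = (full.subset(train_ids), full.subset(test_ids))
            bundle.reports, bundle.models = _train_scenarios(sids, tables, config)
            bundle.reports = a_reports + bundle.reports
            bundle.models.update(a_models)

    bundle.manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_patients": len(cohort),
        "n_reports": len(bundle.reports),
    }
    if config.out_dir:
        _write_bundle(bundle, Path(config.out_dir))
    return bundle


def _write_bundle(bundle: ExperimentBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=1)
    if bundle.reports:
        with open(out_dir / "reports.json", "w") as fh:
            json.dump([r.to_dict() for r in bundle.reports], fh, indent=1)
        compare_reports(bundle.reports).to_csv(out_dir / "ranking.csv", index=False)
    if bundle.clustering is not None:
        bundle.clustering.write(out_dir / "clustering")
    rel = bundle.relevance.get("A")
    if rel is not None:
        rel.to_json(out_dir / "relevance_a.json")
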