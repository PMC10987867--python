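"""Unsupervised exploration of the specific site of origin.

Clinician-reported origin labels are consolidated to seven anatomical
sites and grouped into three macro structures (aortic cusp, LVOT, RVOT).
Patients are clustered by Ward's variance-minimization criterion; the
dendrogram cut height is chosen by a silhouette grid search, and the
result is summarized as a cluster-by-origin frequency table ordered by
dendrogram leaf position with a top/mid/bottom banding of the clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from sklearn.metrics import silhouette_score

from .scenarios import FeatureTable, build_features, patient_context

AOC = "AoC"
MACRO_GROUPS = (AOC, "LVOT", "RVOT")

#: Consolidated 7-way label -> macro anatomical structure.
CONSOLIDATED_TO_MACRO: dict[str, str] = {
    "RCC": AOC,
    "LCC": AOC,
    "RCC/LCC commissure": AOC,
    "LVOT sub valvular": "LVOT",
    "LV summit": "LVOT",
    "RVOT septum": "RVOT",
    "RVOT free wall": "RVOT",
}


@dataclass(frozen=True)
class LabelMap:
    """Raw clinician label -> consolidated 7-way label -> macro group.

    The raw->consolidated mapping is user-supplied (hospitals use dozens
    of free-text site labels); by default the seven consolidated names map
    to themselves.  The consolidated->macro mapping is fixed.
    """

    raw_to_consolidated: Mapping[str, str] = field(
        default_factory=lambda: {k: k for k in CONSOLIDATED_TO_MACRO}
    )

    def __post_init__(self) -> None:
        bad = {v for v in self.raw_to_consolidated.values()} - set(CONSOLIDATED_TO_MACRO)
        if bad:
            raise ValueError(f"mapped values outside the 7 consolidated labels: {bad}")

    def consolidate(self, raw: str) -> tuple[str, str]:
        if raw not in self.raw_to_consolidated:
            raise KeyError(f"unmapped origin label: {raw!r}")
        consolidated = self.raw_to_consolidated[raw]
        return consolidated, CONSOLIDATED_TO_MACRO[consolidated]


def consolidate_labels(
    raw_labels: Sequence[str], label_map: LabelMap | None = None
) -> tuple[list[str], list[str]]:
    """Map raw labels to (consolidated, macro) label lists."""
    label_map = label_map or LabelMap()
    pairs = [label_map.consolidate(r) for r in raw_labels]
    return [p[0] for p in pairs], [p[1] for p in pairs]


# ---------------------------------------------------------------------------
# Ward clustering with silhouette-selected threshold


def ward_linkage(X: np.ndarray) -> np.ndarray:
    """Ward (minimum variance increase) agglomerative linkage, Euclidean."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains NaN/inf")
    return linkage(X, method="ward")


def select_threshold(
    Z: np.ndarray,
    X: np.ndarray,
    candidate_grid: Sequence[float] | None = None,
) -> tuple[float, np.ndarray, float, pd.DataFrame]:
    """Choose the dendrogram cut maximizing the mean silhouette score.

    The default candidate grid is 50 thresholds evenly spaced between the
    smallest and largest merge heights.  Ties go to the larger threshold
    (fewer clusters).  Returns (threshold, assignments, silhouette, trace)
    where trace lists every evaluated candidate.
    """
    X = np.asarray(X, dtype=float)
    heights = Z[:, 2]
    if candidate_grid is None:
        candidate_grid = np.linspace(heights.min(), heights.max(), 50)
    rows = []
    best = None
    for t in sorted(candidate_grid):
        labels = fcluster(Z, t, criterion="distance")
        k = len(np.unique(labels))
        if k < 2 or k >= len(labels):
            rows.append({"threshold": float(t), "n_clusters": k, "silhouette": np.nan})
            continue
        score = float(silhouette_score(X, labels, metric="euclidean"))
        rows.append({"threshold": float(t), "n_clusters": k, "silhouette": score})
        if best is None or score >= best[2] - 1e-12:
            best = (float(t), labels, score)
    if best is None:
        raise ValueError("no candidate threshold produced at least 2 clusters")
    trace = pd.DataFrame(rows)
    return best[0], best[1], best[2], trace


def cluster_label_table(
    Z: np.ndarray,
    assignments: np.ndarray,
    labels: Sequence[str],
) -> tuple[pd.DataFrame, dict[int, str]]:
    """Cluster-by-origin frequency table ordered by dendrogram position.

    Clusters are numbered 1..k in order of first appearance along the
    dendrogram leaf ordering, and banded into thirds (top/mid/bottom; the
    middle band absorbs the remainder, so 25 clusters band as 8/9/8).
    Returns the frequency table (rows = ordered clusters, columns = labels)
    and the cluster -> band mapping.
    """
    assignments = np.asarray(assignments)
    if len(assignments) != len(labels):
        raise ValueError("assignments and labels must have equal length")
    order = leaves_list(Z)
    seen: list[int] = []
    for leaf in order:
        c = int(assignments[leaf])
        if c not in seen:
            seen.append(c)
    rank = {c: i + 1 for i, c in enumerate(seen)}
    k = len(seen)
    label_values = sorted(set(labels))
    table = pd.DataFrame(0, index=range(1, k + 1), columns=label_values)
    for c, lab in zip(assignments, labels):
        table.loc[rank[int(c)], lab] += 1
    table.index.name = "cluster"
    top, bottom = k // 3, k // 3
    bands = {}
    for i in range(1, k + 1):
        if i <= top:
            bands[i] = "top"
        elif i <= k - bottom:
            bands[i] = "mid"
        else:
            bands[i] = "bottom"
    return table, bands


@dataclass
class ClusteringResult:
    """Bundle of the silhouette-selected clustering of a cohort."""

    linkage: np.ndarray
    threshold: float
    assignments: np.ndarray
    silhouette: float
    trace: pd.DataFrame
    frequency_table: pd.DataFrame
    bands: dict[int, str]

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.assignments))

    def macro_purity(self, macro_labels: Sequence[str]) -> float:
        """Fraction of samples in their cluster's majority macro group."""
        macro = np.asarray(macro_labels)
        correct = 0
        for c in np.unique(self.assignments):
            members = macro[self.assignments == c]
            values, counts = np.unique(members, return_counts=True)
            correct += counts.max()
        return correct / len(macro)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            self.linkage, columns=["node_a", "node_b", "height", "size"]
        ).to_csv(directory / "linkage.csv", index=False)
        pd.DataFrame({"assignment": self.assignments}).to_csv(
            directory / "assignments.csv", index_label="sample"
        )
        self.frequency_table.assign(
            band=[self.bands[i] for i in self.frequency_table.index]
        ).to_csv(directory / "frequency_table.csv")
        self.trace.to_csv(directory / "silhouette_trace.csv", index=False)


# ---------------------------------------------------------------------------
# feature space for the unsupervised experiment


def clustering_features(
    cohort: Sequence, *, b_scenario: str = "B.4",
    contexts: Sequence[Mapping] | None = None,
) -> FeatureTable:
    """Feature space for origin clustering: best-B block + decile features.

    Columns are standardized to zero mean / unit variance (constant
    columns are left at zero) so the clinical features and the decile
    voltages contribute on comparable scales.
    """
    if contexts is None:
        contexts = [patient_context(s) for s in cohort]
    b = build_features(b_scenario, cohort, contexts=contexts)
    a = build_features("A.1", cohort, contexts=contexts)
    X = np.hstack([b.X, a.X])
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    return FeatureTable(
        b.patient_ids, b.feature_names + a.feature_names, (X - mu) / sd, b.y
    )


def cluster_cohort(
    cohort: Sequence,
    *,
    label_map: LabelMap | None = None,
    candidate_grid: Sequence[float] | None = None,
    contexts: Sequence[Mapping] | None = None,
) -> ClusteringResult:
    """End-to-end unsupervised run: features, Ward linkage, silhouette cut,
    frequency table over the consolidated origin labels."""
    table = clustering_features(cohort, contexts=contexts)
    raw = [s.clinical.soo_specific for s in cohort]
    if any(r is None for r in raw):
        raise ValueError("clustering requires the specific origin label for every sample")
    consolidated, _ = consolidate_labels(raw, label_map)
    Z = ward_linkage(table.X)
    threshold, assignments, silhouette, trace = select_threshold(Z, table.X, candidate_grid)
    freq, bands = cluster_label_table(Z, assignments, consolidated)
    return ClusteringResult(
        linkage=Z, threshold=threshold, assignments=assignments,
        silhouette=silhouette, trace=trace, frequency_table=freq, bands=bands,
    )
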