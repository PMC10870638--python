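"""Symptom cluster extraction from rotated loading tables.

A symptom cluster is a factor with at least two symptoms whose rotated
loadings meet the reporting threshold (|loading| >= 0.40 by default; the
threshold is inclusive and applied to absolute loadings). Symptoms may
cross-load: an item meeting the threshold on several factors belongs to
each of those clusters. Factors with fewer than two qualifying symptoms are
not adequately defined and are dropped; their items count as unassigned
unless captured by another cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .efa import FactorSolution

__all__ = [
    "SymptomCluster",
    "ClusterSet",
    "extract_clusters",
    "clusters_from_loading_frame",
    "read_loading_table",
    "write_loading_table",
]

DEFAULT_LOADING_THRESHOLD = 0.40


@dataclass
class SymptomCluster:
    """One cluster: members ordered by |loading| descending.

    Ties in |loading| break by catalog (row) order and are flagged, since
    member order feeds the top-k consistency rule downstream.
    """

    cluster_id: str
    members: list[tuple[str, float]]
    label: str | None = None
    tied_members: bool = False

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def codes(self) -> list[str]:
        return [c for c, _ in self.members]

    def loading_of(self, code: str) -> float:
        for c, v in self.members:
            if c == code:
                return v
        raise KeyError(code)

    def top(self, k: int) -> list[str]:
        """Codes of the k highest-|loading| members (all of a tie at the
        k-th position are included)."""
        if k >= self.size:
            return self.codes
        cut = abs(self.members[k - 1][1])
        out = self.codes[:k]
        for c, v in self.members[k:]:
            if abs(v) == cut:
                out.append(c)
            else:
                break
        return out


@dataclass
class ClusterSet:
    """All adequately defined clusters extracted for one group."""

    group: str
    clusters: list[SymptomCluster]
    unassigned: list[str] = field(default_factory=list)
    threshold: float = DEFAULT_LOADING_THRESHOLD
    source: FactorSolution | None = None

    def __len__(self) -> int:
        return len(self.clusters)

    def by_id(self, cluster_id: str) -> SymptomCluster:
        for c in self.clusters:
            if c.cluster_id == cluster_id:
                return c
        raise KeyError(cluster_id)


def clusters_from_loading_frame(
    loadings: pd.DataFrame,
    threshold: float = DEFAULT_LOADING_THRESHOLD,
    group: str = "",
    labels: dict[str, str] | None = None,
    source: FactorSolution | None = None,
) -> ClusterSet:
    """Apply the cluster-extraction rules to an items x factors frame."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    labels = labels or {}
    clusters: list[SymptomCluster] = []
    assigned: set[str] = set()
    row_order = {code: i for i, code in enumerate(loadings.index)}
    for col in loadings.columns:
        vals = loadings[col]
        meets = vals[np.abs(vals) >= threshold]
        if len(meets) < 2:
            continue  # not adequately defined
        members = sorted(
            ((str(c), float(v)) for c, v in meets.items()),
            key=lambda cv: (-abs(cv[1]), row_order[cv[0]]),
        )
        mags = [abs(v) for _, v in members]
        tied = len(mags) != len(set(mags))
        clusters.append(
            SymptomCluster(str(col), members, labels.get(str(col)), tied_members=tied)
        )
        assigned.update(c for c, _ in members)
    unassigned = [str(c) for c in loadings.index if str(c) not in assigned]
    return ClusterSet(group, clusters, unassigned, threshold, source)


def extract_clusters(
    solution: FactorSolution,
    threshold: float = DEFAULT_LOADING_THRESHOLD,
    group: str = "",
    labels: dict[str, str] | None = None,
    factor_names: list[str] | None = None,
) -> ClusterSet:
    """Extract clusters from a rotated factor solution."""
    frame = solution.rotated_frame(factor_names)
    return clusters_from_loading_frame(frame, threshold, group, labels, source=solution)


def read_loading_table(path: str | Path) -> pd.DataFrame:
    """Read an items x factors loading TSV (first column = item code).

    Accepts the same dialect :func:`write_loading_table` emits, so printed
    loading tables can be typed up and fed straight to the comparator.
    """
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    return df.astype(float)


def write_loading_table(loadings: pd.DataFrame, path: str | Path, decimals: int = 3) -> None:
    """Write an items x factors loading TSV, rounded for display."""
    loadings.round(decimals).to_csv(path, sep="\t", index_label="item",
                                    float_format=f"%.{decimals}f")
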