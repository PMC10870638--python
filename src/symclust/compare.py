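"""Stability and consistency of symptom clusters across two groups.

*Stability* asks whether the same clusters appear in both groups. Clusters
are first matched one-to-one by maximizing total shared membership (optimal
assignment on the overlap matrix); a matched pair is stable when it shares
at least two at-threshold symptoms — two being the minimum number of
symptoms that defines a cluster at all.

*Consistency* asks whether the core of a matched cluster is the same: the
top-k highest-loading symptoms must appear in BOTH groups' top-k sets,
with k = 2 when the larger cluster of the pair has at most three symptoms
and k = 3 when it has four or more. A verdict of "2/3" reads: two of the
required three top symptoms are shared, hence not consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .clusters import ClusterSet, SymptomCluster

__all__ = [
    "MatchedClusterPair",
    "ConsistencyVerdict",
    "StabilityReport",
    "match_clusters",
    "is_stable",
    "consistency_k",
    "assess_consistency",
    "compare_cluster_sets",
]


@dataclass
class MatchedClusterPair:
    cluster_a: SymptomCluster | None
    cluster_b: SymptomCluster | None
    shared: list[str] = field(default_factory=list)

    @property
    def overlap(self) -> int:
        return len(self.shared)

    @property
    def both_present(self) -> bool:
        return self.cluster_a is not None and self.cluster_b is not None


@dataclass
class ConsistencyVerdict:
    k: int
    shared_top: int
    consistent: bool
    top_a: list[str]
    top_b: list[str]
    tie_affected: bool = False

    def __str__(self) -> str:
        return f"{self.shared_top}/{self.k}"


@dataclass
class StabilityReport:
    pairs: list[MatchedClusterPair]
    stable_flags: list[bool]
    verdicts: list[ConsistencyVerdict | None]
    unmatched_a: list[SymptomCluster]
    unmatched_b: list[SymptomCluster]
    group_a: str = "younger"
    group_b: str = "older"

    @property
    def n_stable(self) -> int:
        return sum(self.stable_flags)

    @property
    def n_consistent(self) -> int:
        return sum(1 for v in self.verdicts if v is not None and v.consistent)

    @property
    def n_inconsistent(self) -> int:
        return sum(1 for v in self.verdicts if v is not None and not v.consistent)

    def to_dict(self) -> dict:
        return {
            "group_a": self.group_a,
            "group_b": self.group_b,
            "summary": {
                "n_pairs": len(self.pairs),
                "n_stable": self.n_stable,
                "n_consistent": self.n_consistent,
                "n_inconsistent": self.n_inconsistent,
            },
            "pairs": [
                {
                    "cluster_a": p.cluster_a.cluster_id if p.cluster_a else None,
                    "cluster_b": p.cluster_b.cluster_id if p.cluster_b else None,
                    "label": (p.cluster_a.label if p.cluster_a and p.cluster_a.label
                              else (p.cluster_b.label if p.cluster_b else None)),
                    "shared": p.shared,
                    "overlap": p.overlap,
                    "stable": s,
                    "consistency": str(v) if v else None,
                    "consistent": v.consistent if v else None,
                    "top_a": v.top_a if v else None,
                    "top_b": v.top_b if v else None,
                    "tie_affected": v.tie_affected if v else None,
                }
                for p, s, v in zip(self.pairs, self.stable_flags, self.verdicts)
            ],
            "unmatched": {
                self.group_a: [c.cluster_id for c in self.unmatched_a],
                self.group_b: [c.cluster_id for c in self.unmatched_b],
            },
        }

    def render_text(self) -> str:
        lines = [
            f"Cluster comparison: {self.group_a} vs {self.group_b}",
            f"  matched pairs: {len(self.pairs)}  stable: {self.n_stable}  "
            f"consistent: {self.n_consistent}  not consistent: {self.n_inconsistent}",
            "",
        ]
        for p, s, v in zip(self.pairs, self.stable_flags, self.verdicts):
            name = (p.cluster_a.label or p.cluster_a.cluster_id) if p.cluster_a else (
                p.cluster_b.label or p.cluster_b.cluster_id)
            lines.append(f"[{name}]")
            for side, cl in ((self.group_a, p.cluster_a), (self.group_b, p.cluster_b)):
                if cl is None:
                    lines.append(f"  {side:>8}: (absent)")
                else:
                    mem = ", ".join(f"{c} ({v_:.3f})" for c, v_ in cl.members)
                    lines.append(f"  {side:>8}: {mem}")
            lines.append(f"  shared: {p.overlap} -> {'stable' if s else 'NOT stable'}")
            if v is not None:
                tag = "consistent" if v.consistent else "not consistent"
                tie = " (tie-affected)" if v.tie_affected else ""
                lines.append(f"  consistency: {v} -> {tag}{tie}")
            lines.append("")
        for side, un in ((self.group_a, self.unmatched_a), (self.group_b, self.unmatched_b)):
            if un:
                lines.append(f"unmatched in {side}: {[c.cluster_id for c in un]}")
        return "\n".join(lines)


def _shared(a: SymptomCluster, b: SymptomCluster) -> list[str]:
    sb = set(b.codes)
    return [c for c in a.codes if c in sb]


def _shared_loading_sum(a: SymptomCluster, b: SymptomCluster, shared: list[str]) -> float:
    return sum(abs(a.loading_of(c)) + abs(b.loading_of(c)) for c in shared)


def match_clusters(set_a: ClusterSet, set_b: ClusterSet) -> list[MatchedClusterPair]:
    """One-to-one cluster matching maximizing total shared-symptom count.

    Optimal assignment on the overlap matrix; ties in total overlap break
    toward the assignment with the larger summed |loading| of shared
    symptoms, then toward cluster order. Clusters left over when the set
    sizes differ are returned as half-empty pairs.
    """
    if not set_a.clusters or not set_b.clusters:
        raise ValueError("both cluster sets must be nonempty")
    na, nb = len(set_a.clusters), len(set_b.clusters)
    overlap = np.zeros((na, nb))
    tiebreak = np.zeros((na, nb))
    for i, ca in enumerate(set_a.clusters):
        for j, cb in enumerate(set_b.clusters):
            sh = _shared(ca, cb)
            overlap[i, j] = len(sh)
            tiebreak[i, j] = _shared_loading_sum(ca, cb, sh)
    # secondary criteria scaled far below one unit of overlap
    tb_max = tiebreak.max()
    score = overlap + (1e-4 / max(tb_max, 1.0)) * tiebreak
    if min(na, nb) <= 6:
        rows, cols = _brute_force_assignment(score)
    else:
        rows, cols = linear_sum_assignment(-score)
    pairs = []
    used_a, used_b = set(), set()
    for i, j in sorted(zip(rows, cols)):
        ca, cb = set_a.clusters[i], set_b.clusters[j]
        pairs.append(MatchedClusterPair(ca, cb, _shared(ca, cb)))
        used_a.add(i)
        used_b.add(j)
    for i, ca in enumerate(set_a.clusters):
        if i not in used_a:
            pairs.append(MatchedClusterPair(ca, None, []))
    for j, cb in enumerate(set_b.clusters):
        if j not in used_b:
            pairs.append(MatchedClusterPair(None, cb, []))
    return pairs


def _brute_force_assignment(score: np.ndarray) -> tuple[list[int], list[int]]:
    """Exhaustive assignment over the smaller dimension (deterministic
    lexicographic tie-break by index order)."""
    na, nb = score.shape
    if na <= nb:
        best = None
        for perm in permutations(range(nb), na):
            tot = sum(score[i, perm[i]] for i in range(na))
            if best is None or tot > best[0] + 1e-12:
                best = (tot, list(range(na)), list(perm))
        return best[1], best[2]
    cols_rows = _brute_force_assignment(score.T)
    return cols_rows[1], cols_rows[0]


def is_stable(pair: MatchedClusterPair, min_shared: int = 2) -> bool:
    """A pair is stable when both sides exist and share >= ``min_shared``
    at-threshold symptoms (two = the minimum cluster-defining size)."""
    return pair.both_present and pair.overlap >= min_shared


def consistency_k(size_a: int, size_b: int) -> int:
    """Top-set size for the consistency rule.

    Two shared top symptoms are required for pairs whose larger cluster has
    at most three symptoms; three are required once the larger cluster has
    four or more.
    """
    if min(size_a, size_b) < 2:
        raise ValueError("cluster sizes must be >= 2")
    return 2 if max(size_a, size_b) <= 3 else 3


def assess_consistency(pair: MatchedClusterPair) -> ConsistencyVerdict:
    """Top-k shared-symptom consistency verdict for a matched pair.

    Symmetric in the two groups. Ties at the k-th |loading| expand the top
    set (all tied symptoms included) and flag the verdict.
    """
    if not pair.both_present:
        raise ValueError("both clusters must be present to assess consistency")
    a, b = pair.cluster_a, pair.cluster_b
    k = consistency_k(a.size, b.size)
    top_a = a.top(k)
    top_b = b.top(k)
    shared_top = len(set(top_a) & set(top_b))
    tie = len(top_a) > min(k, a.size) or len(top_b) > min(k, b.size)
    return ConsistencyVerdict(
        k=k,
        shared_top=min(shared_top, k),
        consistent=shared_top >= k,
        top_a=top_a,
        top_b=top_b,
        tie_affected=tie,
    )


def compare_cluster_sets(set_a: ClusterSet, set_b: ClusterSet) -> StabilityReport:
    """Full comparison: match, stability flags, consistency verdicts."""
    pairs = match_clusters(set_a, set_b)
    flags = [is_stable(p) for p in pairs]
    verdicts = [assess_consistency(p) if p.both_present else None for p in pairs]
    unmatched_a = [p.cluster_a for p in pairs if p.cluster_b is None and p.cluster_a]
    unmatched_b = [p.cluster_b for p in pairs if p.cluster_a is None and p.cluster_b]
    matched = [
        (p, f, v) for p, f, v in zip(pairs, flags, verdicts) if p.both_present
    ]
    return StabilityReport(
        pairs=[m[0] for m in matched] + [p for p in pairs if not p.both_present],
        stable_flags=[m[1] for m in matched] + [False] * (len(pairs) - len(matched)),
        verdicts=[m[2] for m in matched] + [None] * (len(pairs) - len(matched)),
        unmatched_a=unmatched_a,
        unmatched_b=unmatched_b,
        group_a=set_a.group or "group_a",
        group_b=set_b.group or "group_b",
    )
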