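"""Cluster extraction rules and the stability/consistency classifier."""

import numpy as np
import pandas as pd
import pytest

from symclust import (
    assess_consistency,
    clusters_from_loading_frame,
    compare_cluster_sets,
    consistency_k,
    is_stable,
    match_clusters,
    read_loading_table,
    reference_loadings,
    write_loading_table,
)
from symclust.clusters import ClusterSet, SymptomCluster
from symclust.compare import MatchedClusterPair, _brute_force_assignment


def _cluster(cid, members):
    return SymptomCluster(cid, members)


def _clusterset(group, clusters):
    return ClusterSet(group, clusters)


# -- extraction rules ---------------------------------------------------

def test_threshold_is_inclusive_at_exactly_040():
    frame = pd.DataFrame(
        {"f1": [0.40, 0.41, 0.399], "f2": [0.0, 0.0, 0.0]},
        index=["a", "b", "c"],
    )
    cs = clusters_from_loading_frame(frame)
    assert len(cs.clusters) == 1
    assert cs.clusters[0].codes == ["b", "a"]  # sorted by |loading| desc
    assert cs.unassigned == ["c"]


def test_single_member_factor_is_dropped():
    frame = pd.DataFrame(
        {"f1": [0.8, 0.7, 0.0], "f2": [0.0, 0.0, 0.9]},
        index=["a", "b", "c"],
    )
    cs = clusters_from_loading_frame(frame)
    assert [c.cluster_id for c in cs.clusters] == ["f1"]
    assert cs.unassigned == ["c"]


def test_negative_loadings_count_by_magnitude():
    frame = pd.DataFrame({"f1": [-0.8, 0.5, 0.2]}, index=["a", "b", "c"])
    cs = clusters_from_loading_frame(frame)
    assert cs.clusters[0].codes == ["a", "b"]


def test_cross_loading_item_joins_every_qualifying_cluster():
    younger = reference_loadings("younger")
    cs = clusters_from_loading_frame(younger)
    in_clusters = [c.cluster_id for c in cs.clusters
                   if "difficulty_concentrating" in c.codes]
    assert sorted(in_clusters) == ["fatigue", "psychological"]


def test_loading_ties_are_flagged_and_break_by_row_order():
    frame = pd.DataFrame({"f1": [0.5, 0.7, 0.5]}, index=["a", "b", "c"])
    cs = clusters_from_loading_frame(frame)
    assert cs.clusters[0].codes == ["b", "a", "c"]
    assert cs.clusters[0].tied_members


def test_reference_tables_reproduce_printed_membership():
    younger = clusters_from_loading_frame(reference_loadings("younger"))
    resp = younger.by_id("respiratory")
    assert resp.members == [
        ("difficulty_breathing", 1.049),
        ("shortness_of_breath", 0.824),
        ("chest_tightness", 0.611),
    ]
    older = clusters_from_loading_frame(reference_loadings("older"))
    epi = older.by_id("epithelial")
    assert epi.size == 6
    assert "dizziness" in epi.codes


def test_loading_table_round_trip(tmp_path):
    frame = reference_loadings("older")
    path = tmp_path / "loadings.tsv"
    write_loading_table(frame, path)
    back = read_loading_table(path)
    pd.testing.assert_frame_equal(back, frame, check_names=False, atol=5e-4)


# -- matching -----------------------------------------------------------

def test_identical_sets_match_to_themselves(reference_cluster_sets):
    cs = reference_cluster_sets["younger"]
    pairs = match_clusters(cs, cs)
    assert len(pairs) == len(cs.clusters)
    for p in pairs:
        assert p.cluster_a.cluster_id == p.cluster_b.cluster_id
        assert p.overlap == p.cluster_a.size


def test_matching_is_optimal_not_greedy():
    # overlap matrix [[2,1,0],[2,0,1],[0,2,1]]; optimal total is 5
    A = [
        _cluster("a1", [("a", 0.9), ("b", 0.8), ("c", 0.7)]),
        _cluster("a2", [("a", 0.9), ("b", 0.8), ("d", 0.7)]),
        _cluster("a3", [("e", 0.9), ("f", 0.8), ("g", 0.7)]),
    ]
    B = [
        _cluster("b1", [("a", 0.9), ("b", 0.8)]),
        _cluster("b2", [("c", 0.9), ("e", 0.8), ("f", 0.7)]),
        _cluster("b3", [("d", 0.9), ("g", 0.8)]),
    ]
    overlap = np.array([[2, 1, 0], [2, 0, 1], [0, 2, 1]], dtype=float)
    rows, cols = _brute_force_assignment(overlap)
    assert sum(overlap[i, j] for i, j in zip(rows, cols)) == 5
    pairs = match_clusters(_clusterset("ga", A), _clusterset("gb", B))
    total = sum(p.overlap for p in pairs)
    assert total == 5


def test_unequal_set_sizes_leave_unmatched_clusters():
    A = [_cluster("a1", [("a", 0.9), ("b", 0.8)])]
    B = [
        _cluster("b1", [("a", 0.9), ("b", 0.8)]),
        _cluster("b2", [("x", 0.9), ("y", 0.8)]),
    ]
    pairs = match_clusters(_clusterset("ga", A), _clusterset("gb", B))
    assert len(pairs) == 2
    halves = [p for p in pairs if not p.both_present]
    assert len(halves) == 1
    assert halves[0].cluster_b.cluster_id == "b2"
    assert not is_stable(halves[0])


def test_reference_sets_match_row_for_row(reference_cluster_sets):
    pairs = match_clusters(
        reference_cluster_sets["younger"], reference_cluster_sets["older"]
    )
    assert len(pairs) == 8
    for p in pairs:
        assert p.cluster_a.cluster_id == p.cluster_b.cluster_id


# -- stability ----------------------------------------------------------

def test_disjoint_pair_is_not_stable():
    p = MatchedClusterPair(
        _cluster("a", [("x", 0.9), ("y", 0.8)]),
        _cluster("b", [("u", 0.9), ("v", 0.8)]),
        [],
    )
    assert not is_stable(p)


def test_two_shared_symptoms_suffice():
    a = _cluster("a", [("hot_flashes", 0.807), ("sweats", 0.788)])
    b = _cluster("b", [("hot_flashes", 0.728), ("sweats", 0.783)])
    p = MatchedClusterPair(a, b, ["hot_flashes", "sweats"])
    assert is_stable(p)


# -- consistency --------------------------------------------------------

@pytest.mark.parametrize(
    "sizes,expected",
    [((2, 2), 2), ((3, 3), 2), ((2, 3), 2), ((4, 3), 3), ((3, 5), 3), ((6, 5), 3)],
)
def test_consistency_top_set_size(sizes, expected):
    assert consistency_k(*sizes) == expected


def test_consistency_k_requires_defined_clusters():
    with pytest.raises(ValueError):
        consistency_k(1, 4)


def test_identical_ordering_is_fully_consistent():
    a = _cluster("a", [("x", 0.9), ("y", 0.8), ("z", 0.7), ("w", 0.5)])
    b = _cluster("b", [("x", 0.85), ("y", 0.7), ("z", 0.6), ("w", 0.45)])
    v = assess_consistency(MatchedClusterPair(a, b, ["x", "y", "z", "w"]))
    assert v.k == 3 and v.shared_top == 3 and v.consistent


def test_consistency_is_symmetric_under_group_swap(reference_cluster_sets):
    pairs = match_clusters(
        reference_cluster_sets["younger"], reference_cluster_sets["older"]
    )
    for p in pairs:
        v_ab = assess_consistency(p)
        v_ba = assess_consistency(
            MatchedClusterPair(p.cluster_b, p.cluster_a, p.shared)
        )
        assert (v_ab.k, v_ab.shared_top, v_ab.consistent) == (
            v_ba.k, v_ba.shared_top, v_ba.consistent
        )


def test_shared_top_bounded_by_k_and_sizes(reference_cluster_sets):
    pairs = match_clusters(
        reference_cluster_sets["younger"], reference_cluster_sets["older"]
    )
    for p in pairs:
        v = assess_consistency(p)
        assert 0 <= v.shared_top <= min(v.k, p.cluster_a.size, p.cluster_b.size)
        if v.consistent:
            assert is_stable(p)  # consistent implies stable (min_shared <= k)


def test_tie_at_kth_loading_expands_top_set():
    a = _cluster("a", [("x", 0.9), ("y", 0.5), ("z", 0.5)])
    b = _cluster("b", [("x", 0.8), ("z", 0.7), ("q", 0.5)])
    v = assess_consistency(MatchedClusterPair(a, b, ["x", "z"]))
    # tie at the 2nd loading of a pulls z into its top-2 set
    assert v.tie_affected
    assert set(v.top_a) == {"x", "y", "z"}
    assert v.consistent


# -- full report --------------------------------------------------------

def test_reference_comparison_reproduces_published_verdicts(reference_cluster_sets):
    report = compare_cluster_sets(
        reference_cluster_sets["younger"], reference_cluster_sets["older"]
    )
    verdicts = {
        p.cluster_a.cluster_id: str(v)
        for p, v in zip(report.pairs, report.verdicts)
    }
    assert verdicts == {
        "fatigue": "2/3",
        "respiratory": "3/3",
        "psychological": "3/3",
        "hormonal": "2/2",
        "chemo_toxicity": "1/2",
        "weight_gain": "2/2",
        "gastrointestinal": "0/2",
        "epithelial": "3/3",
    }
    assert report.n_stable == 8
    assert report.n_consistent == 5
    assert report.n_inconsistent == 3


def test_identical_sets_all_stable_and_consistent(reference_cluster_sets):
    cs = reference_cluster_sets["older"]
    report = compare_cluster_sets(cs, cs)
    assert report.n_stable == len(cs.clusters)
    assert report.n_consistent == len(cs.clusters)
    assert report.n_inconsistent == 0


def test_report_serialization_and_text(reference_cluster_sets):
    report = compare_cluster_sets(
        reference_cluster_sets["younger"], reference_cluster_sets["older"]
    )
    d = report.to_dict()
    assert d["summary"]["n_stable"] == 8
    assert len(d["pairs"]) == 8
    text = report.render_text()
    assert "not consistent: 3" in text
    assert "Gastrointestinal" in text or "gastrointestinal" in text
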