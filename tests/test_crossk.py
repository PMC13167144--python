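"""Cross-K anchored alignment, global labels, and pattern edges."""

import math

import numpy as np
import pytest

from admixalign import (
    MembershipMatrix,
    SyntheticSpec,
    align_all_modes,
    brute_force_align,
    build_pattern_edges,
    detect_and_summarize,
    make_split_hierarchy,
    select_anchor_pair,
)
from admixalign.crossk import CrossKError, graph_from_json, graph_to_json, pattern_text
from admixalign.modes import Mode


def _mode(mode_id, values, size=1, within=1.0):
    rep = MembershipMatrix.from_array(values, run_id=mode_id)
    return Mode(
        mode_id=mode_id,
        k=rep.n_clusters,
        member_runs=[f"{mode_id}_r{i}" for i in range(size)],
        representative=rep,
        within_similarity=within,
    )


@pytest.fixture(scope="module")
def zero_noise_hierarchy():
    spec = SyntheticSpec(k=2, noise_scale=math.inf, seed=11)
    h = make_split_hierarchy(2, 6, spec, n_runs_per_k=5)
    modes_by_k = {k: detect_and_summarize(runs) for k, runs in h.runs_by_k.items()}
    return h, modes_by_k, align_all_modes(modes_by_k, criterion="major")


def _base_column_labels(g, h):
    """Global label of every planted base column at each present K level.

    Representatives are in the medoid's (permuted) column order, so the
    planted base must be aligned onto each level's representative to read
    off which global label each base column carries.
    """
    from admixalign import align_same_k

    out = {}
    for k, base in h.bases.items():
        level = g.modes_at(k)
        if not level:
            continue
        mode = level[0]
        res = align_same_k(mode.representative, base)
        assert res.cost == pytest.approx(0.0, abs=1e-9)
        labels = g.cluster_labels[mode.mode_id]
        out[k] = [labels[res.matching.assignment[c]] for c in range(k)]
    return out


class TestSelectAnchorPair:
    def test_single_modes_selected_under_either_criterion(self, random_q):
        m1, m2 = [_mode("K2M1", random_q(6, 2).values)], [_mode("K3M1", random_q(6, 3).values)]
        for criterion in ("best", "major"):
            a, b, res = select_anchor_pair(m1, m2, criterion)
            assert (a.mode_id, b.mode_id) == ("K2M1", "K3M1")
            assert 0.0 <= res.cost <= 1.0

    def test_major_takes_first_listed_mode_after_size_ties(self, random_q):
        # mode ordering already encodes size desc, then within-similarity:
        # two size-18 modes — the higher-similarity one was numbered M1
        m5 = [
            _mode("K5M1", random_q(6, 3).values, size=18, within=0.82),
            _mode("K5M2", random_q(6, 3).values, size=18, within=0.80),
            _mode("K5M3", random_q(6, 3).values, size=14, within=0.85),
        ]
        m6 = [_mode("K6M1", random_q(6, 4).values, size=10)]
        a, b, _ = select_anchor_pair(m5, m6, "major")
        assert a.mode_id == "K5M1"

    def test_best_picks_maximal_similarity_pair(self):
        base = np.array([[0.9, 0.1], [0.1, 0.9], [0.5, 0.5]])
        # X splits A's first column cleanly → similarity 1 with A
        x = np.column_stack([base[:, 0] * 0.6, base[:, 1], base[:, 0] * 0.4])
        a = _mode("K2M1", base)
        b = _mode("K2M2", base[:, ::-1] * 0.2 + 0.4)  # blurred, poorer match
        y = np.column_stack([np.full(3, 0.3), np.full(3, 0.4), np.full(3, 0.3)])
        best = select_anchor_pair([a, b], [_mode("K3M1", y), _mode("K3M2", x)], "best")
        assert (best[0].mode_id, best[1].mode_id) == ("K2M1", "K3M2")
        assert best[2].cost == pytest.approx(0.0, abs=1e-12)

    def test_empty_level_rejected(self, random_q):
        with pytest.raises(CrossKError):
            select_anchor_pair([], [_mode("K3M1", random_q(4, 3).values)], "major")


class TestAlignAllModes:
    def test_zero_noise_hierarchy_aligns_with_zero_cost(self, zero_noise_hierarchy):
        _, _, g = zero_noise_hierarchy
        for _, _, res in g.anchor_pairs.values():
            assert res.cost == pytest.approx(0.0, abs=1e-9)

    def test_exactly_one_new_label_per_k_step(self, zero_noise_hierarchy):
        _, _, g = zero_noise_hierarchy
        seen = {k: set() for k in g.k_values}
        for m in g.modes.values():
            seen[m.k].update(g.cluster_labels[m.mode_id])
        for k in g.k_values:
            assert seen[k] == set(range(1, k + 1))

    def test_every_mode_uses_k_distinct_labels(self, zero_noise_hierarchy):
        _, _, g = zero_noise_hierarchy
        for m in g.modes.values():
            labels = g.cluster_labels[m.mode_id]
            assert len(set(labels)) == m.k

    def test_gap_in_k_aligned_directly_with_two_new_labels(self):
        spec = SyntheticSpec(k=2, noise_scale=math.inf, seed=12)
        h = make_split_hierarchy(2, 4, spec, k_values=(2, 4), n_runs_per_k=4)
        modes_by_k = {k: detect_and_summarize(runs) for k, runs in h.runs_by_k.items()}
        g = align_all_modes(modes_by_k)
        assert list(g.anchor_pairs) == [(2, 4)]
        new_labels = set(g.cluster_labels["K4M1"]) - set(g.cluster_labels["K2M1"])
        assert new_labels == {3, 4}

    def test_single_k_level_graph_has_no_edges(self, random_q):
        modes_by_k = {3: [_mode("K3M1", random_q(6, 3).values)]}
        g = align_all_modes(modes_by_k)
        assert g.edges == {} and g.cluster_labels["K3M1"] == (1, 2, 3)

    def test_no_modes_rejected(self):
        with pytest.raises(CrossKError):
            align_all_modes({})

    def test_composed_matching_equals_direct_for_clean_permutations(self, rng):
        """A non-anchor mode that is a pure relabeling of the anchor must get
        the same cross-K matching as aligning it directly."""
        base = rng.dirichlet(np.ones(3), size=12)
        split = np.column_stack([base[:, 0] * 0.6, base[:, 1], base[:, 2], base[:, 0] * 0.4])
        anchor3 = _mode("K3M1", base, size=3)
        other3 = _mode("K3M2", base[:, [2, 0, 1]], size=1)  # relabeled copy
        anchor4 = _mode("K4M1", split, size=2)
        g = align_all_modes({3: [anchor3, other3], 4: [anchor4]}, criterion="major")
        composed = g.edges[("K3M2", "K4M1")]
        direct = brute_force_align(other3.representative, anchor4.representative)
        assert composed.cost == pytest.approx(direct.cost, abs=1e-9)
        assert composed.matching.assignment == direct.matching.assignment

    def test_labeling_deterministic_across_runs(self, zero_noise_hierarchy):
        h, modes_by_k, g = zero_noise_hierarchy
        g2 = align_all_modes(modes_by_k, criterion="major")
        assert g2.cluster_labels == g.cluster_labels


class TestPatternEdges:
    def test_new_cluster_edges_match_planted_splits(self, zero_noise_hierarchy):
        h, _, g = zero_noise_hierarchy
        expected = _base_column_labels(g, h)
        new_edges = [e for e in build_pattern_edges(g) if e.is_new_cluster_edge]
        assert len(new_edges) == len(h.splits)
        for e in new_edges:
            k2 = int(e.child_mode[1])
            assert e.child_label == k2  # one new label per step, in K order
            assert e.parent_label == expected[k2 - 1][h.splits[k2]]
            # the appended (smaller-fraction) child carries the new label
            assert expected[k2][-1] == k2

    def test_every_cross_k_matching_contributes_k_large_edges(self, zero_noise_hierarchy):
        _, _, g = zero_noise_hierarchy
        edges = build_pattern_edges(g)
        per_pair = {}
        for e in edges:
            per_pair.setdefault((e.parent_mode, e.child_mode), 0)
            per_pair[(e.parent_mode, e.child_mode)] += 1
        for (m1, m2), count in per_pair.items():
            assert count == g.modes[m2].k

    def test_non_anchor_split_pair_yields_two_edges_from_one_parent(self, rng):
        base = rng.dirichlet(np.ones(2), size=10)
        split = np.column_stack([base[:, 0] * 0.6, base[:, 1], base[:, 0] * 0.4])
        modes_by_k = {
            2: [_mode("K2M1", base, size=3)],
            3: [
                _mode("K3M1", split, size=3),
                _mode("K3M2", split[:, [2, 1, 0]], size=1),
            ],
        }
        g = align_all_modes(modes_by_k, criterion="major")
        edges = [
            e
            for e in build_pattern_edges(g)
            if (e.parent_mode, e.child_mode) == ("K2M1", "K3M2")
        ]
        assert not any(e.is_anchor for e in edges)
        parents = [e.parent_label for e in edges]
        assert sorted(parents) == [1, 1, 2]  # two children of cluster 1

    def test_pattern_text_lists_parent_labels_per_child(self, zero_noise_hierarchy):
        _, _, g = zero_noise_hierarchy
        text = pattern_text(g)
        lines = [ln for ln in text.splitlines() if ln]
        assert len(lines) == len(g.edges)
        first = lines[0]
        assert first.startswith("K2M1-K3M1: ") and first.endswith("(anchor)")
        labels = first.split(": ")[1].split(" ")[0].split(",")
        assert len(labels) == 3  # one parent label per K=3 child cluster


class TestGraphSerialization:
    def test_json_round_trip_preserves_structure(self, zero_noise_hierarchy):
        _, _, g = zero_noise_hierarchy
        g2 = graph_from_json(graph_to_json(g), g.modes)
        assert g2.cluster_labels == g.cluster_labels
        assert g2.k_values == g.k_values
        assert set(g2.edges) == set(g.edges)
        for key, res in g.edges.items():
            assert g2.edges[key].matching.assignment == res.matching.assignment
            assert g2.edges[key].cost == pytest.approx(res.cost, abs=1e-12)
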