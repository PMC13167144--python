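"""Similarity networks, community-detection modes, and consensus matrices."""

import math

import numpy as np
import pytest

from admixalign import (
    MembershipMatrix,
    SyntheticSpec,
    build_network,
    detect_and_summarize,
    detect_modes,
    make_base_matrix,
    make_multimodal_collection,
    make_replicates,
    mode_representative,
    within_mode_similarity,
)
from admixalign.modes import ModeDetectionError, network_from_similarities


def _identical_runs(n_runs=3, seed=1):
    base = make_base_matrix(SyntheticSpec(seed=seed, noise_scale=math.inf))
    runs, _ = make_replicates(base, n_runs, noise_scale=math.inf, seed=seed)
    return runs


@pytest.fixture(scope="module")
def dissimilar_network():
    """10 runs planted as 10 mutually distinct solutions (all sims < 0.5)."""
    spec = SyntheticSpec(
        n_individuals=120,
        group_sizes=(5,) * 24,
        k=8,
        n_runs=10,
        n_modes=10,
        seed=7,
        noise_scale=500.0,
        profile_dominant=0.98,
        max_cross_similarity=0.45,
    )
    coll, _ = make_multimodal_collection(spec)
    return build_network(coll.runs)


class TestBuildNetwork:
    def test_identical_runs_give_unit_weights(self):
        net = build_network(_identical_runs(3))
        assert np.allclose(net.weights, 1.0)

    def test_single_run_network(self):
        net = build_network(_identical_runs(1))
        assert net.weights.shape == (1, 1) and net.weights[0, 0] == 1.0

    def test_mixed_k_rejected(self, random_q):
        with pytest.raises(ModeDetectionError, match="mix"):
            build_network([random_q(4, 2), random_q(4, 3)])

    def test_planted_blocks_appear_in_weights(self):
        spec = SyntheticSpec(n_runs=10, n_modes=2, seed=3, mode_assignment=(0,) * 6 + (1,) * 4)
        coll, planted = make_multimodal_collection(spec)
        net = build_network(coll.runs)
        modes = np.array([planted[r] for r in net.run_ids])
        same = modes[:, None] == modes[None, :]
        off = ~np.eye(len(modes), dtype=bool)
        assert net.weights[same & off].min() > 0.95
        assert net.weights[~same].max() < 0.65

    def test_weights_symmetric_unit_diagonal(self, random_q):
        net = build_network([random_q(5, 3, run_id=f"r{i}") for i in range(4)])
        np.testing.assert_array_equal(net.weights, net.weights.T)
        np.testing.assert_array_equal(np.diag(net.weights), np.ones(4))


class TestDetectModes:
    def test_single_mode_when_all_runs_agree(self):
        net = build_network(_identical_runs(10))
        assert [len(p) for p in detect_modes(net)] == [10]

    def test_r_singletons_when_all_runs_differ(self, dissimilar_network):
        partition = detect_modes(dissimilar_network)
        assert [len(p) for p in partition] == [1] * 10

    def test_mcl_agrees_on_both_extremes(self, dissimilar_network):
        assert [len(p) for p in detect_modes(dissimilar_network, method="mcl")] == [1] * 10
        net = build_network(_identical_runs(6))
        assert [len(p) for p in detect_modes(net, method="mcl")] == [6]

    def test_planted_two_block_partition_recovered(self):
        spec = SyntheticSpec(n_runs=10, n_modes=2, seed=3, mode_assignment=(0,) * 6 + (1,) * 4)
        coll, planted = make_multimodal_collection(spec)
        partition = detect_modes(build_network(coll.runs), seed=42)
        assert sorted(len(p) for p in partition) == [4, 6]
        for members in partition:
            assert len({planted[r] for r in members}) == 1

    def test_force_single_tol_bypasses_community_detection(self):
        net = build_network(_identical_runs(5))
        assert [len(p) for p in detect_modes(net, force_single_tol=1e-6)] == [5]

    def test_force_single_tol_inactive_when_dissimilar(self, dissimilar_network):
        partition = detect_modes(dissimilar_network, force_single_tol=1e-6)
        assert len(partition) == 10

    def test_unknown_method_rejected(self):
        net = build_network(_identical_runs(2))
        with pytest.raises(ModeDetectionError, match="unknown"):
            detect_modes(net, method="spectral")

    def test_partition_is_exact(self, dissimilar_network):
        partition = detect_modes(dissimilar_network)
        flat = [r for p in partition for r in p]
        assert sorted(flat) == sorted(dissimilar_network.run_ids)
        assert len(flat) == len(set(flat))

    def test_detection_is_reproducible(self):
        spec = SyntheticSpec(n_runs=10, n_modes=2, seed=5, mode_assignment=(0,) * 5 + (1,) * 5)
        coll, _ = make_multimodal_collection(spec)
        net = build_network(coll.runs)
        assert detect_modes(net, seed=42) == detect_modes(net, seed=42)

    def test_modes_ordered_by_size_then_similarity_then_run_id(self):
        run_ids = ["r1", "r2", "r3", "r4"]
        sims = {
            ("r1", "r2"): 0.99,  # tight pair
            ("r3", "r4"): 0.95,  # looser pair
            ("r1", "r3"): 0.0,
            ("r1", "r4"): 0.0,
            ("r2", "r3"): 0.0,
            ("r2", "r4"): 0.0,
        }
        net = network_from_similarities(run_ids, sims)
        partition = detect_modes(net)
        assert partition == [["r1", "r2"], ["r3", "r4"]]


class TestModeSummaries:
    def test_within_similarity_mean_of_pairs(self):
        net = network_from_similarities(
            ["a", "b", "c"],
            {("a", "b"): 0.9, ("a", "c"): 0.8, ("b", "c"): 0.7},
        )
        assert within_mode_similarity(["a", "b", "c"], net) == pytest.approx(0.8)

    def test_singleton_similarity_is_one(self):
        net = network_from_similarities(["a", "b"], {("a", "b"): 0.2})
        assert within_mode_similarity(["a"], net) == 1.0

    def test_identical_members_similarity_is_one(self):
        net = build_network(_identical_runs(3))
        assert within_mode_similarity(net.run_ids, net) == pytest.approx(1.0)

    def test_representative_of_single_member_is_itself(self, random_q):
        m = random_q(5, 3)
        np.testing.assert_allclose(mode_representative([m]).values, m.values)

    def test_representative_is_entrywise_mean(self):
        a = MembershipMatrix.from_array([[0.6, 0.4], [0.2, 0.8]])
        b = MembershipMatrix.from_array([[0.8, 0.2], [0.4, 0.6]])
        np.testing.assert_allclose(
            mode_representative([a, b]).values, [[0.7, 0.3], [0.3, 0.7]]
        )

    def test_representative_of_empty_list_rejected(self):
        with pytest.raises(ModeDetectionError):
            mode_representative([])

    def test_summaries_have_normalized_representatives_and_mode_ids(self):
        spec = SyntheticSpec(n_runs=8, n_modes=2, seed=9, mode_assignment=(0,) * 5 + (1,) * 3)
        coll, _ = make_multimodal_collection(spec)
        modes = detect_and_summarize(coll.runs)
        assert [m.mode_id for m in modes] == ["K3M1", "K3M2"]
        assert [m.size for m in modes] == [5, 3]
        for mode in modes:
            sums = mode.representative.values.sum(axis=1)
            np.testing.assert_allclose(sums, 1.0, atol=1e-6)
            assert 0.0 <= mode.within_similarity <= 1.0
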