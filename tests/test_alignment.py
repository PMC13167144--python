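"""Optimal cluster matching: cost functional, solvers, and oracles."""

import time

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from admixalign import (
    AlignmentError,
    ClusterMatching,
    MembershipMatrix,
    align_cross_k,
    align_same_k,
    alignment_cost,
    brute_force_align,
    permute_to_match,
)


def _q(values, run_id=""):
    return MembershipMatrix.from_array(values, run_id=run_id)


class TestAlignmentCost:
    def test_identity_on_identical_runs_costs_zero(self, random_q):
        q = random_q(6, 3)
        m = ClusterMatching(source_k=3, target_k=3, assignment=(0, 1, 2))
        assert alignment_cost(q, q, m) == 0.0

    def test_maximally_distant_rows_cost_one(self):
        qa, qb = _q([[1.0, 0.0]]), _q([[0.0, 1.0]])
        m = ClusterMatching(source_k=2, target_k=2, assignment=(0, 1))
        res = alignment_cost(qa, qb, m)
        assert res == pytest.approx(1.0)

    def test_hand_computed_example(self):
        qa = _q([[0.6, 0.4], [0.1, 0.9]])
        qb = _q([[0.5, 0.5], [0.3, 0.7]])
        m = ClusterMatching(source_k=2, target_k=2, assignment=(0, 1))
        # (0.01 + 0.01 + 0.04 + 0.04) / (2 * 2) = 0.025
        assert alignment_cost(qa, qb, m) == pytest.approx(0.025)

    def test_non_surjective_matching_rejected(self):
        with pytest.raises(AlignmentError, match="surjective"):
            ClusterMatching(source_k=2, target_k=2, assignment=(0, 0))

    def test_n_mismatch_rejected(self, random_q):
        m = ClusterMatching(source_k=2, target_k=2, assignment=(0, 1))
        with pytest.raises(AlignmentError, match="different N"):
            alignment_cost(random_q(3, 2), random_q(4, 2), m)


class TestAlignSameK:
    def test_recovers_column_swap_with_cost_zero(self, random_q):
        q = random_q(8, 4)
        perm = [2, 0, 3, 1]
        qp = _q(q.values[:, perm])
        res = align_same_k(q, qp)
        assert res.cost == 0.0 and res.similarity == 1.0
        assert res.matching.assignment == tuple(perm)
        np.testing.assert_allclose(permute_to_match(qp, res.matching).values, q.values)

    def test_k_equals_one_is_trivial(self):
        qa, qb = _q([[1.0], [1.0]]), _q([[1.0], [1.0]])
        res = align_same_k(qa, qb)
        assert res.cost == 0.0 and res.matching.assignment == (0,)

    def test_k_mismatch_directs_to_cross_k(self, random_q):
        with pytest.raises(AlignmentError, match="align_cross_k"):
            align_same_k(random_q(4, 2), random_q(4, 3))

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n, k = int(rng.integers(2, 15)), int(rng.integers(2, 7))
        qa = _q(rng.dirichlet(np.ones(k), size=n))
        qb = _q(rng.dirichlet(np.ones(k), size=n))
        fast, oracle = align_same_k(qa, qb), brute_force_align(qa, qb)
        assert fast.cost == pytest.approx(oracle.cost, abs=1e-9)
        assert fast.matching.assignment == oracle.matching.assignment

    def test_optimal_cost_is_symmetric(self, random_q):
        qa, qb = random_q(10, 4), random_q(10, 4)
        assert align_same_k(qa, qb).cost == pytest.approx(
            align_same_k(qb, qa).cost, abs=1e-9
        )

    def test_cost_invariant_under_input_permutation(self, random_q, rng):
        qa, qb = random_q(10, 4), random_q(10, 4)
        base = align_same_k(qa, qb).cost
        perm = list(rng.permutation(4))
        assert align_same_k(qa, _q(qb.values[:, perm])).cost == pytest.approx(
            base, abs=1e-12
        )
        assert align_same_k(_q(qa.values[:, perm]), qb).cost == pytest.approx(
            base, abs=1e-12
        )

    def test_ties_break_lexicographically(self):
        # two identical uniform columns: every bijection is cost-equal
        qa = _q([[0.5, 0.5], [0.5, 0.5]])
        qb = _q([[0.5, 0.5], [0.5, 0.5]])
        assert align_same_k(qa, qb).matching.assignment == (0, 1)

    def test_k40_alignment_takes_seconds(self, random_q):
        qa, qb = random_q(100, 40), random_q(100, 40)
        t0 = time.perf_counter()
        res = align_same_k(qa, qb)
        assert time.perf_counter() - t0 < 30
        assert 0.0 <= res.cost <= 1.0


class TestAlignCrossK:
    def test_clean_split_costs_zero_and_maps_children_to_parent(self, random_q):
        q = random_q(8, 3)
        v = q.values
        split = np.column_stack([v[:, 0] * 0.6, v[:, 1], v[:, 2], v[:, 0] * 0.4])
        res = align_cross_k(q, _q(split))
        assert res.cost == pytest.approx(0.0, abs=1e-12)
        assert res.matching.assignment == (0, 1, 2, 0)

    def test_wrong_k_order_rejected(self, random_q):
        with pytest.raises(AlignmentError, match="K_small < K_large"):
            align_cross_k(random_q(4, 3), random_q(4, 3))
        with pytest.raises(AlignmentError, match="K_small < K_large"):
            align_cross_k(random_q(4, 4), random_q(4, 3))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_over_surjections(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(2, 15))
        ks = int(rng.integers(1, 5))
        kl = int(rng.integers(ks + 1, 7))
        qs = _q(rng.dirichlet(np.ones(ks), size=n))
        ql = _q(rng.dirichlet(np.ones(kl), size=n))
        fast, oracle = align_cross_k(qs, ql), brute_force_align(qs, ql)
        assert fast.cost == pytest.approx(oracle.cost, abs=1e-9)
        assert fast.matching.assignment == oracle.matching.assignment

    def test_all_zero_source_column_handled_optimally(self, random_q, rng):
        qs = random_q(6, 2)
        ql_vals = rng.dirichlet(np.ones(3), size=6)
        ql_vals = np.column_stack([ql_vals, np.zeros(6)])  # K=4 with a dead cluster
        ql = MembershipMatrix(values=ql_vals / ql_vals.sum(axis=1, keepdims=True))
        fast, oracle = align_cross_k(qs, ql), brute_force_align(qs, ql)
        assert fast.cost == pytest.approx(oracle.cost, abs=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_ilp_solver_agrees_with_dp(self, seed):
        rng = np.random.default_rng(200 + seed)
        qs = _q(rng.dirichlet(np.ones(3), size=10))
        ql = _q(rng.dirichlet(np.ones(5), size=10))
        dp = align_cross_k(qs, ql, method="dp")
        ilp = align_cross_k(qs, ql, method="ilp")
        assert ilp.cost == pytest.approx(dp.cost, abs=1e-8)
        assert ilp.matching.assignment == dp.matching.assignment


class TestBruteForce:
    def test_identical_matrices_identity(self, random_q):
        q = random_q(5, 2)
        res = brute_force_align(q, q)
        assert res.matching.assignment == (0, 1) and res.cost == 0.0

    def test_argument_order_does_not_matter(self, random_q):
        qs, ql = random_q(5, 2), random_q(5, 4)
        assert brute_force_align(qs, ql).cost == brute_force_align(ql, qs).cost

    def test_refuses_large_k(self, random_q):
        with pytest.raises(AlignmentError, match="brute force"):
            brute_force_align(random_q(3, 8), random_q(3, 8))


@settings(deadline=None, derandomize=True, max_examples=25)
@given(
    seed=st.integers(0, 10**6),
    n=st.integers(1, 12),
    k=st.integers(1, 5),
)
def test_cost_always_in_unit_interval_and_complement_of_similarity(seed, n, k):
    """Row-stochasticity bounds the cost to [0, 1] for any pair of runs."""
    rng = np.random.default_rng(seed)
    qa = _q(rng.dirichlet(np.ones(k) * 0.5, size=n))
    qb = _q(rng.dirichlet(np.ones(k) * 2.0, size=n))
    res = align_same_k(qa, qb)
    assert 0.0 <= res.cost <= 1.0
    assert res.similarity == pytest.approx(1.0 - res.cost)
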