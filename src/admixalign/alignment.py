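"""Optimal cluster matching between two membership matrices.

The label-switching problem: two runs of a mixed-membership clustering
program may describe the same solution under different cluster labels, and
runs with different numbers of clusters K relate by clusters splitting or
merging. Both cases reduce to finding the matching of clusters that
minimizes a discrepancy between the two matrices.

Cost functional
---------------
For a target matrix Q_t (the run with smaller or equal K) and a source
matrix Q_s, a matching assigns every source cluster to exactly one target
cluster, covering every target cluster. Source columns assigned to the same
target cluster are *summed* (membership mass is conserved, so a clean
column split aligns with cost exactly 0), giving the merged matrix
``merge(Q_s)`` of the target's shape. The alignment cost is

    cost = || Q_t − merge(Q_s) ||²_F / (2N),      similarity = 1 − cost.

Because both matrices are row-stochastic, every row contributes at most 2
to the squared norm, so cost ∈ [0, 1]; cost 0 holds exactly when the runs
are identical up to the matching.

Solvers
-------
* equal K — the cost separates over column pairs, so the optimum is a
  linear assignment over the K×K matrix of column squared distances
  (Jonker–Volgenant via :func:`scipy.optimize.linear_sum_assignment`).
* unequal K — an integer linear program over binary assignment variables
  x_{cd} with Σ_d x_{cd} = 1 per source cluster and Σ_c x_{cd} ≥ 1 per
  target cluster. The quadratic merge interaction <q_c, q_c'> x_{cd} x_{c'd}
  is linearized with standard product variables; solved with HiGHS through
  :func:`scipy.optimize.milp`.
* :func:`brute_force_align` — exhaustive enumeration, the test oracle.

Cost-equal matchings are canonicalized to the lexicographically smallest
assignment vector, making results deterministic across platforms.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linear_sum_assignment, milp

from .io import MembershipMatrix

#: two matchings whose costs differ by at most this are considered tied
COST_TIE_TOL = 1e-9

#: maximum relative MIP gap accepted from the ILP solver
ILP_REL_GAP = 1e-9

#: binary ILP variables must be within this of {0, 1}
ILP_BINARY_TOL = 1e-6

#: brute-force enumeration refuses above this K
BRUTE_FORCE_MAX_K = 7


class AlignmentError(ValueError):
    """Invalid alignment request (shape mismatch, bad matching, ...)."""


@dataclass(frozen=True)
class ClusterMatching:
    """A surjective map from source clusters onto target clusters.

    ``assignment[c]`` is the target cluster that source cluster ``c`` maps
    to. When ``source_k == target_k`` surjectivity forces a bijection.
    """

    source_k: int
    target_k: int
    assignment: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.source_k < self.target_k:
            raise AlignmentError("source K must be ≥ target K")
        if len(self.assignment) != self.source_k:
            raise AlignmentError(
                f"assignment has length {len(self.assignment)}, expected {self.source_k}"
            )
        targets = set(self.assignment)
        if not all(0 <= d < self.target_k for d in targets):
            raise AlignmentError("assignment contains out-of-range target clusters")
        if targets != set(range(self.target_k)):
            raise AlignmentError(
                f"matching is not surjective: targets {sorted(targets)} "
                f"do not cover 0..{self.target_k - 1}"
            )

    @property
    def is_bijection(self) -> bool:
        return self.source_k == self.target_k

    def inverse_permutation(self) -> tuple[int, ...]:
        """For a bijection, the permutation sending targets back to sources."""
        if not self.is_bijection:
            raise AlignmentError("only bijective matchings can be inverted")
        inv = [0] * self.source_k
        for c, d in enumerate(self.assignment):
            inv[d] = c
        return tuple(inv)


@dataclass(frozen=True)
class AlignmentResult:
    """An optimal (or evaluated) matching together with its cost/similarity."""

    matching: ClusterMatching
    cost: float

    @property
    def similarity(self) -> float:
        return 1.0 - self.cost


def merge_columns(values: np.ndarray, matching: ClusterMatching) -> np.ndarray:
    """Sum source columns by their assigned target cluster → N×K_target."""
    merged = np.zeros((values.shape[0], matching.target_k))
    for c, d in enumerate(matching.assignment):
        merged[:, d] += values[:, c]
    return merged


def alignment_cost(
    qa: MembershipMatrix, qb: MembershipMatrix, matching: ClusterMatching
) -> float:
    """Cost of a given matching of ``qb``'s clusters (source) onto ``qa``'s.

    ``qa`` is the target (smaller-or-equal K). Returns a value in [0, 1].
    """
    if qa.n_individuals != qb.n_individuals:
        raise AlignmentError(
            f"runs have different N: {qa.n_individuals} vs {qb.n_individuals}"
        )
    if matching.source_k != qb.n_clusters or matching.target_k != qa.n_clusters:
        raise AlignmentError("matching shape does not fit the two runs")
    diff = qa.values - merge_columns(qb.values, matching)
    cost = float(np.sum(diff * diff)) / (2.0 * qa.n_individuals)
    # snap float-granularity residue (e.g. from row renormalization) to the
    # exact identity the cost functional promises
    return 0.0 if cost < 1e-15 else cost


def permute_to_match(qb: MembershipMatrix, matching: ClusterMatching) -> MembershipMatrix:
    """Return ``qb`` with columns reordered into the target's labeling.

    Only defined for bijective matchings: output column ``d`` is the source
    column assigned to target ``d``.
    """
    inv = matching.inverse_permutation()
    return MembershipMatrix(
        values=qb.values[:, list(inv)], run_id=qb.run_id, model_id=qb.model_id
    )


def _pair_cost_matrix(qa: np.ndarray, qb: np.ndarray) -> np.ndarray:
    """D[c, d] = squared distance between source column c and target column d."""
    # ||b_c - a_d||^2 = ||b_c||^2 + ||a_d||^2 - 2 <b_c, a_d>
    bb = np.sum(qb * qb, axis=0)
    aa = np.sum(qa * qa, axis=0)
    return bb[:, None] + aa[None, :] - 2.0 * (qb.T @ qa)


def _lap_cost(D: np.ndarray) -> tuple[float, np.ndarray]:
    rows, cols = linear_sum_assignment(D)
    assignment = np.empty(D.shape[0], dtype=int)
    assignment[rows] = cols
    return float(D[rows, cols].sum()), assignment


def _lap_with_fixed(D: np.ndarray, fixed: dict[int, int]) -> float:
    """Optimal LAP objective with some source→target pairs pinned."""
    K = D.shape[0]
    free_rows = [c for c in range(K) if c not in fixed]
    used = set(fixed.values())
    free_cols = [d for d in range(K) if d not in used]
    base = sum(D[c, d] for c, d in fixed.items())
    if not free_rows:
        return base
    sub = D[np.ix_(free_rows, free_cols)]
    rows, cols = linear_sum_assignment(sub)
    return base + float(sub[rows, cols].sum())


def _lex_refine_lap(D: np.ndarray, optimum: float) -> tuple[int, ...]:
    """Lexicographically smallest bijection achieving the optimal LAP cost."""
    K = D.shape[0]
    fixed: dict[int, int] = {}
    for c in range(K):
        used = set(fixed.values())
        for d in range(K):
            if d in used:
                continue
            trial = dict(fixed)
            trial[c] = d
            if _lap_with_fixed(D, trial) <= optimum + COST_TIE_TOL:
                fixed[c] = d
                break
        else:  # pragma: no cover - unreachable if optimum is correct
            raise AlignmentError("tie refinement failed to reproduce the optimum")
    return tuple(fixed[c] for c in range(K))


def align_same_k(qa: MembershipMatrix, qb: MembershipMatrix) -> AlignmentResult:
    """Optimal one-to-one cluster matching between two equal-K runs.

    Returns the bijection of ``qb``'s clusters (source) onto ``qa``'s
    clusters (target) minimizing the alignment cost. Equivalent to the ILP
    formulation but solved as a linear assignment, since at equal K the
    objective separates over column pairs.
    """
    if qa.n_clusters != qb.n_clusters:
        raise AlignmentError(
            f"K mismatch ({qa.n_clusters} vs {qb.n_clusters}); use align_cross_k"
        )
    if qa.n_individuals != qb.n_individuals:
        raise AlignmentError(
            f"runs have different N: {qa.n_individuals} vs {qb.n_individuals}"
        )
    K = qa.n_clusters
    D = _pair_cost_matrix(qa.values, qb.values)
    optimum, _ = _lap_cost(D)
    assignment = _lex_refine_lap(D, optimum)
    matching = ClusterMatching(source_k=K, target_k=K, assignment=assignment)
    cost = alignment_cost(qa, qb, matching)
    return AlignmentResult(matching=matching, cost=cost)


def _cross_k_ilp(
    qa: np.ndarray, qb: np.ndarray, fixed: dict[int, int] | None = None
) -> tuple[float, np.ndarray]:
    """Solve the surjective assignment ILP; returns (2N·cost, assignment).

    ``fixed`` pins chosen source→target assignments (used for tie
    canonicalization). The returned objective includes the constant term.
    """
    n, ks = qa.shape
    kl = qb.shape[1]
    G = qb.T @ qb              # source column Gram matrix
    cross = qb.T @ qa          # <b_c, a_d>
    bb = np.diag(G)
    const = float(np.sum(qa * qa))

    nx = kl * ks
    pairs = list(itertools.combinations(range(kl), 2))
    ny = len(pairs) * ks
    nvar = nx + ny

    def xi(c: int, d: int) -> int:
        return c * ks + d

    obj = np.zeros(nvar)
    for c in range(kl):
        for d in range(ks):
            obj[xi(c, d)] = bb[c] - 2.0 * cross[c, d]
    for p, (c, c2) in enumerate(pairs):
        for d in range(ks):
            obj[nx + p * ks + d] = 2.0 * G[c, c2]

    rows: list[np.ndarray] = []
    lbs: list[float] = []
    ubs: list[float] = []
    # each source cluster assigned exactly once
    for c in range(kl):
        row = np.zeros(nvar)
        row[[xi(c, d) for d in range(ks)]] = 1.0
        rows.append(row)
        lbs.append(1.0)
        ubs.append(1.0)
    # each target cluster covered
    for d in range(ks):
        row = np.zeros(nvar)
        row[[xi(c, d) for c in range(kl)]] = 1.0
        rows.append(row)
        lbs.append(1.0)
        ubs.append(np.inf)
    # linearization: y_{cc'd} >= x_cd + x_c'd - 1
    for p, (c, c2) in enumerate(pairs):
        for d in range(ks):
            row = np.zeros(nvar)
            row[xi(c, d)] = 1.0
            row[xi(c2, d)] = 1.0
            row[nx + p * ks + d] = -1.0
            rows.append(row)
            lbs.append(-np.inf)
            ubs.append(1.0)

    lo = np.zeros(nvar)
    hi = np.ones(nvar)
    if fixed:
        for c, d in fixed.items():
            for d2 in range(ks):
                lo[xi(c, d2)] = hi[xi(c, d2)] = 1.0 if d2 == d else 0.0

    integrality = np.zeros(nvar)
    integrality[:nx] = 1
    res = milp(
        c=obj,
        constraints=LinearConstraint(np.vstack(rows), lbs, ubs),
        integrality=integrality,
        bounds=Bounds(lo, hi),
        options={"mip_rel_gap": ILP_REL_GAP},
    )
    if not res.success:
        raise AlignmentError(f"ILP solver failed: {res.message}")
    x = res.x[:nx].reshape(kl, ks)
    if np.any(np.abs(x - np.round(x)) > ILP_BINARY_TOL):
        raise AlignmentError("ILP returned non-binary assignment variables")
    assignment = np.argmax(np.round(x), axis=1)
    return const + float(res.fun), assignment


#: largest K_large handled by the exact subset-DP solver; above it the ILP runs
DP_MAX_K = 10


def _dp_min_cost(
    source_cols: np.ndarray, residuals: np.ndarray, need_mask: int
) -> float:
    """Exact minimum of Σ_d ||r_d − Σ_{c∈T_d} b_c||² over labeled partitions.

    ``source_cols`` holds the m remaining source columns (n×m); ``residuals``
    the per-target residual columns (n×ks). Targets whose bit is set in
    ``need_mask`` must receive at least one source column. Runs a partition
    DP over source subsets: O(ks · 3^m).
    """
    n, m = source_cols.shape
    ks = residuals.shape[1]
    if m == 0:
        if need_mask:
            return math.inf
        return float(np.sum(residuals * residuals))
    # subset sums of source columns, built incrementally: (2^m, n)
    sums = np.zeros((1 << m, n))
    for mask in range(1, 1 << m):
        low = mask & -mask
        sums[mask] = sums[mask ^ low] + source_cols[:, low.bit_length() - 1]
    full = (1 << m) - 1
    g = np.full(1 << m, math.inf)
    g[0] = 0.0
    for d in range(ks):
        diff = sums - residuals[:, d]  # broadcast: (2^m, n)
        f = np.einsum("ij,ij->i", diff, diff)
        required = bool(need_mask & (1 << d))
        g_new = np.full(1 << m, math.inf)
        for U in range(1 << m):
            gu = g_new[U]
            T = U
            while True:
                if T or not required:
                    prev = g[U ^ T]
                    if prev < math.inf:
                        cand = prev + f[T]
                        if cand < gu:
                            gu = cand
                if T == 0:
                    break
                T = (T - 1) & U
            g_new[U] = gu
        g = g_new
    return float(g[full])


def _align_cross_k_dp(
    q_small: MembershipMatrix, q_large: MembershipMatrix
) -> tuple[float, tuple[int, ...]]:
    """Cross-K optimum by subset DP, with exact lexicographic tie-breaking.

    Returns (squared-norm objective, assignment). The assignment is built
    source cluster by source cluster, at each step taking the smallest
    target that still permits completing to the global optimum.
    """
    A = q_small.values
    B = q_large.values
    ks, kl = A.shape[1], B.shape[1]
    optimum = _dp_min_cost(B, A.copy(), (1 << ks) - 1)
    residuals = A.copy()
    need = (1 << ks) - 1
    assignment: list[int] = []
    for c in range(kl):
        rest = B[:, c + 1 :]
        for d in range(ks):
            new_need = need & ~(1 << d)
            if bin(new_need).count("1") > kl - c - 1:
                continue  # not enough sources left to cover remaining targets
            trial = residuals.copy()
            trial[:, d] -= B[:, c]
            val = _dp_min_cost(rest, trial, new_need)
            if val <= optimum + COST_TIE_TOL:
                residuals = trial
                need = new_need
                assignment.append(d)
                break
        else:  # pragma: no cover - optimum guarantees a choice exists
            raise AlignmentError("cross-K DP failed to reconstruct the optimum")
    return optimum, tuple(assignment)


def align_cross_k(
    q_small: MembershipMatrix,
    q_large: MembershipMatrix,
    refine_ties: bool = True,
    method: str = "auto",
) -> AlignmentResult:
    """Optimal surjective matching of a larger-K run onto a smaller-K run.

    Every cluster of ``q_large`` is assigned to exactly one cluster of
    ``q_small`` and every ``q_small`` cluster receives at least one; the
    assigned columns are summed before computing the cost.

    ``method`` selects the solver: ``"dp"`` (exact subset dynamic program,
    O(K_s·3^K_l), with exact lexicographic tie-breaking), ``"ilp"`` (the
    binary integer program via HiGHS, scaling polynomially in practice), or
    ``"auto"`` — DP up to K_large = :data:`DP_MAX_K`, ILP beyond. Both
    solvers return the same optimal cost. ``refine_ties`` applies only to
    the ILP path, canonicalizing cost-ties to the lexicographically
    smallest assignment at the price of extra solves.
    """
    if q_small.n_clusters >= q_large.n_clusters:
        raise AlignmentError(
            f"align_cross_k requires K_small < K_large "
            f"(got {q_small.n_clusters} and {q_large.n_clusters}); "
            "use align_same_k for equal K or swap the arguments"
        )
    if q_small.n_individuals != q_large.n_individuals:
        raise AlignmentError(
            f"runs have different N: {q_small.n_individuals} vs {q_large.n_individuals}"
        )
    kl, ks = q_large.n_clusters, q_small.n_clusters
    if method not in ("auto", "dp", "ilp"):
        raise AlignmentError(f"unknown cross-K method {method!r}")
    if method == "dp" or (method == "auto" and kl <= DP_MAX_K):
        _, assignment = _align_cross_k_dp(q_small, q_large)
        matching = ClusterMatching(source_k=kl, target_k=ks, assignment=assignment)
        return AlignmentResult(
            matching=matching, cost=alignment_cost(q_small, q_large, matching)
        )
    two_n = 2.0 * q_small.n_individuals
    optimum, assignment = _cross_k_ilp(q_small.values, q_large.values)
    if refine_ties:
        # assignment stays an optimal completion consistent with the fixed
        # prefix; only targets lexicographically below it need a solve.
        fixed: dict[int, int] = {}
        for c in range(kl):
            for d in range(int(assignment[c])):
                try:
                    val, trial_assignment = _cross_k_ilp(
                        q_small.values, q_large.values, {**fixed, c: d}
                    )
                except AlignmentError:
                    continue  # prefix infeasible (surjectivity)
                if val <= optimum + COST_TIE_TOL * two_n:
                    assignment = trial_assignment
                    break
            fixed[c] = int(assignment[c])
    matching = ClusterMatching(source_k=kl, target_k=ks, assignment=tuple(int(a) for a in assignment))
    cost = alignment_cost(q_small, q_large, matching)
    return AlignmentResult(matching=matching, cost=cost)


def _surjections(kl: int, ks: int):
    for assignment in itertools.product(range(ks), repeat=kl):
        if len(set(assignment)) == ks:
            yield assignment


def brute_force_align(qa: MembershipMatrix, qb: MembershipMatrix) -> AlignmentResult:
    """Exhaustive-enumeration oracle for both equal-K and cross-K alignment.

    Arguments may come in either K order; internally the smaller-K run is
    the target. Ties are broken by lexicographic order of the assignment
    vector (first enumerated wins). Refuses K above
    :data:`BRUTE_FORCE_MAX_K`.
    """
    if qb.n_clusters < qa.n_clusters:
        qa, qb = qb, qa
    ks, kl = qa.n_clusters, qb.n_clusters
    if kl > BRUTE_FORCE_MAX_K:
        raise AlignmentError(
            f"brute force refuses K={kl} > {BRUTE_FORCE_MAX_K} (combinatorial blow-up)"
        )
    best_cost = math.inf
    best: tuple[int, ...] | None = None
    candidates = (
        itertools.permutations(range(ks))
        if kl == ks
        else _surjections(kl, ks)
    )
    for assignment in candidates:
        m = ClusterMatching(source_k=kl, target_k=ks, assignment=tuple(assignment))
        cost = alignment_cost(qa, qb, m)
        if cost < best_cost - 1e-15:
            best_cost = cost
            best = tuple(assignment)
    assert best is not None
    matching = ClusterMatching(source_k=kl, target_k=ks, assignment=best)
    return AlignmentResult(matching=matching, cost=best_cost)
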