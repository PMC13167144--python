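"""Mode detection among same-K runs via community detection.

Replicate runs at a fixed K either agree up to label switching or settle
into genuinely distinct solutions ("modes"). All R(R−1)/2 run pairs are
optimally aligned, the similarities become edge weights of a complete
network over the runs, and communities of that network are reported as
modes. At the extremes this yields a single mode of size R (all
differences are label switching) or R singleton modes (all runs differ
substantially).

Edge weighting. Modularity-based community detection is invariant to a
uniform rescaling of edge weights, so raw similarities cannot distinguish
"uniformly similar" from "uniformly dissimilar" collections. Weights are
therefore shifted by a chance-level baseline, w = max(0, sim − 0.5), and
zero-weight edges are dropped: uniformly dissimilar runs leave an empty
graph (R singletons), uniformly similar runs a complete one (one mode).

Each detected mode is summarized by a consensus representative: members
are re-aligned to the mode's medoid (the member most similar to the rest)
and averaged entrywise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .alignment import AlignmentError, ClusterMatching, align_same_k, permute_to_match
from .io import MembershipMatrix

#: similarity baseline subtracted before community detection (see module docs)
SIMILARITY_SHIFT = 0.5

#: default seed for the (stochastic) community detection heuristics
DEFAULT_CD_SEED = 42

#: default Markov-clustering inflation exponent
MCL_INFLATION = 2.0


class ModeDetectionError(ValueError):
    """Invalid mode-detection request."""


@dataclass
class SimilarityNetwork:
    """Complete weighted network over the R same-K runs.

    ``weights`` is symmetric with unit diagonal; entry (i, j) is the optimal
    pairwise alignment similarity of runs i and j.
    """

    weights: np.ndarray
    run_ids: list[str]

    @property
    def n_runs(self) -> int:
        return len(self.run_ids)

    def index_of(self, run_id: str) -> int:
        return self.run_ids.index(run_id)


@dataclass
class Mode:
    """A set of mutually aligned runs with a consensus representative.

    ``mode_id`` follows the 1-based "K5M1" convention: mode 1 of K = 5 is
    the largest mode at that K. ``member_alignments`` maps each member
    run_id to the bijection of its clusters onto the representative's
    labeling (source = member, target = representative).
    """

    mode_id: str
    k: int
    member_runs: list[str]
    representative: MembershipMatrix
    within_similarity: float
    member_alignments: dict[str, ClusterMatching] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.member_runs)


def build_network(runs: Sequence[MembershipMatrix]) -> SimilarityNetwork:
    """Align all run pairs at one K and collect similarities into a network."""
    if not runs:
        raise ModeDetectionError("no runs given")
    ks = {r.n_clusters for r in runs}
    if len(ks) != 1:
        raise ModeDetectionError(f"runs mix several K values: {sorted(ks)}")
    R = len(runs)
    W = np.eye(R)
    for i in range(R):
        for j in range(i + 1, R):
            W[i, j] = W[j, i] = align_same_k(runs[i], runs[j]).similarity
    return SimilarityNetwork(weights=W, run_ids=[r.run_id for r in runs])


def network_from_similarities(
    run_ids: Sequence[str], sims: dict[tuple[str, str], float]
) -> SimilarityNetwork:
    """Build a network from precomputed pairwise similarities (e.g. a CSV)."""
    run_ids = list(run_ids)
    idx = {r: i for i, r in enumerate(run_ids)}
    W = np.eye(len(run_ids))
    for (a, b), s in sims.items():
        W[idx[a], idx[b]] = W[idx[b], idx[a]] = s
    return SimilarityNetwork(weights=W, run_ids=run_ids)


def _louvain_partition(W: np.ndarray, seed: int) -> list[set[int]]:
    R = W.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(R))
    shifted = np.maximum(0.0, W - SIMILARITY_SHIFT)
    for i in range(R):
        for j in range(i + 1, R):
            if shifted[i, j] > 0:
                G.add_edge(i, j, weight=float(shifted[i, j]))
    if G.number_of_edges() == 0:
        return [{i} for i in range(R)]
    return [set(c) for c in nx.community.louvain_communities(G, weight="weight", seed=seed)]


def _mcl_partition(W: np.ndarray, inflation: float = MCL_INFLATION) -> list[set[int]]:
    """Markov clustering: alternate expansion (M²) and inflation (Hadamard
    power + column normalization) on the shifted-similarity flow matrix."""
    R = W.shape[0]
    M = np.maximum(0.0, W - SIMILARITY_SHIFT)
    np.fill_diagonal(M, 1.0)  # self-loops stabilize the iteration
    M = M / M.sum(axis=0, keepdims=True)
    for _ in range(200):
        prev = M
        M = M @ M
        M = np.power(M, inflation)
        M[M < 1e-12] = 0.0
        M = M / M.sum(axis=0, keepdims=True)
        if np.max(np.abs(M - prev)) < 1e-8:
            break
    # clusters = connected components of the converged flow's support
    G = nx.Graph()
    G.add_nodes_from(range(R))
    for i, j in zip(*np.nonzero(M > 1e-6)):
        if i != j:
            G.add_edge(int(i), int(j))
    return [set(c) for c in nx.connected_components(G)]


def detect_modes(
    net: SimilarityNetwork,
    method: str = "louvain",
    force_single_tol: float | None = None,
    seed: int = DEFAULT_CD_SEED,
    mcl_inflation: float = MCL_INFLATION,
) -> list[list[str]]:
    """Partition the runs of a network into modes.

    Returns member run_id lists, ordered largest mode first (ties: higher
    within-mode similarity, then smallest member run_id). When
    ``force_single_tol`` is given and every pairwise dissimilarity
    1 − similarity is below it, all runs are returned as one mode without
    running community detection — useful when minor disagreements are
    acceptable for summarization.
    """
    R = net.n_runs
    if force_single_tol is not None:
        off = ~np.eye(R, dtype=bool)
        if R == 1 or np.max(1.0 - net.weights[off]) < force_single_tol:
            return [list(net.run_ids)]
    if method == "louvain":
        parts = _louvain_partition(net.weights, seed=seed)
    elif method == "mcl":
        parts = _mcl_partition(net.weights, inflation=mcl_inflation)
    else:
        raise ModeDetectionError(f"unknown mode-detection method {method!r}")
    groups = [sorted(p) for p in parts]

    def sort_key(members: list[int]):
        ids = [net.run_ids[i] for i in members]
        return (-len(members), -_mean_pair_weight(net.weights, members), min(ids))

    groups.sort(key=sort_key)
    return [[net.run_ids[i] for i in g] for g in groups]


def _mean_pair_weight(W: np.ndarray, members: Sequence[int]) -> float:
    if len(members) < 2:
        return 1.0
    idx = np.asarray(members)
    sub = W[np.ix_(idx, idx)]
    m = len(members)
    return float((sub.sum() - np.trace(sub)) / (m * (m - 1)))


def within_mode_similarity(members: Sequence[str], net: SimilarityNetwork) -> float:
    """Mean pairwise similarity over a mode's members; 1 for singletons."""
    idx = [net.index_of(r) for r in members]
    if any(i < 0 for i in idx):
        raise ModeDetectionError("member run not present in the network")
    return _mean_pair_weight(net.weights, idx)


def mode_representative(members: Sequence[MembershipMatrix]) -> MembershipMatrix:
    """Consensus of already mutually aligned members: entrywise mean,
    rows renormalized."""
    if not members:
        raise ModeDetectionError("cannot build a representative from no members")
    mean = np.mean([m.values for m in members], axis=0)
    mean = mean / mean.sum(axis=1, keepdims=True)
    return MembershipMatrix(values=mean)


def summarize_mode(
    runs_by_id: dict[str, MembershipMatrix],
    members: Sequence[str],
    net: SimilarityNetwork,
    mode_id: str,
) -> Mode:
    """Build a :class:`Mode`: align members to the medoid and average.

    The medoid — the member with the highest total similarity to the other
    members — provides the common cluster labeling (deterministic; ties go
    to the earlier run_id).
    """
    members = list(members)
    idx = [net.index_of(r) for r in members]
    sub = net.weights[np.ix_(idx, idx)]
    medoid_pos = int(np.argmax(sub.sum(axis=1)))  # argmax takes first on ties
    medoid = runs_by_id[members[medoid_pos]]
    aligned: list[MembershipMatrix] = []
    alignments: dict[str, ClusterMatching] = {}
    for rid in members:
        run = runs_by_id[rid]
        res = align_same_k(medoid, run)
        alignments[rid] = res.matching
        aligned.append(permute_to_match(run, res.matching))
    rep = mode_representative(aligned)
    rep.run_id = mode_id
    return Mode(
        mode_id=mode_id,
        k=medoid.n_clusters,
        member_runs=members,
        representative=rep,
        within_similarity=within_mode_similarity(members, net),
        member_alignments=alignments,
    )


def detect_and_summarize(
    runs: Sequence[MembershipMatrix],
    net: SimilarityNetwork | None = None,
    method: str = "louvain",
    force_single_tol: float | None = None,
    seed: int = DEFAULT_CD_SEED,
    mcl_inflation: float = MCL_INFLATION,
) -> list[Mode]:
    """Full mode detection at one K: network → partition → Mode objects."""
    if net is None:
        net = build_network(runs)
    k = runs[0].n_clusters
    runs_by_id = {r.run_id: r for r in runs}
    partition = detect_modes(
        net,
        method=method,
        force_single_tol=force_single_tol,
        seed=seed,
        mcl_inflation=mcl_inflation,
    )
    return [
        summarize_mode(runs_by_id, members, net, mode_id=f"K{k}M{i + 1}")
        for i, members in enumerate(partition)
    ]
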