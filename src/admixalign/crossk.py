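"""Anchored alignment of modes across numbers of clusters K.

For each adjacent pair of *present* K values K1 < K2 (absent levels are
skipped and the nearest present levels aligned directly), one mode pair is
designated the *anchor* — either the cross-K pair with the highest
alignment similarity, or the major (largest) mode at each level. The
anchor pair is aligned by the surjective cross-K matching; every other
mode at K1 or K2 is aligned to its own level's anchor mode by an equal-K
matching and its cross-K matching is composed through the anchor's. This
yields one consistent global cluster labeling:

* the major mode at the smallest K fixes labels 1..K_min in column order;
* at each step up in K, each lower-K cluster's label is inherited by the
  aligned higher-K cluster closest to it in membership, and every other
  higher-K cluster receives the next unused label (a "new" cluster);
* exactly K2 − K1 new labels appear between present levels K1 and K2.

The *pattern edges* derived from the matchings trace which cluster each
newly emerged cluster splits from — the backbone of the alignment-pattern
graph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alignment import (
    AlignmentError,
    AlignmentResult,
    ClusterMatching,
    align_cross_k,
    align_same_k,
    alignment_cost,
)
from .modes import Mode


class CrossKError(ValueError):
    """Invalid cross-K alignment request."""


@dataclass
class ModeAlignmentGraph:
    """Modes arranged by K with anchored cross-K matchings and global labels.

    ``edges[(m1, m2)]`` holds the cross-K alignment of mode ``m2`` (higher
    K, source) onto mode ``m1`` (lower K, target) for every mode pair at
    adjacent present K levels. ``cluster_labels[mode_id][c]`` is the
    1-based global label (color slot) of local cluster ``c``.
    """

    modes: dict[str, Mode]
    k_values: list[int]
    anchor_pairs: dict[tuple[int, int], tuple[str, str, AlignmentResult]]
    edges: dict[tuple[str, str], AlignmentResult]
    cluster_labels: dict[str, tuple[int, ...]]

    def modes_at(self, k: int) -> list[Mode]:
        out = [m for m in self.modes.values() if m.k == k]
        out.sort(key=lambda m: m.mode_id)
        return out

    @property
    def max_label(self) -> int:
        return max(max(lab) for lab in self.cluster_labels.values())

    def label_order(self, mode_id: str) -> list[int]:
        """Local cluster indices of a mode sorted by global label."""
        labels = self.cluster_labels[mode_id]
        return sorted(range(len(labels)), key=lambda c: labels[c])


@dataclass(frozen=True)
class PatternEdge:
    """One parent→child cluster connection implied by a cross-K matching.

    ``is_new_cluster_edge`` marks children whose global label does not
    exist at the parent's K level — the emergence of a new cluster.
    """

    parent_mode: str
    parent_label: int
    child_mode: str
    child_label: int
    is_anchor: bool
    is_new_cluster_edge: bool


def select_anchor_pair(
    modes_k1: Sequence[Mode], modes_k2: Sequence[Mode], criterion: str = "major"
) -> tuple[Mode, Mode, AlignmentResult]:
    """Choose the anchor mode pair between two K levels.

    ``criterion="major"`` picks the largest mode at each level (mode
    ordering already breaks size ties by within-mode similarity, then
    run_id). ``criterion="best"`` scans all cross-K mode pairs and picks
    the highest alignment similarity; ties keep the first pair in mode
    order.
    """
    if not modes_k1 or not modes_k2:
        raise CrossKError("anchor selection requires modes at both K levels")
    if criterion == "major":
        a, b = modes_k1[0], modes_k2[0]
        return a, b, align_cross_k(a.representative, b.representative)
    if criterion == "best":
        best: tuple[Mode, Mode, AlignmentResult] | None = None
        for m1 in modes_k1:
            for m2 in modes_k2:
                res = align_cross_k(m1.representative, m2.representative)
                if best is None or res.similarity > best[2].similarity + 1e-12:
                    best = (m1, m2, res)
        assert best is not None
        return best
    raise CrossKError(f"unknown anchor criterion {criterion!r}")


def _inherit_labels(
    parent: Mode,
    child: Mode,
    matching: ClusterMatching,
    parent_labels: tuple[int, ...],
    next_label: int,
) -> tuple[tuple[int, ...], int]:
    """Propagate global labels through a cross-K matching.

    Among the child clusters mapped to one parent cluster, the one whose
    membership column is closest to the parent's (smallest squared
    distance; ties to the lower index) inherits the parent's label. The
    remaining clusters are new; they take fresh labels in order of
    decreasing total membership (ties to the lower index).
    """
    k2 = child.k
    labels = [0] * k2
    new_clusters: list[int] = []
    for d in range(parent.k):
        children = [c for c in range(k2) if matching.assignment[c] == d]
        dist = [
            float(
                np.sum(
                    (child.representative.values[:, c] - parent.representative.values[:, d])
                    ** 2
                )
            )
            for c in children
        ]
        inheritor = children[int(np.argmin(dist))]
        labels[inheritor] = parent_labels[d]
        new_clusters.extend(c for c in children if c != inheritor)
    masses = child.representative.values.sum(axis=0)
    new_clusters.sort(key=lambda c: (-masses[c], c))
    for c in new_clusters:
        labels[c] = next_label
        next_label += 1
    return tuple(labels), next_label


def _permutation_labels(
    anchor_labels: tuple[int, ...], matching: ClusterMatching
) -> tuple[int, ...]:
    """Labels of a mode aligned to its level's anchor by a bijection."""
    return tuple(anchor_labels[d] for d in matching.assignment)


def _compose_cross_k(
    m2_to_anchor2: ClusterMatching,
    anchor_cross: ClusterMatching,
    m1_to_anchor1: ClusterMatching,
) -> tuple[int, ...]:
    """Compose mode2 → anchor2 → anchor1 → mode1 into one assignment."""
    anchor1_to_m1 = m1_to_anchor1.inverse_permutation()
    return tuple(
        anchor1_to_m1[anchor_cross.assignment[m2_to_anchor2.assignment[c]]]
        for c in range(m2_to_anchor2.source_k)
    )


def align_all_modes(
    modes_by_k: dict[int, list[Mode]], criterion: str = "major"
) -> ModeAlignmentGraph:
    """Align every mode across all present K levels through anchors.

    Present K values are processed in ascending order; non-consecutive
    levels are aligned directly. Within each adjacent pair, the anchor is
    aligned by the surjective cross-K matching, all other modes reach the
    anchors by equal-K matchings, and their cross-K matchings are composed
    through the anchor's (their cost/similarity is then re-evaluated on
    the representatives, not composed).
    """
    ks = sorted(k for k, ms in modes_by_k.items() if ms)
    if not ks:
        raise CrossKError("no modes at any K level")
    modes: dict[str, Mode] = {m.mode_id: m for k in ks for m in modes_by_k[k]}
    cluster_labels: dict[str, tuple[int, ...]] = {}
    anchor_pairs: dict[tuple[int, int], tuple[str, str, AlignmentResult]] = {}
    edges: dict[tuple[str, str], AlignmentResult] = {}

    k_min = ks[0]
    base = modes_by_k[k_min][0]  # major mode: labels 1..K_min in column order
    cluster_labels[base.mode_id] = tuple(range(1, k_min + 1))
    next_label = k_min + 1

    def _level_matchings(
        anchor: Mode, level_modes: Sequence[Mode]
    ) -> dict[str, ClusterMatching]:
        """Equal-K matching of every mode at a level onto the level's anchor."""
        out = {
            anchor.mode_id: ClusterMatching(
                source_k=anchor.k, target_k=anchor.k, assignment=tuple(range(anchor.k))
            )
        }
        for m in level_modes:
            if m.mode_id != anchor.mode_id:
                out[m.mode_id] = align_same_k(
                    anchor.representative, m.representative
                ).matching
        return out

    def _label_level(
        anchor: Mode, level_modes: Sequence[Mode], matchings: dict[str, ClusterMatching]
    ) -> None:
        """Give unlabeled modes the anchor's labels through their bijections."""
        for m in level_modes:
            if m.mode_id not in cluster_labels:
                cluster_labels[m.mode_id] = _permutation_labels(
                    cluster_labels[anchor.mode_id], matchings[m.mode_id]
                )

    for i, (k1, k2) in enumerate(zip(ks, ks[1:])):
        a1, a2, anchor_res = select_anchor_pair(
            modes_by_k[k1], modes_by_k[k2], criterion=criterion
        )
        lower = _level_matchings(a1, modes_by_k[k1])
        if i == 0 and a1.mode_id != base.mode_id:
            # the base labeling belongs to the major mode; derive the
            # anchor's labels from it before propagating upward
            cluster_labels[a1.mode_id] = _permutation_labels(
                cluster_labels[base.mode_id],
                align_same_k(base.representative, a1.representative).matching,
            )
        _label_level(a1, modes_by_k[k1], lower)
        anchor_pairs[(k1, k2)] = (a1.mode_id, a2.mode_id, anchor_res)
        cluster_labels[a2.mode_id], next_label = _inherit_labels(
            a1, a2, anchor_res.matching, cluster_labels[a1.mode_id], next_label
        )
        upper = _level_matchings(a2, modes_by_k[k2])
        _label_level(a2, modes_by_k[k2], upper)
        # cross-K edges for every mode pair, composed through the anchors
        for m1 in modes_by_k[k1]:
            for m2 in modes_by_k[k2]:
                if m1.mode_id == a1.mode_id and m2.mode_id == a2.mode_id:
                    edges[(m1.mode_id, m2.mode_id)] = anchor_res
                    continue
                assignment = _compose_cross_k(
                    upper[m2.mode_id], anchor_res.matching, lower[m1.mode_id]
                )
                matching = ClusterMatching(
                    source_k=m2.k, target_k=m1.k, assignment=assignment
                )
                cost = alignment_cost(m1.representative, m2.representative, matching)
                edges[(m1.mode_id, m2.mode_id)] = AlignmentResult(
                    matching=matching, cost=cost
                )

    if len(ks) == 1:
        _label_level(base, modes_by_k[k_min], _level_matchings(base, modes_by_k[k_min]))

    return ModeAlignmentGraph(
        modes=modes,
        k_values=ks,
        anchor_pairs=anchor_pairs,
        edges=edges,
        cluster_labels=cluster_labels,
    )


def build_pattern_edges(g: ModeAlignmentGraph) -> list[PatternEdge]:
    """One edge per (parent cluster → child cluster) of every cross-K matching.

    A child is flagged as a new-cluster edge when its global label does not
    occur at the parent's K level. For non-anchor pairs several children of
    one parent produce several edges from it.
    """
    out: list[PatternEdge] = []
    labels_at_k: dict[int, set[int]] = {}
    for m in g.modes.values():
        labels_at_k.setdefault(m.k, set()).update(g.cluster_labels[m.mode_id])
    for (m1_id, m2_id), res in sorted(g.edges.items()):
        m1 = g.modes[m1_id]
        is_anchor = any(
            (a1 == m1_id and a2 == m2_id) for a1, a2, _ in g.anchor_pairs.values()
        )
        parent_labels = g.cluster_labels[m1_id]
        child_labels = g.cluster_labels[m2_id]
        for c, d in enumerate(res.matching.assignment):
            out.append(
                PatternEdge(
                    parent_mode=m1_id,
                    parent_label=parent_labels[d],
                    child_mode=m2_id,
                    child_label=child_labels[c],
                    is_anchor=is_anchor,
                    is_new_cluster_edge=child_labels[c] not in labels_at_k[m1.k],
                )
            )
    return out


def pattern_text(g: ModeAlignmentGraph) -> str:
    """Plain-text alignment patterns, one line per cross-K mode pair.

    Format: ``K2M1-K3M1: 1,2,1 (anchor)`` — the 1-based global label of the
    parent cluster for each child cluster, children in local column order.
    """
    lines = []
    for (m1_id, m2_id), res in sorted(g.edges.items()):
        parent_labels = g.cluster_labels[m1_id]
        parts = ",".join(str(parent_labels[d]) for d in res.matching.assignment)
        is_anchor = any(
            (a1 == m1_id and a2 == m2_id) for a1, a2, _ in g.anchor_pairs.values()
        )
        suffix = " (anchor)" if is_anchor else ""
        lines.append(f"{m1_id}-{m2_id}: {parts}{suffix}")
    return "\n".join(lines) + "\n"


def graph_to_json(g: ModeAlignmentGraph) -> str:
    """Serialize the mode alignment graph (without representative matrices)."""
    payload = {
        "k_values": g.k_values,
        "modes": [
            {
                "mode_id": m.mode_id,
                "k": m.k,
                "size": m.size,
                "within_similarity": m.within_similarity,
                "member_runs": m.member_runs,
            }
            for m in sorted(g.modes.values(), key=lambda m: (m.k, m.mode_id))
        ],
        "cluster_labels": {mid: list(lab) for mid, lab in sorted(g.cluster_labels.items())},
        "anchor_pairs": [
            {
                "k1": k1,
                "k2": k2,
                "mode1": a1,
                "mode2": a2,
                "cost": res.cost,
                "similarity": res.similarity,
                "assignment": list(res.matching.assignment),
            }
            for (k1, k2), (a1, a2, res) in sorted(g.anchor_pairs.items())
        ],
        "edges": [
            {
                "mode1": m1,
                "mode2": m2,
                "cost": res.cost,
                "similarity": res.similarity,
                "assignment": list(res.matching.assignment),
            }
            for (m1, m2), res in sorted(g.edges.items())
        ],
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def graph_from_json(
    text: str, modes: dict[str, Mode]
) -> ModeAlignmentGraph:
    """Rebuild a graph from :func:`graph_to_json` output plus Mode objects."""
    payload = json.loads(text)
    edges: dict[tuple[str, str], AlignmentResult] = {}
    for e in payload["edges"]:
        m1, m2 = e["mode1"], e["mode2"]
        matching = ClusterMatching(
            source_k=modes[m2].k, target_k=modes[m1].k, assignment=tuple(e["assignment"])
        )
        edges[(m1, m2)] = AlignmentResult(matching=matching, cost=e["cost"])
    anchor_pairs: dict[tuple[int, int], tuple[str, str, AlignmentResult]] = {}
    for a in payload["anchor_pairs"]:
        key = (a["k1"], a["k2"])
        anchor_pairs[key] = (a["mode1"], a["mode2"], edges[(a["mode1"], a["mode2"])])
    return ModeAlignmentGraph(
        modes=modes,
        k_values=list(payload["k_values"]),
        anchor_pairs=anchor_pairs,
        edges=edges,
        cluster_labels={
            mid: tuple(lab) for mid, lab in payload["cluster_labels"].items()
        },
    )
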