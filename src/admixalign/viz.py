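"""Figures: stacked bar plots, the multipartite graph of modes, and the
alignment pattern graph.

Colors are a pure function of the global cluster label: label ℓ always maps
to palette entry ℓ − 1, in every plot of a session, so a cluster chain
followed across K keeps its color. The palette concatenates matplotlib's
tab20, tab20b and tab20c categorical maps (60 distinguishable colors).

Individuals can be reordered for visual clarity: grouped by their
population label, and sorted within each group by descending membership in
the group's dominant cluster of a chosen reference mode. The same order is
applied to every bar plot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg", force=False)  # headless-safe; no-op if already set

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.lines import Line2D

from .crossk import ModeAlignmentGraph, PatternEdge
from .io import MembershipMatrix, PopulationLabels

logger = logging.getLogger(__name__)

#: edges at the graph's minimum similarity are drawn at this gray luminance
MIN_SIMILARITY_GRAY = 0.8

#: above this many individuals a rendering-resolution warning is logged
LARGE_N_WARNING = 5000


class VisualizationError(ValueError):
    """Invalid visualization request."""


def color_palette() -> list[tuple[float, float, float, float]]:
    """Fixed categorical palette keyed by global label (label ℓ → entry ℓ−1).

    Order: tab20 entries 0..19, then tab20b 0..19, then tab20c 0..19.
    """
    colors = []
    for name in ("tab20", "tab20b", "tab20c"):
        cmap = plt.get_cmap(name)
        colors.extend(cmap(i) for i in range(cmap.N))
    return colors


def label_color(label: int) -> tuple[float, float, float, float]:
    palette = color_palette()
    return palette[(label - 1) % len(palette)]


@dataclass
class DisplayOrder:
    """A permutation of individuals used consistently across all bar plots."""

    individual_order: tuple[int, ...]
    reference_mode: str = ""

    def __post_init__(self) -> None:
        n = len(self.individual_order)
        if sorted(self.individual_order) != list(range(n)):
            raise VisualizationError("individual_order is not a permutation")


def reorder_individuals(
    ref: MembershipMatrix, labels: PopulationLabels | None, reference_mode: str = ""
) -> DisplayOrder:
    """Group individuals by label; sort each group by its dominant cluster.

    The dominant cluster of a group is the cluster with the largest total
    membership over the group's individuals (ties to the lower index);
    within the group, individuals are sorted by descending membership in
    that cluster with a stable sort, so equal values keep input order.
    Without labels the whole cohort is one group.
    """
    n = ref.n_individuals
    if labels is None:
        labels = PopulationLabels(labels=["all"] * n)
    if len(labels) != n:
        raise VisualizationError(
            f"label file has {len(labels)} entries but the matrix has {n} individuals"
        )
    order: list[int] = []
    for _, idx in labels.indices_by_group().items():
        dominant = int(np.argmax(ref.values[idx].sum(axis=0)))
        vals = ref.values[idx, dominant]
        within = np.argsort(-vals, kind="stable")
        order.extend(int(idx[i]) for i in within)
    return DisplayOrder(individual_order=tuple(order), reference_mode=reference_mode)


def _bar_segments(
    ax: plt.Axes,
    m: MembershipMatrix,
    order: Sequence[int],
    colors: Mapping[int, tuple] | None,
    cluster_labels: Sequence[int] | None,
) -> None:
    values = m.values[list(order)]
    n, k = values.shape
    if n > LARGE_N_WARNING:
        logger.warning(
            "bar plot with %d individuals; rendering may be slow (data is never subsampled)",
            n,
        )
    if cluster_labels is None:
        cluster_labels = list(range(1, k + 1))
    x = np.arange(n)
    bottom = np.zeros(n)
    # draw clusters in global-label order so colors stack consistently
    for c in sorted(range(k), key=lambda c: cluster_labels[c]):
        col = (
            colors[cluster_labels[c]]
            if colors is not None
            else label_color(cluster_labels[c])
        )
        ax.bar(x, values[:, c], bottom=bottom, width=1.0, color=col, linewidth=0)
        bottom += values[:, c]
    ax.set_xlim(-0.5, n - 0.5)
    ax.set_ylim(0, 1)
    ax.set_xticks([])
    ax.set_yticks([])


def _group_annotations(
    ax: plt.Axes, labels: PopulationLabels, order: Sequence[int], names: bool = True
) -> None:
    ordered = [labels.labels[i] for i in order]
    boundaries = [i for i in range(1, len(ordered)) if ordered[i] != ordered[i - 1]]
    for b in boundaries:
        ax.axvline(b - 0.5, color="black", linewidth=0.6)
    if names:
        starts = [0] + boundaries
        ends = boundaries + [len(ordered)]
        for s, e in zip(starts, ends):
            ax.text(
                (s + e - 1) / 2.0,
                -0.08,
                ordered[s],
                ha="center",
                va="top",
                fontsize=6,
                rotation=90,
                transform=ax.get_xaxis_transform(),
                clip_on=False,
            )


def plot_mode_barplot(
    m: MembershipMatrix,
    order: DisplayOrder | None,
    path: str | Path,
    colors: Mapping[int, tuple] | None = None,
    cluster_labels: Sequence[int] | None = None,
    labels: PopulationLabels | None = None,
    title: str | None = None,
    dpi: int = 150,
) -> None:
    """One stacked, color-coded bar per individual; groups separated/labeled."""
    idx = (
        list(order.individual_order)
        if order is not None
        else list(range(m.n_individuals))
    )
    fig, ax = plt.subplots(figsize=(max(4, m.n_individuals / 40), 1.8))
    _bar_segments(ax, m, idx, colors, cluster_labels)
    if labels is not None:
        _group_annotations(ax, labels, idx)
    if title:
        ax.set_title(title, fontsize=8)
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)


def _similarity_to_gray(sim: float, sim_min: float) -> str:
    """Similarity 1 → black; the graph's minimum similarity → light gray."""
    if sim >= 1.0 - 1e-12 or sim_min >= 1.0 - 1e-12:
        return "0.0"
    frac = (1.0 - sim) / (1.0 - sim_min)
    return f"{min(1.0, max(0.0, frac)) * MIN_SIMILARITY_GRAY:.3f}"


def _mode_grid_axes(
    fig: plt.Figure, g: ModeAlignmentGraph
) -> dict[str, plt.Axes]:
    """Axes laid out rows-by-K (ascending top→bottom), modes left→right."""
    ks = g.k_values
    ncols = max(len(g.modes_at(k)) for k in ks)
    axes: dict[str, plt.Axes] = {}
    gs = fig.add_gridspec(len(ks), ncols, hspace=0.9, wspace=0.15)
    for row, k in enumerate(ks):
        for col, mode in enumerate(g.modes_at(k)):
            axes[mode.mode_id] = fig.add_subplot(gs[row, col])
    return axes


def plot_multipartite(
    g: ModeAlignmentGraph,
    order: DisplayOrder | None,
    path: str | Path,
    labels: PopulationLabels | None = None,
    dpi: int = 150,
) -> None:
    """The multipartite graph of bar plots: modes by K, cost-labeled edges.

    Each mode's panel shows its bar plot with the mode size in parentheses
    at the upper left and the within-mode similarity at the upper right.
    Edges connect modes at adjacent K levels, labeled by alignment cost;
    edge gray level encodes similarity (1 → black, lower → lighter).
    """
    n = next(iter(g.modes.values())).representative.n_individuals
    idx = list(order.individual_order) if order is not None else list(range(n))
    fig = plt.figure(figsize=(max(6, n / 30) * max(len(g.modes_at(k)) for k in g.k_values), 2.0 * len(g.k_values)))
    axes = _mode_grid_axes(fig, g)
    for mode in g.modes.values():
        ax = axes[mode.mode_id]
        _bar_segments(ax, mode.representative, idx, None, g.cluster_labels[mode.mode_id])
        if labels is not None and mode.k == g.k_values[-1]:
            _group_annotations(ax, labels, idx)
        ax.text(0.0, 1.05, f"{mode.mode_id} ({mode.size})", fontsize=8, transform=ax.transAxes)
        ax.text(1.0, 1.05, f"sim={mode.within_similarity:.3f}", fontsize=8, ha="right", transform=ax.transAxes)
    if g.edges:
        sim_min = min(res.similarity for res in g.edges.values())
        for (m1, m2), res in sorted(g.edges.items()):
            ax1, ax2 = axes[m1], axes[m2]
            xy1 = (0.5, -0.35)
            xy2 = (0.5, 1.25)
            p1 = fig.transFigure.inverted().transform(ax1.transAxes.transform(xy1))
            p2 = fig.transFigure.inverted().transform(ax2.transAxes.transform(xy2))
            color = _similarity_to_gray(res.similarity, sim_min)
            fig.add_artist(
                Line2D([p1[0], p2[0]], [p1[1], p2[1]], color=color, linewidth=1.2)
            )
            mid = ((p1[0] + p2[0]) / 2, (p1[1] + p2[1]) / 2)
            fig.text(
                mid[0],
                mid[1],
                f"{res.cost:.3g}" if res.cost >= 5e-4 else "0",
                fontsize=7,
                ha="center",
                va="center",
                bbox=dict(facecolor="white", edgecolor="none", pad=0.5),
            )
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)


def plot_alignment_pattern(
    edges: Sequence[PatternEdge],
    g: ModeAlignmentGraph,
    path: str | Path,
    dpi: int = 150,
) -> None:
    """The alignment pattern graph: one node per cluster per mode.

    Nodes are colored by global label and laid out as in the multipartite
    view, clusters ordered by label so newly emerged clusters append to the
    right. Edges to newly formed clusters are drawn prominently; direct
    label matches are dimmed. Anchor-pair edges are solid, others dashed.
    """
    fig = plt.figure(figsize=(2.5 * max(len(g.modes_at(k)) for k in g.k_values) * 2, 1.6 * len(g.k_values)))
    axes = _mode_grid_axes(fig, g)
    node_pos: dict[tuple[str, int], tuple[float, float]] = {}
    for mode in g.modes.values():
        ax = axes[mode.mode_id]
        ax.set_xlim(-0.5, g.max_label - 0.5)
        ax.set_ylim(-1, 1)
        ax.axis("off")
        ax.set_title(mode.mode_id, fontsize=8)
        ordered = sorted(g.cluster_labels[mode.mode_id])
        for pos, lab in enumerate(ordered):
            ax.scatter([pos], [0], s=120, color=label_color(lab), zorder=3)
            ax.text(pos, 0, str(lab), fontsize=6, ha="center", va="center", zorder=4)
            xy = fig.transFigure.inverted().transform(ax.transData.transform((pos, 0)))
            node_pos[(mode.mode_id, lab)] = tuple(xy)
    for e in edges:
        p1 = node_pos[(e.parent_mode, e.parent_label)]
        p2 = node_pos[(e.child_mode, e.child_label)]
        fig.add_artist(
            Line2D(
                [p1[0], p2[0]],
                [p1[1], p2[1]],
                color="black" if e.is_new_cluster_edge else "gray",
                alpha=1.0 if e.is_new_cluster_edge else 0.15,
                linewidth=1.8 if e.is_new_cluster_edge else 0.8,
                linestyle="-" if e.is_anchor else "--",
            )
        )
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
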