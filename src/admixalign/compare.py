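"""Model comparison: per-model mode detection interleaved by K.

A "model" is an opaque tag — a different clustering program, a different
optimizer setting, or a different downstream choice. Rather than pooling
all runs into one set of modes, each model's runs go through the full
single-model pipeline independently (networks, modes, cross-K alignment);
the per-model modes are then displayed next to each other, grouped by K,
with one row band per model and alternating background shading.

To make colors comparable across models, each non-reference model's modes
are aligned (equal-K, on representatives) to the reference model's major
mode at the same K; only labels/colors change — representative values are
never altered. Clusters with negligible mean membership (as produced by
programs that encourage empty clusters at large K) are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .alignment import align_same_k
from .crossk import ModeAlignmentGraph, align_all_modes
from .io import MembershipMatrix, PopulationLabels, RunCollection
from .modes import Mode, detect_and_summarize
from .viz import DisplayOrder, _bar_segments, _group_annotations

#: clusters whose mean membership falls below this are flagged as empty
DEFAULT_EMPTY_EPSILON = 0.01


class ComparisonError(ValueError):
    """Invalid model-comparison request."""


def flag_empty_clusters(m: MembershipMatrix, epsilon: float = DEFAULT_EMPTY_EPSILON) -> set[int]:
    """Cluster indices whose mean membership over individuals is < epsilon."""
    if epsilon < 0:
        raise ComparisonError("epsilon must be ≥ 0")
    means = m.values.mean(axis=0)
    return {int(c) for c in np.flatnonzero(means < epsilon)}


@dataclass
class ModelResult:
    """One model's complete single-model pipeline output."""

    model_id: str
    modes_by_k: dict[int, list[Mode]]
    graph: ModeAlignmentGraph


@dataclass
class ModelComparison:
    """Per-model results plus cross-model color-comparable labels.

    ``cluster_labels[(model_id, mode_id)]`` maps each mode's local cluster
    index to a global label shared across models at the same K.
    ``empty_clusters`` flags near-empty clusters per (model, mode).
    """

    reference: str
    model_order: list[str]
    results: dict[str, ModelResult]
    cluster_labels: dict[tuple[str, str], tuple[int, ...]] = field(default_factory=dict)
    similarity_to_reference: dict[tuple[str, str], float] = field(default_factory=dict)
    empty_clusters: dict[tuple[str, str], set[int]] = field(default_factory=dict)

    def k_values(self) -> list[int]:
        ks: set[int] = set()
        for r in self.results.values():
            ks.update(r.modes_by_k)
        return sorted(ks)

    def rows(self) -> list[tuple[int, str, Mode]]:
        """Display rows: K ascending, models in order, modes within model."""
        out = []
        for k in self.k_values():
            for model_id in self.model_order:
                for mode in self.results[model_id].modes_by_k.get(k, []):
                    out.append((k, model_id, mode))
        return out


def run_single_model(
    model_id: str,
    collection: RunCollection,
    cd_method: str = "louvain",
    cd_seed: int = 42,
    force_single_tol: float | None = None,
    anchor_criterion: str = "major",
) -> ModelResult:
    """The full one-model pipeline: modes at each K, then cross-K alignment."""
    modes_by_k = {
        k: detect_and_summarize(
            runs, method=cd_method, seed=cd_seed, force_single_tol=force_single_tol
        )
        for k, runs in collection.by_k.items()
    }
    graph = align_all_modes(modes_by_k, criterion=anchor_criterion)
    return ModelResult(model_id=model_id, modes_by_k=modes_by_k, graph=graph)


def compare_models(
    collections: Mapping[str, RunCollection],
    reference: str | None = None,
    cd_method: str = "louvain",
    cd_seed: int = 42,
    force_single_tol: float | None = None,
    anchor_criterion: str = "major",
    empty_epsilon: float = DEFAULT_EMPTY_EPSILON,
) -> ModelComparison:
    """Run each model's pipeline independently, then make colors comparable.

    At every K present in both the reference and another model, each of the
    other model's modes is aligned to the reference's major mode at that K
    and relabeled through the reference's global labels. At K levels absent
    from the reference, the model keeps its own labels.
    """
    if len(collections) < 2:
        raise ComparisonError("model comparison needs at least two models")
    model_order = list(collections)
    reference = reference if reference is not None else model_order[0]
    if reference not in collections:
        raise ComparisonError(f"reference model {reference!r} not among inputs")
    ns = {mid: c.n_individuals for mid, c in collections.items()}
    if len(set(ns.values())) != 1:
        raise ComparisonError(f"models disagree on the number of individuals: {ns}")

    results = {
        mid: run_single_model(
            mid,
            coll,
            cd_method=cd_method,
            cd_seed=cd_seed,
            force_single_tol=force_single_tol,
            anchor_criterion=anchor_criterion,
        )
        for mid, coll in collections.items()
    }
    cmp = ModelComparison(reference=reference, model_order=model_order, results=results)
    ref_result = results[reference]
    for mid, res in results.items():
        for k, modes in res.modes_by_k.items():
            ref_modes = ref_result.modes_by_k.get(k, [])
            for mode in modes:
                key = (mid, mode.mode_id)
                cmp.empty_clusters[key] = flag_empty_clusters(
                    mode.representative, empty_epsilon
                )
                if mid == reference or not ref_modes:
                    cmp.cluster_labels[key] = res.graph.cluster_labels[mode.mode_id]
                    cmp.similarity_to_reference[key] = (
                        1.0 if mid == reference else float("nan")
                    )
                    continue
                ref_major = ref_modes[0]
                ares = align_same_k(ref_major.representative, mode.representative)
                ref_labels = ref_result.graph.cluster_labels[ref_major.mode_id]
                cmp.cluster_labels[key] = tuple(
                    ref_labels[d] for d in ares.matching.assignment
                )
                cmp.similarity_to_reference[key] = ares.similarity
    return cmp


def comparison_summary(cmp: ModelComparison) -> pd.DataFrame:
    """Tabular summary: one row per (model, K, mode)."""
    rows = []
    for k, model_id, mode in cmp.rows():
        key = (model_id, mode.mode_id)
        empty = sorted(cmp.empty_clusters.get(key, set()))
        rows.append(
            {
                "model": model_id,
                "K": k,
                "mode_id": mode.mode_id,
                "size": mode.size,
                "within_similarity": mode.within_similarity,
                "similarity_to_reference": cmp.similarity_to_reference.get(key, float("nan")),
                "empty_clusters": ";".join(str(c + 1) for c in empty),
            }
        )
    return pd.DataFrame(rows)


def plot_model_comparison(
    cmp: ModelComparison,
    order: DisplayOrder | None,
    path: str | Path,
    labels: PopulationLabels | None = None,
    dpi: int = 150,
) -> None:
    """Interleaved-by-K bar plots with alternating per-model row shading.

    K increases top to bottom; within each K there is one row band per
    model (reference first), shaded alternately so models are easy to tell
    apart. Bars use the cross-model-aligned labels; flagged near-empty
    clusters are annotated on their panel.
    """
    rows = cmp.rows()
    if not rows:
        raise ComparisonError("nothing to plot")
    n = rows[0][2].representative.n_individuals
    idx = list(order.individual_order) if order is not None else list(range(n))
    max_modes = max(
        len(res.modes_by_k.get(k, []))
        for res in cmp.results.values()
        for k in cmp.k_values()
    )
    band_keys = []  # one band per (K, model) with ≥1 mode
    for k in cmp.k_values():
        for mid in cmp.model_order:
            if cmp.results[mid].modes_by_k.get(k):
                band_keys.append((k, mid))
    fig = plt.figure(figsize=(max(6, n / 30) * max_modes, 1.9 * len(band_keys)))
    gs = fig.add_gridspec(len(band_keys), max_modes, hspace=1.0, wspace=0.15)
    shade = {mid: i % 2 == 0 for i, mid in enumerate(cmp.model_order)}
    for row, (k, mid) in enumerate(band_keys):
        modes = cmp.results[mid].modes_by_k[k]
        for col, mode in enumerate(modes):
            ax = fig.add_subplot(gs[row, col])
            key = (mid, mode.mode_id)
            _bar_segments(ax, mode.representative, idx, None, cmp.cluster_labels[key])
            if shade[mid]:
                ax.set_facecolor("0.88")
                fig.patches.append(
                    plt.Rectangle(
                        (-0.02, -0.25),
                        1.04,
                        1.5,
                        transform=ax.transAxes,
                        facecolor="0.88",
                        zorder=-1,
                    )
                )
            ax.text(
                0.0,
                1.05,
                f"{mid} {mode.mode_id} ({mode.size})",
                fontsize=8,
                transform=ax.transAxes,
            )
            ax.text(
                1.0,
                1.05,
                f"sim={mode.within_similarity:.3f}",
                fontsize=8,
                ha="right",
                transform=ax.transAxes,
            )
            empty = cmp.empty_clusters.get(key, set())
            if empty:
                ax.text(
                    0.5,
                    -0.3,
                    "empty: " + ",".join(str(c + 1) for c in sorted(empty)),
                    fontsize=7,
                    ha="center",
                    color="crimson",
                    transform=ax.transAxes,
                )
            if labels is not None and row == len(band_keys) - 1:
                _group_annotations(ax, labels, idx)
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
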