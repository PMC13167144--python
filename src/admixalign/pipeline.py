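"""The modular analysis pipeline and its on-disk artifact contracts.

Each step reads only documented inputs and writes only documented outputs,
all in open text formats, so any stage can be replaced by a custom tool
with compatible files:

========  =======================================  ===========================
step      reads                                    writes (under output_dir)
========  =======================================  ===========================
align     input_dir                                alignments.csv
modes     input_dir, alignments.csv                modes.csv, modes/<mode>.Q,
                                                   aligned/<run>.Q
acrossk   modes.csv, modes/<mode>.Q                crossk_graph.json,
                                                   alignment_pattern.txt,
                                                   aligned_modes/<mode>.Q
plot      modes.csv, modes/<mode>.Q,               plots/*.png (and .pdf)
          crossk_graph.json, labels_file
compmodels one input dir per model                 comparison.csv,
                                                   plots/model_comparison.*
========  =======================================  ===========================

``alignments.csv`` has one row per same-K run pair: run_a (target), run_b
(source), K_a, K_b, cost, similarity, and the assignment as comma-joined
1-based target cluster labels per source cluster. Aligned per-run matrices
(``aligned/``) have columns permuted into their mode representative's
labeling; ``aligned_modes/`` hold representatives with columns ordered by
global label. Data artifacts are byte-reproducible for a fixed config and
seed; timing/metadata go to ``logs/`` so they never perturb the data files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .alignment import align_same_k
from .compare import (
    DEFAULT_EMPTY_EPSILON,
    compare_models,
    comparison_summary,
    plot_model_comparison,
)
from .crossk import (
    align_all_modes,
    build_pattern_edges,
    graph_from_json,
    graph_to_json,
    pattern_text,
)
from .io import (
    MembershipMatrix,
    PopulationLabels,
    RunCollection,
    load_collection,
    parse_admixture_q,
    read_labels,
    write_aligned_matrix,
    write_membership,
)
from .modes import (
    DEFAULT_CD_SEED,
    Mode,
    detect_modes,
    network_from_similarities,
    summarize_mode,
)
from .viz import (
    DisplayOrder,
    plot_alignment_pattern,
    plot_mode_barplot,
    plot_multipartite,
    reorder_individuals,
)

logger = logging.getLogger(__name__)

#: float format used for CSV artifacts (full precision would be noise;
#: 12 significant digits round-trip all quantities the pipeline compares)
CSV_FLOAT_FORMAT = "%.12g"


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class PipelineError(RuntimeError):
    """A step could not run, e.g. a missing upstream artifact."""


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on, with documented defaults.

    ======================  =========== =====================================
    field                   default     meaning
    ======================  =========== =====================================
    input_dir               (required)  directory of membership matrices
    input_format            auto        admixture | structure | faststructure | auto
    labels_file             None        one population label per line
    output_dir              (required)  artifact directory
    cd_method               louvain     community detection: louvain | mcl
    cd_seed                 42          seed for community detection
    force_single_tol        None        if set, one mode when all pairwise
                                        dissimilarities fall below it
    anchor_criterion        major       anchor mode pair: major | best
    reorder_reference       largest_k   bar-plot order from the major mode at
                                        the largest (or smallest) K
    empty_epsilon           0.01        mean-membership threshold for flagging
                                        near-empty clusters
    plot_formats            (png,)      image formats written by plot steps
    dpi                     150         figure resolution
    model_dirs              {}          model_id → input dir (compmodels)
    reference_model         None        compmodels reference (default: first)
    ======================  =========== =====================================
    """

    input_dir: str = ""
    input_format: str = "auto"
    labels_file: str | None = None
    output_dir: str = "admixalign_output"
    cd_method: str = "louvain"
    cd_seed: int = DEFAULT_CD_SEED
    force_single_tol: float | None = None
    anchor_criterion: str = "major"
    reorder_reference: str = "largest_k"
    empty_epsilon: float = DEFAULT_EMPTY_EPSILON
    plot_formats: tuple[str, ...] = ("png",)
    dpi: int = 150
    model_dirs: dict[str, str] = field(default_factory=dict)
    reference_model: str | None = None

    def __post_init__(self) -> None:
        enums = {
            "input_format": ("admixture", "structure", "faststructure", "auto"),
            "cd_method": ("louvain", "mcl"),
            "anchor_criterion": ("major", "best"),
            "reorder_reference": ("largest_k", "smallest_k"),
        }
        for name, allowed in enums.items():
            if getattr(self, name) not in allowed:
                raise ConfigError(
                    f"{name} must be one of {allowed}, got {getattr(self, name)!r}"
                )
        if self.force_single_tol is not None and self.force_single_tol < 0:
            raise ConfigError("force_single_tol must be ≥ 0")
        if self.empty_epsilon < 0:
            raise ConfigError("empty_epsilon must be ≥ 0")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a YAML config; keyword arguments (CLI flags) win."""
        try:
            data = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: invalid YAML ({exc})") from None
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "plot_formats" in data:
            data["plot_formats"] = tuple(data["plot_formats"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _out(cfg: PipelineConfig) -> Path:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_meta(cfg: PipelineConfig, step: str, started: float) -> None:
    logs = _out(cfg) / "logs"
    logs.mkdir(exist_ok=True)
    meta = {
        "step": step,
        "config_hash": cfg.config_hash(),
        "cd_seed": cfg.cd_seed,
        "version": __version__,
        "elapsed_seconds": round(time.time() - started, 3),
    }
    (logs / f"{step}_meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    logger.info("step %s finished in %.2fs (config %s)", step, meta["elapsed_seconds"], meta["config_hash"])


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"missing upstream artifact {path}; run the '{producer}' step first"
        )
    return path


def _load_inputs(cfg: PipelineConfig) -> RunCollection:
    if not cfg.input_dir:
        raise ConfigError("input_dir is required")
    return load_collection(
        cfg.input_dir, format=cfg.input_format, labels_file=cfg.labels_file
    )


def step_align(cfg: PipelineConfig) -> Path:
    """All same-K pairwise alignments → ``alignments.csv``."""
    started = time.time()
    coll = _load_inputs(cfg)
    rows = []
    for k, runs in coll.by_k.items():
        for i in range(len(runs)):
            for j in range(i + 1, len(runs)):
                res = align_same_k(runs[i], runs[j])
                rows.append(
                    {
                        "run_a": runs[i].run_id,
                        "run_b": runs[j].run_id,
                        "K_a": k,
                        "K_b": k,
                        "cost": res.cost,
                        "similarity": res.similarity,
                        "assignment": ",".join(
                            str(d + 1) for d in res.matching.assignment
                        ),
                    }
                )
    out = _out(cfg) / "alignments.csv"
    pd.DataFrame(rows).to_csv(out, index=False, float_format=CSV_FLOAT_FORMAT)
    _write_meta(cfg, "align", started)
    return out


def _read_alignments(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"run_a": str, "run_b": str})


def step_modes(cfg: PipelineConfig) -> Path:
    """Mode detection per K from ``alignments.csv`` → modes.csv + matrices."""
    started = time.time()
    out = _out(cfg)
    align_csv = _require(out / "alignments.csv", "align")
    coll = _load_inputs(cfg)
    table = _read_alignments(align_csv)
    mode_rows = []
    (out / "modes").mkdir(exist_ok=True)
    (out / "aligned").mkdir(exist_ok=True)
    for k, runs in coll.by_k.items():
        sub = table[table["K_a"] == k]
        sims = {
            (row.run_a, row.run_b): float(row.similarity) for row in sub.itertuples()
        }
        net = network_from_similarities([r.run_id for r in runs], sims)
        partition = detect_modes(
            net,
            method=cfg.cd_method,
            force_single_tol=cfg.force_single_tol,
            seed=cfg.cd_seed,
        )
        runs_by_id = {r.run_id: r for r in runs}
        for i, members in enumerate(partition):
            mode = summarize_mode(runs_by_id, members, net, mode_id=f"K{k}M{i + 1}")
            write_membership(mode.representative, out / "modes" / f"{mode.mode_id}.Q")
            for rid in members:
                matching = mode.member_alignments[rid]
                write_aligned_matrix(
                    runs_by_id[rid],
                    list(matching.inverse_permutation()),
                    out / "aligned" / rid,
                )
            mode_rows.append(
                {
                    "mode_id": mode.mode_id,
                    "K": k,
                    "size": mode.size,
                    "within_similarity": mode.within_similarity,
                    "members": ";".join(members),
                }
            )
    modes_csv = out / "modes.csv"
    pd.DataFrame(mode_rows).to_csv(modes_csv, index=False, float_format=CSV_FLOAT_FORMAT)
    _write_meta(cfg, "modes", started)
    return modes_csv


def _load_modes(cfg: PipelineConfig) -> dict[int, list[Mode]]:
    out = _out(cfg)
    modes_csv = _require(out / "modes.csv", "modes")
    table = pd.read_csv(modes_csv, dtype={"mode_id": str, "members": str})
    modes_by_k: dict[int, list[Mode]] = {}
    for row in table.itertuples():
        rep_path = _require(out / "modes" / f"{row.mode_id}.Q", "modes")
        rep = parse_admixture_q(rep_path)
        rep.run_id = row.mode_id
        mode = Mode(
            mode_id=row.mode_id,
            k=int(row.K),
            member_runs=str(row.members).split(";"),
            representative=rep,
            within_similarity=float(row.within_similarity),
        )
        modes_by_k.setdefault(int(row.K), []).append(mode)
    for ms in modes_by_k.values():
        ms.sort(key=lambda m: int(m.mode_id.split("M")[1]))
    return modes_by_k


def step_acrossk(cfg: PipelineConfig) -> Path:
    """Cross-K anchored alignment → graph JSON, pattern text, aligned modes."""
    started = time.time()
    out = _out(cfg)
    modes_by_k = _load_modes(cfg)
    graph = align_all_modes(modes_by_k, criterion=cfg.anchor_criterion)
    graph_json = out / "crossk_graph.json"
    graph_json.write_text(graph_to_json(graph) + "\n")
    (out / "alignment_pattern.txt").write_text(pattern_text(graph))
    (out / "aligned_modes").mkdir(exist_ok=True)
    for mode in graph.modes.values():
        write_aligned_matrix(
            mode.representative,
            graph.label_order(mode.mode_id),
            out / "aligned_modes" / f"{mode.mode_id}.Q",
        )
    _write_meta(cfg, "acrossk", started)
    return graph_json


def _display_order(cfg: PipelineConfig, graph, labels: PopulationLabels | None) -> DisplayOrder:
    ks = graph.k_values
    k_ref = ks[-1] if cfg.reorder_reference == "largest_k" else ks[0]
    ref_mode = graph.modes_at(k_ref)[0]
    return reorder_individuals(ref_mode.representative, labels, reference_mode=ref_mode.mode_id)


def step_plot(cfg: PipelineConfig) -> Path:
    """Render the multipartite graph, pattern graph, and per-mode bar plots."""
    started = time.time()
    out = _out(cfg)
    modes_by_k = _load_modes(cfg)
    graph_json = _require(out / "crossk_graph.json", "acrossk")
    modes = {m.mode_id: m for ms in modes_by_k.values() for m in ms}
    graph = graph_from_json(graph_json.read_text(), modes)
    labels = read_labels(cfg.labels_file) if cfg.labels_file else None
    order = _display_order(cfg, graph, labels)
    plots = out / "plots"
    plots.mkdir(exist_ok=True)
    edges = build_pattern_edges(graph)
    for fmt in cfg.plot_formats:
        plot_multipartite(graph, order, plots / f"multipartite.{fmt}", labels=labels, dpi=cfg.dpi)
        plot_alignment_pattern(edges, graph, plots / f"alignment_pattern.{fmt}", dpi=cfg.dpi)
        for mode in modes.values():
            plot_mode_barplot(
                mode.representative,
                order,
                plots / f"{mode.mode_id}.{fmt}",
                cluster_labels=graph.cluster_labels[mode.mode_id],
                labels=labels,
                title=f"{mode.mode_id} ({mode.size})  sim={mode.within_similarity:.3f}",
                dpi=cfg.dpi,
            )
    _write_meta(cfg, "plot", started)
    return plots


def step_compmodels(cfg: PipelineConfig) -> Path:
    """Per-model pipelines + cross-model comparison CSV and figure."""
    started = time.time()
    if len(cfg.model_dirs) < 2:
        raise ConfigError("compmodels needs model_dirs with at least two models")
    out = _out(cfg)
    collections = {
        mid: load_collection(
            d, format=cfg.input_format, labels_file=cfg.labels_file, model_id=mid
        )
        for mid, d in cfg.model_dirs.items()
    }
    cmp = compare_models(
        collections,
        reference=cfg.reference_model,
        cd_method=cfg.cd_method,
        cd_seed=cfg.cd_seed,
        force_single_tol=cfg.force_single_tol,
        anchor_criterion=cfg.anchor_criterion,
        empty_epsilon=cfg.empty_epsilon,
    )
    summary = comparison_summary(cmp)
    csv_path = out / "comparison.csv"
    summary.to_csv(csv_path, index=False, float_format=CSV_FLOAT_FORMAT)
    labels = read_labels(cfg.labels_file) if cfg.labels_file else None
    ref_graph = cmp.results[cmp.reference].graph
    order = _display_order(cfg, ref_graph, labels)
    plots = out / "plots"
    plots.mkdir(exist_ok=True)
    for fmt in cfg.plot_formats:
        plot_model_comparison(
            cmp, order, plots / f"model_comparison.{fmt}", labels=labels, dpi=cfg.dpi
        )
    _write_meta(cfg, "compmodels", started)
    return csv_path


def run_pipeline(cfg: PipelineConfig) -> Path:
    """The integrated pipeline: align → modes → acrossk → plot."""
    step_align(cfg)
    step_modes(cfg)
    step_acrossk(cfg)
    step_plot(cfg)
    return _out(cfg)
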