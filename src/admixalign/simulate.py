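"""Synthetic replicate membership matrices with planted ground truth.

Emulates the inputs of a population-structure alignment analysis: a cohort
of N individuals in labeled groups, clustered R times at each K by a
stochastic program. Each run carries

* *label switching* — a recorded random column permutation;
* *noise* — per-row Dirichlet resampling around the planted profile, with
  concentration ``noise_scale`` × the profile row (larger = less noise);
* optionally *multimodality* — several planted base solutions, realized as
  distinct group→cluster assignment maps that are provably not column
  permutations of one another;
* optionally a *split hierarchy* — the K+1 base equals the K base with one
  recorded column split in two, giving ground truth for cross-K alignment.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alignment import align_same_k
from .io import MembershipMatrix, PopulationLabels, RunCollection

#: dominant-cluster mass of a planted group profile; 0.95 makes distinct
#: group→cluster maps separable (optimal cross-map similarity ≲ 0.6 at K = 3)
#: while leaving visible admixture in the off-clusters
PROFILE_DOMINANT = 0.95

#: default Dirichlet concentration multiplier (rows concentrate around the
#: profile; ~50 gives within-mode alignment similarities around 0.99)
DEFAULT_NOISE_SCALE = 50.0

#: planted modes are redrawn until every pairwise base similarity is at most
#: this; 0.6 is the boundary between "mostly the same solution" and
#: "genuinely distinct" at the default profile sharpness
DEFAULT_MAX_CROSS_SIMILARITY = 0.6

#: fraction of a split column's mass kept by the original cluster (≠ 0.5 so
#: the inheriting child is unambiguous)
SPLIT_KEEP_FRACTION = 0.6


class SimulationError(ValueError):
    """Invalid synthetic-fixture specification."""


@dataclass
class SyntheticSpec:
    """Study conditions for a synthetic collection.

    Defaults describe a small admixture-like cohort: 6 groups of 10
    individuals, K = 3 clusters, 10 replicate runs, moderate noise.
    """

    n_individuals: int = 60
    group_sizes: tuple[int, ...] = (10, 10, 10, 10, 10, 10)
    k: int = 3
    n_runs: int = 10
    n_modes: int = 1
    mode_assignment: tuple[int, ...] | None = None
    noise_scale: float = DEFAULT_NOISE_SCALE
    seed: int = 0
    max_cross_similarity: float = DEFAULT_MAX_CROSS_SIMILARITY
    profile_dominant: float = PROFILE_DOMINANT

    def __post_init__(self) -> None:
        if sum(self.group_sizes) != self.n_individuals:
            raise SimulationError(
                f"group_sizes sum to {sum(self.group_sizes)} ≠ n_individuals {self.n_individuals}"
            )
        if self.n_modes > self.n_runs:
            raise SimulationError("n_modes cannot exceed n_runs")
        if self.mode_assignment is not None:
            if len(self.mode_assignment) != self.n_runs:
                raise SimulationError("mode_assignment length must equal n_runs")
            if set(self.mode_assignment) != set(range(self.n_modes)):
                raise SimulationError("mode_assignment must use every mode index")

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)

    def group_labels(self) -> PopulationLabels:
        labels: list[str] = []
        for g, sz in enumerate(self.group_sizes):
            labels.extend([f"Pop{g + 1}"] * sz)
        return PopulationLabels(labels=labels)


def _profiles_from_map(
    group_to_cluster: np.ndarray, k: int, dominant: float = PROFILE_DOMINANT
) -> np.ndarray:
    """One profile row per group, mass ``dominant`` on the group's cluster."""
    G = len(group_to_cluster)
    profiles = np.full((G, k), (1.0 - dominant) / (k - 1) if k > 1 else 0.0)
    profiles[np.arange(G), group_to_cluster] = dominant if k > 1 else 1.0
    return profiles


def _expand_profiles(profiles: np.ndarray, group_sizes: tuple[int, ...]) -> np.ndarray:
    return np.repeat(profiles, group_sizes, axis=0)


def _dirichlet_rows(base: np.ndarray, noise_scale: float, rng: np.random.Generator) -> np.ndarray:
    if math.isinf(noise_scale):
        return base.copy()
    alpha = noise_scale * base + 1e-6
    out = np.empty_like(base)
    for i in range(base.shape[0]):
        out[i] = rng.dirichlet(alpha[i])
    return out


def make_base_matrix(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> MembershipMatrix:
    """Planted solution: group profiles with Dirichlet row noise.

    Group g's profile is dominated by cluster g mod K; requires K ≥ number
    of distinct dominant clusters requested, i.e. K ≥ min(K, n_groups) — an
    error is raised if K < 1 or there are more clusters than profiles can
    distinguish sensibly.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    if spec.k < 1:
        raise SimulationError("k must be ≥ 1")
    if spec.k > spec.n_groups:
        raise SimulationError(
            f"k={spec.k} distinct dominant profiles requested but only "
            f"{spec.n_groups} groups available"
        )
    gmap = np.arange(spec.n_groups) % spec.k
    base = _expand_profiles(
        _profiles_from_map(gmap, spec.k, spec.profile_dominant), spec.group_sizes
    )
    values = _dirichlet_rows(base, spec.noise_scale, rng)
    return MembershipMatrix.from_array(values, run_id="base")


def make_replicates(
    base: MembershipMatrix,
    n_runs: int,
    permute: bool = True,
    noise_scale: float = DEFAULT_NOISE_SCALE,
    seed: int = 0,
    run_prefix: str = "R",
) -> tuple[list[MembershipMatrix], list[tuple[int, ...]]]:
    """Replicates of one solution: row noise then a recorded column permutation.

    The recorded permutation ``perm`` satisfies replicate = noisy_base[:, perm];
    aligning a replicate back onto the base recovers it (as the matching's
    inverse permutation) whenever noise leaves the optimum unchanged.
    """
    rng = np.random.default_rng(seed)
    k = base.n_clusters
    runs: list[MembershipMatrix] = []
    perms: list[tuple[int, ...]] = []
    for r in range(n_runs):
        noisy = _dirichlet_rows(base.values, noise_scale, rng)
        perm = tuple(rng.permutation(k)) if permute else tuple(range(k))
        runs.append(
            MembershipMatrix.from_array(
                noisy[:, list(perm)], run_id=f"{run_prefix}{r + 1:03d}.Q"
            )
        )
        perms.append(perm)
    return runs, perms


def _map_similarity(map_a: np.ndarray, map_b: np.ndarray, spec: SyntheticSpec) -> float:
    """Optimal alignment similarity of the noise-free runs implied by two maps."""
    qa = MembershipMatrix.from_array(
        _expand_profiles(
            _profiles_from_map(map_a, spec.k, spec.profile_dominant), spec.group_sizes
        )
    )
    qb = MembershipMatrix.from_array(
        _expand_profiles(
            _profiles_from_map(map_b, spec.k, spec.profile_dominant), spec.group_sizes
        )
    )
    return align_same_k(qa, qb).similarity


def _draw_mode_maps(spec: SyntheticSpec, rng: np.random.Generator) -> list[np.ndarray]:
    """Planted group→cluster maps for each mode, mutually dissimilar.

    Mode 0 uses the canonical map g → g mod K; each further mode is drawn
    by rejection until its noise-free similarity to every earlier mode is
    at most ``spec.max_cross_similarity`` (which also guarantees it is not
    a column permutation of any earlier mode).
    """
    maps = [np.arange(spec.n_groups) % spec.k]
    for _ in range(1, spec.n_modes):
        for _attempt in range(2000):
            cand = rng.integers(0, spec.k, size=spec.n_groups)
            if len(set(cand.tolist())) < spec.k:
                continue  # every cluster must be some group's dominant cluster
            if all(
                _map_similarity(cand, m, spec) <= spec.max_cross_similarity
                for m in maps
            ):
                maps.append(cand)
                break
        else:
            raise SimulationError(
                f"could not plant {spec.n_modes} mutually dissimilar modes with "
                f"k={spec.k}, {spec.n_groups} groups "
                f"(max_cross_similarity={spec.max_cross_similarity}); "
                "increase k or the number of groups"
            )
    return maps


def default_mode_assignment(n_runs: int, n_modes: int) -> tuple[int, ...]:
    """Contiguous blocks, as even as possible, earlier modes get the extras."""
    sizes = [n_runs // n_modes] * n_modes
    for m in range(n_runs % n_modes):
        sizes[m] += 1
    out: list[int] = []
    for m, sz in enumerate(sizes):
        out.extend([m] * sz)
    return tuple(out)


def make_multimodal_collection(
    spec: SyntheticSpec,
) -> tuple[RunCollection, dict[str, int]]:
    """A same-K collection with planted modes; returns (runs, run→mode map)."""
    rng = np.random.default_rng(spec.seed)
    maps = _draw_mode_maps(spec, rng)
    assignment = spec.mode_assignment or default_mode_assignment(spec.n_runs, spec.n_modes)
    bases = [
        _expand_profiles(
            _profiles_from_map(m, spec.k, spec.profile_dominant), spec.group_sizes
        )
        for m in maps
    ]
    runs: list[MembershipMatrix] = []
    planted: dict[str, int] = {}
    for r, mode in enumerate(assignment):
        noisy = _dirichlet_rows(bases[mode], spec.noise_scale, rng)
        perm = list(rng.permutation(spec.k))
        run_id = f"K{spec.k}R{r + 1:03d}.Q"
        runs.append(MembershipMatrix.from_array(noisy[:, perm], run_id=run_id))
        planted[run_id] = mode
    return RunCollection(runs=runs, labels=spec.group_labels()), planted


@dataclass
class SplitHierarchy:
    """Runs across K with recorded parent→child column splits.

    ``splits[k2]`` is the column index (in the K = k2 − 1 base) that was
    split when moving to k2; the retained child keeps that column index and
    the new child is appended as the rightmost column of the k2 base.
    """

    runs_by_k: dict[int, list[MembershipMatrix]]
    bases: dict[int, MembershipMatrix]
    splits: dict[int, int] = field(default_factory=dict)
    permutations: dict[int, list[tuple[int, ...]]] = field(default_factory=dict)

    def collection(self, labels: PopulationLabels | None = None) -> RunCollection:
        runs = [r for k in sorted(self.runs_by_k) for r in self.runs_by_k[k]]
        return RunCollection(runs=runs, labels=labels)


def make_split_hierarchy(
    k_min: int,
    k_max: int,
    spec: SyntheticSpec,
    k_values: tuple[int, ...] | None = None,
    n_runs_per_k: int | None = None,
    permute: bool = True,
) -> SplitHierarchy:
    """Nested solutions across K: each K+1 base splits one column of the K base.

    The split column is chosen (seeded) among the columns of the current
    base; its mass is divided :data:`SPLIT_KEEP_FRACTION` /
    1 − :data:`SPLIT_KEEP_FRACTION` between the original position and a new
    rightmost column, so the merged matrix reconstructs the parent exactly
    (cross-K alignment cost 0 at zero noise). ``k_values`` restricts which
    levels get replicate runs (ground truth for non-consecutive K).
    """
    if k_min >= k_max:
        raise SimulationError("k_min must be < k_max")
    if spec.k != k_min:
        spec = SyntheticSpec(
            n_individuals=spec.n_individuals,
            group_sizes=spec.group_sizes,
            k=k_min,
            n_runs=spec.n_runs,
            noise_scale=spec.noise_scale,
            seed=spec.seed,
        )
    rng = np.random.default_rng(spec.seed)
    n_runs = n_runs_per_k if n_runs_per_k is not None else spec.n_runs
    base = make_base_matrix(
        SyntheticSpec(
            n_individuals=spec.n_individuals,
            group_sizes=spec.group_sizes,
            k=k_min,
            n_runs=n_runs,
            noise_scale=math.inf,  # bases are noise-free; noise enters per replicate
            seed=spec.seed,
        ),
        rng,
    )
    bases: dict[int, MembershipMatrix] = {k_min: base}
    splits: dict[int, int] = {}
    for k2 in range(k_min + 1, k_max + 1):
        prev = bases[k2 - 1].values
        col = int(rng.integers(0, prev.shape[1]))
        splits[k2] = col
        nxt = np.column_stack([prev, prev[:, col] * (1.0 - SPLIT_KEEP_FRACTION)])
        nxt[:, col] = prev[:, col] * SPLIT_KEEP_FRACTION
        bases[k2] = MembershipMatrix.from_array(nxt, run_id=f"base_K{k2}")
    wanted = tuple(k_values) if k_values is not None else tuple(range(k_min, k_max + 1))
    runs_by_k: dict[int, list[MembershipMatrix]] = {}
    permutations: dict[int, list[tuple[int, ...]]] = {}
    for k in wanted:
        if k not in bases:
            raise SimulationError(f"k_values entry {k} outside [{k_min}, {k_max}]")
        runs, perms = make_replicates(
            bases[k],
            n_runs,
            permute=permute,
            noise_scale=spec.noise_scale,
            seed=int(rng.integers(0, 2**31 - 1)),
            run_prefix=f"K{k}R",
        )
        runs_by_k[k] = runs
        permutations[k] = perms
    return SplitHierarchy(
        runs_by_k=runs_by_k, bases=bases, splits=splits, permutations=permutations
    )
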