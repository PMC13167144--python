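"""Reading, validation, and writing of membership (Q) matrices.

A membership matrix is the per-run output of a mixed-membership clustering
program: one row per individual, one column per latent cluster, each row a
probability vector of membership coefficients. Three on-disk dialects are
supported:

* ADMIXTURE ``.Q`` — whitespace-delimited floats, one individual per row,
  no header.
* fastStructure ``.meanQ`` — same shape as ``.Q``.
* Structure run files — the ``Inferred ancestry of individuals`` block;
  the columns after the ``:`` separator are the membership coefficients.

Rows that drift from unit sum by at most ``ROW_SUM_DRIFT`` (rounding noise
from fixed-precision program output) are renormalized with a logged warning;
larger drift is treated as file corruption and rejected.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: maximum tolerated |row sum - 1| before normalization; beyond this the
#: file is considered corrupt rather than merely rounded.
ROW_SUM_DRIFT = 0.05

#: row sums after normalization must be within this of 1.
NORMALIZED_TOL = 1e-6


class MembershipError(ValueError):
    """Base class for membership-matrix I/O and validation failures."""


class MembershipFormatError(MembershipError):
    """The file does not conform to the expected dialect."""


class MembershipValidationError(MembershipError):
    """The parsed numbers violate membership-matrix invariants."""


@dataclass
class MembershipMatrix:
    """One run's N×K row-stochastic matrix of membership coefficients.

    Attributes
    ----------
    values:
        Float array of shape (N, K); every entry in [0, 1] and every row
        summing to 1 within :data:`NORMALIZED_TOL`.
    run_id:
        Identifier of the run, by convention the source file name.
    model_id:
        Optional tag for the model (program / settings) that produced the run.
    """

    values: np.ndarray
    run_id: str = ""
    model_id: str | None = None

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_clusters(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_array(
        cls,
        values: Iterable,
        run_id: str = "",
        model_id: str | None = None,
    ) -> "MembershipMatrix":
        """Validate and row-normalize an array into a membership matrix.

        Raises
        ------
        MembershipValidationError
            On negative entries, entries above 1 + drift, or rows whose sum
            is outside [1 − ROW_SUM_DRIFT, 1 + ROW_SUM_DRIFT].
        """
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise MembershipValidationError(
                f"membership matrix must be 2-D with N ≥ 1, K ≥ 1; got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise MembershipValidationError("non-finite membership coefficients")
        if np.any(arr < 0):
            i, j = np.argwhere(arr < 0)[0]
            raise MembershipValidationError(
                f"negative membership coefficient {arr[i, j]:g} at row {i + 1}, column {j + 1}"
            )
        sums = arr.sum(axis=1)
        bad = np.abs(sums - 1.0) > ROW_SUM_DRIFT
        if np.any(bad):
            i = int(np.argmax(bad))
            raise MembershipValidationError(
                f"row {i + 1} sums to {sums[i]:.6g}, outside "
                f"[{1 - ROW_SUM_DRIFT}, {1 + ROW_SUM_DRIFT}]; file looks corrupt"
            )
        if np.any(np.abs(sums - 1.0) > NORMALIZED_TOL):
            logger.warning(
                "run %s: %d row(s) renormalized (max drift %.3g)",
                run_id or "<memory>",
                int(np.sum(np.abs(sums - 1.0) > NORMALIZED_TOL)),
                float(np.max(np.abs(sums - 1.0))),
            )
        arr = arr / sums[:, None]
        return cls(values=arr, run_id=run_id, model_id=model_id)


@dataclass
class PopulationLabels:
    """Per-individual group labels, e.g. population names.

    ``group_order`` lists each distinct label once, in display order
    (order of first appearance when read from a file).
    """

    labels: list[str]
    group_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.group_order:
            seen: dict[str, None] = {}
            for lab in self.labels:
                seen.setdefault(lab, None)
            self.group_order = list(seen)
        if sorted(set(self.labels)) != sorted(self.group_order):
            raise MembershipValidationError(
                "group_order must contain each distinct label exactly once"
            )

    def __len__(self) -> int:
        return len(self.labels)

    def indices_by_group(self) -> dict[str, np.ndarray]:
        """Row indices of each group, in input order, keyed in group_order."""
        arr = np.asarray(self.labels)
        return {g: np.flatnonzero(arr == g) for g in self.group_order}


@dataclass
class RunCollection:
    """All R runs of an analysis, grouped by their number of clusters K."""

    runs: list[MembershipMatrix]
    labels: PopulationLabels | None = None

    @property
    def by_k(self) -> dict[int, list[MembershipMatrix]]:
        out: dict[int, list[MembershipMatrix]] = {}
        for r in self.runs:
            out.setdefault(r.n_clusters, []).append(r)
        return {k: out[k] for k in sorted(out)}

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def n_individuals(self) -> int:
        return self.runs[0].n_individuals

    def k_values(self) -> list[int]:
        return sorted(self.by_k)


def _parse_numeric_rows(path: Path) -> np.ndarray:
    rows: list[list[float]] = []
    width: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            try:
                row = [float(x) for x in parts]
            except ValueError as exc:
                raise MembershipFormatError(
                    f"{path}: line {lineno}: non-numeric field ({exc})"
                ) from None
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise MembershipFormatError(
                    f"{path}: line {lineno}: expected {width} columns, got {len(row)} (ragged rows)"
                )
            rows.append(row)
    if not rows:
        raise MembershipFormatError(f"{path}: no numeric rows found")
    return np.asarray(rows, dtype=float)


def parse_admixture_q(path: str | Path, model_id: str | None = None) -> MembershipMatrix:
    """Read an ADMIXTURE ``.Q`` (or fastStructure ``.meanQ``) file.

    K is inferred from the column count; rows are validated and normalized.
    """
    path = Path(path)
    if not path.is_file():
        raise MembershipFormatError(f"{path}: no such file")
    arr = _parse_numeric_rows(path)
    return MembershipMatrix.from_array(arr, run_id=path.name, model_id=model_id)


#: fastStructure .meanQ files share the .Q layout.
parse_faststructure_meanq = parse_admixture_q

_STRUCTURE_BLOCK = "Inferred ancestry of individuals"
_STRUCTURE_NUMIND = re.compile(r"^\s*(\d+)\s+individuals\b")


def parse_structure_run(path: str | Path, model_id: str | None = None) -> MembershipMatrix:
    """Extract the membership block from a Structure run output file.

    Only the per-individual membership columns (after the ``:``) are kept;
    the label/missingness metadata columns are discarded. If the file
    declares an individual count, a truncated block is an error.
    """
    path = Path(path)
    if not path.is_file():
        raise MembershipFormatError(f"{path}: no such file")
    text = path.read_text()
    declared_n: int | None = None
    for line in text.splitlines():
        m = _STRUCTURE_NUMIND.match(line)
        if m:
            declared_n = int(m.group(1))
            break
    if _STRUCTURE_BLOCK not in text:
        raise MembershipFormatError(
            f"{path}: '{_STRUCTURE_BLOCK}' block not found; not a Structure run file?"
        )
    block = text.split(_STRUCTURE_BLOCK, 1)[1]
    rows: list[list[float]] = []
    for line in block.splitlines():
        stripped = line.strip()
        if rows and not stripped:
            break  # blank line terminates the block once started
        if ":" not in line:
            continue
        tail = line.rsplit(":", 1)[1].split()
        if not tail:
            continue
        try:
            rows.append([float(x) for x in tail])
        except ValueError:
            continue  # header or annotation line containing ':'
    if not rows:
        raise MembershipFormatError(f"{path}: membership block is empty")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise MembershipFormatError(f"{path}: ragged membership block (widths {sorted(widths)})")
    if declared_n is not None and len(rows) != declared_n:
        raise MembershipFormatError(
            f"{path}: membership block has {len(rows)} individuals, "
            f"but the file declares {declared_n}"
        )
    return MembershipMatrix.from_array(np.asarray(rows), run_id=path.name, model_id=model_id)


def read_labels(path: str | Path) -> PopulationLabels:
    """Read a one-label-per-line population file."""
    path = Path(path)
    labels = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not labels:
        raise MembershipFormatError(f"{path}: empty label file")
    return PopulationLabels(labels=labels)


_FORMAT_SUFFIXES: Mapping[str, tuple[str, ...]] = {
    "admixture": (".q",),
    "faststructure": (".meanq",),
}


def _candidate_files(directory: Path, format: str) -> list[Path]:
    files = sorted(p for p in directory.iterdir() if p.is_file())
    if format in _FORMAT_SUFFIXES:
        suff = _FORMAT_SUFFIXES[format]
        return [p for p in files if p.suffix.lower() in suff]
    if format == "structure":
        return [p for p in files if _STRUCTURE_BLOCK in p.read_text()]
    if format == "auto":
        qlike = [p for p in files if p.suffix.lower() in (".q", ".meanq")]
        if qlike:
            return qlike
        return [p for p in files if _STRUCTURE_BLOCK in p.read_text()]
    raise MembershipError(f"unknown input format {format!r}")


def load_collection(
    directory: str | Path,
    format: str = "auto",
    labels_file: str | Path | None = None,
    model_id: str | None = None,
) -> RunCollection:
    """Load every run in a directory, grouped by K.

    Files are loaded in lexicographic filename order (the run order is part
    of the reproducibility contract). All runs must share the same number
    of individuals N; K may differ across files and usually does.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise MembershipError(f"{directory}: not a directory")
    files = _candidate_files(directory, format)
    if not files:
        raise MembershipError(f"{directory}: no parseable runs found (format={format})")
    runs: list[MembershipMatrix] = []
    for p in files:
        if format == "structure" or (format == "auto" and p.suffix.lower() not in (".q", ".meanq")):
            runs.append(parse_structure_run(p, model_id=model_id))
        else:
            runs.append(parse_admixture_q(p, model_id=model_id))
    n0 = runs[0].n_individuals
    mismatched = [r.run_id for r in runs if r.n_individuals != n0]
    if mismatched:
        raise MembershipValidationError(
            f"runs disagree on the number of individuals: {runs[0].run_id} has {n0}, "
            f"but these differ: {', '.join(mismatched)}"
        )
    labels = None
    if labels_file is not None:
        labels = read_labels(labels_file)
        if len(labels) != n0:
            raise MembershipValidationError(
                f"label file has {len(labels)} lines but runs have {n0} individuals"
            )
    return RunCollection(runs=runs, labels=labels)


def write_membership(m: MembershipMatrix, path: str | Path) -> None:
    """Write a membership matrix in ``.Q`` layout at full double precision."""
    np.savetxt(path, m.values, fmt="%.17g")


def write_aligned_matrix(
    m: MembershipMatrix, permutation: Sequence[int], path: str | Path
) -> None:
    """Write ``m`` with its columns relabeled by ``permutation``.

    ``permutation[j]`` is the input column placed at output position ``j``
    (i.e. the output is ``values[:, permutation]``). Row contents are
    written at full precision so the file round-trips bit-identically.
    """
    perm = list(permutation)
    if sorted(perm) != list(range(m.n_clusters)):
        raise MembershipError(
            f"relabeling {perm} is not a permutation of 0..{m.n_clusters - 1}"
        )
    np.savetxt(path, m.values[:, perm], fmt="%.17g")
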