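"""Data model and I/O for bipartite mating networks.

A mating network records which male-female pairs copulated, as an m x f
binary incidence matrix (males are rows, females are columns), optionally
weighted by copulation counts.  Node degree equals mating success, the
trait every downstream metric operates on.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MatingNetwork",
    "DegreeSummary",
    "from_incidence",
    "from_edge_list",
    "to_edge_list",
    "degrees",
    "mating_density",
    "read_edge_list_csv",
    "write_edge_list_csv",
    "read_matrix_csv",
    "write_matrix_csv",
]


@dataclass(frozen=True)
class MatingNetwork:
    """Bipartite mating network.

    Parameters
    ----------
    incidence : ndarray of shape (m, f)
        Binary matrix; ``incidence[i, j] == 1`` means male ``i`` and female
        ``j`` copulated at least once.  Males are rows, females columns.
    weights : ndarray of shape (m, f), optional
        Non-negative integer copulation counts.  Must be positive exactly
        where ``incidence`` is 1.
    male_ids, female_ids : tuple of str, optional
        Node labels; unique, with lengths m and f.
    """

    incidence: np.ndarray
    weights: np.ndarray | None = None
    male_ids: tuple[str, ...] | None = None
    female_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        inc = np.asarray(self.incidence)
        if inc.ndim != 2 or inc.shape[0] < 1 or inc.shape[1] < 1:
            raise ValueError("incidence must be a 2-D array with m, f >= 1")
        if not np.isin(inc, (0, 1)).all():
            raise ValueError("incidence entries must be 0 or 1")
        inc = inc.astype(np.int8, copy=True)
        inc.setflags(write=False)
        object.__setattr__(self, "incidence", inc)
        if self.weights is not None:
            w = np.asarray(self.weights)
            if w.shape != inc.shape:
                raise ValueError("weights shape must match incidence")
            if np.any(w < 0) or not np.issubdtype(w.dtype, np.integer):
                raise ValueError("weights must be non-negative integers")
            if np.any((w > 0) != (inc == 1)):
                raise ValueError("weights must be positive exactly on edges")
            w = w.astype(np.int64, copy=True)
            w.setflags(write=False)
            object.__setattr__(self, "weights", w)
        for ids, n, what in (
            (self.male_ids, inc.shape[0], "male_ids"),
            (self.female_ids, inc.shape[1], "female_ids"),
        ):
            if ids is not None:
                if len(ids) != n:
                    raise ValueError(f"{what} must have length {n}")
                if len(set(ids)) != len(ids):
                    raise ValueError(f"{what} must be unique")

    @property
    def n_males(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_females(self) -> int:
        return self.incidence.shape[1]

    @property
    def n_edges(self) -> int:
        """Number of distinct mating pairs (binary edge count E)."""
        return int(self.incidence.sum())

    @property
    def is_weighted(self) -> bool:
        return self.weights is not None

    def effective_weights(self) -> np.ndarray:
        """Copulation counts; unweighted networks count each edge once."""
        return self.weights if self.weights is not None else self.incidence.astype(np.int64)

    def male_labels(self) -> tuple[str, ...]:
        if self.male_ids is not None:
            return self.male_ids
        return tuple(f"M{i}" for i in range(self.n_males))

    def female_labels(self) -> tuple[str, ...]:
        if self.female_ids is not None:
            return self.female_ids
        return tuple(f"F{j}" for j in range(self.n_females))


@dataclass(frozen=True)
class DegreeSummary:
    """Per-sex degree (mating success) accounting.

    Variances are population moments (``ddof=0``); they are used only for
    zero-variance checks and descriptive reporting, where the convention
    does not matter.
    """

    male_degrees: np.ndarray
    female_degrees: np.ndarray
    male_mean: float = field(init=False)
    male_var: float = field(init=False)
    female_mean: float = field(init=False)
    female_var: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("male_degrees", "female_degrees"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "male_mean", float(self.male_degrees.mean()))
        object.__setattr__(self, "male_var", float(self.male_degrees.var()))
        object.__setattr__(self, "female_mean", float(self.female_degrees.mean()))
        object.__setattr__(self, "female_var", float(self.female_degrees.var()))


def from_incidence(
    matrix: Iterable[Iterable[int]] | np.ndarray,
    weights: np.ndarray | None = None,
    male_ids: Sequence[str] | None = None,
    female_ids: Sequence[str] | None = None,
) -> MatingNetwork:
    """Build a network from a (nested-list or array) incidence matrix."""
    inc = np.asarray(matrix)
    return MatingNetwork(
        incidence=inc,
        weights=None if weights is None else np.asarray(weights),
        male_ids=None if male_ids is None else tuple(male_ids),
        female_ids=None if female_ids is None else tuple(female_ids),
    )


def from_edge_list(rows: Iterable[tuple]) -> MatingNetwork:
    """Build a network from ``(male_id, female_id[, count])`` rows.

    Node order follows first appearance.  Duplicate (male, female) rows
    accumulate their counts into the edge weight — repeated copulations
    between the same pair are meaningful data, not errors.

    Raises
    ------
    ValueError
        On an empty row list, blank ids, or a non-positive count (the
        offending row index is reported).
    """
    males: dict[str, int] = {}
    females: dict[str, int] = {}
    edges: dict[tuple[int, int], int] = {}
    n = 0
    for idx, row in enumerate(rows):
        if len(row) == 2:
            male, female = row
            count = 1
        elif len(row) == 3:
            male, female, count = row
            count = 1 if count is None else count
        else:
            raise ValueError(f"row {idx}: expected 2 or 3 fields, got {len(row)}")
        male, female = str(male), str(female)
        if not male or not female:
            raise ValueError(f"row {idx}: ids must be non-empty strings")
        if not float(count).is_integer() or int(count) <= 0:
            raise ValueError(f"row {idx}: count must be a positive integer, got {count!r}")
        i = males.setdefault(male, len(males))
        j = females.setdefault(female, len(females))
        edges[(i, j)] = edges.get((i, j), 0) + int(count)
        n += 1
    if n == 0:
        raise ValueError("empty network: no edges given")
    w = np.zeros((len(males), len(females)), dtype=np.int64)
    for (i, j), count in edges.items():
        w[i, j] = count
    return MatingNetwork(
        incidence=(w > 0).astype(np.int8),
        weights=w,
        male_ids=tuple(males),
        female_ids=tuple(females),
    )


def to_edge_list(net: MatingNetwork) -> list[tuple[str, str, int]]:
    """Inverse of :func:`from_edge_list`: one row per edge, row-major order."""
    w = net.effective_weights()
    m_ids, f_ids = net.male_labels(), net.female_labels()
    rows = []
    for i, j in zip(*np.nonzero(net.incidence)):
        rows.append((m_ids[i], f_ids[j], int(w[i, j])))
    return rows


def degrees(net: MatingNetwork) -> DegreeSummary:
    """Row and column sums of the incidence matrix: mating success per node."""
    return DegreeSummary(
        male_degrees=net.incidence.sum(axis=1),
        female_degrees=net.incidence.sum(axis=0),
    )


def mating_density(net: MatingNetwork) -> float:
    """Proportion of possible male-female pairs that mated: E / (m * f)."""
    return net.n_edges / (net.n_males * net.n_females)


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def read_edge_list_csv(path) -> MatingNetwork:
    """Read an edge-list CSV with header ``male_id,female_id[,count]``."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ValueError("empty network: no edges given")
        header = [h.strip().lower() for h in header]
        if header[:2] != ["male_id", "female_id"]:
            raise ValueError("expected header starting 'male_id,female_id'")
        rows = []
        for rec in reader:
            if not rec or not any(field.strip() for field in rec):
                continue
            if len(rec) >= 3 and rec[2].strip():
                rows.append((rec[0].strip(), rec[1].strip(), int(rec[2])))
            else:
                rows.append((rec[0].strip(), rec[1].strip()))
    return from_edge_list(rows)


def write_edge_list_csv(net: MatingNetwork, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["male_id", "female_id", "count"])
        writer.writerows(to_edge_list(net))


def read_matrix_csv(path) -> MatingNetwork:
    """Read a matrix CSV: first row female ids, first column male ids,
    cells are copulation counts (0 = no edge)."""
    with open(path, newline="") as fh:
        rows = [rec for rec in csv.reader(fh) if rec]
    if len(rows) < 2 or len(rows[0]) < 2:
        raise ValueError("matrix CSV needs at least one male and one female")
    female_ids = [c.strip() for c in rows[0][1:]]
    male_ids = [rec[0].strip() for rec in rows[1:]]
    counts = np.array([[int(c) for c in rec[1:]] for rec in rows[1:]], dtype=np.int64)
    if counts.shape != (len(male_ids), len(female_ids)):
        raise ValueError("ragged matrix CSV")
    return MatingNetwork(
        incidence=(counts > 0).astype(np.int8),
        weights=counts,
        male_ids=tuple(male_ids),
        female_ids=tuple(female_ids),
    )


def write_matrix_csv(net: MatingNetwork, path) -> None:
    w = net.effective_weights()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([""] + list(net.female_labels()))
        for i, label in enumerate(net.male_labels()):
            writer.writerow([label] + [int(x) for x in w[i]])
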