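"""Domain types and I/O for ordinal comparison data and rank-cluster partitions.

Objects are identified by name in every file and log; internally they are
0-based integer indices into a label table held by :class:`RankingDataset`.

An observation is an ordered *prefix* of preferred objects (most-preferred
first) together with the set of objects the judge considered:

* complete ranking  — every object considered and every object ranked;
* partial ranking   — only the top ``R`` of the considered objects ordered;
* incomplete ranking — the judge considered a strict subset of the objects;
* pairwise comparison — an incomplete ranking of exactly two objects.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "RankingObservation",
    "RankingDataset",
    "Partition",
    "WorthState",
    "Hyperparams",
    "ValidationError",
    "read_rankings_csv",
    "write_rankings_csv",
    "read_pairwise_csv",
    "canonicalize",
    "enumerate_partitions",
    "bell_number",
]

CONSIDERED_DELIM = ";"


class ValidationError(ValueError):
    """Raised when input data violate a structural invariant."""


@dataclass(frozen=True)
class RankingObservation:
    """One judge's ordered prefix of preferred objects plus the considered set.

    Parameters
    ----------
    ranked
        Object indices in preference order, most-preferred first.
    considered
        Indices of all objects the judge compared when ranking.
    """

    ranked: tuple[int, ...]
    considered: frozenset[int]

    def __init__(self, ranked: Iterable[int], considered: Iterable[int]):
        object.__setattr__(self, "ranked", tuple(int(j) for j in ranked))
        object.__setattr__(self, "considered", frozenset(int(j) for j in considered))
        if len(set(self.ranked)) != len(self.ranked):
            raise ValidationError(f"duplicate object in ranking {self.ranked}")
        if not self.ranked:
            raise ValidationError("empty ranking: at least one object must be ranked")
        if len(self.considered) < 2:
            raise ValidationError("considered set must contain at least 2 objects")
        if not set(self.ranked) <= self.considered:
            extra = set(self.ranked) - self.considered
            raise ValidationError(f"ranked objects {sorted(extra)} not in considered set")

    @property
    def n_ranked(self) -> int:
        return len(self.ranked)

    @property
    def n_considered(self) -> int:
        return len(self.considered)

    @property
    def is_pairwise(self) -> bool:
        return self.n_considered == 2


@dataclass
class RankingDataset:
    """A collection of ranking observations over a common object universe.

    ``observations`` may be empty: an empty dataset carries no likelihood
    information, which is exactly what prior-recovery runs of the sampler
    need. The file readers reject empty files.
    """

    n_objects: int
    observations: list[RankingObservation] = field(default_factory=list)
    object_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.n_objects < 2:
            raise ValidationError("need at least 2 objects")
        if self.object_labels is None:
            self.object_labels = [f"obj{j + 1}" for j in range(self.n_objects)]
        if len(self.object_labels) != self.n_objects:
            raise ValidationError("object_labels length must equal n_objects")
        for i, obs in enumerate(self.observations):
            bad = [j for j in obs.considered if not 0 <= j < self.n_objects]
            if bad:
                raise ValidationError(f"observation {i}: object index out of range: {bad}")

    @property
    def n_observations(self) -> int:
        return len(self.observations)

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self) -> Iterator[RankingObservation]:
        return iter(self.observations)

    def label(self, j: int) -> str:
        return self.object_labels[j]


@dataclass(frozen=True)
class Partition:
    """An assignment of ``J`` objects to ``K`` nonempty rank-clusters.

    Labels are canonical: clusters are numbered 0, 1, ... by ascending
    smallest member, so two structurally equal partitions compare equal.
    """

    assignment: tuple[int, ...]

    def __init__(self, assignment: Sequence[int]):
        object.__setattr__(self, "assignment", _canonical_labels(assignment))

    @property
    def n_objects(self) -> int:
        return len(self.assignment)

    @property
    def n_clusters(self) -> int:
        return max(self.assignment) + 1

    @property
    def cluster_members(self) -> tuple[tuple[int, ...], ...]:
        members: list[list[int]] = [[] for _ in range(self.n_clusters)]
        for j, k in enumerate(self.assignment):
            members[k].append(j)
        return tuple(tuple(m) for m in members)

    @property
    def cluster_sizes(self) -> tuple[int, ...]:
        sizes = [0] * self.n_clusters
        for k in self.assignment:
            sizes[k] += 1
        return tuple(sizes)

    def same_cluster(self, j: int, jp: int) -> bool:
        return self.assignment[j] == self.assignment[jp]

    def __str__(self) -> str:
        return "|".join(",".join(str(j) for j in m) for m in self.cluster_members)


def _canonical_labels(assignment: Sequence[int]) -> tuple[int, ...]:
    assignment = [int(k) for k in assignment]
    if not assignment:
        raise ValidationError("empty partition")
    seen = sorted(set(assignment))
    if seen != list(range(len(seen))):
        raise ValidationError(f"cluster labels must be 0..K-1 with no gaps, got {seen}")
    relabel: dict[int, int] = {}
    out = []
    for k in assignment:
        if k not in relabel:
            relabel[k] = len(relabel)
        out.append(relabel[k])
    return tuple(out)


def canonicalize(partition: Partition) -> Partition:
    """Relabel clusters by ascending smallest member (idempotent)."""
    return Partition(partition.assignment)


@dataclass(frozen=True)
class WorthState:
    """A partition paired with one positive worth per cluster.

    ``cluster_worths[k]`` is the shared worth of every object in cluster
    ``k``; ``expanded_worths`` broadcasts it to a length-``J`` vector. Two
    objects have equal expanded worth iff they share a cluster, so cluster
    worths are required pairwise distinct (an almost-sure event under any
    continuous prior).
    """

    partition: Partition
    cluster_worths: tuple[float, ...]

    def __init__(self, partition: Partition, cluster_worths: Sequence[float]):
        cw = tuple(float(w) for w in cluster_worths)
        if len(cw) != partition.n_clusters:
            raise ValidationError(
                f"{len(cw)} worths for {partition.n_clusters} clusters"
            )
        if any(w <= 0 for w in cw):
            raise ValidationError("cluster worths must be strictly positive")
        if len(set(cw)) != len(cw):
            raise ValidationError("cluster worths must be pairwise distinct")
        object.__setattr__(self, "partition", partition)
        object.__setattr__(self, "cluster_worths", cw)

    @property
    def expanded_worths(self) -> tuple[float, ...]:
        return tuple(self.cluster_worths[k] for k in self.partition.assignment)

    @property
    def n_clusters(self) -> int:
        return self.partition.n_clusters


@dataclass(frozen=True)
class Hyperparams:
    """Hyperparameters of the partition-and-slab prior.

    ``nu`` is the Poisson rate on the number of rank-clusters K (truncated
    to 1..J); ``a`` and ``b`` are the shape and rate of the Gamma slab on
    cluster worths.
    """

    nu: float = 2.0
    a: float = 1.0
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.nu <= 0 or self.a <= 0 or self.b <= 0:
            raise ValidationError("hyperparameters must be strictly positive")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def _collect_names(rows: list[dict], rank_cols: list[str], has_considered: bool) -> list[str]:
    names: list[str] = []
    seen: set[str] = set()
    for row in rows:
        cells = [row.get(c, "") or "" for c in rank_cols]
        if has_considered:
            cells += (row.get("considered") or "").split(CONSIDERED_DELIM)
        for name in cells:
            name = name.strip()
            if name and name not in seen:
                seen.add(name)
                names.append(name)
    return names


def read_rankings_csv(
    path: str | Path,
    object_labels: Sequence[str] | None = None,
) -> RankingDataset:
    """Read ranking observations from CSV.

    Expected header: ``judge,rank_1,...,rank_M[,considered]``. Each row lists
    object names in preference order; trailing blank rank cells make the
    ranking partial. The optional ``considered`` column holds a
    semicolon-separated set of names; when absent, the judge is assumed to
    have considered all objects.

    Parameters
    ----------
    path
        CSV file to read.
    object_labels
        Fixes the object universe and its index order. By default the
        universe is every name appearing in the file, in order of first
        appearance.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValidationError(f"{path}: empty file")
        rank_cols = [c for c in reader.fieldnames if c.startswith("rank_")]
        if not rank_cols:
            raise ValidationError(f"{path}: no rank_* columns found")
        rank_cols.sort(key=lambda c: int(c.split("_", 1)[1]))
        has_considered = "considered" in reader.fieldnames
        rows = list(reader)
    if not rows:
        raise ValidationError(f"{path}: no observations")

    if object_labels is None:
        object_labels = _collect_names(rows, rank_cols, has_considered)
    index = {name: j for j, name in enumerate(object_labels)}
    J = len(object_labels)

    observations = []
    for r, row in enumerate(rows, start=2):  # header is line 1
        cells = [(row.get(c) or "").strip() for c in rank_cols]
        n_lead = next((s for s, cell in enumerate(cells) if not cell), len(cells))
        if any(cells[n_lead:]):
            raise ValidationError(f"{path} line {r}: gap in ranked prefix")
        ranked_names = cells[:n_lead]
        if not ranked_names:
            raise ValidationError(f"{path} line {r}: no ranked objects")
        unknown = [n for n in ranked_names if n not in index]
        if unknown:
            raise ValidationError(f"{path} line {r}: unknown object name(s) {unknown}")
        if len(set(ranked_names)) != len(ranked_names):
            raise ValidationError(f"{path} line {r}: duplicate object within row")
        if has_considered and (row.get("considered") or "").strip():
            cons_names = [
                n.strip() for n in row["considered"].split(CONSIDERED_DELIM) if n.strip()
            ]
            unknown = [n for n in cons_names if n not in index]
            if unknown:
                raise ValidationError(f"{path} line {r}: unknown object name(s) {unknown}")
            considered = {index[n] for n in cons_names}
        else:
            considered = set(range(J))
        ranked = [index[n] for n in ranked_names]
        if not set(ranked) <= considered:
            raise ValidationError(
                f"{path} line {r}: ranked object outside considered set"
            )
        try:
            observations.append(RankingObservation(ranked, considered))
        except ValidationError as exc:
            raise ValidationError(f"{path} line {r}: {exc}") from exc

    return RankingDataset(J, observations, list(object_labels))


def write_rankings_csv(data: RankingDataset, path: str | Path) -> None:
    """Write a dataset in the ``judge,rank_1,...,considered`` layout.

    Round-trips with :func:`read_rankings_csv`: row order and ranked
    prefixes are preserved; the considered column is written explicitly.
    """
    max_r = max((obs.n_ranked for obs in data.observations), default=1)
    header = ["judge"] + [f"rank_{s + 1}" for s in range(max_r)] + ["considered"]
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for i, obs in enumerate(data.observations, start=1):
            ranked = [data.label(j) for j in obs.ranked]
            ranked += [""] * (max_r - len(ranked))
            cons = CONSIDERED_DELIM.join(data.label(j) for j in sorted(obs.considered))
            writer.writerow([i] + ranked + [cons])


def read_pairwise_csv(
    path: str | Path,
    object_labels: Sequence[str] | None = None,
) -> RankingDataset:
    """Read pairwise comparisons from a ``winner,loser`` CSV.

    Each row becomes an incomplete ranking of two objects with the winner
    ranked first.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"winner", "loser"} <= set(reader.fieldnames):
            raise ValidationError(f"{path}: expected header winner,loser")
        rows = [(row["winner"].strip(), row["loser"].strip()) for row in reader]
    if not rows:
        raise ValidationError(f"{path}: no observations")

    if object_labels is None:
        object_labels = []
        seen: set[str] = set()
        for w, l in rows:
            for name in (w, l):
                if name not in seen:
                    seen.add(name)
                    object_labels.append(name)
    index = {name: j for j, name in enumerate(object_labels)}

    observations = []
    for r, (w, l) in enumerate(rows, start=2):
        if w == l:
            raise ValidationError(f"{path} line {r}: winner equals loser ({w!r})")
        for name in (w, l):
            if name not in index:
                raise ValidationError(f"{path} line {r}: unknown object name {name!r}")
        observations.append(RankingObservation([index[w]], {index[w], index[l]}))
    return RankingDataset(len(object_labels), observations, list(object_labels))


# ---------------------------------------------------------------------------
# Partition enumeration (test oracle and exact prior computations, small J)
# ---------------------------------------------------------------------------

_MAX_ENUM_J = 10


def enumerate_partitions(J: int) -> list[Partition]:
    """All set partitions of {0..J-1}, canonical, in stable order.

    Guarded to ``J <= 10`` (Bell(10) = 115975); intended as an exact oracle
    for prior and posterior computations on small object sets.
    """
    if not 1 <= J <= _MAX_ENUM_J:
        raise ValueError(f"enumerate_partitions supports 1 <= J <= {_MAX_ENUM_J}")
    out: list[Partition] = []

    def grow(assignment: list[int], n_used: int) -> None:
        j = len(assignment)
        if j == J:
            out.append(Partition(assignment))
            return
        for k in range(n_used + 1):  # existing clusters plus one new
            assignment.append(k)
            grow(assignment, max(n_used, k + 1))
            assignment.pop()

    grow([], 0)
    return out


def bell_number(J: int) -> int:
    """Bell number via the triangle recurrence (arbitrary precision)."""
    row = [1]
    for _ in range(J - 1):
        new = [row[-1]]
        for x in row:
            new.append(new[-1] + x)
        row = new
    return row[-1]
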