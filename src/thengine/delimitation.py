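"""Species-hypothesis delimitation.

A species hypothesis (SH) is a set of individuals whose pairwise marker
distances connect them at a chosen percent-distance threshold. Delimitation
is single-linkage: two individuals share an SH iff they are joined by a path
whose every edge is within the threshold, so the intraspecific variation of
an SH (its maximum internal pairwise distance) can legitimately exceed the
threshold through chaining.

A coarse greedy centroid pre-clustering pass (default 20% distance, i.e.
80% similarity) may partition large inputs into compound clusters first;
fine-threshold delimitation then runs within each compound cluster. This is
a scaling device, not a change of semantics: cross-compound merging is
impossible by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distancekit import DISTANCE_TOL, DistanceMatrix

__all__ = [
    "CompoundCluster",
    "SpeciesPartition",
    "SpeciesHypothesisRecord",
    "DEFAULT_THRESHOLDS",
    "precluster",
    "single_linkage",
    "intraspecific_variation",
    "choose_reference",
    "delimit",
    "species_hypotheses",
]

#: Default delimitation grid in percent distance (97–99.5% identity).
DEFAULT_THRESHOLDS = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)

#: Default compound-cluster threshold: 20% distance = 80% similarity.
DEFAULT_PRECLUSTER_THRESHOLD = 20.0


@dataclass(frozen=True)
class CompoundCluster:
    """A coarse pre-cluster around a centroid individual."""

    centroid_pid: str
    member_pids: frozenset[str]

    def __post_init__(self) -> None:
        if self.centroid_pid not in self.member_pids:
            raise ValueError("compound-cluster centroid must be a member")


@dataclass(frozen=True)
class SpeciesPartition:
    """All SHs delimited from one matrix at one threshold.

    ``clusters`` are tuples of sorted pids; clusters are ordered by their
    smallest member pid, disjoint, and jointly cover the input.
    """

    threshold: float
    clusters: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cluster in self.clusters:
            if not cluster:
                raise ValueError("empty cluster in partition")
            if seen & set(cluster):
                raise ValueError("overlapping clusters in partition")
            seen.update(cluster)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def cluster_of(self, pid: str) -> tuple[str, ...]:
        for cluster in self.clusters:
            if pid in cluster:
                return cluster
        raise KeyError(pid)


@dataclass
class SpeciesHypothesisRecord:
    """One SH: its members, delimitation threshold, and statistics."""

    member_pids: frozenset[str]
    threshold: float
    intraspecific_variation: float
    reference_pid: str
    name_decision: object | None = None  # filled by the nomenclature module
    accession: object | None = None  # filled by the registry
    local_id: str = field(default="")

    def __post_init__(self) -> None:
        if self.reference_pid not in self.member_pids:
            raise ValueError("SH reference must be a member")


def precluster(
    matrix: DistanceMatrix,
    distance_threshold: float = DEFAULT_PRECLUSTER_THRESHOLD,
    lengths: dict[str, int] | None = None,
) -> list[CompoundCluster]:
    """Greedy centroid pre-clustering into compound clusters.

    Pids are visited by decreasing sequence length then ascending pid; each
    is assigned to the first existing centroid within ``distance_threshold``,
    else it opens a new centroid. Output is sorted by descending size then
    centroid pid. ``lengths`` defaults to 0 for all pids (matrix-only mode).
    """
    lengths = lengths or {}
    order = sorted(matrix.ids, key=lambda p: (-lengths.get(p, 0), p))
    centroids: list[str] = []
    members: dict[str, list[str]] = {}
    for pid in order:
        for centroid in centroids:
            if matrix[pid, centroid] <= distance_threshold + DISTANCE_TOL:
                members[centroid].append(pid)
                break
        else:
            centroids.append(pid)
            members[pid] = [pid]
    clusters = [
        CompoundCluster(centroid_pid=c, member_pids=frozenset(members[c])) for c in centroids
    ]
    clusters.sort(key=lambda c: (-len(c.member_pids), c.centroid_pid))
    return clusters


def single_linkage(matrix: DistanceMatrix, threshold: float) -> SpeciesPartition:
    """Single-linkage partition at a percent-distance threshold.

    Two pids share a cluster iff they are connected by a path whose every
    edge distance is ≤ threshold (inclusive, to an absolute tolerance of
    1e-9). Clusters are reported in order of smallest member pid.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    ids = list(matrix.ids)
    if not ids:
        return SpeciesPartition(threshold=threshold, clusters=())
    adjacency = csr_matrix(matrix.data <= threshold + DISTANCE_TOL)
    _, labels = connected_components(adjacency, directed=False)
    groups: dict[int, list[str]] = {}
    for pid, lab in zip(ids, labels):
        groups.setdefault(int(lab), []).append(pid)
    clusters = sorted((tuple(sorted(g)) for g in groups.values()), key=lambda c: c[0])
    return SpeciesPartition(threshold=threshold, clusters=tuple(clusters))


def intraspecific_variation(cluster: frozenset[str] | tuple[str, ...], matrix: DistanceMatrix) -> float:
    """Maximum pairwise distance within a cluster; 0 for singletons."""
    pids = sorted(cluster)
    if not pids:
        raise ValueError("empty cluster has no intraspecific variation")
    if len(pids) == 1:
        return 0.0
    idx = [matrix.index(p) for p in pids]
    return float(np.max(matrix.data[np.ix_(idx, idx)]))


def choose_reference(
    cluster: frozenset[str] | tuple[str, ...],
    matrix: DistanceMatrix,
    lengths: dict[str, int] | None = None,
) -> str:
    """The medoid of a cluster: the member minimizing its maximum distance
    to the other members; ties broken by longest sequence, then smallest pid."""
    pids = sorted(cluster)
    if not pids:
        raise ValueError("empty cluster has no reference")
    lengths = lengths or {}
    idx = [matrix.index(p) for p in pids]
    sub = matrix.data[np.ix_(idx, idx)]
    eccentricity = sub.max(axis=1)
    return min(zip(pids, eccentricity), key=lambda t: (t[1], -lengths.get(t[0], 0), t[0]))[0]


def delimit(
    matrix: DistanceMatrix,
    thresholds: list[float] | tuple[float, ...] = DEFAULT_THRESHOLDS,
    use_preclusters: bool = False,
    lengths: dict[str, int] | None = None,
    precluster_threshold: float = DEFAULT_PRECLUSTER_THRESHOLD,
) -> dict[float, SpeciesPartition]:
    """Delimit SHs at every threshold in a grid.

    With ``use_preclusters`` the matrix is first partitioned into compound
    clusters; single-linkage then runs within each compound cluster and the
    per-compound partitions are concatenated.
    """
    if not thresholds:
        raise ValueError("at least one threshold required")
    for t in thresholds:
        if t <= 0:
            raise ValueError(f"threshold must be positive: {t}")
    if use_preclusters:
        compounds = precluster(matrix, distance_threshold=precluster_threshold, lengths=lengths)
        blocks = [matrix.filter(sorted(c.member_pids)) for c in compounds]
    else:
        blocks = [matrix]

    result: dict[float, SpeciesPartition] = {}
    for t in thresholds:
        clusters: list[tuple[str, ...]] = []
        for block in blocks:
            clusters.extend(single_linkage(block, t).clusters)
        clusters.sort(key=lambda c: c[0])
        result[t] = SpeciesPartition(threshold=t, clusters=tuple(clusters))
    return result


def species_hypotheses(
    matrix: DistanceMatrix,
    threshold: float,
    lengths: dict[str, int] | None = None,
    use_preclusters: bool = False,
) -> list[SpeciesHypothesisRecord]:
    """Delimit at one threshold and build full SH records with statistics."""
    partition = delimit(
        matrix, thresholds=[threshold], use_preclusters=use_preclusters, lengths=lengths
    )[threshold]
    records = []
    for k, cluster in enumerate(partition.clusters):
        records.append(
            SpeciesHypothesisRecord(
                member_pids=frozenset(cluster),
                threshold=threshold,
                intraspecific_variation=intraspecific_variation(cluster, matrix),
                reference_pid=choose_reference(cluster, matrix, lengths=lengths),
                local_id=f"SH-local-{threshold}-{k:04d}",
            )
        )
    return records
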