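"""Taxon hypotheses above the species level.

Two construction modes:

* **Backbone pooling** — every occupied backbone node above species rank
  becomes a taxon hypothesis (TH) whose member set is the union of all
  individuals of the SHs attached anywhere in its subtree. A genus TH pools
  the SHs carrying that genus name; an order TH pools its genera, and so on
  up to the kingdom. SHs attached above species rank (e.g. identified only
  to order) contribute from that node upward.

* **OTU ladders** — with no backbone at all, THs are computed level by
  level from the distance matrix with strictly increasing thresholds; the
  single-linkage refinement property guarantees that each lower-level TH
  nests inside exactly one higher-level TH. Levels can later be bound to
  classification ranks, at which point the THs stop being OTUs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .backbone import Attachment, Backbone
from .delimitation import single_linkage
from .distancekit import DistanceMatrix
from .records import Rank

__all__ = [
    "TaxonHypothesisRecord",
    "LevelSpec",
    "OtuHierarchy",
    "build_from_backbone",
    "build_otu_levels",
    "bind_level_to_rank",
]


@dataclass
class TaxonHypothesisRecord:
    """A TH: a pooled dataset of individuals at one level of the hierarchy."""

    level: Rank | str  # a backbone rank, or an OTU level id like "z_2"
    member_pids: frozenset[str]
    node_id: str | None = None
    name: str | None = None
    child_refs: list[str] = field(default_factory=list)
    parent_ref: str | None = None
    accession: object | None = None
    local_id: str = ""

    def __post_init__(self) -> None:
        if not self.member_pids:
            raise ValueError("TH requires a nonempty member set")


@dataclass(frozen=True)
class LevelSpec:
    """One rung of an OTU ladder: a level id and its distance threshold."""

    level_id: str
    threshold: float


def build_from_backbone(
    attachments: list[Attachment], backbone: Backbone
) -> list[TaxonHypothesisRecord]:
    """Pool attached SHs upward along the backbone into THs.

    Emits one TH per backbone node of rank above species whose subtree
    contains at least one attached SH; unoccupied nodes emit nothing.
    Species-level datasets are the SHs themselves, so no TH is emitted at
    species rank. Child/parent references are wired along the backbone
    (SH local ids appear as children of the nearest emitted TH).
    """
    attached_at: dict[str, list] = {}
    for att in attachments:
        attached_at.setdefault(att.node_id, []).append(att.sh)
    for shs in attached_at.values():
        shs.sort(key=lambda sh: sorted(sh.member_pids))

    members_below: dict[str, frozenset[str]] = {}
    emitted: dict[str, TaxonHypothesisRecord] = {}

    def visit(node_id: str) -> frozenset[str]:
        pool: set[str] = set()
        child_th_refs: list[str] = []
        for child in backbone.children(node_id):
            child_members = visit(child)
            pool.update(child_members)
            if child in emitted:
                child_th_refs.append(emitted[child].local_id)
            elif child_members:
                # occupied species node: its SHs are the children
                child_th_refs.extend(
                    sh.local_id or f"SH@{child}" for sh in attached_at.get(child, [])
                )
        for sh in attached_at.get(node_id, []):
            pool.update(sh.member_pids)
        members_below[node_id] = frozenset(pool)
        node = backbone.nodes[node_id]
        if pool and node.rank is not Rank.SPECIES:
            direct_sh_refs = [
                sh.local_id or f"SH@{node_id}" for sh in attached_at.get(node_id, [])
            ]
            emitted[node_id] = TaxonHypothesisRecord(
                level=node.rank,
                member_pids=frozenset(pool),
                node_id=node_id,
                name=node.name,
                child_refs=child_th_refs + direct_sh_refs,
                local_id=f"TH@{node_id}",
            )
        return members_below[node_id]

    visit(backbone.root_id)

    # wire parent references along the backbone between emitted THs
    for node_id, th in emitted.items():
        parent = backbone.nodes[node_id].parent_id
        while parent is not None and parent not in emitted:
            parent = backbone.nodes[parent].parent_id
        th.parent_ref = emitted[parent].local_id if parent else None

    return sorted(emitted.values(), key=lambda t: (-int(t.level), t.local_id))


@dataclass
class OtuHierarchy:
    """THs per OTU level plus the audit trail of rank bindings."""

    levels: dict[str, list[TaxonHypothesisRecord]]
    level_order: list[str]
    bindings: dict[str, Rank] = field(default_factory=dict)
    audit: list[tuple[str, Rank]] = field(default_factory=list)


def build_otu_levels(
    matrix: DistanceMatrix, levels: list[LevelSpec]
) -> OtuHierarchy:
    """Compute THs level by level with no backbone.

    ``levels`` must have strictly increasing thresholds with level height.
    Every single-linkage cluster at a level becomes one TH (the number of
    OTUs at a level always equals the number of THs); nesting references
    follow the refinement of partitions across thresholds.
    """
    if not levels:
        raise ValueError("at least one level required")
    thresholds = [spec.threshold for spec in levels]
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("level thresholds must be strictly increasing")

    per_level: dict[str, list[TaxonHypothesisRecord]] = {}
    previous: list[TaxonHypothesisRecord] = []
    for spec in levels:
        partition = single_linkage(matrix, spec.threshold)
        ths = [
            TaxonHypothesisRecord(
                level=spec.level_id,
                member_pids=frozenset(cluster),
                local_id=f"TH@{spec.level_id}#{k:04d}",
            )
            for k, cluster in enumerate(partition.clusters)
        ]
        by_pid = {pid: th for th in ths for pid in th.member_pids}
        for lower in previous:
            parent = by_pid[next(iter(lower.member_pids))]
            if not lower.member_pids <= parent.member_pids:
                raise AssertionError("refinement violated across OTU levels")
            lower.parent_ref = parent.local_id
            parent.child_refs.append(lower.local_id)
        for th in ths:
            th.child_refs.sort()
        per_level[spec.level_id] = ths
        previous = ths
    return OtuHierarchy(levels=per_level, level_order=[s.level_id for s in levels])


def bind_level_to_rank(hierarchy: OtuHierarchy, level_id: str, rank: Rank) -> OtuHierarchy:
    """Bind an OTU level to a classification rank after the fact.

    All THs of the level are annotated with the rank (they are then no
    longer OTUs); re-binding overwrites the previous binding, and every
    binding is recorded in the hierarchy's audit list.
    """
    if level_id not in hierarchy.levels:
        raise KeyError(f"unknown OTU level: {level_id!r}")
    hierarchy.bindings[level_id] = rank
    hierarchy.audit.append((level_id, rank))
    for th in hierarchy.levels[level_id]:
        th.level = rank
    return hierarchy
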