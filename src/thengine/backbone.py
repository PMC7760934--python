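"""Ranked taxonomic backbone and SH attachment.

The backbone is a rooted tree of named, ranked nodes (kingdom down to
species). Named SHs attach to the node carrying their assigned name and
rank as *unranked children of their nearest Latin-name parent*; SHs that
cannot be placed (unnamed, name absent from the backbone, or unresolvable
homonyms) remain communicable by PID and are reported as unplaced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .nomenclature import NameDecision, NameBasis
from .records import Individual, Rank, effective_identification

__all__ = ["BackboneNode", "Backbone", "load_backbone", "attach_sh", "attach_all", "Attachment", "Unplaced"]


@dataclass(frozen=True)
class BackboneNode:
    node_id: str
    name: str
    rank: Rank
    parent_id: str | None


@dataclass
class Backbone:
    """A validated classification tree."""

    classification_id: str
    nodes: dict[str, BackboneNode]
    root_id: str = field(init=False)
    _children: dict[str, list[str]] = field(init=False, default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        roots = [n for n in self.nodes.values() if n.parent_id is None]
        if len(roots) != 1:
            raise ValueError(f"backbone must have exactly one root, found {len(roots)}")
        self.root_id = roots[0].node_id
        for node in self.nodes.values():
            if node.parent_id is not None:
                if node.parent_id not in self.nodes:
                    raise ValueError(
                        f"node {node.node_id!r} references missing parent {node.parent_id!r}"
                    )
                parent = self.nodes[node.parent_id]
                if parent.rank <= node.rank:
                    raise ValueError(
                        f"parent {parent.node_id!r} rank must be higher than child {node.node_id!r}"
                    )
                self._children.setdefault(node.parent_id, []).append(node.node_id)
        self._check_acyclic()
        seen: set[tuple[str, Rank, tuple[str, ...]]] = set()
        for node in self.nodes.values():
            key = (node.name, node.rank, tuple(self.lineage(node.node_id)))
            if key in seen:
                raise ValueError(f"duplicate (name, rank, lineage): {node.name!r}")
            seen.add(key)

    def _check_acyclic(self) -> None:
        for node in self.nodes.values():
            slow: str | None = node.node_id
            visited: set[str] = set()
            while slow is not None:
                if slow in visited:
                    raise ValueError(f"cycle in backbone involving node {slow!r}")
                visited.add(slow)
                slow = self.nodes[slow].parent_id

    def children(self, node_id: str) -> list[str]:
        return sorted(self._children.get(node_id, []))

    def lineage(self, node_id: str) -> list[str]:
        """Root-to-node chain of names."""
        chain: list[str] = []
        current: str | None = node_id
        while current is not None:
            chain.append(self.nodes[current].name)
            current = self.nodes[current].parent_id
        return chain[::-1]

    def lineage_nodes(self, node_id: str) -> list[BackboneNode]:
        chain: list[BackboneNode] = []
        current: str | None = node_id
        while current is not None:
            chain.append(self.nodes[current])
            current = self.nodes[current].parent_id
        return chain[::-1]

    def find_nodes(self, name: str, rank: Rank) -> list[BackboneNode]:
        return sorted(
            (n for n in self.nodes.values() if n.name == name and n.rank == rank),
            key=lambda n: n.node_id,
        )

    def lineage_names_for(self, name: str, rank: Rank) -> dict[Rank, str] | None:
        """Rank→name mapping of the lineage of the unique (name, rank) node.

        Returns None if the node is absent or the name is a homonym at that
        rank (several lineages would qualify).
        """
        nodes = self.find_nodes(name, rank)
        if len(nodes) != 1:
            return None
        return {n.rank: n.name for n in self.lineage_nodes(nodes[0].node_id)}

    def descendants(self, node_id: str) -> list[str]:
        """node_id plus all nodes below it, depth-first."""
        out = [node_id]
        for child in self.children(node_id):
            out.extend(self.descendants(child))
        return out


def load_backbone(path: str | Path, classification_id: str = "default") -> Backbone:
    """Load a backbone from a TSV with columns node_id, parent_id, name, rank.

    An empty parent_id marks the root. Validation failures (cycles, missing
    parents, rank inversions, duplicated name+rank+lineage) raise
    ``ValueError`` naming the offending nodes.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"node_id", "parent_id", "name", "rank"}
    if not required.issubset(frame.columns):
        raise ValueError(f"backbone TSV must have columns {sorted(required)}")
    nodes: dict[str, BackboneNode] = {}
    for row in frame.to_dict("records"):
        node_id = row["node_id"].strip()
        if node_id in nodes:
            raise ValueError(f"duplicate node_id {node_id!r}")
        parent = row["parent_id"].strip() or None
        nodes[node_id] = BackboneNode(
            node_id=node_id,
            name=" ".join(row["name"].split()),
            rank=Rank.from_name(row["rank"]),
            parent_id=parent,
        )
    return Backbone(classification_id=classification_id, nodes=nodes)


@dataclass(frozen=True)
class Attachment:
    """A named SH placed as an unranked child of a backbone node."""

    sh: object  # SpeciesHypothesisRecord
    node_id: str
    classification_id: str


@dataclass(frozen=True)
class Unplaced:
    sh: object
    reason: str  # "unnamed" | "unmatched" | "homonym"


def attach_sh(
    sh,
    decision: NameDecision,
    backbone: Backbone,
    members: list[Individual] | None = None,
) -> Attachment | Unplaced:
    """Attach one named SH to the backbone node carrying its (name, rank).

    Homonyms (the same name at the same rank in several lineages) are
    disambiguated by walking the members' higher-rank effective
    identifications; if no unique candidate lineage remains the SH is
    returned unplaced with reason ``"homonym"`` rather than guessed.
    """
    if decision.basis is NameBasis.UNNAMED or decision.taxon_name is None:
        return Unplaced(sh=sh, reason="unnamed")
    candidates = backbone.find_nodes(decision.taxon_name, decision.rank)
    if not candidates:
        return Unplaced(sh=sh, reason="unmatched")
    if len(candidates) > 1:
        candidates = _disambiguate(candidates, backbone, members or [])
        if len(candidates) != 1:
            return Unplaced(sh=sh, reason="homonym")
    return Attachment(
        sh=sh, node_id=candidates[0].node_id, classification_id=backbone.classification_id
    )


def _disambiguate(candidates, backbone: Backbone, members: list[Individual]):
    higher_names: set[tuple[Rank, str]] = set()
    for m in members:
        eff = effective_identification(m)
        if eff is not None and eff.rank > Rank.GENUS:
            higher_names.add((eff.rank, eff.taxon_name))
    if not higher_names:
        return candidates
    kept = []
    for node in candidates:
        lineage = {n.rank: n.name for n in backbone.lineage_nodes(node.node_id)}
        if all(lineage.get(rank) == name for rank, name in higher_names if rank in lineage):
            kept.append(node)
    return kept


def attach_all(
    shs_with_decisions,
    backbone: Backbone,
    individuals: dict[str, Individual] | None = None,
) -> tuple[list[Attachment], list[Unplaced]]:
    """Attach a batch of (sh, decision) pairs; returns (attachments, unplaced)."""
    attachments: list[Attachment] = []
    unplaced: list[Unplaced] = []
    for sh, decision in shs_with_decisions:
        members = None
        if individuals is not None:
            members = [individuals[p] for p in sorted(sh.member_pids) if p in individuals]
        result = attach_sh(sh, decision, backbone, members=members)
        (attachments if isinstance(result, Attachment) else unplaced).append(result)
    return attachments, unplaced
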