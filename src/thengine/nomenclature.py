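"""Taxon-name assignment for species hypotheses.

An SH is named from the identifications of its members. The decision
cascade, in priority order:

1. a type specimen in the dataset fixes the name (nomenclatural anchoring);
2. several types with distinct names → the earliest-published type name
   wins (a pluggable proxy for code priority);
3. no types: a single uncontradicted species-rank name among the members'
   effective identifications is adopted ("Genus sp." determinations of the
   same genus do not contradict a binomial);
4. conflicting species names with a consensus fraction configured → the
   modal species name, if frequent enough (the BIN-style 80% rule);
5. otherwise the name falls back to the lowest rank at which all effective
   identifications agree — typically the shared genus;
6. failing all of that the SH stays unnamed and is communicable by PID only.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field

from .records import Individual, Identification, Rank, effective_identification

__all__ = ["NameBasis", "NameDecision", "assign_name"]


class NameBasis(enum.Enum):
    TYPE = "type"
    TYPE_PRIORITY = "type_priority"
    UNANIMOUS = "unanimous"
    CONSENSUS = "consensus"
    COMMON_RANK = "common_rank"
    UNNAMED = "unnamed"


@dataclass(frozen=True)
class NameDecision:
    """Outcome of naming one SH."""

    taxon_name: str | None
    rank: Rank | None
    basis: NameBasis
    conflicts: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if (self.basis is NameBasis.UNNAMED) != (self.taxon_name is None):
            raise ValueError("unnamed basis iff no taxon name")


def assign_name(
    members: list[Individual],
    consensus_fraction: float | None = None,
    backbone=None,
) -> NameDecision:
    """Choose the name and rank of an SH from its members.

    ``consensus_fraction``, when set (e.g. 0.8), enables modal-name
    consensus among conflicting species-rank identifications. ``backbone``
    (a :class:`thengine.backbone.Backbone`), when given, supplies lineages
    for the common-rank ascent; without it only the genus token of binomials
    and same-rank name agreement are used.
    """
    if not members:
        raise ValueError("cannot name an empty SH")

    decision = _from_types(members)
    if decision is not None:
        return decision

    effective = [e for e in (effective_identification(m) for m in members) if e is not None]
    if not effective:
        return NameDecision(None, None, NameBasis.UNNAMED)

    species_idents = [e for e in effective if e.rank is Rank.SPECIES]
    species_names = sorted({e.taxon_name for e in species_idents})

    if len(species_names) == 1 and not _higher_rank_conflict(
        species_names[0], effective, backbone
    ):
        return NameDecision(species_names[0], Rank.SPECIES, NameBasis.UNANIMOUS)

    if len(species_names) > 1 and consensus_fraction is not None:
        counts = Counter(e.taxon_name for e in species_idents)
        top = counts.most_common()
        modal_name, modal_count = top[0]
        tie = len(top) > 1 and top[1][1] == modal_count
        if not tie and modal_count / len(species_idents) >= consensus_fraction:
            return NameDecision(
                modal_name,
                Rank.SPECIES,
                NameBasis.CONSENSUS,
                conflicts=tuple(species_names),
            )

    conflicts = tuple(species_names) if len(species_names) > 1 else ()
    common = _common_rank(effective, backbone)
    if common is not None:
        name, rank = common
        return NameDecision(name, rank, NameBasis.COMMON_RANK, conflicts=conflicts)
    return NameDecision(None, None, NameBasis.UNNAMED, conflicts=conflicts)


def _from_types(members: list[Individual]) -> NameDecision | None:
    types = [m for m in members if m.is_type]
    if not types:
        return None
    names = sorted({m.type_name_year[0] for m in types})
    if len(names) == 1:
        return NameDecision(names[0], Rank.SPECIES, NameBasis.TYPE)
    # Several types with distinct names: earliest publication year wins,
    # residual ties broken lexicographically.
    winner = min(types, key=lambda m: (m.type_name_year[1], m.type_name_year[0]))
    return NameDecision(
        winner.type_name_year[0],
        Rank.SPECIES,
        NameBasis.TYPE_PRIORITY,
        conflicts=tuple(names),
    )


def _higher_rank_conflict(binomial: str, effective: list[Identification], backbone) -> bool:
    """Does any higher-rank identification contradict the binomial?

    A genus-rank determination conflicts iff its genus differs from the
    binomial's genus. Ranks above genus are checked against the backbone
    lineage of the binomial's genus when a backbone is available; without
    one they are treated as compatible.
    """
    genus = binomial.split()[0]
    for ident in effective:
        if ident.rank is Rank.SPECIES:
            continue
        if ident.rank is Rank.GENUS:
            if ident.genus_token != genus:
                return True
        elif backbone is not None:
            lineage_names = backbone.lineage_names_for(genus, Rank.GENUS)
            if lineage_names is not None and lineage_names.get(ident.rank) not in (
                None,
                ident.taxon_name,
            ):
                return True
    return False


def _common_rank(effective: list[Identification], backbone) -> tuple[str, Rank] | None:
    """Lowest rank at which every effective identification agrees."""
    for rank in sorted(Rank):
        if rank is Rank.SPECIES:
            continue
        names = {_name_at_rank(e, rank, backbone) for e in effective}
        if None not in names and len(names) == 1:
            return names.pop(), rank
    return None


def _name_at_rank(ident: Identification, rank: Rank, backbone) -> str | None:
    if ident.rank is rank:
        return ident.genus_token if rank is Rank.GENUS else ident.taxon_name
    if ident.rank > rank:
        return None  # identification is less resolved than the asked rank
    if rank is Rank.GENUS:
        return ident.genus_token
    if backbone is None:
        return None
    anchor_name = ident.genus_token if ident.rank in (Rank.SPECIES, Rank.GENUS) else ident.taxon_name
    anchor_rank = Rank.GENUS if ident.rank in (Rank.SPECIES, Rank.GENUS) else ident.rank
    lineage = backbone.lineage_names_for(anchor_name, anchor_rank)
    return None if lineage is None else lineage.get(rank)
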