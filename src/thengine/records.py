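"""Individuals and their identifications.

An *individual* is the atomic unit of every taxon dataset: one specimen or
sequence record, carrying its own persistent identifier (PID), an ordered
history of taxonomic identifications, and an optional type-specimen flag.
Species and higher-level hypotheses are sets of individuals; everything the
engine delimits, names, or versions is ultimately a set of these records.
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

__all__ = [
    "Rank",
    "IdentificationSource",
    "Identification",
    "Individual",
    "read_individuals",
    "ambiguity_filter",
    "effective_identification",
    "IUPAC_CODES",
]

#: All IUPAC nucleotide one-letter codes, including ambiguity symbols and gaps.
IUPAC_CODES = frozenset("ACGTURYSWKMBDHVN")

#: Unambiguous nucleotides; everything else counts toward the ambiguity budget.
_UNAMBIGUOUS = frozenset("ACGT")


class Rank(enum.IntEnum):
    """Linnean ranks, ordered so that a larger value is less resolved."""

    SPECIES = 1
    GENUS = 2
    FAMILY = 3
    ORDER = 4
    CLASS = 5
    PHYLUM = 6
    KINGDOM = 7

    @classmethod
    def from_name(cls, name: str) -> "Rank":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown rank: {name!r}") from None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name.lower()


class IdentificationSource(enum.IntEnum):
    """Provenance of an identification; larger value = higher priority."""

    AUTOMATED = 1
    SEQUENCE_ANNOTATION = 2
    SPECIMEN_EXPERT = 3

    @classmethod
    def from_name(cls, name: str) -> "IdentificationSource":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown identification source: {name!r}") from None


def _normalize_name(name: str) -> str:
    return " ".join(name.split())


@dataclass(frozen=True)
class Identification:
    """One dated taxonomic determination of an individual.

    ``taxon_name`` is a Latin name at ``rank``; a genus-rank determination may
    be written either as the bare genus or as ``"Genus sp."``.
    """

    taxon_name: str
    rank: Rank
    date: _dt.date
    source: IdentificationSource = IdentificationSource.SPECIMEN_EXPERT

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxon_name", _normalize_name(self.taxon_name))
        if not self.taxon_name:
            raise ValueError("identification requires a taxon name")
        if not isinstance(self.date, _dt.date):
            raise TypeError("identification date must be a datetime.date")
        if self.rank is Rank.SPECIES:
            tokens = self.taxon_name.split()
            if len(tokens) != 2 or tokens[1] == "sp.":
                raise ValueError(
                    f"species-rank identification must be a binomial: {self.taxon_name!r}"
                )

    @property
    def genus_token(self) -> str | None:
        """The genus this identification implies, when one is implied.

        Species binomials imply their first token; genus-rank names imply the
        name itself (with a trailing ``sp.`` stripped). Higher ranks imply no
        genus.
        """
        if self.rank is Rank.SPECIES:
            return self.taxon_name.split()[0]
        if self.rank is Rank.GENUS:
            name = self.taxon_name
            if name.endswith(" sp."):
                name = name[:-4].strip()
            return name
        return None


@dataclass
class Individual:
    """A single specimen or sequence record with its PID and history."""

    pid: str
    sequence: str | None = None
    identifications: list[Identification] = field(default_factory=list)
    is_type: bool = False
    type_name_year: tuple[str, int] | None = None

    def __post_init__(self) -> None:
        if not self.pid:
            raise ValueError("individual requires a non-empty pid")
        if self.is_type and self.type_name_year is None:
            raise ValueError(f"type individual {self.pid!r} requires a type name and year")
        if self.sequence is not None:
            seq = self.sequence.strip().upper()
            bad = set(seq) - IUPAC_CODES
            if bad:
                raise ValueError(
                    f"individual {self.pid!r}: non-IUPAC symbols in sequence: {sorted(bad)}"
                )
            self.sequence = seq

    @property
    def length(self) -> int:
        return len(self.sequence) if self.sequence else 0

    def ambiguity_count(self) -> int:
        if self.sequence is None:
            raise ValueError(f"individual {self.pid!r} has no sequence")
        return sum(1 for c in self.sequence if c not in _UNAMBIGUOUS)


def effective_identification(ind: Individual) -> Identification | None:
    """The identification currently in force for an individual.

    The most recent determination supersedes earlier ones (a re-identification
    replaces the original name). Date ties are broken by source priority
    (specimen expert > sequence annotation > automated); a residual tie keeps
    the last-listed entry.
    """
    if not ind.identifications:
        return None
    indexed = list(enumerate(ind.identifications))
    return max(indexed, key=lambda t: (t[1].date, t[1].source, t[0]))[1]


def read_individuals(fasta_path: str | Path, metadata_path: str | Path) -> list[Individual]:
    """Load individuals from a FASTA file and its metadata sidecar.

    The sidecar is a UTF-8 TSV with columns ``pid, taxon_name, rank, date,
    source, is_type, type_name, type_year``; repeated rows for one pid encode
    multiple identifications. Individuals are returned in FASTA file order;
    a pid without metadata rows gets an empty identification history.

    Raises ``ValueError`` on a duplicated FASTA pid or a metadata row whose
    pid has no FASTA record.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    pids: list[str] = []
    seqs: dict[str, str] = {}
    for rec in records:
        if rec.id in seqs:
            raise ValueError(f"duplicate pid in FASTA: {rec.id!r}")
        pids.append(rec.id)
        seqs[rec.id] = str(rec.seq)

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
    rows_by_pid: dict[str, list[dict]] = {}
    for row in meta.to_dict("records"):
        pid = row.get("pid", "")
        if pid not in seqs:
            raise ValueError(f"metadata row references pid absent from FASTA: {pid!r}")
        rows_by_pid.setdefault(pid, []).append(row)

    individuals = []
    for pid in pids:
        idents: list[Identification] = []
        is_type = False
        type_name_year = None
        for row in rows_by_pid.get(pid, []):
            if row.get("taxon_name", ""):
                idents.append(
                    Identification(
                        taxon_name=row["taxon_name"],
                        rank=Rank.from_name(row.get("rank", "species")),
                        date=_dt.date.fromisoformat(row["date"]),
                        source=IdentificationSource.from_name(
                            row.get("source") or "specimen_expert"
                        ),
                    )
                )
            if str(row.get("is_type", "")).strip().lower() in {"1", "true", "yes"}:
                is_type = True
                type_name_year = (row["type_name"], int(row["type_year"]))
        individuals.append(
            Individual(
                pid=pid,
                sequence=seqs[pid],
                identifications=idents,
                is_type=is_type,
                type_name_year=type_name_year,
            )
        )
    return individuals


def ambiguity_filter(
    individuals: list[Individual], max_ambiguous: int = 6
) -> tuple[list[Individual], list[Individual]]:
    """Partition individuals by ambiguous-nucleotide content.

    Sequences containing more than ``max_ambiguous`` ambiguous nucleotides
    (any IUPAC symbol outside A/C/G/T, case-insensitive) are excluded from
    downstream delimitation. Returns ``(kept, excluded)`` preserving input
    order; every individual must carry a sequence.
    """
    kept: list[Individual] = []
    excluded: list[Individual] = []
    for ind in individuals:
        if ind.sequence is None:
            raise ValueError(f"individual {ind.pid!r} has no sequence; cannot filter")
        (kept if ind.ambiguity_count() <= max_ambiguous else excluded).append(ind)
    return kept, excluded
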