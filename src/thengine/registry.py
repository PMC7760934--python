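"""Persistent identifiers for taxon datasets, versioned across releases.

Identity of a taxon dataset is *content plus delimitation*: the stable
digest of its sorted member pids together with the descriptor of how it was
delimited (kind, threshold or level or rank, trait set). If the content of
a dataset changes — an individual added or removed — a new identifier must
be issued; equally, the same member set delimited at a different threshold
is a different dataset and gets its own identifier. Conversely an unchanged
(content, delimitation) pair keeps its serial forever, gaining only a new
release suffix in each frozen snapshot.

Serials are never reused, releases form an append-only lineage, and the
registry persists as JSON lines so that re-running an identical pipeline
reproduces byte-identical tables.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

__all__ = [
    "DelimitationDescriptor",
    "Accession",
    "RegistryEntry",
    "Release",
    "Registry",
    "issue",
    "release",
    "track_individual",
    "diff_releases",
]


@dataclass(frozen=True)
class DelimitationDescriptor:
    """How a dataset was delimited; part of its identity key."""

    kind: str  # "sh" | "th_backbone" | "th_otu"
    threshold_or_level: str  # percent threshold, OTU level id, or rank name
    trait_set: str = "ITS"

    _KINDS = ("sh", "th_backbone", "th_otu")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"descriptor kind must be one of {self._KINDS}")
        if not str(self.threshold_or_level):
            raise ValueError("descriptor requires a threshold or level")

    @classmethod
    def sh(cls, threshold: float, trait_set: str = "ITS") -> "DelimitationDescriptor":
        return cls(kind="sh", threshold_or_level=f"{float(threshold):g}", trait_set=trait_set)


@dataclass(frozen=True)
class Accession:
    """A rendered dataset identifier: prefix + zero-padded serial [+ suffix]."""

    prefix: str  # "SH" or "TH"
    serial: int
    release_suffix: str | None = None

    def __post_init__(self) -> None:
        if self.prefix not in ("SH", "TH"):
            raise ValueError("accession prefix must be SH or TH")
        if self.serial < 0:
            raise ValueError("accession serial must be nonnegative")

    def rendered(self) -> str:
        base = f"{self.prefix}{self.serial:06d}"
        return base if self.release_suffix is None else f"{base}.{self.release_suffix}"


def member_digest(member_pids) -> str:
    """Stable content digest: SHA-256 of newline-joined sorted pids."""
    joined = "\n".join(sorted(member_pids))
    return hashlib.sha256(joined.encode("utf-8")).hexdigest()


@dataclass
class RegistryEntry:
    digest: str
    descriptor: DelimitationDescriptor
    serial: int
    member_pids: tuple[str, ...]
    classification_ids: tuple[str, ...] = ()

    @property
    def prefix(self) -> str:
        return "SH" if self.descriptor.kind == "sh" else "TH"

    def accession(self, release_suffix: str | None = None) -> Accession:
        return Accession(prefix=self.prefix, serial=self.serial, release_suffix=release_suffix)


@dataclass
class Release:
    """A frozen snapshot of the registry under one release code."""

    release_code: str
    created: str
    entries: dict[tuple[str, DelimitationDescriptor], RegistryEntry]
    parent_release: str | None = None

    def accessions(self) -> dict[tuple[str, DelimitationDescriptor], Accession]:
        return {k: e.accession(self.release_code) for k, e in self.entries.items()}

    def dois(self, resolver_prefix: str = "https://doi.example/10.15156") -> dict[str, str]:
        """DOI-like URI per entry (stand-ins for minted DOIs)."""
        return {
            e.accession(self.release_code).rendered(): f"{resolver_prefix}/{e.accession(self.release_code).rendered()}"
            for e in self.entries.values()
        }


@dataclass
class Registry:
    """The live identifier registry: entries, serial counter, release lineage."""

    entries: dict[tuple[str, DelimitationDescriptor], RegistryEntry] = field(default_factory=dict)
    releases: list[Release] = field(default_factory=list)
    next_serial: int = 1
    clock: object = None  # injectable timestamp source for reproducible tables

    def _now(self) -> str:
        if self.clock is not None:
            return self.clock()
        return _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")

    # -- persistence (JSON lines: one entry per line, then one line per release)

    def dump(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for (digest, desc), entry in sorted(
                self.entries.items(), key=lambda kv: kv[1].serial
            ):
                fh.write(
                    json.dumps(
                        {
                            "record": "entry",
                            "digest": digest,
                            "descriptor": asdict(desc),
                            "serial": entry.serial,
                            "member_pids": list(entry.member_pids),
                            "classification_ids": list(entry.classification_ids),
                        },
                        sort_keys=True,
                    )
                    + "\n"
                )
            for rel in self.releases:
                fh.write(
                    json.dumps(
                        {
                            "record": "release",
                            "release_code": rel.release_code,
                            "created": rel.created,
                            "parent_release": rel.parent_release,
                            "serials": sorted(e.serial for e in rel.entries.values()),
                        },
                        sort_keys=True,
                    )
                    + "\n"
                )

    @classmethod
    def load(cls, path: str | Path) -> "Registry":
        reg = cls()
        release_rows = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                row = json.loads(line)
                if row["record"] == "entry":
                    desc = DelimitationDescriptor(**row["descriptor"])
                    entry = RegistryEntry(
                        digest=row["digest"],
                        descriptor=desc,
                        serial=row["serial"],
                        member_pids=tuple(row["member_pids"]),
                        classification_ids=tuple(row["classification_ids"]),
                    )
                    reg.entries[(entry.digest, desc)] = entry
                    reg.next_serial = max(reg.next_serial, entry.serial + 1)
                else:
                    release_rows.append(row)
        by_serial = {e.serial: e for e in reg.entries.values()}
        for row in release_rows:
            entries = {
                (by_serial[s].digest, by_serial[s].descriptor): by_serial[s]
                for s in row["serials"]
            }
            reg.releases.append(
                Release(
                    release_code=row["release_code"],
                    created=row["created"],
                    entries=entries,
                    parent_release=row["parent_release"],
                )
            )
        return reg


def issue(member_pids, descriptor: DelimitationDescriptor, registry: Registry) -> Accession:
    """Issue (or retrieve) the accession for a (member set, delimitation) pair.

    Identical content under an identical descriptor anywhere in the lineage
    returns the existing accession; anything else — changed membership or a
    different threshold/level over the same members — mints a fresh serial.
    """
    pids = sorted(set(member_pids))
    if not pids:
        raise ValueError("cannot issue an accession for an empty member set")
    digest = member_digest(pids)
    key = (digest, descriptor)
    if key in registry.entries:
        return registry.entries[key].accession()
    entry = RegistryEntry(
        digest=digest,
        descriptor=descriptor,
        serial=registry.next_serial,
        member_pids=tuple(pids),
    )
    registry.next_serial += 1
    registry.entries[key] = entry
    return entry.accession()


def release(registry: Registry, release_code: str) -> Release:
    """Freeze the current registry state under a release code.

    Every current entry is snapshotted; its rendered accession gains the
    release suffix. Duplicate release codes within a lineage are rejected;
    releasing an empty registry is an error.
    """
    if not registry.entries:
        raise ValueError("cannot release an empty registry")
    if any(r.release_code == release_code for r in registry.releases):
        raise ValueError(f"duplicate release code {release_code!r}")
    parent = registry.releases[-1].release_code if registry.releases else None
    snapshot = Release(
        release_code=release_code,
        created=registry._now(),
        entries=dict(registry.entries),
        parent_release=parent,
    )
    registry.releases.append(snapshot)
    return snapshot


def track_individual(pid: str, registry: Registry) -> list[tuple[str, str, DelimitationDescriptor]]:
    """Chronological membership history of one individual across releases.

    Returns ``(release_code, rendered accession, descriptor)`` triples;
    an unknown pid yields an empty history.
    """
    history = []
    for rel in registry.releases:
        for entry in sorted(rel.entries.values(), key=lambda e: e.serial):
            if pid in entry.member_pids:
                history.append(
                    (rel.release_code, entry.accession(rel.release_code).rendered(), entry.descriptor)
                )
    return history


def diff_releases(r1: Release, r2: Release, registry: Registry) -> dict[str, set[str]]:
    """Classify dataset fates between two releases of one lineage.

    ``unchanged``: identical (digest, descriptor) present in both.
    ``split``: an r1 dataset strictly covering ≥2 r2 datasets (members-wise,
    within the same descriptor kind); ``merged``: the converse; remaining
    r1-only datasets are ``retired`` and r2-only are ``new``. Rendered
    accessions (with release suffixes) are reported.
    """
    codes = {rel.release_code for rel in registry.releases}
    if r1.release_code not in codes or r2.release_code not in codes:
        raise ValueError("releases must belong to this registry lineage")

    unchanged = set()
    r1_only, r2_only = [], []
    for key, e in r1.entries.items():
        if key in r2.entries:
            unchanged.add(e.accession(r1.release_code).rendered())
        else:
            r1_only.append(e)
    for key, e in r2.entries.items():
        if key not in r1.entries:
            r2_only.append(e)

    split, merged = set(), set()
    matched_r1, matched_r2 = set(), set()
    for e1 in r1_only:
        s1 = set(e1.member_pids)
        covered = [e2 for e2 in r2_only if set(e2.member_pids) < s1]
        if len(covered) >= 2 and set().union(*(set(c.member_pids) for c in covered)) == s1:
            split.add(e1.accession(r1.release_code).rendered())
            matched_r1.add(e1.serial)
            matched_r2.update(c.serial for c in covered)
    for e2 in r2_only:
        s2 = set(e2.member_pids)
        covered = [e1 for e1 in r1_only if set(e1.member_pids) < s2]
        if len(covered) >= 2 and set().union(*(set(c.member_pids) for c in covered)) == s2:
            merged.add(e2.accession(r2.release_code).rendered())
            matched_r2.add(e2.serial)
            matched_r1.update(c.serial for c in covered)

    retired = {
        e.accession(r1.release_code).rendered() for e in r1_only if e.serial not in matched_r1
    }
    new = {
        e.accession(r2.release_code).rendered() for e in r2_only if e.serial not in matched_r2
    }
    return {"unchanged": unchanged, "split": split, "merged": merged, "new": new, "retired": retired}
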