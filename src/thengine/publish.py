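"""Export taxon datasets: per-dataset FASTA and Darwin Core checklists.

The checklist is the interchange format that carries a backbone plus its
attached SHs to biodiversity portals: ranked backbone rows, then one
``unranked`` row per SH under its nearest Latin-name parent. Column names
follow Darwin Core terms (taxonID, parentNameUsageID, scientificName,
taxonRank) in a plain TSV.
"""

from __future__ import annotations

from io import StringIO
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .backbone import Attachment, Backbone
from .records import Individual, Rank
from .registry import Release

__all__ = ["export_fasta", "export_checklist", "write_checklist", "CHECKLIST_COLUMNS"]

CHECKLIST_COLUMNS = ["taxonID", "parentNameUsageID", "scientificName", "taxonRank"]


def export_fasta(
    member_pids,
    individuals: dict[str, Individual],
    accession: str = "",
    name: str = "",
) -> str:
    """FASTA text for one SH/TH dataset.

    One record per member in sorted pid order; headers carry
    ``pid |accession|name``. Members without sequences are a hard error
    (all of them are listed).
    """
    pids = sorted(set(member_pids))
    if not pids:
        raise ValueError("cannot export an empty member set")
    missing = [p for p in pids if p not in individuals or individuals[p].sequence is None]
    if missing:
        raise ValueError(f"members without sequences: {missing}")
    records = [
        SeqRecord(Seq(individuals[p].sequence), id=p, description=f"|{accession}|{name}")
        for p in pids
    ]
    buffer = StringIO()
    SeqIO.write(records, buffer, "fasta")
    return buffer.getvalue()


def export_checklist(
    release: Release,
    backbone: Backbone,
    attachments: list[Attachment],
) -> pd.DataFrame:
    """Build the checklist table for a frozen release.

    Rows: every occupied backbone node (a node with an attached SH in its
    subtree), depth-first with name-sorted siblings, followed by one
    unranked row per SH under its attachment node. An unnamed SH's
    scientificName falls back to its rendered accession. Attachments to
    nodes absent from the backbone are a hard error.
    """
    for att in attachments:
        if att.node_id not in backbone.nodes:
            raise ValueError(f"attachment references unknown backbone node {att.node_id!r}")

    occupied: set[str] = set()
    for att in attachments:
        current: str | None = att.node_id
        while current is not None:
            occupied.add(current)
            current = backbone.nodes[current].parent_id

    shs_at: dict[str, list[Attachment]] = {}
    for att in attachments:
        shs_at.setdefault(att.node_id, []).append(att)

    accession_by_key = {
        (e.digest, e.descriptor): e.accession(release.release_code).rendered()
        for e in release.entries.values()
    }

    rows: list[dict[str, str]] = []

    def visit(node_id: str, parent_row_id: str) -> None:
        if node_id not in occupied:
            return
        node = backbone.nodes[node_id]
        rows.append(
            {
                "taxonID": node.node_id,
                "parentNameUsageID": parent_row_id,
                "scientificName": node.name,
                "taxonRank": str(node.rank),
            }
        )
        for att in sorted(shs_at.get(node_id, []), key=_attachment_sort_key):
            sh = att.sh
            rendered = _sh_accession(sh, accession_by_key)
            name = None
            if getattr(sh, "name_decision", None) is not None:
                name = sh.name_decision.taxon_name
            rows.append(
                {
                    "taxonID": rendered,
                    "parentNameUsageID": node.node_id,
                    "scientificName": name or rendered,
                    "taxonRank": "unranked",
                }
            )
        for child in sorted(backbone.children(node_id), key=lambda c: backbone.nodes[c].name):
            visit(child, node_id)

    visit(backbone.root_id, "")
    return pd.DataFrame(rows, columns=CHECKLIST_COLUMNS)


def _attachment_sort_key(att: Attachment):
    return sorted(att.sh.member_pids)


def _sh_accession(sh, accession_by_key: dict) -> str:
    from .registry import member_digest

    if getattr(sh, "accession", None) is not None:
        acc = sh.accession
        return acc.rendered() if hasattr(acc, "rendered") else str(acc)
    digest = member_digest(sh.member_pids)
    for (d, _desc), rendered in accession_by_key.items():
        if d == digest:
            return rendered
    return sh.local_id or f"SH-{digest[:12]}"


def write_checklist(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)
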