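"""Readers and writers for the plain-text formats used by the pipeline.

Formats
-------
FASTA
    Protein sequences; the header token before the first whitespace is the
    accession. Parsed with Bio.SeqIO.
Quant table (TSV)
    Columns ``accession``, ``sequence``, ``offsets`` (semicolon-joined 1-based
    positions of modified cysteines within the peptide; empty for unenriched
    records), ``plex``, then one column per reporter channel label. Empty
    cells are missing intensities, never zeros.
Layout (plain text)
    One ``[plex <id>]`` section per plex; an optional ``reference<TAB><cond>``
    line; then one line per channel: ``label<TAB>condition<TAB>replicate<TAB>
    treatment``. ``#`` starts a comment.
Annotations (TSV)
    Two columns ``class`` and ``accession``, with header.

All writers emit deterministic column and row order so that repeated runs are
byte-identical.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, Iterable, List, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datamodel import (
    AnnotationSet,
    ChannelAssignment,
    DataModelError,
    PeptideQuantRecord,
    PlexLayout,
    ProteinDatabase,
)


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> ProteinDatabase:
    """Read a protein FASTA file into a :class:`ProteinDatabase`.

    Duplicate accessions and empty sequences are rejected.
    """
    db = ProteinDatabase({})
    for record in SeqIO.parse(str(path), "fasta"):
        db.add(record.id, str(record.seq))
    if len(db) == 0:
        raise FormatError(f"{path}: no FASTA records")
    return db


def write_fasta(database: ProteinDatabase, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=acc, description="")
        for acc, seq in sorted(database.items())
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Quant tables
# ---------------------------------------------------------------------------

_META_COLUMNS = ["accession", "sequence", "offsets", "plex"]


def read_quant_table(
    path: str | Path,
    layouts: Sequence[PlexLayout],
    enriched: bool,
) -> List[PeptideQuantRecord]:
    """Read a peptide quant TSV, validating channels against the layouts.

    Every channel named by a layout must have a column; missing cells become
    missing intensities. Enriched records must carry at least one modified
    offset.
    """
    by_plex = {layout.plex_id: layout for layout in layouts}
    table = pd.read_csv(
        path, sep="\t",
        dtype={"accession": str, "sequence": str, "plex": str, "offsets": str},
    )
    for col in _META_COLUMNS:
        if col != "offsets" and col not in table.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    all_labels: List[str] = []
    for layout in layouts:
        for label in layout.channel_labels:
            if label not in all_labels:
                all_labels.append(label)
            if label not in table.columns:
                raise FormatError(
                    f"{path}: channel {label!r} named by layout "
                    f"{layout.plex_id!r} is absent from the header"
                )

    records: List[PeptideQuantRecord] = []
    for row in table.itertuples(index=False, name=None):
        # positional zip: itertuples would mangle channel names like "127N"
        rowd = dict(zip(table.columns, row))
        plex_id = str(rowd["plex"])
        if plex_id not in by_plex:
            raise FormatError(f"{path}: unknown plex {plex_id!r}")
        layout = by_plex[plex_id]
        raw_off = rowd.get("offsets", "")
        if raw_off is None or (isinstance(raw_off, float) and math.isnan(raw_off)):
            raw_off = ""
        raw_off = str(raw_off).strip()
        offsets = tuple(int(x) for x in raw_off.split(";") if x != "") if raw_off else ()
        if enriched and not offsets:
            raise FormatError(
                f"{path}: enriched record {rowd['accession']}/{rowd['sequence']} "
                "has no modified offset"
            )
        intensities: Dict[str, float] = {}
        for label in layout.channel_labels:
            value = rowd[label]
            if value is None or (isinstance(value, float) and math.isnan(value)):
                continue
            value = float(value)
            if value < 0:
                raise FormatError(
                    f"{path}: negative intensity {value} for "
                    f"{rowd['accession']}/{rowd['sequence']} channel {label!r}"
                )
            intensities[label] = value
        record = PeptideQuantRecord(
            protein_accession=str(rowd["accession"]),
            base_sequence=str(rowd["sequence"]),
            modified_offsets=offsets,
            intensities=intensities,
            plex_id=plex_id,
        )
        records.append(record.validate())
    return records


def write_quant_table(
    records: Iterable[PeptideQuantRecord],
    layouts: Sequence[PlexLayout],
    path: str | Path,
) -> None:
    """Write records to the quant-table TSV schema (missing cells left empty)."""
    labels: List[str] = []
    for layout in layouts:
        for label in layout.channel_labels:
            if label not in labels:
                labels.append(label)
    rows = []
    for rec in records:
        row: Dict[str, object] = {
            "accession": rec.protein_accession,
            "sequence": rec.base_sequence,
            "offsets": ";".join(str(o) for o in rec.modified_offsets),
            "plex": rec.plex_id,
        }
        for label in labels:
            row[label] = rec.intensities.get(label, float("nan"))
        rows.append(row)
    frame = pd.DataFrame(rows, columns=_META_COLUMNS + labels)
    frame = frame.sort_values(_META_COLUMNS, kind="mergesort").reset_index(drop=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Layouts
# ---------------------------------------------------------------------------

def read_layout(path: str | Path) -> List[PlexLayout]:
    """Parse a plain-text layout file into one :class:`PlexLayout` per section."""
    layouts: List[PlexLayout] = []
    plex_id: str | None = None
    reference = "D2"
    channels: List[ChannelAssignment] = []

    def flush() -> None:
        nonlocal channels
        if plex_id is not None:
            layouts.append(
                PlexLayout(plex_id=plex_id, channels=channels, reference_condition=reference)
            )
        channels = []

    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("["):
                if not line.endswith("]"):
                    raise FormatError(f"{path}:{lineno}: unterminated section header")
                parts = line[1:-1].split()
                if len(parts) != 2 or parts[0] != "plex":
                    raise FormatError(
                        f"{path}:{lineno}: expected '[plex <id>]', got {line!r}"
                    )
                flush()
                plex_id = parts[1]
                reference = "D2"
                continue
            fields = line.split("\t")
            if plex_id is None:
                raise FormatError(f"{path}:{lineno}: channel line before any [plex] section")
            if fields[0] == "reference":
                if len(fields) != 2:
                    raise FormatError(f"{path}:{lineno}: reference line needs one value")
                reference = fields[1]
                continue
            if len(fields) != 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 'label<TAB>condition<TAB>replicate<TAB>"
                    f"treatment', got {line!r}"
                )
            label, condition, replicate, treatment = fields
            try:
                rep = int(replicate)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: replicate {replicate!r} is not an integer")
            try:
                channels.append(
                    ChannelAssignment(
                        label=label, condition=condition, replicate=rep, treatment=treatment
                    )
                )
            except DataModelError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    flush()
    if not layouts:
        raise FormatError(f"{path}: no plex sections found")
    return layouts


def write_layout(layouts: Sequence[PlexLayout], path: str | Path) -> None:
    with open(path, "w") as handle:
        for layout in layouts:
            handle.write(f"[plex {layout.plex_id}]\n")
            handle.write(f"reference\t{layout.reference_condition}\n")
            for ch in layout.channels:
                handle.write(f"{ch.label}\t{ch.condition}\t{ch.replicate}\t{ch.treatment}\n")
            handle.write("\n")


# ---------------------------------------------------------------------------
# Annotations and generic tables
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> AnnotationSet:
    table = pd.read_csv(path, sep="\t", dtype=str)
    if list(table.columns[:2]) != ["class", "accession"]:
        raise FormatError(f"{path}: expected columns 'class' and 'accession'")
    annotations = AnnotationSet()
    for name, group in table.groupby("class", sort=True):
        annotations.add_class(str(name), group["accession"].tolist())
    return annotations


def write_annotations(annotations: AnnotationSet, path: str | Path) -> None:
    rows = [
        {"class": name, "accession": acc}
        for name, members in sorted(annotations.items())
        for acc in sorted(members)
    ]
    pd.DataFrame(rows, columns=["class", "accession"]).to_csv(path, sep="\t", index=False)


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write any result table as TSV with stable column order."""
    frame.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
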