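"""Shared data model for multiplexed cysteine-reactivity experiments.

The containers here are deliberately small: a :class:`PlexLayout` describes how
the reporter channels of one isobaric (TMT) plex map onto biological
conditions, replicates and lysate treatments; a :class:`PeptideQuantRecord` is
one quantified peptide observation (probe-enriched or unenriched) with its
per-channel reporter intensities; :class:`ProteinDatabase` and
:class:`AnnotationSet` carry the protein sequences and protein-class
annotations needed to place modified cysteines and to interpret hit lists.
Heavy lifting (normalization, rollup, calling) happens on long-format pandas
frames derived from these records; see :mod:`cysreact.quant`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Set, Tuple

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
VALID_AA = frozenset(STANDARD_AA) | {"X"}

#: Allowed lysate treatments for a channel. "none" is the control arm;
#: "ATP" marks nucleotide add-back channels; "inhibitor" marks covalent
#: electrophile competition channels.
TREATMENTS = frozenset({"none", "ATP", "inhibitor"})


class DataModelError(ValueError):
    """Invalid content for one of the shared data types."""


@dataclass(frozen=True)
class ChannelAssignment:
    """One reporter channel of a plex: label, condition, replicate, treatment."""

    label: str
    condition: str
    replicate: int
    treatment: str = "none"

    def __post_init__(self) -> None:
        if not self.label:
            raise DataModelError("channel label must be nonempty")
        if not self.condition:
            raise DataModelError(f"channel {self.label!r}: condition must be nonempty")
        if self.replicate < 1:
            raise DataModelError(
                f"channel {self.label!r}: replicate must be >= 1, got {self.replicate}"
            )
        if self.treatment not in TREATMENTS:
            raise DataModelError(
                f"channel {self.label!r}: treatment {self.treatment!r} not in {sorted(TREATMENTS)}"
            )


@dataclass
class PlexLayout:
    """Channel -> (condition, replicate, treatment) map for one TMT plex.

    The reference condition (activated T cells, "D2", by default) must be
    present in every plex so that within-plex ratios to the reference are
    always computable.
    """

    plex_id: str
    channels: List[ChannelAssignment]
    reference_condition: str = "D2"

    def __post_init__(self) -> None:
        if not self.plex_id:
            raise DataModelError("plex_id must be nonempty")
        if not self.channels:
            raise DataModelError(f"plex {self.plex_id!r}: no channels")
        labels = [c.label for c in self.channels]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise DataModelError(f"plex {self.plex_id!r}: duplicate channel labels {dupes}")
        if self.reference_condition not in {c.condition for c in self.channels}:
            raise DataModelError(
                f"plex {self.plex_id!r}: reference condition "
                f"{self.reference_condition!r} has no channel"
            )

    @property
    def channel_labels(self) -> List[str]:
        return [c.label for c in self.channels]

    @property
    def conditions(self) -> List[str]:
        seen: List[str] = []
        for c in self.channels:
            if c.condition not in seen:
                seen.append(c.condition)
        return seen

    def channels_for(self, condition: str, treatment: str | None = None) -> List[ChannelAssignment]:
        return [
            c
            for c in self.channels
            if c.condition == condition and (treatment is None or c.treatment == treatment)
        ]


@dataclass
class PeptideQuantRecord:
    """One quantified peptide with per-channel reporter intensities.

    ``modified_offsets`` are 1-based positions of probe-modified cysteines
    within ``base_sequence``; unenriched (whole-proteome) records carry an
    empty tuple. Missing channels are simply absent from ``intensities`` —
    they are never encoded as zeros.
    """

    protein_accession: str
    base_sequence: str
    modified_offsets: Tuple[int, ...]
    intensities: Dict[str, float]
    plex_id: str

    def validate(self) -> "PeptideQuantRecord":
        if not self.protein_accession:
            raise DataModelError("protein_accession must be nonempty")
        if not self.base_sequence:
            raise DataModelError("base_sequence must be nonempty")
        for off in self.modified_offsets:
            if off < 1 or off > len(self.base_sequence):
                raise DataModelError(
                    f"{self.protein_accession}/{self.base_sequence}: offset {off} out of range"
                )
            if self.base_sequence[off - 1] != "C":
                raise DataModelError(
                    f"{self.protein_accession}/{self.base_sequence}: offset {off} "
                    f"points at {self.base_sequence[off - 1]!r}, expected 'C'"
                )
        if not self.intensities:
            raise DataModelError(
                f"{self.protein_accession}/{self.base_sequence}: no intensity present"
            )
        for label, value in self.intensities.items():
            if value < 0:
                raise DataModelError(
                    f"{self.protein_accession}/{self.base_sequence}: negative intensity "
                    f"{value} in channel {label!r}"
                )
        return self


class ProteinDatabase:
    """Accession -> full amino-acid sequence, with alphabet validation."""

    def __init__(self, sequences: Mapping[str, str]):
        self._sequences: Dict[str, str] = {}
        for accession, seq in sequences.items():
            self.add(accession, seq)

    def add(self, accession: str, sequence: str) -> None:
        if accession in self._sequences:
            raise DataModelError(f"duplicate accession {accession!r}")
        if not sequence:
            raise DataModelError(f"accession {accession!r}: empty sequence")
        bad = set(sequence) - VALID_AA
        if bad:
            raise DataModelError(
                f"accession {accession!r}: invalid residues {sorted(bad)}"
            )
        self._sequences[accession] = sequence

    def __getitem__(self, accession: str) -> str:
        return self._sequences[accession]

    def __contains__(self, accession: str) -> bool:
        return accession in self._sequences

    def __len__(self) -> int:
        return len(self._sequences)

    def __iter__(self):
        return iter(self._sequences)

    def items(self):
        return self._sequences.items()

    def __eq__(self, other) -> bool:
        return isinstance(other, ProteinDatabase) and self._sequences == other._sequences


class AnnotationSet:
    """Protein-class annotations: class name -> set of accessions.

    Classes may overlap (a protein can be both mitochondrial and
    nucleotide-binding); class names are unique.
    """

    def __init__(self, classes: Mapping[str, Iterable[str]] | None = None):
        self._classes: Dict[str, Set[str]] = {}
        if classes:
            for name, members in classes.items():
                self.add_class(name, members)

    def add_class(self, name: str, members: Iterable[str]) -> None:
        if not name:
            raise DataModelError("class name must be nonempty")
        if name in self._classes:
            raise DataModelError(f"duplicate class name {name!r}")
        self._classes[name] = set(members)

    @property
    def class_names(self) -> List[str]:
        return sorted(self._classes)

    def members(self, name: str) -> Set[str]:
        return set(self._classes[name])

    def classes_of(self, accession: str) -> List[str]:
        return sorted(n for n, m in self._classes.items() if accession in m)

    def __len__(self) -> int:
        return len(self._classes)

    def __contains__(self, name: str) -> bool:
        return name in self._classes

    def items(self):
        return self._classes.items()

    def __eq__(self, other) -> bool:
        return isinstance(other, AnnotationSet) and self._classes == other._classes
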