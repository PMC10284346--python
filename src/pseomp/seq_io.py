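"""Reading, validating and labelling protein sequences.

Sequences are plain strings over the 20 standard amino-acid letters.
Non-standard residues (B, J, O, U, X, Z, gaps, ``*``) are handled by a
validation *policy*:

``strict``
    reject the record (default; the pseudo amino acid composition is
    defined only over the 20 standard residues),
``drop``
    delete offending characters and warn,
``map``
    apply conservative substitutions (B→D, Z→E, U→C), drop anything else.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Alphabetically ordered single-letter codes of the 20 standard amino acids.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

_AMBIGUITY_MAP = {"B": "D", "Z": "E", "U": "C"}

POLICIES = ("strict", "drop", "map")


class Label(str, Enum):
    """Class label of a protein record."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"


class SequenceValidationError(ValueError):
    """Raised when a sequence violates the residue alphabet under ``strict``."""


@dataclass(frozen=True)
class ProteinRecord:
    """One validated amino-acid sequence with an optional class label."""

    id: str
    sequence: str
    label: Label = Label.UNKNOWN

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise SequenceValidationError(
                f"record {self.id!r}: non-standard residue(s) "
                f"{sorted(bad)} (use a validation policy)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class DatasetManifest:
    """Ordered collection of labelled records.

    Record order is stable so that leave-one-out fold order is
    deterministic.
    """

    records: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate record id {rec.id!r} in manifest")
            seen.add(rec.id)

    @property
    def n_pos(self) -> int:
        return sum(1 for r in self.records if r.label is Label.POSITIVE)

    @property
    def n_neg(self) -> int:
        return sum(1 for r in self.records if r.label is Label.NEGATIVE)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def labels(self) -> list[int]:
        """0/1 vector in record order (positive → 1)."""
        return [1 if r.label is Label.POSITIVE else 0 for r in self.records]


def clean_sequence(seq: str, *, policy: str = "strict", record_id: str = "?") -> str:
    """Upper-case and apply the residue-validation policy to one sequence."""
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    seq = seq.upper().replace("-", "").replace(".", "").replace("*", "")
    bad = [c for c in seq if c not in _AA_SET]
    if not bad:
        return seq
    if policy == "strict":
        raise SequenceValidationError(
            f"record {record_id!r}: non-standard residue(s) "
            f"{sorted(set(bad))} under strict policy"
        )
    out = []
    dropped = []
    for c in seq:
        if c in _AA_SET:
            out.append(c)
        elif policy == "map" and c in _AMBIGUITY_MAP:
            out.append(_AMBIGUITY_MAP[c])
        else:
            dropped.append(c)
    if dropped:
        warnings.warn(
            f"record {record_id!r}: dropped {len(dropped)} non-standard "
            f"residue(s) {sorted(set(dropped))}",
            stacklevel=2,
        )
    return "".join(out)


def read_fasta(
    path: str | Path,
    label: Label | str = Label.UNKNOWN,
    *,
    policy: str = "strict",
) -> list[ProteinRecord]:
    """Read a FASTA file and return labelled, validated records.

    Raises on empty files, duplicate ids, and records left with zero
    valid residues after cleaning.
    """
    label = Label(label)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate FASTA id {entry.id!r} in {path}")
        seen.add(entry.id)
        seq = clean_sequence(str(entry.seq), policy=policy, record_id=entry.id)
        if not seq:
            raise ValueError(
                f"record {entry.id!r} in {path} has no valid residues after cleaning"
            )
        records.append(ProteinRecord(id=entry.id, sequence=seq, label=label))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA (unwrapped lines, byte-stable round trip)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=None)
        writer.write_file(seq_records)


def read_labels_tsv(path: str | Path) -> dict[str, Label]:
    """Read a two-column (id, label) TSV into a mapping."""
    labels: dict[str, Label] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            rec_id, lab = parts
            if rec_id in labels:
                raise ValueError(f"{path}:{lineno}: duplicate id {rec_id!r}")
            labels[rec_id] = Label(lab)
    if not labels:
        raise ValueError(f"no labels found in {path}")
    return labels


def write_labels_tsv(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.id}\t{r.label.value}\n")


def apply_labels(
    records: Sequence[ProteinRecord], labels: dict[str, Label]
) -> list[ProteinRecord]:
    """Relabel records from an (id → label) mapping; unknown ids are errors."""
    out = []
    for r in records:
        if r.id not in labels:
            raise ValueError(f"no label for record {r.id!r} in label manifest")
        out.append(ProteinRecord(id=r.id, sequence=r.sequence, label=labels[r.id]))
    return out


def build_manifest(
    pos_records: Sequence[ProteinRecord],
    neg_records: Sequence[ProteinRecord],
) -> DatasetManifest:
    """Concatenate positives then negatives into an order-stable manifest."""
    for r in pos_records:
        if r.label is not Label.POSITIVE:
            raise ValueError(f"record {r.id!r} in pos_records has label {r.label.value}")
    for r in neg_records:
        if r.label is not Label.NEGATIVE:
            raise ValueError(f"record {r.id!r} in neg_records has label {r.label.value}")
    return DatasetManifest(records=list(pos_records) + list(neg_records))
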