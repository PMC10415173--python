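"""Sequence and label-table input/output.

Reads FASTA/FASTQ into lightweight records, joins them with a TSV label
table at one taxonomic rank, and cuts long sequences into the fixed-length
fragments the downstream feature extraction expects (1500 nt by default,
the typical length of a metagenomic pseudo-read in this pipeline).

Coordinates are 0-based half-open throughout. Sequences are normalized to
upper-case DNA (``U`` becomes ``T``); IUPAC ambiguity codes are kept and
handled later, at k-mer counting time.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "SeqRecord",
    "LabeledDataset",
    "SequenceIOError",
    "read_fasta",
    "read_fastq",
    "write_fasta",
    "read_labels",
    "fragment",
    "attach_labels",
]

KNOWN_RANKS = ("superkingdom", "phylum", "genus")


class SequenceIOError(ValueError):
    """Raised for malformed FASTA/FASTQ/label-table input."""


@dataclass(frozen=True)
class SeqRecord:
    """One named DNA sequence (upper-case, ``U`` already folded to ``T``)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceIOError("record id must be non-empty")
        if not self.sequence:
            raise SequenceIOError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LabeledDataset:
    """Parallel records and taxon labels at a single rank.

    ``rank`` is informational; labels are opaque strings and the class set
    is simply the set of distinct labels.
    """

    records: list = field(default_factory=list)
    labels: list = field(default_factory=list)
    rank: str | None = None

    def __post_init__(self) -> None:
        if len(self.records) != len(self.labels):
            raise ValueError(
                f"records ({len(self.records)}) and labels ({len(self.labels)}) differ in length"
            )
        for lab in self.labels:
            if not isinstance(lab, str) or not lab:
                raise ValueError("every label must be a non-empty string")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _validate_fasta_head(path: Path) -> None:
    """Cheap structural pre-check so errors carry a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise SequenceIOError(
                    f"{path}: line {lineno}: expected FASTA header starting with '>'"
                )
            return
    raise SequenceIOError(f"{path}: line 1: empty file, no FASTA records")


def _collect(path: Path, fmt: str) -> list[SeqRecord]:
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), fmt):
        if rec.id in seen:
            raise SequenceIOError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SeqRecord(id=rec.id, sequence=_normalize(str(rec.seq))))
    if not records:
        raise SequenceIOError(f"{path}: no {fmt.upper()} records found")
    return records


def read_fasta(path) -> list[SeqRecord]:
    """Read a (possibly multi-line) FASTA file, preserving record order.

    Raises :class:`SequenceIOError` on empty input, a non-FASTA first line
    (with its line number), or duplicate ids (naming the id).
    """
    path = Path(path)
    _validate_fasta_head(path)
    return _collect(path, "fasta")


def read_fastq(path) -> list[SeqRecord]:
    """Read FASTQ; qualities are discarded (the pipeline never uses them)."""
    return _collect(Path(path), "fastq")


def write_fasta(records: Iterable[SeqRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_labels(path) -> dict[str, str]:
    """Read a two-column TSV (id, label) into a dict.

    Lines starting with ``#`` and a literal ``id<TAB>label`` header are
    skipped. A row with a missing label raises with its line number.
    """
    path = Path(path)
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and row[0].strip() == ""):
                continue
            if row[0].startswith("#"):
                continue
            if lineno == 1 and row[0].strip().lower() == "id":
                continue
            if len(row) < 2 or row[1].strip() == "":
                raise SequenceIOError(f"{path}: line {lineno}: missing label")
            rid = row[0].strip()
            if rid in out:
                raise SequenceIOError(f"{path}: duplicate id {rid!r} in label table")
            out[rid] = row[1].strip()
    if not out:
        raise SequenceIOError(f"{path}: label table is empty")
    return out


def fragment(records: Iterable[SeqRecord], length: int) -> list[SeqRecord]:
    """Cut each record into consecutive non-overlapping windows of ``length``.

    A trailing remainder shorter than ``length`` is dropped; a record
    shorter than ``length`` yields no fragments. Fragment ids are
    ``<parent>:<start>-<end>`` in 0-based half-open coordinates.
    """
    if length < 1:
        raise ValueError("fragment length must be >= 1")
    out: list[SeqRecord] = []
    for rec in records:
        n_frag = len(rec.sequence) // length
        for j in range(n_frag):
            start, end = j * length, (j + 1) * length
            out.append(SeqRecord(id=f"{rec.id}:{start}-{end}", sequence=rec.sequence[start:end]))
    return out


def attach_labels(
    records: Sequence[SeqRecord],
    label_map: Mapping[str, str],
    rank: str | None = None,
) -> LabeledDataset:
    """Join records to labels by id; the join must be total."""
    labels = []
    for rec in records:
        if rec.id not in label_map:
            raise SequenceIOError(f"no label for record {rec.id!r}")
        labels.append(label_map[rec.id])
    return LabeledDataset(records=list(records), labels=labels, rank=rank)
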