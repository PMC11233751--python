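"""Readers and writers for the standard formats the pipeline touches.

Conventions
-----------
* All in-memory coordinates are 0-based half-open; GFF3 on disk is 1-based
  inclusive (converted on the way in and out).
* Residues are upper-cased on input and IUPAC ambiguity codes other than N
  are collapsed to N: downstream tallying treats non-ACGT as unusable, so
  nothing is gained by carrying the full code table around.
* FASTQ is streamed (NovaSeq-scale libraries in the motivating study);
  FASTA and GFF3 are small (references, annotations) and loaded whole.

FASTA/FASTQ parsing is delegated to Biopython; GFF3 line parsing to
gffutils. This module only enforces the pipeline's own invariants on top.
"""
from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from gffutils.feature import feature_from_line

from . import _dna
from .errors import AlignmentError, FormatError

__all__ = [
    "SequenceRecord",
    "ReadRecord",
    "ReadBatch",
    "Feature",
    "Alignment",
    "parse_fasta",
    "write_fasta",
    "parse_fastq",
    "write_fastq",
    "parse_gff3",
    "write_gff3",
    "read_alignment",
    "write_alignment",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class SequenceRecord:
    """A named DNA sequence over {A, C, G, T, N, -}."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.residues:
            raise FormatError(f"sequence record {self.id!r} has no residues")
        self.residues = _dna.normalize(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ReadRecord:
    """One sequencing read with per-base Phred quality scores.

    ``mate`` is 1 or 2 for paired reads and 0 for unpaired.
    """

    id: str
    sequence: str
    qualities: Sequence[int]
    mate: int = 0

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise FormatError(
                f"read {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )
        if self.mate not in (0, 1, 2):
            raise FormatError(f"read {self.id!r}: mate must be 0, 1 or 2")
        self.sequence = _dna.normalize(self.sequence, allow_gap=False)


@dataclass
class ReadBatch:
    """A column-packed batch of equal-length reads for the vectorised paths.

    ``seqs`` is an (n_reads, read_length) uint8 array of ASCII codes. The
    scalar API works on :class:`ReadRecord`; simulators and the tallying hot
    path use this to avoid materialising millions of Python objects.
    """

    seqs: np.ndarray
    mate: int = 0
    quality: int = 30
    id_prefix: str = "read"

    def __post_init__(self) -> None:
        if self.seqs.ndim != 2 or self.seqs.dtype != np.uint8:
            raise ValueError("ReadBatch.seqs must be a 2-D uint8 array")

    def __len__(self) -> int:
        return self.seqs.shape[0]

    @property
    def read_length(self) -> int:
        return self.seqs.shape[1]

    def to_records(self) -> Iterator[ReadRecord]:
        quals = [self.quality] * self.read_length
        for i in range(len(self)):
            yield ReadRecord(
                id=f"{self.id_prefix}{i:07d}",
                sequence=_dna.decode(self.seqs[i]),
                qualities=quals,
                mate=self.mate,
            )

    @classmethod
    def from_records(cls, reads: Iterable[ReadRecord]) -> "ReadBatch":
        seqs = [_dna.encode(r.sequence) for r in reads]
        if not seqs:
            return cls(seqs=np.zeros((0, 0), dtype=np.uint8))
        lengths = {s.size for s in seqs}
        if len(lengths) != 1:
            raise ValueError("ReadBatch requires equal-length reads")
        return cls(seqs=np.vstack(seqs))


@dataclass
class Feature:
    """An annotated interval, stored 0-based half-open."""

    seqid: str
    start: int
    end: int
    strand: str
    type: str
    name: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"feature {self.name!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"feature {self.name!r}: unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Alignment:
    """A multiple sequence alignment: equal-length gapped rows."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) < 2:
            raise AlignmentError("alignment needs at least 2 taxa")
        if len(self.taxa) != len(set(self.taxa)):
            raise AlignmentError("duplicate taxon ids in alignment")
        if len(self.rows) != len(self.taxa):
            raise AlignmentError("taxa/rows length mismatch")
        width = len(self.rows[0])
        for taxon, row in zip(self.taxa, self.rows):
            if len(row) != width:
                raise AlignmentError(
                    f"taxon {taxon!r} has row length {len(row)}, expected {width}"
                )
        self.rows = [_dna.normalize(r) for r in self.rows]

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def to_matrix(self) -> np.ndarray:
        """(n_taxa, length) uint8 matrix of ASCII codes."""
        return np.frombuffer("".join(self.rows).encode("ascii"), dtype=np.uint8).reshape(
            len(self.taxa), self.length
        )


# ---------------------------------------------------------------------------
# FASTA


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def parse_fasta(path) -> list[SequenceRecord]:
    """Read a (possibly wrapped) multi-record FASTA file."""
    with _open_text(path) as handle:
        text = handle.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip() == "":
            continue
        if not line.startswith(">"):
            raise FormatError(f"{path}: line {lineno}: expected FASTA header")
        break
    else:
        raise FormatError(f"{path}: empty FASTA file")
    records = []
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        if not str(rec.seq):
            raise FormatError(f"{path}: record {rec.id!r} has no residues")
        records.append(
            SequenceRecord(id=rec.id, residues=str(rec.seq), description=rec.description)
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    with _open_text(path, "wt") as out:
        for rec in records:
            header = rec.description if rec.description.startswith(rec.id) else rec.id
            out.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                out.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ


def _infer_mate(title: str) -> tuple[str, int]:
    name = title.split()[0]
    if name.endswith("/1"):
        return name[:-2], 1
    if name.endswith("/2"):
        return name[:-2], 2
    return name, 0


def parse_fastq(path) -> Iterator[ReadRecord]:
    """Stream a 4-line Phred+33 FASTQ file (.gz transparent)."""
    with _open_text(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            name, mate = _infer_mate(title)
            yield ReadRecord(
                id=name,
                sequence=seq,
                qualities=[ord(q) - 33 for q in qual],
                mate=mate,
            )


def write_fastq(reads: ReadBatch | Iterable[ReadRecord], path) -> None:
    with _open_text(path, "wt") as out:
        if isinstance(reads, ReadBatch):
            qual = chr(reads.quality + 33) * reads.read_length
            suffix = f"/{reads.mate}" if reads.mate else ""
            for i in range(len(reads)):
                out.write(
                    f"@{reads.id_prefix}{i:07d}{suffix}\n"
                    f"{_dna.decode(reads.seqs[i])}\n+\n{qual}\n"
                )
        else:
            for read in reads:
                suffix = f"/{read.mate}" if read.mate else ""
                qual = "".join(chr(q + 33) for q in read.qualities)
                out.write(f"@{read.id}{suffix}\n{read.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# GFF3


def parse_gff3(path) -> list[Feature]:
    """Read gene/tRNA/rRNA features from a GFF3 file, sorted by start."""
    features: list[Feature] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                gff = feature_from_line(line)
            except Exception as exc:  # gffutils raises bare ValueError subclasses
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if gff.end < gff.start:
                raise FormatError(
                    f"{path}: line {lineno}: end {gff.end} < start {gff.start}"
                )
            if gff.strand not in ("+", "-"):
                raise FormatError(
                    f"{path}: line {lineno}: unknown strand {gff.strand!r}"
                )
            attrs = gff.attributes
            name = (attrs.get("Name") or attrs.get("gene") or attrs.get("ID") or [""])[0]
            features.append(
                Feature(
                    seqid=gff.seqid,
                    start=gff.start - 1,
                    end=gff.end,
                    strand=gff.strand,
                    type=gff.featuretype,
                    name=name,
                )
            )
    features.sort(key=lambda f: (f.start, f.end, f.name))
    return features


def write_gff3(features: Iterable[Feature], path, source: str = "amphihap") -> None:
    with _open_text(path, "wt") as out:
        out.write("##gff-version 3\n")
        for f in sorted(features, key=lambda f: (f.start, f.end, f.name)):
            out.write(
                "\t".join(
                    [
                        f.seqid,
                        source,
                        f.type,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        f"ID={f.name};Name={f.name}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# aligned FASTA


def read_alignment(path) -> Alignment:
    records = parse_fasta(path)
    if len(records) < 2:
        raise AlignmentError(f"{path}: alignment needs at least 2 taxa")
    width = len(records[0].residues)
    for rec in records:
        if len(rec.residues) != width:
            raise AlignmentError(
                f"{path}: taxon {rec.id!r} has length {len(rec.residues)}, "
                f"expected {width}"
            )
    return Alignment(taxa=[r.id for r in records], rows=[r.residues for r in records])


def write_alignment(aln: Alignment, path) -> None:
    write_fasta(
        (SequenceRecord(id=t, residues=r) for t, r in zip(aln.taxa, aln.rows)), path
    )
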