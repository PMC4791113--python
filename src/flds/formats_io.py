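"""Sequence-format I/O and coverage computation.

Conventions shared by the whole pipeline:

* coordinates are 0-based, half-open everywhere in memory; the only place
  a 1-based coordinate appears is SAM ingestion/emission (per the SAM spec);
* sequences are uppercase DNA over ``{A, C, G, T, N}``; ``U`` is accepted on
  input and normalized to ``T``;
* FASTQ qualities are Phred+33;
* only primary, mapped alignments are retained from SAM.

FASTA/FASTQ parsing is done line-by-line here rather than through a library
reader so that format errors can name the offending line, which the
validation contract requires.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pysam

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_VALID_BASES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised for malformed FASTA/FASTQ/SAM/TSV input."""


@dataclass
class SequenceRecord:
    """A contig or genome segment: id, DNA sequence, free-text description."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if len(self.sequence) < 1:
            raise FormatError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SequenceRead:
    """A sequencing read with per-base Phred quality scores.

    ``mate`` is 1 or 2 for paired-end reads, ``None`` for unpaired.
    """

    id: str
    sequence: str
    qualities: list[int]
    mate: int | None = None

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise FormatError(
                f"read {self.id!r}: quality length {len(self.qualities)} != "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Alignment:
    """Placement of a read on a contig, 0-based half-open on the contig.

    ``strand`` is '+' when the read sequence matches the contig forward
    strand, '-' when its reverse complement does.
    """

    read_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"
    n_mismatches: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"alignment {self.read_id!r}: invalid interval "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise ValueError(f"alignment {self.read_id!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CoverageVector:
    """Per-base read depth along one contig."""

    contig_id: str
    depth: np.ndarray = field(repr=False)

    def mean(self) -> float:
        return float(np.mean(self.depth))

    def min(self) -> int:
        return int(np.min(self.depth))

    def __len__(self) -> int:
        return len(self.depth)


# ---------------------------------------------------------------------------
# FASTA


def _normalize_sequence(raw: str, lineno: int) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise FormatError(
            f"line {lineno}: invalid nucleotide(s) {sorted(bad)!r}"
        )
    return seq


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Parse a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased and U is normalized to T.  Duplicate ids,
    empty sequences and headerless sequence lines raise :class:`FormatError`
    naming the line.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"line {header_line}: record {header!r} has no sequence")
        name, _, desc = header.partition(" ")
        if name in seen:
            raise FormatError(f"line {header_line}: duplicate record id {name!r}")
        seen.add(name)
        records.append(SequenceRecord(id=name, sequence=seq, description=desc))

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"line {lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FormatError(f"line {lineno}: sequence before any header")
                chunks.append(_normalize_sequence(line.strip(), lineno))
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ (4-line records, Phred+33)


def read_fastq(path: str | os.PathLike, mate: int | None = None) -> list[SequenceRead]:
    """Parse a 4-line-record FASTQ file; qualities decoded from Phred+33."""
    reads: list[SequenceRead] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4 != 0:
        raise FormatError(
            f"line {len(lines)}: truncated FASTQ record (line count not a multiple of 4)"
        )
    for i in range(0, len(lines), 4):
        lineno = i + 1
        head, seq, plus, qual = lines[i:i + 4]
        if not head.startswith("@"):
            raise FormatError(f"line {lineno}: expected '@' header, got {head[:20]!r}")
        if not plus.startswith("+"):
            raise FormatError(f"line {lineno + 2}: expected '+' separator")
        if len(seq) != len(qual):
            raise FormatError(
                f"line {lineno + 3}: quality length {len(qual)} != sequence length {len(seq)}"
            )
        seq = _normalize_sequence(seq, lineno + 1)
        reads.append(SequenceRead(
            id=head[1:].split()[0],
            sequence=seq,
            qualities=[ord(c) - 33 for c in qual],
            mate=mate,
        ))
    return reads


def write_fastq(reads: Iterable[SequenceRead], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.qualities)
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# SAM


def read_sam(path: str | os.PathLike) -> list[Alignment]:
    """Read primary, mapped alignments from a SAM file.

    POS is converted from SAM's 1-based convention to the pipeline's 0-based
    half-open intervals; the end coordinate is the reference end implied by
    the CIGAR (M/D/=/X consume reference).  Unmapped, secondary and
    supplementary records are skipped.
    """
    _validate_sam_references(path)
    alignments: list[Alignment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.reference_id < 0 or rec.reference_end is None:
                continue
            try:
                nm = int(rec.get_tag("NM"))
            except KeyError:
                nm = 0
            alignments.append(Alignment(
                read_id=rec.query_name,
                contig_id=rec.reference_name,
                start=rec.reference_start,
                end=rec.reference_end,
                strand="-" if rec.is_reverse else "+",
                n_mismatches=nm,
            ))
    return alignments


def _validate_sam_references(path: str | os.PathLike) -> None:
    """Reject mapped records naming a reference absent from the header
    (the underlying parser only warns and silently unmaps them)."""
    refs: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("@"):
                if line.startswith("@SQ"):
                    for field in line.rstrip("\n").split("\t"):
                        if field.startswith("SN:"):
                            refs.add(field[3:])
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 11:
                raise FormatError(f"line {lineno}: SAM record with "
                                  f"{len(fields)} fields")
            rname = fields[2]
            if rname != "*" and rname not in refs:
                raise FormatError(
                    f"line {lineno}: reference {rname!r} absent from header")


def write_sam(alignments: Sequence[Alignment], contig_lengths: dict[str, int],
              path: str | os.PathLike,
              read_sequences: dict[str, str] | None = None) -> None:
    """Write alignments as SAM v1.6 (1-based POS, ungapped CIGAR).

    The internal mapper is ungapped, so every record's CIGAR is a single
    match run.  If ``read_sequences`` is given, SEQ is emitted on the
    reference strand; otherwise SEQ is '*'.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": length} for name, length in contig_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = aln.read_id
            rec.reference_name = aln.contig_id
            rec.reference_start = aln.start
            rec.flag = 16 if aln.strand == "-" else 0
            rec.mapping_quality = 60
            length = aln.end - aln.start
            rec.cigarstring = f"{length}M"
            if read_sequences and aln.read_id in read_sequences:
                seq = read_sequences[aln.read_id]
                if aln.strand == "-":
                    seq = reverse_complement(seq)
                rec.query_sequence = seq
                rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            rec.set_tag("NM", aln.n_mismatches)
            out.write(rec)


# ---------------------------------------------------------------------------
# Coverage


def compute_coverage(alignments: Sequence[Alignment], contig_length: int,
                     contig_id: str | None = None) -> CoverageVector:
    """Per-base depth: ``depth[i]`` = number of alignments with start <= i < end.

    All alignments must lie on a single contig and within its bounds.
    """
    if contig_id is None:
        contig_id = alignments[0].contig_id if alignments else ""
    diff = np.zeros(contig_length + 1, dtype=np.int64)
    for aln in alignments:
        if aln.contig_id != contig_id and contig_id:
            raise ValueError(
                f"alignment on {aln.contig_id!r} mixed into coverage of {contig_id!r}"
            )
        if aln.end > contig_length:
            raise ValueError(
                f"alignment {aln.read_id!r} end {aln.end} exceeds contig length "
                f"{contig_length}"
            )
        diff[aln.start] += 1
        diff[aln.end] -= 1
    return CoverageVector(contig_id=contig_id, depth=np.cumsum(diff[:-1]))


# ---------------------------------------------------------------------------
# TSV sidecars

def write_tsv(rows: Iterable[dict], path: str | os.PathLike,
              columns: Sequence[str] | None = None) -> None:
    """Write dict rows as a TSV with a header row (pandas-backed)."""
    import pandas as pd

    df = pd.DataFrame(list(rows))
    if columns is not None:
        df = df.reindex(columns=list(columns))
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | os.PathLike):
    import pandas as pd

    return pd.read_csv(path, sep="\t")
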