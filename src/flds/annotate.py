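"""Genome characterization scans: ORFs, ribosomal frameshift signals,
poly(A) tails and mitovirus-style UGA read-through.

Frameshift-signal classes (scanned in RNA space, T read as U):

* ``minus1_XXXYYYZ`` — the -1 slippery heptamer: XXX any three identical
  nucleotides, YYY either AAA or UUU, Z one of A, U, C;
* ``plus1_CCCUUUU`` — the +1 signal CCCUUUU;
* ``plus1_UCCUUUCGU`` — the +1 signal UCCUUUCGU.

A window can satisfy several classes (CCCUUUU is also a valid -1 heptamer
with XXX=CCC, YYY=UUU, Z=U); every satisfied class is reported separately.

The UGA read-through count supports recognizing mitovirus-like segments:
genomes translated by mold-mitochondrial-style decoding read UGA as
tryptophan, so their coding strand shows a long open frame interrupted by
multiple in-frame UGA codons under the standard code.
"""

from __future__ import annotations

from dataclasses import dataclass

from flds.formats_io import SequenceRecord, reverse_complement

STOP_CODONS = {"TAA", "TAG", "TGA"}
MITO_STOP_CODONS = {"TAA", "TAG"}  # UGA decoded as Trp


@dataclass
class Orf:
    """An ATG-initiated open reading frame, 0-based half-open on ``strand``.

    Coordinates are on the forward strand of the contig; for ``strand == '-'``
    they delimit the region whose reverse complement is the ORF.  ``end``
    includes the stop codon when one is present (``complete`` is False when
    the frame runs off the contig edge).
    """

    contig_id: str
    start: int
    end: int
    strand: str
    frame: int
    complete: bool = True

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    @property
    def length_aa(self) -> int:
        return self.length_nt // 3 - (1 if self.complete else 0)


@dataclass
class FrameshiftHit:
    contig_id: str
    position: int
    strand: str
    motif_class: str
    matched_string: str


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def is_minus1_heptamer(window: str) -> bool:
    """Slippery-site predicate on a 7-mer in RNA space."""
    w = _rna(window)
    if len(w) != 7:
        return False
    return (
        w[0] == w[1] == w[2]
        and w[0] in "ACGU"
        and w[3:6] in ("AAA", "UUU")
        and w[6] in "AUC"
    )


def classify_window(window: str) -> list[str]:
    """All frameshift-signal classes satisfied by a window (may be empty)."""
    w = _rna(window)
    classes: list[str] = []
    if len(w) == 7 and is_minus1_heptamer(w):
        classes.append("minus1_XXXYYYZ")
    if len(w) == 7 and w == "CCCUUUU":
        classes.append("plus1_CCCUUUU")
    if len(w) == 9 and w == "UCCUUUCGU":
        classes.append("plus1_UCCUUUCGU")
    return classes


def scan_frameshift_signals(
    sequence: str | SequenceRecord,
    region: tuple[int, int] | None = None,
    contig_id: str = "",
    both_strands: bool = False,
) -> list[FrameshiftHit]:
    """Scan for -1/+1 ribosomal frameshift signals.

    ``region`` restricts the scan to a half-open interval (e.g. the region
    upstream of the 2nd CDS); default is the whole sequence.  Windows
    satisfying several classes yield one hit per class.  With
    ``both_strands`` the reverse strand is scanned too; reverse hits carry
    reverse-strand coordinates (position of the window start on the reverse
    complement), so no hit is ever double-counted.
    """
    if isinstance(sequence, SequenceRecord):
        contig_id = contig_id or sequence.id
        sequence = sequence.sequence
    seq = sequence.upper().replace("U", "T")
    if region is None:
        region = (0, len(seq))
    lo, hi = region
    if not (0 <= lo <= hi <= len(seq)):
        raise ValueError(f"region {region} outside sequence of length {len(seq)}")

    def scan_strand(s: str, strand: str, offset: int) -> list[FrameshiftHit]:
        hits = []
        for width in (7, 9):
            for p in range(len(s) - width + 1):
                window = s[p:p + width]
                for cls in classify_window(window):
                    hits.append(FrameshiftHit(
                        contig_id=contig_id,
                        position=p + offset,
                        strand=strand,
                        motif_class=cls,
                        matched_string=_rna(window),
                    ))
        return hits

    sub = seq[lo:hi]
    hits = scan_strand(sub, "+", lo)
    if both_strands:
        hits.extend(scan_strand(reverse_complement(sub), "-", 0))
    hits.sort(key=lambda h: (h.strand, h.position, h.motif_class))
    return hits


def find_orfs(sequence: str | SequenceRecord, min_aa: int = 100,
              contig_id: str = "") -> list[Orf]:
    """All ATG-initiated ORFs of at least ``min_aa`` codons, both strands.

    Every qualifying ATG is reported, so nested/overlapping ORFs all appear.
    ORFs running off the contig edge without a stop are reported with
    ``complete=False``.  Results are sorted by forward-strand start.
    """
    if isinstance(sequence, SequenceRecord):
        contig_id = contig_id or sequence.id
        sequence = sequence.sequence
    seq = sequence.upper().replace("U", "T")
    n = len(seq)
    orfs: list[Orf] = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for frame in range(3):
            p = frame
            starts: list[int] = []
            while p + 3 <= n:
                codon = s[p:p + 3]
                if codon == "ATG":
                    starts.append(p)
                if codon in STOP_CODONS:
                    for st in starts:
                        _emit(orfs, contig_id, strand, frame, st, p + 3, True,
                              min_aa, n)
                    starts = []
                p += 3
            for st in starts:  # ran off the edge with no stop
                edge = st + ((n - st) // 3) * 3
                _emit(orfs, contig_id, strand, frame, st, edge, False, min_aa, n)
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def _emit(orfs: list[Orf], contig_id: str, strand: str, frame: int,
          start: int, end: int, complete: bool, min_aa: int, n: int) -> None:
    aa = (end - start) // 3 - (1 if complete else 0)
    if aa < min_aa:
        return
    if strand == "+":
        fstart, fend = start, end
    else:  # map back to forward-strand coordinates
        fstart, fend = n - end, n - start
    orfs.append(Orf(contig_id=contig_id, start=fstart, end=fend, strand=strand,
                    frame=frame, complete=complete))


def upstream_of_second_cds(orfs: list[Orf]) -> tuple[int, int] | None:
    """Interval from the 1st CDS start to the 2nd CDS start (forward strand).

    The two leading CDSs are approximated by the two longest forward-strand
    ORFs in start order; returns None when fewer than two exist.
    """
    fwd = sorted([o for o in orfs if o.strand == "+"],
                 key=lambda o: (o.start, -o.length_nt))
    # keep the longest ORF per distinct stop, then take the first two
    by_end: dict[int, Orf] = {}
    for o in fwd:
        if o.end not in by_end or o.length_nt > by_end[o.end].length_nt:
            by_end[o.end] = o
    ordered = sorted(by_end.values(), key=lambda o: o.start)
    if len(ordered) < 2:
        return None
    return ordered[0].start, ordered[1].start


def detect_polya(sequence: str | SequenceRecord, min_run: int = 10,
                 window: int = 20) -> tuple[bool, tuple[int, int] | None]:
    """True iff an A-run of at least ``min_run`` lies within the 3' window.

    Case- and U/T-spelling-insensitive.  Returns the run's 0-based half-open
    coordinates when found (longest run; ties to the most 3' one).
    """
    if isinstance(sequence, SequenceRecord):
        sequence = sequence.sequence
    seq = sequence.upper().replace("U", "T")
    n = len(seq)
    lo = max(0, n - window)
    best: tuple[int, int] | None = None
    run_start = None
    for i in range(lo, n + 1):
        if i < n and seq[i] == "A":
            if run_start is None:
                run_start = i
        else:
            if run_start is not None:
                if i - run_start >= min_run and (
                        best is None or i - run_start >= best[1] - best[0]):
                    best = (run_start, i)
                run_start = None
    return best is not None, best


def count_uga_readthrough(sequence: str | SequenceRecord,
                          orf_frame: int | None = None,
                          flag_threshold: int = 2) -> tuple[int, bool]:
    """Count in-frame UGA codons inside the longest read-through ORF.

    The sequence is translated with UGA decoded as tryptophan (mold
    mitochondrial style), the longest ATG-initiated ORF under that code is
    located, and the UGA codons inside it — which would terminate standard
    translation — are counted.  A count of ``flag_threshold`` (default 2)
    or more flags the segment as mitovirus-like.

    ``orf_frame`` restricts the search to one forward frame (0-2); default
    searches all three forward frames.
    """
    if isinstance(sequence, SequenceRecord):
        sequence = sequence.sequence
    seq = sequence.upper().replace("U", "T")
    frames = [orf_frame] if orf_frame is not None else [0, 1, 2]
    best_len = -1
    best_count = 0
    for frame in frames:
        if frame not in (0, 1, 2):
            raise ValueError(f"invalid frame {frame}")
        starts: list[int] = []
        p = frame
        while p + 3 <= len(seq):
            codon = seq[p:p + 3]
            if codon == "ATG":
                starts.append(p)
            if codon in MITO_STOP_CODONS and starts:
                st = starts[0]
                length = p + 3 - st
                if length > best_len:
                    best_len = length
                    best_count = _count_tga(seq, st, p)
                starts = []
            p += 3
        if starts:
            st = starts[0]
            edge = st + ((len(seq) - st) // 3) * 3
            if edge - st > best_len:
                best_len = edge - st
                best_count = _count_tga(seq, st, edge)
    return best_count, best_count >= flag_threshold


def _count_tga(seq: str, start: int, end: int) -> int:
    return sum(1 for p in range(start, end, 3) if seq[p:p + 3] == "TGA")
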