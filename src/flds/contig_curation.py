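"""Contig confirmation filters and genome-segment terminal-end detection.

A contig is *confirmed* when it was built at >= 3x per-base coverage,
>= 10x average coverage and is >= 1,000 bp long (all inclusive).

A *terminal end* is a position near a contig end where dominant reads —
strictly more than 10 — stop at exactly the same coordinate.  A predicted
terminus is *confirmed* by the presence of adjacent PCR-primer sequence in
the supporting reads' trim records (the loop-primer ligation signature), or
by a poly(A) tail at the contig 3' end.  A contig whose two ends both carry
confirmed termini is a full-length genome segment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from flds.annotate import detect_polya
from flds.formats_io import Alignment, CoverageVector, SequenceRecord
from flds.primers import DEFAULT_PRIMER_SET
from flds.trim_map import TrimRecord, _hamming_le

logger = logging.getLogger(__name__)


@dataclass
class QCThresholds:
    """Contig confirmation thresholds (all inclusive)."""

    min_per_base_coverage: int = 3
    min_average_coverage: float = 10.0
    min_length: int = 1000

    def __post_init__(self) -> None:
        if min(self.min_per_base_coverage, self.min_average_coverage,
               self.min_length) <= 0:
            raise ValueError("QC thresholds must be positive")


@dataclass
class TerminalParams:
    min_support: int = 10          # strict: support must exceed this
    window: int = 100              # nt from each contig end considered
    min_primer_reads: int = 1
    primer_min_overlap: int = 10
    primer_max_mismatch: int = 1
    polya_min_run: int = 10
    polya_window: int = 20


@dataclass
class TerminalCall:
    """One called terminal end of a contig.

    ``position`` is the 0-based coordinate of the terminal base itself
    (for the right side this is the last covered base, i.e. the exclusive
    alignment end minus one).
    """

    contig_id: str
    side: str  # left | right
    position: int
    support: int
    primer_confirmed: bool
    polyA: bool

    @property
    def status(self) -> str:
        return "confirmed" if (self.primer_confirmed or self.polyA) else "unconfirmed"


@dataclass
class SegmentStatus:
    contig_id: str
    completeness: str  # full-length | partial
    left_call: TerminalCall | None = None
    right_call: TerminalCall | None = None


@dataclass
class StopTables:
    """Read-stop counts near the two contig ends, with supporting alignments.

    ``left`` is keyed by alignment start; ``right`` by the exclusive
    alignment end (so a stop at the very last base has key == contig length).
    """

    contig_id: str
    contig_length: int
    window: int
    left: dict[int, int] = field(default_factory=dict)
    right: dict[int, int] = field(default_factory=dict)
    left_support: dict[int, list[Alignment]] = field(default_factory=dict)
    right_support: dict[int, list[Alignment]] = field(default_factory=dict)


def qc_filter(
    contigs: list[SequenceRecord],
    coverage_vectors: dict[str, CoverageVector],
    thresholds: QCThresholds | None = None,
) -> tuple[list[SequenceRecord], list[dict]]:
    """Apply the contig confirmation filters.

    Returns the passing contigs and a per-contig report listing every
    failed criterion.  A contig without a coverage vector is an error.
    """
    thr = thresholds or QCThresholds()
    passing: list[SequenceRecord] = []
    report: list[dict] = []
    for contig in contigs:
        if contig.id not in coverage_vectors:
            raise ValueError(f"no coverage vector for contig {contig.id!r}")
        cov = coverage_vectors[contig.id]
        reasons = []
        if len(contig.sequence) < thr.min_length:
            reasons.append(f"length<{thr.min_length}")
        if cov.min() < thr.min_per_base_coverage:
            reasons.append(f"per_base_coverage<{thr.min_per_base_coverage}")
        if cov.mean() < thr.min_average_coverage:
            reasons.append(f"average_coverage<{thr.min_average_coverage}")
        report.append({
            "contig_id": contig.id,
            "length": len(contig.sequence),
            "min_coverage": cov.min(),
            "mean_coverage": round(cov.mean(), 3),
            "passed": not reasons,
            "failure_reasons": ";".join(reasons),
        })
        if not reasons:
            passing.append(contig)
    return passing, report


def tally_read_stops(
    alignments: list[Alignment],
    contig_length: int,
    window: int = 100,
) -> StopTables:
    """Count read stops (alignment boundaries) near the contig ends.

    Left table: alignments starting at p for p in [0, window).
    Right table: alignments ending (exclusive) at p for p in
    (contig_length - window, contig_length].
    """
    if window > contig_length:
        logger.info("stop-tally window %d clamped to contig length %d",
                    window, contig_length)
        window = contig_length
    contig_id = alignments[0].contig_id if alignments else ""
    tables = StopTables(contig_id=contig_id, contig_length=contig_length,
                        window=window)
    for aln in alignments:
        if contig_id and aln.contig_id != contig_id:
            raise ValueError("tally_read_stops: alignments span several contigs")
        if aln.start < window:
            tables.left[aln.start] = tables.left.get(aln.start, 0) + 1
            tables.left_support.setdefault(aln.start, []).append(aln)
        if aln.end > contig_length - window:
            tables.right[aln.end] = tables.right.get(aln.end, 0) + 1
            tables.right_support.setdefault(aln.end, []).append(aln)
    return tables


def _piece_matches_primer(piece: str, params: TerminalParams) -> bool:
    """Does a removed prefix/suffix derive from PC2 (either orientation)?

    Accepts any overlap of at least ``primer_min_overlap`` nt, with at most
    ``primer_max_mismatch`` mismatches, between an end of the removed piece
    and an end of the primer.
    """
    if len(piece) < params.primer_min_overlap:
        return False
    for primer in DEFAULT_PRIMER_SET:
        hi = min(len(piece), len(primer))
        for o in range(hi, params.primer_min_overlap - 1, -1):
            if (_hamming_le(piece[-o:], primer[-o:], params.primer_max_mismatch)
                    or _hamming_le(piece[:o], primer[:o], params.primer_max_mismatch)):
                return True
    return False


def _primer_evidence(supporting: list[Alignment],
                     trim_records: dict[str, TrimRecord],
                     side: str, params: TerminalParams) -> int:
    """Count supporting reads whose removed piece adjacent to the stop is
    PC2-derived.

    For a left-side stop the adjacent piece is the removed prefix of a
    plus-strand read (its 5' end sits on the stop) and the removed suffix
    of a minus-strand read; mirrored for the right side.
    """
    n = 0
    for aln in supporting:
        rec = trim_records.get(aln.read_id)
        if rec is None:
            continue
        if side == "left":
            piece = rec.removed_prefix if aln.strand == "+" else rec.removed_suffix
        else:
            piece = rec.removed_suffix if aln.strand == "+" else rec.removed_prefix
        if piece and _piece_matches_primer(piece, params):
            n += 1
    return n


def call_termini(
    stop_tables: StopTables,
    trim_records: dict[str, TrimRecord],
    contig_sequence: str,
    params: TerminalParams | None = None,
) -> list[TerminalCall]:
    """Call at most one terminal end per contig side.

    A position qualifies when its stop count strictly exceeds
    ``min_support`` (dominant reads, more than 10 by default) and is
    maximal in its table; ties go to the position closest to the contig
    end.  Primer confirmation requires at least ``min_primer_reads``
    supporting reads with PC2-derived removed sequence adjacent to the
    stop; a poly(A) tail at the contig 3' end confirms the right side
    instead.
    """
    p = params or TerminalParams()
    calls: list[TerminalCall] = []
    has_polya, _ = detect_polya(contig_sequence, p.polya_min_run, p.polya_window)

    for side in ("left", "right"):
        table = stop_tables.left if side == "left" else stop_tables.right
        support_map = (stop_tables.left_support if side == "left"
                       else stop_tables.right_support)
        qualifying = {pos: c for pos, c in table.items() if c > p.min_support}
        if not qualifying:
            continue
        top = max(qualifying.values())
        tied = [pos for pos, c in qualifying.items() if c == top]
        pos = min(tied) if side == "left" else max(tied)
        supporting = support_map[pos]
        primer_n = _primer_evidence(supporting, trim_records, side, p)
        calls.append(TerminalCall(
            contig_id=stop_tables.contig_id,
            side=side,
            position=pos if side == "left" else pos - 1,
            support=top,
            primer_confirmed=primer_n >= p.min_primer_reads,
            polyA=has_polya if side == "right" else False,
        ))
    return calls


def classify_completeness(
    contig: SequenceRecord,
    terminal_calls: list[TerminalCall],
) -> SegmentStatus:
    """Full-length iff confirmed calls exist on both sides; else partial.

    Two confirmed calls on the same side make the terminus ambiguous and
    raise an error.
    """
    left = [c for c in terminal_calls if c.side == "left" and c.status == "confirmed"]
    right = [c for c in terminal_calls if c.side == "right" and c.status == "confirmed"]
    for side, group in (("left", left), ("right", right)):
        if len(group) > 1:
            raise ValueError(
                f"contig {contig.id!r}: {len(group)} confirmed {side} termini "
                f"(ambiguous)")
    full = bool(left) and bool(right)
    return SegmentStatus(
        contig_id=contig.id,
        completeness="full-length" if full else "partial",
        left_call=left[0] if left else None,
        right_call=right[0] if right else None,
    )
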