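"""FLDS versus total RNA-seq comparison statistics.

Per-contig relative read frequency (mapped reads / trimmed library total),
fold enrichment between the two libraries, per-contig coverage coefficient
of variation (population SD of depth over mean depth), and Table-style
library summaries.  Read counting is per distinct read id, mates counted
separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from flds.formats_io import Alignment, CoverageVector


@dataclass
class EnrichmentRecord:
    """Per-contig read frequencies in the two libraries and derived stats.

    ``fold`` is freq_flds / freq_rnaseq, or NaN ("undefined") when the
    contig attracted no RNA-seq reads at all — such contigs are excluded
    from the mean fold.
    """

    contig_id: str
    freq_flds: float
    freq_rnaseq: float
    fold: float  # NaN when undefined
    cv_flds: float | None = None
    cv_rnaseq: float | None = None

    @property
    def fold_defined(self) -> bool:
        return not math.isnan(self.fold)


@dataclass
class LibrarySummary:
    library: str
    trimmed_reads: int
    viral_reads: int
    viral_rate: float  # percent, one decimal
    unmapped_reads: int
    unmapped_rate: float


def contig_read_frequency(
    alignments: list[Alignment], total_trimmed_reads: int,
) -> dict[str, float]:
    """Distinct mapped reads per contig divided by the trimmed-library total."""
    if total_trimmed_reads <= 0:
        raise ValueError("total_trimmed_reads must be positive")
    reads_per_contig: dict[str, set[str]] = {}
    for aln in alignments:
        reads_per_contig.setdefault(aln.contig_id, set()).add(aln.read_id)
    return {cid: len(reads) / total_trimmed_reads
            for cid, reads in reads_per_contig.items()}


def fold_enrichment(
    freq_flds: dict[str, float],
    freq_rnaseq: dict[str, float],
    contigs: list[str] | None = None,
) -> tuple[list[EnrichmentRecord], float]:
    """Per-contig fold enrichment and the arithmetic mean over defined folds.

    Contigs absent from the RNA-seq library (frequency 0) get an undefined
    (NaN) fold and are excluded from the mean; the mean is NaN when no fold
    is defined.
    """
    if contigs is None:
        contigs = sorted(set(freq_flds) | set(freq_rnaseq))
    records: list[EnrichmentRecord] = []
    defined: list[float] = []
    for cid in contigs:
        ff = freq_flds.get(cid, 0.0)
        fr = freq_rnaseq.get(cid, 0.0)
        if fr > 0.0:
            fold = ff / fr
            defined.append(fold)
        else:
            fold = math.nan
        records.append(EnrichmentRecord(contig_id=cid, freq_flds=ff,
                                        freq_rnaseq=fr, fold=fold))
    mean = sum(defined) / len(defined) if defined else math.nan
    return records, mean


def coverage_cv(coverage: CoverageVector | np.ndarray) -> float:
    """Coefficient of variation: population SD of per-base depth over mean."""
    depth = coverage.depth if isinstance(coverage, CoverageVector) else np.asarray(coverage)
    mean = float(np.mean(depth))
    if mean <= 0.0:
        raise ValueError("coverage_cv undefined for all-zero coverage")
    return float(np.std(depth)) / mean


def summarize_libraries(
    libraries: dict[str, tuple[int, list[Alignment]]],
    viral_contig_set: set[str],
) -> list[LibrarySummary]:
    """Table-style per-library read classification.

    ``libraries`` maps a library name to (trimmed read total, alignments).
    Reads mapped to contigs in ``viral_contig_set`` are viral; the remainder
    (unmapped or mapped to minor/other contigs) is the unmapped category.
    Rates are percentages rounded to one decimal and sum to 100 within
    rounding.
    """
    out: list[LibrarySummary] = []
    for name, (total, alignments) in libraries.items():
        if total <= 0:
            raise ValueError(f"library {name!r}: non-positive trimmed total")
        viral_ids: set[str] = set()
        for aln in alignments:
            if aln.contig_id in viral_contig_set:
                viral_ids.add(aln.read_id)
        n_viral = len(viral_ids)
        if n_viral > total:
            raise ValueError(f"library {name!r}: viral reads exceed trimmed total")
        n_other = total - n_viral
        out.append(LibrarySummary(
            library=name,
            trimmed_reads=total,
            viral_reads=n_viral,
            viral_rate=round(100.0 * n_viral / total, 1),
            unmapped_reads=n_other,
            unmapped_rate=round(100.0 * n_other / total, 1),
        ))
    return out


def build_enrichment_table(
    aln_flds: list[Alignment], total_flds: int,
    aln_rnaseq: list[Alignment], total_rnaseq: int,
    coverage_flds: dict[str, CoverageVector] | None = None,
    coverage_rnaseq: dict[str, CoverageVector] | None = None,
    contigs: list[str] | None = None,
) -> tuple[list[EnrichmentRecord], float]:
    """Convenience: frequencies, folds and coverage CVs in one pass."""
    ff = contig_read_frequency(aln_flds, total_flds)
    fr = contig_read_frequency(aln_rnaseq, total_rnaseq)
    records, mean = fold_enrichment(ff, fr, contigs)
    for rec in records:
        if coverage_flds and rec.contig_id in coverage_flds:
            cov = coverage_flds[rec.contig_id]
            rec.cv_flds = coverage_cv(cov) if cov.mean() > 0 else None
        if coverage_rnaseq and rec.contig_id in coverage_rnaseq:
            cov = coverage_rnaseq[rec.contig_id]
            rec.cv_rnaseq = coverage_cv(cov) if cov.mean() > 0 else None
    return records, mean
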