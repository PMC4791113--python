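"""Ground-truthed simulation of viral communities and sequencing libraries.

The simulator emulates the structural artifacts that the FLDS informatics
relies on, not the wet-lab physics:

* multi-segment viral genomes (1–12.5 kb) whose segments share an
  identical, species-unique 5'-terminal sequence (default 9 nt);
* genome-type variants of a species created by point mutation to a target
  identity;
* dsRNA fragmentation as per-molecule breakpoints (fragment sizes are
  approximately exponential), so each molecule's outermost fragments stop
  exactly at the true termini — the read-stop pileup the terminal caller
  detects;
* loop-primer ligation + single-primer PCR, abstracted as the reverse
  complement of PC2 carried on a read immediately outside a fragment end
  that coincides with a true segment terminus;
* a terminal-weight multiplier reproducing the elevated terminal coverage
  of FLDS libraries;
* a total RNA-seq library dominated by rRNA, with a small viral fraction
  and a random-priming end-loss model under which no read boundary falls
  exactly on a segment terminus.

Every emitted read carries exactly one :class:`ReadOrigin` record; the
complete :class:`GroundTruth` makes recall/precision of the downstream
callers measurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from flds.formats_io import SequenceRecord, SequenceRead, reverse_complement, write_tsv
from flds.primers import PC2_RC

logger = logging.getLogger(__name__)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class VirusSpec:
    """Ground-truth description of one viral species in the community."""

    species_id: str
    n_segments: int
    segment_lengths: list[int]
    molecule: str  # dsRNA | ssRNA
    terminal_motif_5p: str
    has_polyA: bool
    relative_abundance: float


@dataclass
class SimConfig:
    """Study conditions for the simulated community and libraries.

    Fractions are in [0, 1]; the seed is mandatory and is the single source
    of randomness for community, FLDS library and RNA-seq library (each
    stage derives its own independent stream from it).
    """

    seed: int
    n_species: int = 8
    segments_per_species: tuple[int, int] = (1, 3)
    segment_counts: Sequence[int] | None = None  # explicit per-species counts
    segment_length_range: tuple[int, int] = (1000, 12500)
    terminal_motif_k: int = 9
    genome_type_duplication_rate: float = 0.25
    duplication_identity_range: tuple[float, float] = (0.70, 0.95)
    ssrna_fraction: float = 0.2
    polya_fraction: float = 0.5  # of ssRNA species
    polya_length: int = 20
    abundance_sigma: float = 0.8
    min_relative_abundance: float = 0.1
    read_length: int = 300
    mean_fragment_length: int = 500
    terminal_boost: float = 3.0
    flds_coverage: float = 300.0
    flds_nonviral_fraction: float = 0.018
    rnaseq_n_reads: int = 200_000
    rnaseq_rrna_fraction: float = 0.56
    rnaseq_viral_fraction: float = 0.003
    rnaseq_end_loss: int = 20
    substitution_error_rate: float = 0.001
    quality_score: int = 37

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("SimConfig.seed is mandatory")
        for name in ("genome_type_duplication_rate", "ssrna_fraction",
                     "polya_fraction", "flds_nonviral_fraction",
                     "rnaseq_rrna_fraction", "rnaseq_viral_fraction",
                     "substitution_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.rnaseq_rrna_fraction + self.rnaseq_viral_fraction > 1.0:
            raise ValueError("rnaseq rRNA + viral fractions exceed 1")
        if self.segment_length_range[0] <= self.terminal_motif_k:
            raise ValueError(
                f"minimum segment length {self.segment_length_range[0]} cannot "
                f"hold a {self.terminal_motif_k} nt terminal motif")
        if self.terminal_boost < 0:
            raise ValueError("terminal_boost must be >= 0")


@dataclass
class ReadOrigin:
    """Provenance of one emitted read (exactly one record per read)."""

    read_id: str
    library: str  # flds | rnaseq
    source_id: str  # segment id, or rRNA_* / mRNA_* / nonviral_*
    start: int
    end: int
    strand: str
    terminus: str  # "", "left", "right"


@dataclass
class GroundTruth:
    """Per-read provenance for one simulated library."""

    library: str
    origins: dict[str, ReadOrigin] = field(default_factory=dict)

    def add(self, origin: ReadOrigin) -> None:
        if origin.read_id in self.origins:
            raise ValueError(f"duplicate ground-truth read id {origin.read_id!r}")
        self.origins[origin.read_id] = origin

    def viral_read_ids(self, viral_sources: set[str]) -> set[str]:
        return {r for r, o in self.origins.items() if o.source_id in viral_sources}

    def to_tsv(self, path) -> None:
        write_tsv(
            (asdict(o) for o in self.origins.values()),
            path,
            columns=["read_id", "library", "source_id", "start", "end",
                     "strand", "terminus"],
        )


@dataclass
class Community:
    """A simulated viral community plus its bookkeeping.

    ``segments`` double as the 'contigs' downstream stages map against —
    de novo assembly is outside this pipeline's scope.
    """

    segments: list[SequenceRecord]
    specs: list[VirusSpec]
    segment_species: dict[str, str]
    segment_genome_type: dict[str, str]
    segment_abundance: dict[str, float]

    def segment(self, seg_id: str) -> SequenceRecord:
        for rec in self.segments:
            if rec.id == seg_id:
                return rec
        raise KeyError(seg_id)

    @property
    def species_segments(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for seg_id, sp in self.segment_species.items():
            out.setdefault(sp, []).append(seg_id)
        return {sp: sorted(v) for sp, v in sorted(out.items())}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode("ascii")


def mutate_to_identity(sequence: str, target_identity: float,
                       rng: np.random.Generator,
                       protect_prefix: int = 0,
                       protect_suffix: int = 0) -> str:
    """Point-mutate a sequence to approximately a target fractional identity.

    Exactly ``round((1 - target) * len)`` distinct positions are substituted
    to a different base; positions in the protected prefix/suffix (terminal
    motif, poly(A) tail) are never touched.
    """
    if not 0.0 < target_identity <= 1.0:
        raise ValueError(f"target identity {target_identity} outside (0, 1]")
    n = len(sequence)
    n_mut = int(round((1.0 - target_identity) * n))
    candidates = np.arange(protect_prefix, n - protect_suffix)
    if n_mut > len(candidates):
        raise ValueError("too few mutable positions for requested identity")
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    pos = rng.choice(candidates, size=n_mut, replace=False)
    for p in pos:
        choices = BASES[BASES != arr[p]]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def generate_community(config: SimConfig, seed: int | None = None) -> Community:
    """Draw a viral community under the configured study conditions.

    Deterministic for a given (config, seed): running twice yields
    byte-identical segment sequences and bookkeeping.
    """
    config.validate()
    rng = np.random.default_rng([seed if seed is not None else config.seed, 0])
    k = config.terminal_motif_k
    lo, hi = config.segment_length_range

    # species-unique terminal motifs
    motifs: list[str] = []
    seen: set[str] = set()
    while len(motifs) < config.n_species:
        m = _random_seq(rng, k)
        if m not in seen:
            seen.add(m)
            motifs.append(m)

    # relative abundances: lognormal, normalized to mean 1, floored so every
    # species is deep enough for terminal detection at the default coverage
    w = rng.lognormal(0.0, config.abundance_sigma, config.n_species)
    w = w / w.mean()
    w = np.maximum(w, config.min_relative_abundance)

    if config.segment_counts is not None:
        if len(config.segment_counts) != config.n_species:
            raise ValueError("segment_counts length != n_species")
        seg_counts = list(config.segment_counts)
    else:
        seg_counts = list(rng.integers(config.segments_per_species[0],
                                       config.segments_per_species[1] + 1,
                                       config.n_species))

    segments: list[SequenceRecord] = []
    specs: list[VirusSpec] = []
    segment_species: dict[str, str] = {}
    segment_genome_type: dict[str, str] = {}
    segment_abundance: dict[str, float] = {}

    for s in range(config.n_species):
        species_id = f"VIR{s + 1:02d}"
        molecule = "ssRNA" if rng.random() < config.ssrna_fraction else "dsRNA"
        has_polya = molecule == "ssRNA" and rng.random() < config.polya_fraction
        lengths = [int(x) for x in rng.integers(lo, hi + 1, seg_counts[s])]
        spec = VirusSpec(
            species_id=species_id,
            n_segments=seg_counts[s],
            segment_lengths=lengths,
            molecule=molecule,
            terminal_motif_5p=motifs[s],
            has_polyA=has_polya,
            relative_abundance=float(w[s]),
        )
        specs.append(spec)
        for j, length in enumerate(lengths, start=1):
            body = _random_seq(rng, length - k)
            seq = motifs[s] + body
            tail = config.polya_length if has_polya else 0
            if tail:
                seq = seq[:-tail] + "A" * tail
            seg_id = f"{species_id}_s{j}"
            segments.append(SequenceRecord(
                id=seg_id, sequence=seq,
                description=f"{molecule} species={species_id} type=A"))
            segment_species[seg_id] = species_id
            segment_genome_type[seg_id] = "A"
            segment_abundance[seg_id] = float(w[s])

        if rng.random() < config.genome_type_duplication_rate:
            j = int(rng.integers(1, seg_counts[s] + 1))
            parent = next(r for r in segments if r.id == f"{species_id}_s{j}")
            target = float(rng.uniform(*config.duplication_identity_range))
            tail = config.polya_length if has_polya else 0
            variant_seq = mutate_to_identity(
                parent.sequence, target, rng,
                protect_prefix=k, protect_suffix=tail)
            var_id = f"{species_id}_s{j}B"
            segments.append(SequenceRecord(
                id=var_id, sequence=variant_seq,
                description=f"{spec.molecule} species={species_id} type=B "
                            f"target_identity={target:.3f}"))
            segment_species[var_id] = species_id
            segment_genome_type[var_id] = "B"
            # minor variant, floored so it stays detectable at default depth
            segment_abundance[var_id] = float(
                max(w[s] * rng.uniform(0.05, 0.4), config.min_relative_abundance))

    return Community(
        segments=segments,
        specs=specs,
        segment_species=segment_species,
        segment_genome_type=segment_genome_type,
        segment_abundance=segment_abundance,
    )


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    n_err = rng.binomial(len(arr), rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(arr), size=n_err, replace=False)
    for p in pos:
        choices = BASES[BASES != arr[p]]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def _fragment_breakpoints(length: int, mean_len: float,
                          rng: np.random.Generator) -> list[tuple[int, int]]:
    """Break one molecule copy into pieces at Poisson-scattered positions."""
    n_bp = rng.poisson(max(length / mean_len - 1.0, 0.0))
    if n_bp == 0:
        return [(0, length)]
    cuts = np.unique(rng.integers(1, length, n_bp))
    bounds = [0, *cuts.tolist(), length]
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def simulate_flds_library(
    community: Community, config: SimConfig, seed: int | None = None,
) -> tuple[list[SequenceRead], list[SequenceRead], GroundTruth]:
    """Simulate a paired-end FLDS library from the community.

    Each segment is present as ``round(flds_coverage x abundance)`` molecule
    copies; each copy is fragmented at random breakpoints, so its outermost
    fragments end exactly at the true termini.  Every fragment yields a read
    pair from its two ends; a read whose fragment end coincides with a true
    terminus carries the reverse complement of PC2 immediately outside the
    terminal base.  Terminus-abutting fragments are emitted
    ``terminal_boost`` times in expectation (PCR favoring loop-primer
    amplicons), reproducing elevated terminal coverage.  Non-viral
    contaminant read pairs are added at ``flds_nonviral_fraction``.
    """
    config.validate()
    if not community.segments:
        raise ValueError("empty community")
    rng = np.random.default_rng([seed if seed is not None else config.seed, 1])
    rl = config.read_length
    err = config.substitution_error_rate
    r1: list[SequenceRead] = []
    r2: list[SequenceRead] = []
    truth = GroundTruth(library="flds")
    counter = 0

    def emit_pair(seq: str, source_id: str, s: int, e: int,
                  left_term: bool, right_term: bool) -> None:
        nonlocal counter
        counter += 1
        base = f"fl{counter:07d}"
        flen = e - s
        # R1: plus strand from the fragment's left end
        if left_term:
            ins = min(rl - len(PC2_RC), flen)
            raw1 = PC2_RC + seq[s:s + ins]
            o1 = ReadOrigin(f"{base}/1", "flds", source_id, s, s + ins, "+", "left")
        else:
            ins = min(rl, flen)
            raw1 = seq[s:s + ins]
            o1 = ReadOrigin(f"{base}/1", "flds", source_id, s, s + ins, "+", "")
        # R2: minus strand from the fragment's right end
        if right_term:
            ins2 = min(rl - len(PC2_RC), flen)
            raw2 = PC2_RC + reverse_complement(seq[e - ins2:e])
            o2 = ReadOrigin(f"{base}/2", "flds", source_id, e - ins2, e, "-", "right")
        else:
            ins2 = min(rl, flen)
            raw2 = reverse_complement(seq[e - ins2:e])
            o2 = ReadOrigin(f"{base}/2", "flds", source_id, e - ins2, e, "-", "")
        raw1 = _apply_errors(raw1, err, rng)
        raw2 = _apply_errors(raw2, err, rng)
        r1.append(SequenceRead(o1.read_id, raw1, [config.quality_score] * len(raw1), mate=1))
        r2.append(SequenceRead(o2.read_id, raw2, [config.quality_score] * len(raw2), mate=2))
        truth.add(o1)
        truth.add(o2)

    for rec in community.segments:
        length = len(rec.sequence)
        abundance = community.segment_abundance[rec.id]
        copies = max(1, int(round(config.flds_coverage * abundance)))
        for _ in range(copies):
            for (s, e) in _fragment_breakpoints(length, config.mean_fragment_length, rng):
                left_term = s == 0
                right_term = e == length
                if left_term or right_term:
                    b = config.terminal_boost
                    n_emit = int(b) + (1 if rng.random() < b - int(b) else 0)
                else:
                    n_emit = 1
                for _ in range(n_emit):
                    emit_pair(rec.sequence, rec.id, s, e, left_term, right_term)

    # non-viral contaminants
    n_contam = 0
    if config.flds_nonviral_fraction > 0:
        n_viral_pairs = counter
        f = config.flds_nonviral_fraction
        n_contam = int(round(n_viral_pairs * f / (1.0 - f)))
        pool = [(f"nonviral_{i + 1}", _random_seq(rng, 2000)) for i in range(3)]
        for _ in range(n_contam):
            pid = int(rng.integers(0, len(pool)))
            name, pseq = pool[pid]
            flen = int(rng.integers(300, 701))
            s = int(rng.integers(0, len(pseq) - flen + 1))
            emit_pair(pseq, name, s, s + flen, False, False)

    logger.info("FLDS library: %d read pairs (%d contaminant)", counter, n_contam)
    return r1, r2, truth


def simulate_rnaseq_library(
    community: Community, config: SimConfig, seed: int | None = None,
) -> tuple[list[SequenceRead], list[SequenceRead], GroundTruth]:
    """Simulate a total RNA-seq library over the same community.

    Read pairs are drawn from a synthetic rRNA pool
    (``rnaseq_rrna_fraction``), a host mRNA pool, and the viral segments
    (``rnaseq_viral_fraction``).  Viral fragment boundaries are uniform but
    constrained to [1, L-1] (random-priming end loss), so no read boundary
    ever coincides exactly with a true segment terminus and no terminal
    read-stop pileup forms — the structural contrast with FLDS.
    """
    config.validate()
    if not community.segments:
        raise ValueError("empty community")
    rng = np.random.default_rng([seed if seed is not None else config.seed, 2])
    rl = config.read_length
    err = config.substitution_error_rate
    n_pairs = config.rnaseq_n_reads // 2
    p_rrna = config.rnaseq_rrna_fraction
    p_viral = config.rnaseq_viral_fraction
    counts = rng.multinomial(n_pairs, [p_rrna, p_viral, 1.0 - p_rrna - p_viral])

    rrna_pool = [("rRNA_SSU", _random_seq(rng, 1800)),
                 ("rRNA_LSU", _random_seq(rng, 2900))]
    mrna_pool = [(f"mRNA_{i + 1:03d}", _random_seq(rng, int(rng.integers(500, 3001))))
                 for i in range(40)]

    seg_ids = [r.id for r in community.segments]
    seg_w = np.array([community.segment_abundance[i] * len(community.segment(i))
                      for i in seg_ids], dtype=float)
    seg_p = seg_w / seg_w.sum()

    r1: list[SequenceRead] = []
    r2: list[SequenceRead] = []
    truth = GroundTruth(library="rnaseq")
    counter = 0

    def emit_pair(seq: str, source_id: str, s: int, e: int) -> None:
        nonlocal counter
        counter += 1
        base = f"rs{counter:07d}"
        ins = min(rl, e - s)
        raw1 = _apply_errors(seq[s:s + ins], err, rng)
        raw2 = _apply_errors(reverse_complement(seq[e - ins:e]), err, rng)
        r1.append(SequenceRead(f"{base}/1", raw1, [config.quality_score] * len(raw1), mate=1))
        r2.append(SequenceRead(f"{base}/2", raw2, [config.quality_score] * len(raw2), mate=2))
        truth.add(ReadOrigin(f"{base}/1", "rnaseq", source_id, s, s + ins, "+", ""))
        truth.add(ReadOrigin(f"{base}/2", "rnaseq", source_id, e - ins, e, "-", ""))

    def draw_fragment(length: int, constrained: bool) -> tuple[int, int]:
        flen = int(np.clip(rng.normal(400, 60), 250, 600))
        if constrained:
            flen = min(flen, length - 2)
            s = int(rng.integers(1, length - flen))  # s >= 1, e <= length - 1
        else:
            flen = min(flen, length)
            s = int(rng.integers(0, length - flen + 1))
        return s, s + flen

    for _ in range(counts[0]):
        pid = int(rng.integers(0, len(rrna_pool)))
        name, pseq = rrna_pool[pid]
        s, e = draw_fragment(len(pseq), False)
        emit_pair(pseq, name, s, e)
    for _ in range(counts[1]):
        sid = seg_ids[int(rng.choice(len(seg_ids), p=seg_p))]
        rec = community.segment(sid)
        s, e = draw_fragment(len(rec.sequence), True)
        emit_pair(rec.sequence, sid, s, e)
    for _ in range(counts[2]):
        pid = int(rng.integers(0, len(mrna_pool)))
        name, pseq = mrna_pool[pid]
        s, e = draw_fragment(len(pseq), False)
        emit_pair(pseq, name, s, e)

    logger.info("RNA-seq library: %d read pairs (rRNA %d, viral %d, mRNA %d)",
                counter, counts[0], counts[1], counts[2])
    return r1, r2, truth
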