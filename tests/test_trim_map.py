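"""Primer trimming with sidecar reconstruction, and the minimal mapper."""

import numpy as np
import pytest

from flds.formats_io import SequenceRead, SequenceRecord, reverse_complement
from flds.primers import PC2, PC2_RC
from flds.simulate import SimConfig, generate_community, simulate_flds_library
from flds.trim_map import MapperConfig, map_reads, trim_reads


def _read(seq, rid="r1", qual=37):
    return SequenceRead(rid, seq, [qual] * len(seq))


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestTrimReads:
    def test_full_pc2_prefix_removed(self):
        rng = np.random.default_rng(0)
        insert = _random_seq(rng, 100)
        trimmed, (rec,) = trim_reads([_read(PC2 + insert)])
        assert rec.removed_prefix == PC2
        assert trimmed[0].sequence == insert

    def test_clean_read_untouched(self):
        rng = np.random.default_rng(1)
        seq = _random_seq(rng, 120)
        trimmed, (rec,) = trim_reads([_read(seq)])
        assert trimmed[0].sequence == seq
        assert (rec.removed_prefix, rec.removed_suffix, rec.quality_clipped) == \
            ("", "", 0)

    def test_partial_primer_at_three_prime_removed(self):
        rng = np.random.default_rng(2)
        insert = _random_seq(rng, 100)
        trimmed, (rec,) = trim_reads([_read(insert + PC2[:12])])
        assert rec.removed_suffix == PC2[:12]
        assert trimmed[0].sequence == insert

    def test_overlap_below_minimum_kept(self):
        rng = np.random.default_rng(3)
        insert = "G" * 100  # no accidental primer overlap
        trimmed, (rec,) = trim_reads([_read(insert + PC2[:8])])
        assert rec.removed_suffix == ""
        assert trimmed[0].sequence == insert + PC2[:8]

    def test_one_mismatch_in_primer_tolerated(self):
        insert = "G" * 100
        mutated = "A" + PC2_RC[1:]
        trimmed, (rec,) = trim_reads([_read(mutated + insert)])
        assert rec.removed_prefix == mutated
        assert trimmed[0].sequence == insert

    def test_quality_clipping_is_suffix_only(self):
        seq = "ACGT" * 30
        quals = [37] * 100 + [5] * 20
        trimmed, (rec,) = trim_reads([SequenceRead("r1", seq, quals)])
        assert rec.quality_clipped == 20
        assert rec.removed_prefix == ""
        assert trimmed[0].sequence == seq[:100]

    def test_short_reads_dropped_without_record(self):
        trimmed, records = trim_reads([_read("ACGT" * 10)])  # 40 nt < 50
        assert trimmed == [] and records == []

    def test_empty_primer_set_rejected(self):
        with pytest.raises(ValueError):
            trim_reads([_read("A" * 60)], primer_set=())

    def test_reconstruction_invariant_on_simulated_library(self):
        cfg = SimConfig(seed=5, n_species=2, segment_length_range=(1000, 2000),
                        flds_coverage=20.0)
        com = generate_community(cfg)
        r1, r2, _ = simulate_flds_library(com, cfg)
        raw = {r.id: r.sequence for r in r1 + r2}
        trimmed, records = trim_reads(r1 + r2)
        bodies = {r.id: r.sequence for r in trimmed}
        assert records  # something retained
        for rec in records:
            original = raw[rec.read_id]
            body = bodies[rec.read_id]
            assert original.startswith(rec.removed_prefix)
            assert original.endswith(rec.removed_suffix)
            core_end = len(original) - len(rec.removed_suffix) - rec.quality_clipped
            assert original[len(rec.removed_prefix):core_end] == body


class TestMapReads:
    def test_error_free_reads_map_to_ground_truth_origin(self):
        cfg = SimConfig(seed=6, n_species=2, segment_length_range=(1000, 2000),
                        flds_coverage=15.0, substitution_error_rate=0.0,
                        flds_nonviral_fraction=0.0)
        com = generate_community(cfg)
        r1, r2, truth = simulate_flds_library(com, cfg)
        trimmed, _ = trim_reads(r1 + r2)
        alignments = {a.read_id: a for a in map_reads(trimmed, com.segments)}
        assert len(alignments) == len(trimmed)  # completeness on clean data
        for read in trimmed:
            o = truth.origins[read.id]
            a = alignments[read.id]
            assert (a.contig_id, a.start, a.end, a.strand) == \
                (o.source_id, o.start, o.end, o.strand)
            assert a.n_mismatches == 0

    def test_repeat_between_contigs_unmapped_when_unique_required(self):
        rng = np.random.default_rng(7)
        shared = _random_seq(rng, 400)
        contigs = [
            SequenceRecord("cA", shared + _random_seq(rng, 600)),
            SequenceRecord("cB", _random_seq(rng, 600) + shared),
        ]
        read = _read(shared[50:350])
        assert map_reads([read], contigs, MapperConfig(require_unique=True)) == []
        (aln,) = map_reads([read], contigs, MapperConfig(require_unique=False))
        assert (aln.contig_id, aln.start) == ("cA", 50)  # lexicographic tie rule

    def test_reverse_strand_reads_mapped(self):
        rng = np.random.default_rng(8)
        contig = SequenceRecord("c", _random_seq(rng, 1000))
        read = _read(reverse_complement(contig.sequence[200:500]))
        (aln,) = map_reads([read], [contig])
        assert (aln.start, aln.end, aln.strand) == (200, 500, "-")

    def test_reported_mismatch_rate_sound(self):
        cfg = SimConfig(seed=9, n_species=2, segment_length_range=(1000, 2000),
                        flds_coverage=15.0, substitution_error_rate=0.01)
        com = generate_community(cfg)
        r1, r2, _ = simulate_flds_library(com, cfg)
        trimmed, _ = trim_reads(r1 + r2)
        seqs = {c.id: c.sequence for c in com.segments}
        reads = {r.id: r.sequence for r in trimmed}
        for a in map_reads(trimmed, com.segments):
            body = reads[a.read_id]
            if a.strand == "-":
                body = reverse_complement(body)
            ref = seqs[a.contig_id][a.start:a.end]
            mm = sum(1 for x, y in zip(ref, body) if x != y)
            assert mm == a.n_mismatches
            assert mm / len(body) <= 0.03

    def test_one_percent_errors_high_mapping_rate_to_origin(self):
        # 10,000 full-length reads carrying 1% substitutions
        cfg = SimConfig(seed=10, n_species=3, segment_length_range=(1000, 3000),
                        genome_type_duplication_rate=0.0)
        com = generate_community(cfg)
        rng = np.random.default_rng(44)
        reads, origins = [], {}
        bases = np.array(list("ACGT"))
        for i in range(10_000):
            contig = com.segments[int(rng.integers(0, len(com.segments)))]
            start = int(rng.integers(0, len(contig.sequence) - 300))
            body = np.array(list(contig.sequence[start:start + 300]))
            errs = rng.random(300) < 0.01
            for p in np.nonzero(errs)[0]:
                body[p] = rng.choice(bases[bases != body[p]])
            rid = f"r{i}"
            reads.append(_read("".join(body), rid))
            origins[rid] = (contig.id, start)
        correct = sum(
            (a.contig_id, a.start) == origins[a.read_id]
            for a in map_reads(reads, com.segments))
        assert correct / len(reads) >= 0.99
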