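"""Simulator: determinism, ground-truth completeness and structural artifacts."""

import numpy as np
import pytest
from scipy import stats

from flds.classify import pairwise_identity
from flds.primers import PC2_RC
from flds.simulate import (
    SimConfig,
    generate_community,
    mutate_to_identity,
    simulate_flds_library,
    simulate_rnaseq_library,
)


def _tiny_config(**overrides):
    defaults = dict(seed=7, n_species=2, segment_length_range=(1000, 3000),
                    flds_coverage=40.0, rnaseq_n_reads=10_000)
    defaults.update(overrides)
    return SimConfig(**defaults)


class TestCommunity:
    def test_seeded_determinism_byte_identical(self):
        cfg = _tiny_config()
        a = generate_community(cfg)
        b = generate_community(cfg)
        assert [(r.id, r.sequence) for r in a.segments] == \
            [(r.id, r.sequence) for r in b.segments]

    def test_segments_of_one_species_share_terminal_nine_mer(self, small_community):
        for spec in small_community.specs:
            kmers = {small_community.segment(s).sequence[:9]
                     for s in small_community.species_segments[spec.species_id]}
            assert kmers == {spec.terminal_motif_5p}

    def test_terminal_motifs_unique_across_species(self, small_community):
        motifs = [s.terminal_motif_5p for s in small_community.specs]
        assert len(set(motifs)) == len(motifs)

    def test_variant_identity_hits_requested_target(self):
        rng = np.random.default_rng(4)
        parent = "".join(rng.choice(list("ACGT"), 2000))
        variant = mutate_to_identity(parent, 0.85, rng)
        assert 84.0 <= pairwise_identity(parent, variant) <= 86.0

    def test_infeasible_motif_length_rejected(self):
        with pytest.raises(ValueError, match="terminal motif"):
            SimConfig(seed=1, segment_length_range=(8, 100)).validate()


class TestFldsLibrary:
    def test_ground_truth_covers_every_read_exactly_once(self, small_flds_library):
        r1, r2, truth = small_flds_library
        ids = [r.id for r in r1] + [r.id for r in r2]
        assert len(ids) == len(set(ids))
        assert set(ids) == set(truth.origins)

    def test_zero_nonviral_fraction_means_all_viral(self):
        cfg = _tiny_config(flds_nonviral_fraction=0.0)
        com = generate_community(cfg)
        _, _, truth = simulate_flds_library(com, cfg)
        seg_ids = {r.id for r in com.segments}
        assert all(o.source_id in seg_ids for o in truth.origins.values())

    def test_terminus_reads_carry_pc2_adjacent_to_terminal_base(self):
        cfg = _tiny_config(substitution_error_rate=0.0)
        com = generate_community(cfg)
        r1, r2, truth = simulate_flds_library(com, cfg)
        by_id = {r.id: r for r in r1 + r2}
        n_term = 0
        for rid, origin in truth.origins.items():
            if origin.terminus:
                n_term += 1
                assert by_id[rid].sequence.startswith(PC2_RC)
        assert n_term > 0

    def test_every_terminus_has_dominant_stop_pileup(self, small_flds_library,
                                                     small_community):
        _, _, truth = small_flds_library
        stops: dict[tuple[str, str], int] = {}
        for o in truth.origins.values():
            if o.terminus:
                stops[(o.source_id, o.terminus)] = \
                    stops.get((o.source_id, o.terminus), 0) + 1
        for rec in small_community.segments:
            assert stops.get((rec.id, "left"), 0) > 10
            assert stops.get((rec.id, "right"), 0) > 10

    def test_uniform_fragmentation_interior_stops_poisson_bounded(self):
        # terminal_boost=1, one deep segment: no interior start position may
        # exceed the Poisson 99.99th percentile of the uniform model
        cfg = SimConfig(seed=13, n_species=1, segment_counts=[1],
                        segment_length_range=(5000, 5000), flds_coverage=500.0,
                        terminal_boost=1.0, genome_type_duplication_rate=0.0,
                        flds_nonviral_fraction=0.0)
        com = generate_community(cfg)
        _, _, truth = simulate_flds_library(com, cfg)
        length = len(com.segments[0].sequence)
        starts = np.zeros(length, dtype=int)
        n_frag = 0
        for o in truth.origins.values():
            if o.strand == "+":
                n_frag += 1
                starts[o.start] += 1
        interior = starts[1:]
        lam = (n_frag - starts[0]) / (length - 1)
        bound = stats.poisson.ppf(0.9999, lam)
        assert interior.max() <= bound

    def test_seeded_determinism(self):
        cfg = _tiny_config()
        com = generate_community(cfg)
        a = simulate_flds_library(com, cfg)
        b = simulate_flds_library(com, cfg)
        assert [(r.id, r.sequence) for r in a[0]] == [(r.id, r.sequence) for r in b[0]]


class TestRnaseqLibrary:
    def test_viral_read_count_within_binomial_bounds(self):
        cfg = _tiny_config(rnaseq_n_reads=100_000)
        com = generate_community(cfg)
        _, _, truth = simulate_rnaseq_library(com, cfg)
        seg_ids = {r.id for r in com.segments}
        n_viral = sum(o.source_id in seg_ids for o in truth.origins.values())
        n_pairs = len(truth.origins) // 2
        p = cfg.rnaseq_viral_fraction
        sigma = np.sqrt(n_pairs * p * (1 - p))
        assert abs(n_viral / 2 - n_pairs * p) <= 3 * sigma

    def test_zero_rrna_fraction(self):
        cfg = _tiny_config(rnaseq_rrna_fraction=0.0)
        com = generate_community(cfg)
        _, _, truth = simulate_rnaseq_library(com, cfg)
        assert not any(o.source_id.startswith("rRNA")
                       for o in truth.origins.values())

    def test_no_read_boundary_at_true_terminus(self):
        cfg = _tiny_config(rnaseq_n_reads=60_000, rnaseq_viral_fraction=0.05)
        com = generate_community(cfg)
        _, _, truth = simulate_rnaseq_library(com, cfg)
        lengths = {r.id: len(r.sequence) for r in com.segments}
        stops_at_terminus = 0
        for o in truth.origins.values():
            if o.source_id in lengths:
                if o.start == 0 or o.end == lengths[o.source_id]:
                    stops_at_terminus += 1
        assert stops_at_terminus <= 10

    def test_fractions_summing_over_one_rejected(self):
        cfg = _tiny_config(rnaseq_rrna_fraction=0.9, rnaseq_viral_fraction=0.2)
        com_cfg = _tiny_config()
        com = generate_community(com_cfg)
        with pytest.raises(ValueError, match="exceed 1"):
            simulate_rnaseq_library(com, cfg)
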