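"""Shared fixtures: a small seeded community and its processed FLDS library."""

from __future__ import annotations

import pytest

from flds.formats_io import compute_coverage
from flds.simulate import SimConfig, generate_community, simulate_flds_library
from flds.trim_map import map_reads, trim_reads


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(seed=11, n_species=3, segment_length_range=(1000, 4000),
                     flds_coverage=120.0, rnaseq_n_reads=20_000)


@pytest.fixture(scope="session")
def small_community(small_config):
    return generate_community(small_config)


@pytest.fixture(scope="session")
def small_flds_library(small_community, small_config):
    return simulate_flds_library(small_community, small_config)


@pytest.fixture(scope="session")
def small_mapped(small_community, small_config, small_flds_library):
    """(community, trimmed reads, trim-record map, alignments by contig)."""
    r1, r2, _ = small_flds_library
    trimmed, recs = trim_reads(r1 + r2)
    alignments = map_reads(trimmed, small_community.segments)
    by_contig = {c.id: [] for c in small_community.segments}
    for aln in alignments:
        by_contig[aln.contig_id].append(aln)
    return small_community, trimmed, {r.read_id: r for r in recs}, by_contig


@pytest.fixture(scope="session")
def small_coverage(small_community, small_mapped):
    _, _, _, by_contig = small_mapped
    return {c.id: compute_coverage(by_contig[c.id], len(c.sequence), c.id)
            for c in small_community.segments}
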