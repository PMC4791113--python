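"""Nucleotide-identity species demarcation and segment-to-virus grouping.

Viral contigs recovered from one community are organized on two levels:

* **genome types** — near-identical sequence variants, linked at > 90%
  nucleotide identity (strict);
* **species** — genome types linked at 70–90% identity; 90.0 exactly falls
  in the species band.  Below 70% contigs are unrelated.

Both levels are single-linkage connected components of the pairwise
percent-identity graph.  Within each genome type the contig supported by
the most mapped reads is the *major contig*, the representative used
downstream.

Independently of identity, full-length segments are grouped into
multi-segment viruses by identical 5'-terminal k-mers (default k=9),
because segment termini are conserved within a viral genome for
replication/encapsidation.  A terminal k-mer shared across different
species-level clusters is not distinguishable and such segments are left
ungrouped rather than misgrouped.

Percent identity is computed from a global alignment with free end gaps
(match +1, mismatch -1, gap -1, terminal gaps unpenalized):
``identity = matches / alignment columns`` with flanking free-end-gap
columns excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from flds.formats_io import SequenceRecord, reverse_complement

logger = logging.getLogger(__name__)

MATCH = 1
MISMATCH = -1
GAP = -1

# Identity bands (percent).  Strictly above GENOME_TYPE_BAND links contigs
# into one genome type; [SPECIES_BAND, GENOME_TYPE_BAND] links genome types
# of one species; below SPECIES_BAND contigs are unrelated.
GENOME_TYPE_BAND = 90.0
SPECIES_BAND = 70.0


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().replace("U", "T").encode("ascii"), dtype=np.uint8)


def _score_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Forward dynamic-programming matrix, free end gaps, linear gap cost.

    Row-wise vectorized: the in-row left-gap chain
    ``H[i,j] = max(cand[j], H[i,j-1] + GAP)`` is a prefix maximum of
    ``cand[k] + k`` because GAP == -1 per column.
    """
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1), dtype=np.int16)
    idx = np.arange(m + 1, dtype=np.int16)
    # scores fit int16: |score| <= 12.5k and score+idx <= 25k < 2^15
    sub_rows = {base: np.where(b == base, MATCH, MISMATCH).astype(np.int16)
                for base in np.unique(a)}
    cand = np.empty(m + 1, dtype=np.int16)
    for i in range(1, n + 1):
        prev = H[i - 1]
        cand[0] = 0  # free leading gap
        np.add(prev[:-1], sub_rows[a[i - 1]], out=cand[1:])
        np.maximum(cand[1:], prev[1:] + GAP, out=cand[1:])
        H[i] = np.maximum.accumulate(cand + idx) - idx
    return H


def _best_end(H: np.ndarray) -> tuple[int, int]:
    """Cell where the optimal free-end-gap alignment ends.

    Ties are broken deterministically: last row left-to-right first, then
    last column top-to-bottom.
    """
    n = H.shape[0] - 1
    m = H.shape[1] - 1
    flat = np.concatenate([H[n, :], H[:, m]])
    k = int(np.argmax(flat))
    if k <= m:
        return n, k
    return k - (m + 1), m


def pairwise_identity(seq_a: str | SequenceRecord, seq_b: str | SequenceRecord) -> float:
    """Percent nucleotide identity between two sequences.

    Global alignment with free end gaps; identity is matches divided by the
    number of alignment columns, excluding flanking free-end-gap columns,
    times 100.  Returns 0.0 when the optimal alignment has no aligned
    columns at all.
    """
    a_str = seq_a.sequence if isinstance(seq_a, SequenceRecord) else seq_a
    b_str = seq_b.sequence if isinstance(seq_b, SequenceRecord) else seq_b
    if not a_str or not b_str:
        raise ValueError("pairwise_identity requires two non-empty sequences")
    # canonical argument order: co-optimal alignments are resolved by fixed
    # tie-breaks, so symmetry is guaranteed by aligning in a fixed order
    if (len(a_str), a_str) > (len(b_str), b_str):
        a_str, b_str = b_str, a_str
    a, b = _encode(a_str), _encode(b_str)
    H = _score_matrix(a, b)
    i, j = _best_end(H)
    matches = 0
    columns = 0
    # Traceback with move priority diagonal > up > left; stops at the matrix
    # border, which excludes the leading free end gaps.
    while i > 0 and j > 0:
        s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
        h = H[i, j]
        if h == H[i - 1, j - 1] + s:
            matches += 1 if s == MATCH else 0
            i -= 1
            j -= 1
        elif h == H[i - 1, j] + GAP:
            i -= 1
        else:
            j -= 1
        columns += 1
    if columns == 0:
        return 0.0
    return 100.0 * matches / columns


@dataclass
class IdentityMatrix:
    """Symmetric percent-identity matrix over a set of contigs."""

    ids: list[str]
    values: np.ndarray = field(repr=False)
    orientation: dict[tuple[str, str], str] = field(default_factory=dict, repr=False)

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def to_rows(self) -> list[dict]:
        rows = []
        for i, a in enumerate(self.ids):
            for j in range(i + 1, len(self.ids)):
                rows.append({
                    "contig_a": a,
                    "contig_b": self.ids[j],
                    "percent_identity": round(float(self.values[i, j]), 3),
                })
        return rows


def build_identity_matrix(records: list[SequenceRecord],
                          check_revcomp: bool = True) -> IdentityMatrix:
    """All-vs-all percent identity; each pair is scored in both orientations
    (assembler strand is arbitrary) and the better orientation kept."""
    n = len(records)
    values = np.full((n, n), 0.0)
    np.fill_diagonal(values, 100.0)
    orientation: dict[tuple[str, str], str] = {}
    for i in range(n):
        for j in range(i + 1, n):
            fwd = pairwise_identity(records[i].sequence, records[j].sequence)
            best, orient = fwd, "+"
            if check_revcomp:
                rev = pairwise_identity(
                    records[i].sequence, reverse_complement(records[j].sequence))
                if rev > fwd:
                    best, orient = rev, "-"
            values[i, j] = values[j, i] = best
            orientation[(records[i].id, records[j].id)] = orient
    return IdentityMatrix(ids=[r.id for r in records], values=values,
                          orientation=orientation)


@dataclass
class SpeciesCluster:
    """One viral species: genome-type groups plus a major contig per type."""

    species_id: str
    genome_types: list[list[str]]
    major_contigs: list[str]

    @property
    def members(self) -> list[str]:
        return [c for gt in self.genome_types for c in gt]


class _UnionFind:
    def __init__(self, items: list[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic root: lexicographically smaller wins
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra

    def components(self) -> list[list[str]]:
        groups: dict[str, list[str]] = {}
        for x in self.parent:
            groups.setdefault(self.find(x), []).append(x)
        return [sorted(v) for _, v in sorted(groups.items())]


def cluster_contigs(matrix: IdentityMatrix,
                    read_counts: dict[str, int] | None = None) -> list[SpeciesCluster]:
    """Demarcate species and genome types from the identity matrix.

    Single-linkage: genome types are connected components of the strict
    > 90% graph; species are components of the >= 70% graph.  The major
    contig of a genome type is its member with the most mapped reads
    (ties: lexicographically first id).  Order of input contigs never
    affects the result.
    """
    ids = sorted(matrix.ids)
    counts = read_counts or {}
    species_uf = _UnionFind(ids)
    type_uf = _UnionFind(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            ident = matrix.get(a, b)
            if ident >= SPECIES_BAND:
                species_uf.union(a, b)
            if ident > GENOME_TYPE_BAND:
                type_uf.union(a, b)

    type_components = type_uf.components()
    type_of = {m: tuple(comp) for comp in type_components for m in comp}
    clusters: list[SpeciesCluster] = []
    for k, comp in enumerate(species_uf.components(), start=1):
        genome_types = sorted({type_of[m] for m in comp})
        # major = highest read count, ties to the lexicographically first id
        majors = [
            sorted(gt, key=lambda c: (-counts.get(c, 0), c))[0]
            for gt in genome_types
        ]
        clusters.append(SpeciesCluster(
            species_id=f"SP{k:03d}",
            genome_types=[list(gt) for gt in genome_types],
            major_contigs=majors,
        ))
    return clusters


@dataclass
class VirusGenomeGroup:
    """Full-length segments assigned to one virus by a shared 5' k-mer."""

    group_id: str
    members: list[str]
    terminal_kmer: str
    k: int


def group_segments_by_termini(
    segments: list[SequenceRecord],
    k: int = 9,
    species_of: dict[str, str] | None = None,
) -> tuple[list[VirusGenomeGroup], list[str]]:
    """Group full-length segments sharing an identical 5'-terminal k-mer.

    Unrelated segments of one multi-segment virus share a conserved terminal
    sequence while belonging to different identity-level species clusters,
    so a k-mer spanning several clusters is the expected bisegmented /
    multi-segment signal.  The distinguishability condition guards the
    converse: every species-level cluster must map to a single terminal
    k-mer.  A cluster whose members carry two different terminal k-mers
    (when ``species_of`` is supplied) contradicts terminal conservation —
    every k-mer group touching such a cluster is dissolved and its segments
    are reported ungrouped rather than misgrouped.  Singleton groups are
    allowed.

    Returns ``(groups, ungrouped_segment_ids)``.
    """
    if k < 4:
        raise ValueError(f"terminal k-mer length {k} < 4 is not distinguishing")
    for seg in segments:
        if len(seg.sequence) < k:
            raise ValueError(
                f"segment {seg.id!r} shorter ({len(seg.sequence)} nt) than k={k}"
            )
    by_kmer: dict[str, list[str]] = {}
    kmer_of: dict[str, str] = {}
    for seg in segments:
        kmer = seg.sequence[:k]
        by_kmer.setdefault(kmer, []).append(seg.id)
        kmer_of[seg.id] = kmer

    tainted_kmers: set[str] = set()
    if species_of is not None:
        cluster_kmers: dict[str, set[str]] = {}
        for seg_id, kmer in kmer_of.items():
            cluster = species_of.get(seg_id)
            if cluster is not None:
                cluster_kmers.setdefault(cluster, set()).add(kmer)
        for cluster, kmers in cluster_kmers.items():
            if len(kmers) > 1:
                logger.warning(
                    "species cluster %s carries %d distinct terminal %d-mers "
                    "%s; dissolving the affected groups", cluster, len(kmers),
                    k, sorted(kmers))
                tainted_kmers.update(kmers)

    groups: list[VirusGenomeGroup] = []
    ungrouped: list[str] = []
    n = 0
    for kmer in sorted(by_kmer):
        members = sorted(by_kmer[kmer])
        if kmer in tainted_kmers:
            ungrouped.extend(members)
            continue
        n += 1
        groups.append(VirusGenomeGroup(
            group_id=f"VG{n:03d}", members=members, terminal_kmer=kmer, k=k))
    return groups, ungrouped
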