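# Methods

## The problem and the model

dsRNA virome sequencing by loop-primer ligation (FLDS) yields libraries
with two structural properties the informatics relies on: (i) reads whose
fragment end coincides with a true genome-segment terminus stop exactly at
the terminal base, producing a dominant read-stop pileup there, and (ii)
those reads carry PC2 primer sequence (`CCGAATTCCCGGGATCC`, or its reverse
complement) immediately outside the terminal base, which trimming removes
and which the trim sidecar preserves as evidence. Total RNA-seq of the
same community, primed randomly, shows neither property: read boundaries
near termini are diffuse and primer evidence is absent. The pipeline turns
these contrasts into curated full-length genome segments and comparative
statistics.

Coordinates are 0-based half-open throughout; SAM ingestion/emission is
the only 1-based surface. Sequences are normalized to uppercase DNA
(U → T) on input; motif scanning re-maps T → U because frameshift signals
are RNA-space patterns. Reads are counted per distinct read id, mates
separately.

## Stages and their parameters

**Trimming** (`trim_map.trim_reads`). Longest primer overlap at either read
end (≥ 10 nt, ≤ 1 mismatch, against PC2 and its reverse complement) is
removed and recorded verbatim in a `TrimRecord`; then a width-4 sliding
window trims the 3′ end while the window mean quality is below Q20,
followed by removal of any remaining sub-threshold trailing bases. Reads
shorter than 50 nt afterwards are dropped. The reference protocol used a
commercial workbench with unstated defaults, so all four constants are
explicit configuration here.

**Mapping** (`trim_map.map_reads`). Exact 21-mer seeds (both orientations,
seeds every 42 nt plus the read's final position) anchor candidate
placements; ungapped extension counts substitutions; the best placement is
reported if its mismatch rate is ≤ 0.03. Ties are unmapped under
`require_unique` (default), otherwise resolved to the lexicographically
smallest (contig, start, strand). The mapper is substitution-only by
design — the simulator introduces no indels — and is a pluggable stage:
any external SAM can be fed to the downstream stages instead.

**Contig confirmation** (`contig_curation.qc_filter`). Per-base coverage
≥ 3, mean coverage ≥ 10, length ≥ 1,000 bp, all inclusive ("at least").

**Terminal calling** (`contig_curation.call_termini`). Read stops are
tallied within 100 nt of each contig end (left table keyed by alignment
start, right table by exclusive end). A position qualifies when its count
strictly exceeds 10 ("more than 10 reads"); the maximal position wins, ties
going to the position closest to the contig end, one call per side. Primer
confirmation requires ≥ 1 supporting read whose removed piece adjacent to
the stop (removed prefix for plus-strand reads at a left stop, mirrored
otherwise) overlaps PC2 by ≥ 10 nt with ≤ 1 mismatch. A poly(A) tail —
an A-run of ≥ 10 nt within the 3′-terminal 20 nt — confirms the right side
instead (the poly(A) exception; run length and window are this package's
quantification, the protocol states none). A contig with confirmed calls
on both sides is a full-length segment; two confirmed calls on one side
are an error (ambiguous terminus).

**Demarcation** (`classify`). Percent identity comes from a global
alignment with free end gaps (match +1, mismatch −1, gap −1, terminal gaps
unpenalized): identity = matches / alignment columns, flanking free-end-gap
columns excluded. The DP is vectorized row-wise in int16 (valid because
|score| ≤ sequence length ≤ 12.5 kb < 2¹⁵); the in-row left-gap chain is a
prefix maximum since the gap cost is −1 per column. Arguments are
canonicalized (shorter/lexicographically smaller first) before alignment:
co-optimal alignments are resolved by fixed tie-breaks (diagonal > up >
left; alignment end chosen last-row-first, then last column), and without a
canonical order those tie-breaks would make identity asymmetric.
Each contig pair is scored in both orientations (assembler strand is
arbitrary) and the better orientation kept. Genome types are single-linkage
components of the strict > 90% graph, species of the ≥ 70% graph; 90.0
exactly falls in the species band (the published wording leaves the
boundary open). The major contig of a genome type is its member with most
mapped reads.

**Segment grouping** (`classify.group_segments_by_termini`). Full-length
segments sharing an identical 5′-terminal 9-mer form one virus group. The
distinguishability guard uses the identity clustering: a species-level
cluster whose members carry two *different* terminal k-mers contradicts
terminal conservation, so every k-mer group touching such a cluster is
dissolved and its segments reported ungrouped rather than misgrouped.
Limitation: two unrelated viruses given identical terminal motifs are
indistinguishable without taxonomic evidence (out of scope) and would be
grouped together; the simulator therefore assigns species-unique motifs,
and the collision tests inject the detectable (variant-linked) form.
Grouping uses 5′ termini only; a 3′ check is not implemented because the
published evidence is 5′-terminal.

**Annotation** (`annotate`). ORFs are ATG-initiated, ≥ 100 codons by
default, both strands, every qualifying ATG reported (nested ORFs
included), edge-running ORFs flagged incomplete. They are a proxy for CDS
predictions (similarity-based CDS calling is out of scope). The "upstream
region of the 2nd CDS" is quantified as the interval between the starts of
the two leading forward-strand ORFs. Frameshift windows satisfying several
classes are reported once per class (CCCUUUU is also a valid −1 heptamer);
reverse-strand scans report reverse-strand coordinates and are off by
default. UGA read-through: the longest ATG-initiated ORF under
mold-mitochondrial decoding (UGA = Trp) is located per frame and its
internal standard-code UGA stops counted; ≥ 2 flags a mitovirus-like
segment.

**Comparison** (`compare_stats`). Frequencies are distinct mapped reads
over the trimmed library total; folds with an RNA-seq frequency of zero
are undefined and excluded from the arithmetic mean (the published mean
coexists with contigs absent from RNA-seq, implying the same exclusion).
CV uses the population (n-denominator) standard deviation; the source does
not specify n vs n−1.

## The simulator: what it emulates, and what it does not

`generate_community` draws `n_species` viruses (default 8) with 1–3
segments of 1,000–12,500 nt (the span of reported full-length segments),
a species-unique 9 nt 5′-terminal motif installed on every segment,
dsRNA/ssRNA molecule types (20% ssRNA, half of those polyadenylated with a
20 nt tail), and lognormal relative abundances (σ = 0.8) normalized to
mean 1 and floored at 0.1 so every segment clears the confirmation
thresholds at the default depth. With probability 0.25 a species gains a
genome-type variant by point mutation to a target identity drawn
U[0.70, 0.95]; the upper cap stays below near-duplicate identities because
variants above ~0.97 identity contain runs of > 300 identical nt, which
make 300 nt reads unmappable under unique mapping and would break per-base
QC for both variants — the cap keeps genome types resolvable at the
design's read length. Variant abundance is a U[0.05, 0.4] fraction of the
parent's, floored at 0.1.

`simulate_flds_library` represents each segment as
round(300 × abundance) molecule copies; each copy is cut at
Poisson-scattered breakpoints (mean fragment ≈ 500 nt), so the outermost
pieces of every copy end exactly at the true termini — that, not an ad hoc
weight, is the origin of the terminal pileup. Each fragment yields a read
pair (300 nt) from its two ends; terminus-coincident reads are prefixed
with the reverse complement of PC2; terminus-abutting fragments are
emitted 3× in expectation (`terminal_boost`, emulating the elevated
terminal coverage of loop-primer libraries; the source reports the effect
only qualitatively, so the factor is this package's choice). Non-viral
contaminant pairs are added at 1.8% to echo the reported ~98.2% viral read
rate. Substitution errors at 0.1%; constant Q37 qualities (quality-trim
tests degrade tails explicitly).

`simulate_rnaseq_library` draws 200,000 reads (a desk-scale stand-in for
the multi-million-read comparison library): 56% from a synthetic rRNA
pool, 0.3% from viral segments, the rest from a synthetic host mRNA pool.
Viral fragment boundaries are uniform but constrained to [1, L−1]
(random-priming end loss, default margin parameterized at 20 nt), so no
read boundary coincides with a true terminus.

Simplifications to keep in mind when reading test results: only
terminus-coincident reads carry primer sequence (in the real chemistry all
fragment ends are ligated; interior primer carry-over is irrelevant to the
caller because interior stops are never dominant, so it is not modeled);
rRNA/mRNA backgrounds are random composites, not real sequences — taxonomy
is out of scope; there are no indel errors, no PCR duplicates, and no
assembly step (the simulated segments double as the contigs, so the
pipeline's recall statements are about terminal detection and
classification, not about assembler behavior on real data).

## Problem sizes and numerical choices

The validation suite and the acceptance script run the full study at
8 species / 14 segments (plus any genome-type variants), ~300× FLDS depth
(~160 k reads) and 200 k RNA-seq reads — sizes chosen so the whole suite
completes in a couple of minutes on one CPU while every terminus still
receives a > 10-read pileup with wide margin. Identity matrices allocate
one (n+1)×(m+1) int16 DP table per pair (≤ ~310 MB at the maximal 12.5 kb
pair). Degenerate inputs: empty sequences are rejected by
`pairwise_identity`; an all-zero coverage vector has no CV; a stop-tally
window longer than the contig is clamped; fragments longer than a segment
are truncated to the full segment by construction of the breakpoint model.

## Known limitations

Assembly, BLAST/MEGAN taxonomy, rRNA reconstruction and RdRp phylogenetics
are out of scope. The mapper has no gapped or spliced alignment. The
poly(A) confirmation applies to the right (3′) side of the contig as
assembled. Grouping cannot detect terminal-motif collisions between
viruses that share no identity-level link. Desk-scale enrichment means
(~320–455× across seeds) are a property of the simulated study design, not
a reproduction of the field study's value, which derives from multi-million
read libraries and assembled contigs.
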