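# flds — dsRNA virome informatics: terminal-end detection, species demarcation and FLDS-vs-RNA-seq statistics

RNA viruses rarely leave a DNA trace, but almost all of them produce
long double-stranded RNA (dsRNA) — as genome or as replicative
intermediate. FLDS (fragmented and loop-primer-ligated dsRNA sequencing)
exploits this: purified dsRNA is fragmented, a loop primer is ligated to
every fragment end, and single-primer PCR (primer **PC2**,
`CCGAATTCCCGGGATCC`) produces a sequencing library in which reads derived
from the *true ends of viral genome segments* stop exactly at the terminal
base and carry primer sequence immediately outside it.

This package implements the informatics half of that protocol for
virome researchers, as a tested Python library and `flds` command line
tool:

* **Contig confirmation** — a contig is kept when built at ≥ 3× per-base
  coverage, ≥ 10× average coverage and ≥ 1,000 bp.
* **Terminal-end detection** — a position near a contig end where more
  than 10 reads stop at the same coordinate is a candidate terminus; it is
  *confirmed* by adjacent PC2-derived sequence in the supporting reads'
  trim records, or by a 3′ poly(A) tail. Contigs confirmed on both sides
  are full-length genome segments.
* **Species / genome-type demarcation** — from pairwise nucleotide
  identity (global alignment, free end gaps): identity > 90% links contigs
  into one *genome type*; 70–90% links genome types of one *species*;
  within a genome type the contig with the most mapped reads is the
  *major contig*.
* **Segment composition** — full-length segments sharing an identical
  5′-terminal k-mer (default k = 9) are grouped into one multi-segment
  virus, because segment termini are conserved within a viral genome.
* **Annotation scans** — ATG-initiated ORFs; −1 ribosomal frameshift
  heptamers XXXYYYZ (XXX three identical nucleotides, YYY ∈ {AAA, UUU},
  Z ∈ {A, U, C}) and +1 signals CCCUUUU / UCCUUUCGU, scanned in RNA space
  upstream of the 2nd CDS; poly(A) tails; in-frame UGA codons read through
  under mold-mitochondrial decoding (≥ 2 flags a mitovirus-like segment).
* **Library comparison** — per-contig read frequency
  f = mapped reads / trimmed library total, fold enrichment
  f_FLDS / f_RNA-seq (undefined folds excluded from the mean), and
  coverage uniformity as CV = σ(depth) / mean(depth).
* **Simulator** — seeded, ground-truthed generation of multi-segment viral
  communities and of FLDS / total RNA-seq read libraries reproducing the
  structural artifacts above (terminal read-stop pileups with primer
  carry-over in FLDS; rRNA-dominated RNA-seq with ~0.3% viral reads and no
  terminal stops).

## Worked example

Run the whole pipeline on a small simulated community:

```bash
flds run --seed 11 --out runout
```

or, in Python:

```python
from flds.pipeline import PipelineConfig, run_pipeline
from flds.simulate import SimConfig

cfg = PipelineConfig(seed=11, sim=SimConfig(
    seed=11, n_species=3, segment_length_range=(1000, 4000),
    flds_coverage=100.0, rnaseq_n_reads=20_000))
manifest = run_pipeline(cfg, "runout")
```

The manifest printed for this config and seed:

```
contigs_in                       6
flds_trimmed_reads               10754
rnaseq_trimmed_reads             20000
contigs_passing_qc               6
full_length_segments             6
terminal_calls                   12
species_clusters                 5
genome_groups                    3
flds_viral_rate_percent          98.0
rnaseq_viral_rate_percent        0.3
mean_fold_enrichment             382.4
```

Reading it: the simulated community has 3 viral species with 6 genome
segments total (one species carries a genome-type variant, hence 5
identity-level clusters); all 6 contigs pass the coverage/length filters,
both termini of every segment are recovered and confirmed (12 terminal
calls, 6 full-length segments), and grouping by conserved 5′-terminal
9-mers reassembles exactly the 3 multi-segment viruses. 98.0% of trimmed
FLDS reads map to the viral contigs versus 0.3% of total RNA-seq reads —
a ~380-fold mean per-contig enrichment.

Per-stage outputs (QC report, terminal calls, identity matrix, clusters,
virus groups, ORF/frameshift annotation, enrichment table) are written as
TSV next to the manifest; each stage is also available as its own
subcommand (`flds sim|trim|map|curate|classify|annotate|compare`) operating
on FASTA/FASTQ/SAM/TSV files, so externally produced alignments can be
substituted for the built-in mapper.

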