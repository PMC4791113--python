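"""End-to-end orchestration: sim -> trim -> map -> curate -> classify ->
annotate -> compare, under a single config and seed.

Every stage logs one structured line with its input/output counts, and the
run manifest aggregates the same counts, so identical (config, seed) runs
produce identical manifests.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from flds import __version__
from flds.annotate import count_uga_readthrough, detect_polya, find_orfs, \
    scan_frameshift_signals, upstream_of_second_cds
from flds.classify import build_identity_matrix, cluster_contigs, \
    group_segments_by_termini
from flds.compare_stats import build_enrichment_table, summarize_libraries
from flds.contig_curation import QCThresholds, TerminalParams, \
    call_termini, classify_completeness, qc_filter, tally_read_stops
from flds.formats_io import compute_coverage, write_fasta, write_fastq, \
    write_sam, write_tsv
from flds.simulate import Community, SimConfig, generate_community, \
    simulate_flds_library, simulate_rnaseq_library
from flds.trim_map import MapperConfig, map_reads, trim_reads

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class TrimConfig:
    quality_threshold: int = 20
    min_overlap: int = 10
    max_primer_mismatch: int = 1
    min_length: int = 50


@dataclass
class PipelineConfig:
    """All module parameter blocks plus the seed, defaulting to the published
    protocol values (QC 3x/10x/1000 bp, terminal support > 10, 70/90 identity
    bands, k = 9)."""

    seed: int = 1
    sim: SimConfig = None  # filled from seed when absent
    trim: TrimConfig = field(default_factory=TrimConfig)
    mapper: MapperConfig = field(default_factory=MapperConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    terminal: TerminalParams = field(default_factory=TerminalParams)
    terminal_kmer: int = 9
    min_orf_aa: int = 100

    def __post_init__(self) -> None:
        if self.sim is None:
            self.sim = SimConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        blocks = {
            "sim": SimConfig, "trim": TrimConfig, "mapper": MapperConfig,
            "qc": QCThresholds, "terminal": TerminalParams,
        }
        kwargs = {}
        for key, value in raw.items():
            if key in blocks:
                if key == "sim" and "seed" not in value:
                    value = {**value, "seed": raw.get("seed", 1)}
                value = {k: tuple(v) if isinstance(v, list) else v
                         for k, v in value.items()}
                kwargs[key] = blocks[key](**value)
            elif key in ("seed", "terminal_kmer", "min_orf_aa"):
                kwargs[key] = value
            else:
                raise ValueError(f"unknown config block {key!r}")
        return cls(**kwargs)

    def to_yaml(self, path: str | os.PathLike) -> None:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj

        with open(path, "w") as fh:
            yaml.safe_dump(clean(dataclasses.asdict(self)), fh, sort_keys=True)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - abort names the stage
                raise PipelineError(name, exc) from exc
            return out
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig, outdir: str | os.PathLike,
                 overwrite: bool = False) -> dict:
    """Run the whole pipeline; returns the run manifest (also written to
    ``manifest.tsv`` and ``manifest.txt`` in ``outdir``).

    Refuses to reuse an output directory containing a manifest unless
    ``overwrite`` is set; a failing stage aborts with the stage name, and
    outputs of completed stages are retained.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if (out / "manifest.tsv").exists() and not overwrite:
        raise PipelineError("setup", FileExistsError(
            f"{out}/manifest.tsv exists; pass overwrite=True to redo the run"))

    manifest: dict = {"flds_version": __version__, "seed": config.seed}
    config.to_yaml(out / "config.yaml")

    community, flds_lib, rnaseq_lib = _run_sim(config, out)
    manifest["contigs_in"] = len(community.segments)
    manifest["true_species"] = len(community.specs)

    trimmed_flds, trim_recs_flds = _run_trim(config, flds_lib, out, "flds")
    trimmed_rna, trim_recs_rna = _run_trim(config, rnaseq_lib, out, "rnaseq")
    manifest["flds_trimmed_reads"] = len(trimmed_flds)
    manifest["rnaseq_trimmed_reads"] = len(trimmed_rna)

    aln_flds = _run_map(config, trimmed_flds, community, out, "flds")
    aln_rna = _run_map(config, trimmed_rna, community, out, "rnaseq")
    manifest["flds_mapped_reads"] = len(aln_flds)
    manifest["rnaseq_mapped_reads"] = len(aln_rna)

    passing, statuses, calls = _run_curate(
        config, community, aln_flds, trim_recs_flds, out)
    manifest["contigs_passing_qc"] = len(passing)
    manifest["full_length_segments"] = sum(
        1 for s in statuses if s.completeness == "full-length")
    manifest["terminal_calls"] = len(calls)

    clusters, groups, ungrouped = _run_classify(
        config, passing, statuses, aln_flds, out)
    manifest["species_clusters"] = len(clusters)
    manifest["genome_groups"] = len(groups)
    manifest["ungrouped_segments"] = len(ungrouped)

    annotation_rows = _run_annotate(config, passing, out)
    manifest["frameshift_hits"] = int(sum(r["frameshift_hits"] for r in annotation_rows))
    manifest["polya_contigs"] = int(sum(r["polya"] for r in annotation_rows))

    summaries, mean_fold = _run_compare(
        config, clusters, community, aln_flds, len(trimmed_flds),
        aln_rna, len(trimmed_rna), out)
    for s in summaries:
        manifest[f"{s.library}_viral_rate_percent"] = s.viral_rate
    manifest["mean_fold_enrichment"] = (
        round(mean_fold, 1) if mean_fold == mean_fold else "undefined")

    write_tsv(({"key": k, "value": v} for k, v in manifest.items()),
              out / "manifest.tsv")
    with open(out / "manifest.txt", "w") as fh:
        fh.write("FLDS pipeline run manifest\n")
        for k, v in manifest.items():
            fh.write(f"  {k:32s} {v}\n")
    logger.info("pipeline done: %s", manifest)
    return manifest


@_stage("sim")
def _run_sim(config: PipelineConfig, out: Path):
    community = generate_community(config.sim)
    flds_lib = simulate_flds_library(community, config.sim)
    rnaseq_lib = simulate_rnaseq_library(community, config.sim)
    write_fasta(community.segments, out / "community.fasta")
    for name, lib in (("flds", flds_lib), ("rnaseq", rnaseq_lib)):
        r1, r2, truth = lib
        write_fastq(r1, out / f"{name}_R1.fastq")
        write_fastq(r2, out / f"{name}_R2.fastq")
        truth.to_tsv(out / f"{name}_truth.tsv")
    logger.info("stage=sim contigs=%d flds_pairs=%d rnaseq_pairs=%d",
                len(community.segments), len(flds_lib[0]), len(rnaseq_lib[0]))
    return community, flds_lib, rnaseq_lib


@_stage("trim")
def _run_trim(config: PipelineConfig, lib, out: Path, name: str):
    r1, r2, _ = lib
    trimmed, recs = trim_reads(
        r1 + r2,
        quality_threshold=config.trim.quality_threshold,
        min_overlap=config.trim.min_overlap,
        max_primer_mismatch=config.trim.max_primer_mismatch,
        min_length=config.trim.min_length,
    )
    write_fastq(trimmed, out / f"{name}_trimmed.fastq")
    write_tsv((dataclasses.asdict(r) for r in recs), out / f"{name}_trim_sidecar.tsv")
    logger.info("stage=trim lib=%s in=%d retained=%d", name, len(r1) + len(r2),
                len(trimmed))
    return trimmed, {r.read_id: r for r in recs}


@_stage("map")
def _run_map(config: PipelineConfig, reads, community: Community, out: Path,
             name: str):
    alignments = map_reads(reads, community.segments, config.mapper)
    write_sam(alignments, {r.id: len(r.sequence) for r in community.segments},
              out / f"{name}.sam")
    logger.info("stage=map lib=%s reads=%d mapped=%d", name, len(reads),
                len(alignments))
    return alignments


@_stage("curate")
def _run_curate(config: PipelineConfig, community: Community, alignments,
                trim_records, out: Path):
    by_contig: dict[str, list] = {r.id: [] for r in community.segments}
    for aln in alignments:
        by_contig[aln.contig_id].append(aln)
    coverage = {r.id: compute_coverage(by_contig[r.id], len(r.sequence), r.id)
                for r in community.segments}
    passing, report = qc_filter(community.segments, coverage, config.qc)
    write_tsv(report, out / "qc_report.tsv")

    statuses, all_calls = [], []
    for contig in passing:
        tables = tally_read_stops(by_contig[contig.id], len(contig.sequence),
                                  config.terminal.window)
        calls = call_termini(tables, trim_records, contig.sequence,
                             config.terminal)
        all_calls.extend(calls)
        statuses.append(classify_completeness(contig, calls))
    write_tsv(({
        "contig_id": c.contig_id, "side": c.side, "position": c.position,
        "support": c.support, "primer_confirmed": c.primer_confirmed,
        "polyA": c.polyA, "status": c.status} for c in all_calls),
        out / "terminal_calls.tsv")
    write_tsv(({
        "contig_id": s.contig_id, "completeness": s.completeness}
        for s in statuses), out / "segment_status.tsv")
    logger.info("stage=curate contigs=%d passing=%d full_length=%d",
                len(community.segments), len(passing),
                sum(1 for s in statuses if s.completeness == "full-length"))
    return passing, statuses, all_calls


@_stage("classify")
def _run_classify(config: PipelineConfig, passing, statuses, aln_flds,
                  out: Path):
    read_counts: dict[str, int] = {}
    for aln in aln_flds:
        read_counts[aln.contig_id] = read_counts.get(aln.contig_id, 0) + 1
    matrix = build_identity_matrix(passing)
    write_tsv(matrix.to_rows(), out / "identity_matrix.tsv")
    clusters = cluster_contigs(matrix, read_counts)
    rows = []
    species_of = {}
    for cl in clusters:
        for gt_index, gt in enumerate(cl.genome_types):
            for contig in gt:
                species_of[contig] = cl.species_id
                rows.append({
                    "contig_id": contig,
                    "species": cl.species_id,
                    "genome_type": chr(ord("A") + gt_index),
                    "major": contig == cl.major_contigs[gt_index],
                    "mapped_reads": read_counts.get(contig, 0),
                })
    write_tsv(rows, out / "clusters.tsv")

    full_ids = {s.contig_id for s in statuses if s.completeness == "full-length"}
    full_segments = [c for c in passing if c.id in full_ids]
    groups, ungrouped = group_segments_by_termini(
        full_segments, config.terminal_kmer, species_of)
    write_tsv(({
        "group_id": g.group_id, "members": ",".join(g.members),
        "terminal_kmer": g.terminal_kmer} for g in groups),
        out / "virus_groups.tsv")
    logger.info("stage=classify species=%d groups=%d ungrouped=%d",
                len(clusters), len(groups), len(ungrouped))
    return clusters, groups, ungrouped


@_stage("annotate")
def _run_annotate(config: PipelineConfig, passing, out: Path):
    rows = []
    for contig in passing:
        orfs = find_orfs(contig, min_aa=config.min_orf_aa)
        region = upstream_of_second_cds(orfs)
        hits = scan_frameshift_signals(contig, region=region)
        polya, _ = detect_polya(contig)
        uga, mito_like = count_uga_readthrough(contig)
        rows.append({
            "contig_id": contig.id,
            "n_orfs": len(orfs),
            "frameshift_hits": len(hits),
            "polya": polya,
            "uga_readthrough": uga,
            "mitovirus_like": mito_like,
        })
    write_tsv(rows, out / "annotation_summary.tsv")
    logger.info("stage=annotate contigs=%d", len(rows))
    return rows


@_stage("compare")
def _run_compare(config: PipelineConfig, clusters, community: Community,
                 aln_flds, total_flds, aln_rna, total_rna, out: Path):
    majors = sorted({m for cl in clusters for m in cl.major_contigs})
    by_contig_flds: dict[str, list] = {}
    for aln in aln_flds:
        by_contig_flds.setdefault(aln.contig_id, []).append(aln)
    by_contig_rna: dict[str, list] = {}
    for aln in aln_rna:
        by_contig_rna.setdefault(aln.contig_id, []).append(aln)
    lengths = {r.id: len(r.sequence) for r in community.segments}
    cov_flds = {c: compute_coverage(by_contig_flds.get(c, []), lengths[c], c)
                for c in majors}
    cov_rna = {c: compute_coverage(by_contig_rna.get(c, []), lengths[c], c)
               for c in majors}
    records, mean_fold = build_enrichment_table(
        aln_flds, total_flds, aln_rna, total_rna,
        coverage_flds=cov_flds, coverage_rnaseq=cov_rna, contigs=majors)
    write_tsv(({
        "contig_id": r.contig_id,
        "freq_flds": r.freq_flds, "freq_rnaseq": r.freq_rnaseq,
        "fold": r.fold if r.fold_defined else "undefined",
        "cv_flds": r.cv_flds, "cv_rnaseq": r.cv_rnaseq} for r in records),
        out / "enrichment.tsv")

    viral_set = {r.id for r in community.segments}
    summaries = summarize_libraries(
        {"flds": (total_flds, aln_flds), "rnaseq": (total_rna, aln_rna)},
        viral_set)
    write_tsv(({
        "library": s.library, "trimmed_reads": s.trimmed_reads,
        "viral_reads": s.viral_reads, "viral_rate": s.viral_rate,
        "unmapped_reads": s.unmapped_reads, "unmapped_rate": s.unmapped_rate}
        for s in summaries), out / "library_summary.tsv")
    logger.info("stage=compare majors=%d mean_fold=%s", len(majors), mean_fold)
    return summaries, mean_fold
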