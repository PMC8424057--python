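"""Pipeline driver: assign → sort → mark duplicates → shard → call → merge.

Regions are the unit of parallelism; within-region work is sequential and
deterministic, and results are assembled in region order regardless of
completion order, so every final artifact is invariant to the worker count.
"""

from __future__ import annotations

import json
import logging
import os
import shlex
import subprocess
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

from . import dupmark, shards
from .regions import UNPLACED_REGION, DEFAULT_TARGET_SIZE, RegionTable, build_regions
from .sam import ReadBatch, SamHeader, parse_sam_line, to_keyed
from .shards import CallerTemplate, ShardManifest

__all__ = [
    "PipelineConfig",
    "PreprocessResult",
    "StageError",
    "ConfigError",
    "load_alignments",
    "assign_batches",
    "preprocess",
    "full_pipeline",
]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is part of the message."""


class ConfigError(ValueError):
    """The pipeline configuration is invalid."""


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run."""

    reference_index_path: str | None = None
    region_target_size: int = DEFAULT_TARGET_SIZE
    n_chunks: int = 1
    max_parallel_workers: int = 1
    caller_template: CallerTemplate | None = None
    pad: int = 0
    seed: int = 0
    output_dir: str = "."
    log_level: str = "INFO"
    aligner_command: str | None = None  # optional: {r1} {r2} {out_sam}
    reference_fasta: str | None = None

    def validate(self) -> None:
        if self.max_parallel_workers < 1:
            raise ConfigError("max_parallel_workers must be >= 1")
        if self.pad < 0:
            raise ConfigError("pad must be >= 0")
        if self.region_target_size < 1:
            raise ConfigError("region_target_size must be >= 1")
        for p in (self.reference_index_path, self.reference_fasta):
            if p is not None and not os.path.exists(p):
                raise ConfigError(f"path does not exist: {p}")


@dataclass
class PreprocessResult:
    """Artifacts and accounting of the pre-processing stage."""

    manifest: ShardManifest
    region_counts: dict[int, int]
    duplicate_decisions: int
    duplicate_qnames: set[str]
    unplaced_count: int
    total_records: int
    mc_fallback_count: int = 0
    report_path: str | None = None

    @property
    def placed_count(self) -> int:
        return sum(self.region_counts.values())


def load_alignments(path: str) -> tuple[SamHeader, list]:
    """Read a SAM (text) or BAM file into (header, KeyedRead list).

    SAM text is parsed line by line (with line numbers in errors); BAM is
    decoded through pysam and re-serialised to SAM text values.
    """
    keyed = []
    if path.endswith(".bam"):
        import pysam

        with pysam.AlignmentFile(path, "rb", check_sq=False) as bam:
            header = SamHeader.from_text(str(bam.header))
            for aln in bam.fetch(until_eof=True):
                keyed.append(to_keyed(parse_sam_line(aln.to_string())))
        return header, keyed
    header_lines: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("@"):
                header_lines.append(line)
                continue
            try:
                keyed.append(to_keyed(parse_sam_line(line)))
            except Exception as exc:
                raise StageError(
                    f"preprocess: malformed alignment record at line {lineno}: {exc}"
                ) from exc
    return SamHeader(header_lines), keyed


def assign_batches(
    keyed_reads, table: RegionTable
) -> tuple[dict[int, ReadBatch], int]:
    """Route keyed reads into per-region batches by their own POS.

    Unmapped reads, reads with RNAME ``*`` and reads on contigs absent from
    the table go to the unplaced pseudo-region.  Returns
    ``(region_id -> sealed batch, n_unknown_contig)``.
    """
    batches: dict[int, ReadBatch] = {}
    unknown = 0
    for k in keyed_reads:
        if k.rname == "*" or k.pos == 0:
            rid = UNPLACED_REGION
        else:
            try:
                rid = table.assign_region(k.rname, k.pos)
            except KeyError:
                unknown += 1
                logger.warning("contig %r absent from region table; read unplaced", k.rname)
                rid = UNPLACED_REGION
        batches.setdefault(rid, ReadBatch(rid)).append(k)
    return {rid: b.seal() for rid, b in batches.items()}, unknown


def _route_candidates(
    pairs, fragments, table: RegionTable
) -> dict[int, tuple[list, list]]:
    """Group candidates by routing region.

    A pair is routed to the region containing its smaller canonical end; a
    fragment to the region containing its own end.  Coordinates are clamped
    into the contig span (clipping can push an unclipped coordinate past an
    edge).  All members of one duplicate group share their end coordinates,
    so every group lands complete in exactly one routing region.
    """
    routed: dict[int, tuple[list, list]] = {}
    for c in pairs:
        rname, coord, _ = c.key.end1
        rid = table.assign_region_clamped(rname, coord)
        routed.setdefault(rid, ([], []))[0].append(c)
    for c in fragments:
        rname, coord, _ = c.key.end1
        rid = table.assign_region_clamped(rname, coord)
        routed.setdefault(rid, ([], []))[1].append(c)
    return routed


def preprocess(
    input_path: str,
    table: RegionTable,
    outdir: str,
    max_workers: int = 1,
    header: SamHeader | None = None,
    keyed_reads=None,
) -> PreprocessResult:
    """Sort, duplicate-mark and shard an alignment file per region.

    Either ``input_path`` (SAM/BAM) or pre-loaded ``(header, keyed_reads)``
    may be given.  Emits one indexed BAM shard per region under ``outdir``,
    an ``unplaced.sam`` for reads outside the partition, a JSON manifest and
    a machine-readable run report with conservation checks.
    """
    os.makedirs(outdir, exist_ok=True)
    if keyed_reads is None or header is None:
        header, keyed_reads = load_alignments(input_path)
    total = len(keyed_reads)

    batches, _ = assign_batches(keyed_reads, table)
    unplaced = batches.pop(UNPLACED_REGION, None)

    # contig rank for canonical pair-end ordering
    contig_rank = {name: i for i, (name, _) in enumerate(table.contig_order)}
    rg_lb = header.rg_to_lb()

    # candidates are built from all mapped primary records so read pairs
    # spanning a region boundary are joined before routing
    all_records = [rec for b in batches.values() for rec in b.records()]
    pairs, fragments = dupmark.build_pair_candidates(
        all_records, rg_lb, contig_rank=contig_rank
    )
    routed = _route_candidates(pairs, fragments, table)

    def mark_one(rid: int):
        p, f = routed[rid]
        return dupmark.mark_duplicates(p, f)

    with ThreadPoolExecutor(max_workers=max(1, max_workers)) as pool:
        decision_sets = list(pool.map(mark_one, sorted(routed)))
    decisions: set = set()
    for ds in decision_sets:
        decisions |= ds

    # per storage region: sort, apply marks, write shard
    def process_region(rid: int):
        sorted_batch = dupmark.sort_region(batches[rid])
        marked, matched = dupmark.apply_marks(sorted_batch, decisions)
        shard_path = os.path.join(outdir, f"region_{rid:04d}.bam")
        entry = shards.write_region_shard(
            marked, header, table.region(rid), shard_path
        )
        return rid, entry, matched

    region_ids = sorted(batches)
    with ThreadPoolExecutor(max_workers=max(1, max_workers)) as pool:
        results = list(pool.map(process_region, region_ids))

    matched_all: set = set()
    manifest = ShardManifest()
    region_counts: dict[int, int] = {}
    for rid, entry, matched in sorted(results, key=lambda t: t[0]):
        manifest.entries.append(entry)
        region_counts[rid] = entry.read_count
        matched_all |= matched
    # empty regions still get (empty) shards so callers can run uniformly
    for region in table:
        if region.region_id not in region_counts:
            shard_path = os.path.join(outdir, f"region_{region.region_id:04d}.bam")
            entry = shards.write_region_shard(
                ReadBatch(region.region_id).seal(), header, region, shard_path
            )
            manifest.entries.append(entry)
            region_counts[region.region_id] = 0
    manifest.entries.sort(key=lambda e: e.region_id)

    unmatched = decisions - matched_all
    if unmatched:
        raise dupmark.ReconciliationError(
            f"{len(unmatched)} duplicate decisions matched no stored record, "
            f"e.g. {sorted(unmatched)[:3]}"
        )

    unplaced_count = len(unplaced) if unplaced is not None else 0
    if unplaced is not None:
        with open(os.path.join(outdir, "unplaced.sam"), "w") as fh:
            fh.write(header.to_text())
            for k in unplaced:
                fh.write(k.sam + "\n")

    manifest_path = os.path.join(outdir, "manifest.json")
    manifest.save(manifest_path)
    placed = sum(region_counts.values())
    report = {
        "total_records": total,
        "placed_records": placed,
        "unplaced_records": unplaced_count,
        "duplicate_decisions": len(decisions),
        "duplicate_pairs_and_fragments_flagged": len({q for q, _ in decisions}),
        "region_read_counts": {str(r): c for r, c in sorted(region_counts.items())},
        "conservation_ok": placed + unplaced_count == total,
    }
    report_path = os.path.join(outdir, "preprocess_report.json")
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1)
    if not report["conservation_ok"]:
        raise StageError("preprocess: read-count conservation check failed")
    for rid, count in region_counts.items():
        logger.info("region %d: %d reads", rid, count)
    logger.info(
        "preprocess: %d records, %d placed, %d duplicate decisions",
        total, placed, len(decisions),
    )
    return PreprocessResult(
        manifest=manifest,
        region_counts=region_counts,
        duplicate_decisions=len(decisions),
        duplicate_qnames={q for q, _ in decisions},
        unplaced_count=unplaced_count,
        total_records=total,
        report_path=report_path,
    )


def _run_aligner_on_chunks(
    config: PipelineConfig, r1: str, r2: str | None, workdir: str
) -> str:
    """Chunk FASTQ input and run the external aligner per chunk; returns the
    path of the concatenated SAM."""
    import shutil as _shutil

    from . import fastq as fq

    assert config.aligner_command is not None
    exe = shlex.split(config.aligner_command)[0]
    if _shutil.which(exe) is None and not os.path.exists(exe):
        raise ConfigError(f"aligner executable {exe!r} not found")
    chunk_dir = os.path.join(workdir, "chunks")
    plan = fq.write_chunks(r1, r2, config.n_chunks, chunk_dir)
    merged = os.path.join(workdir, "aligned.sam")
    with open(merged, "w") as out:
        for ci in range(len(plan)):
            c1 = os.path.join(chunk_dir, f"chunk_{ci:04d}_R1.fastq")
            c2 = os.path.join(chunk_dir, f"chunk_{ci:04d}_R2.fastq")
            out_sam = os.path.join(chunk_dir, f"chunk_{ci:04d}.sam")
            cmd = config.aligner_command.format(r1=c1, r2=c2, out_sam=out_sam)
            proc = subprocess.run(shlex.split(cmd), capture_output=True, text=True)
            if proc.returncode != 0:
                raise StageError(
                    f"align: chunk {ci} failed (exit {proc.returncode})"
                )
            with open(out_sam) as fh:
                for line in fh:
                    if ci > 0 and line.startswith("@"):
                        continue  # keep one header
                    out.write(line)
    return merged


def full_pipeline(
    config: PipelineConfig,
    input_sam_or_bam: str | None = None,
    fastq_r1: str | None = None,
    fastq_r2: str | None = None,
) -> str:
    """Run chunk (optional) → preprocess → call → merge; returns the merged
    VCF path.  Raises :class:`StageError` / :class:`ConfigError` on failure.
    """
    config.validate()
    os.makedirs(config.output_dir, exist_ok=True)
    if config.reference_index_path is None:
        raise ConfigError("reference_index_path is required")
    from .regions import read_fai

    table = build_regions(
        read_fai(config.reference_index_path), config.region_target_size
    )

    if input_sam_or_bam is None:
        if fastq_r1 is None or config.aligner_command is None:
            raise ConfigError(
                "either a pre-aligned SAM/BAM or FASTQ plus an aligner command is required"
            )
        input_sam_or_bam = _run_aligner_on_chunks(
            config, fastq_r1, fastq_r2, config.output_dir
        )

    pre_dir = os.path.join(config.output_dir, "shards")
    result = preprocess(
        input_sam_or_bam, table, pre_dir, max_workers=config.max_parallel_workers
    )

    if config.caller_template is None:
        raise ConfigError("caller_template is required for the full pipeline")
    call_dir = os.path.join(config.output_dir, "calls")
    manifest = shards.run_region_callers(
        result.manifest,
        config.caller_template,
        table,
        config.reference_fasta or "",
        call_dir,
        max_parallel=config.max_parallel_workers,
        pad=config.pad,
    )
    manifest.save(os.path.join(config.output_dir, "manifest.json"))
    failed = [e for e in manifest.entries if e.status == "failed"]
    if failed:
        raise StageError(
            f"call: {len(failed)} region(s) failed, e.g. region {failed[0].region_id} "
            f"(exit {failed[0].exit_code})"
        )

    done = [e for e in manifest.entries if e.status == "done" and e.vcf_path]
    done.sort(key=lambda e: e.region_id)
    merged = os.path.join(config.output_dir, "merged.vcf")
    n = shards.merge_vcfs(
        [e.vcf_path for e in done],
        table,
        merged,
        region_ids=[e.region_id for e in done],
        padded=config.pad > 0,
    )
    run_report = {
        "stages": ["preprocess", "call", "merge"],
        "total_records": result.total_records,
        "placed_records": result.placed_count,
        "duplicate_decisions": result.duplicate_decisions,
        "regions": len(table),
        "merged_vcf_records": n,
        "merged_vcf": merged,
    }
    with open(os.path.join(config.output_dir, "run_report.json"), "w") as fh:
        json.dump(run_report, fh, indent=1)
    logger.info("pipeline complete: %d VCF records in %s", n, merged)
    return merged
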