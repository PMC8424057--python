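"""Record-synchronized chunking of paired FASTQ files.

Splits R1/R2 into a configurable number of balanced chunks so each chunk
can feed an independent downstream aligner instance.  Chunking is by record
index (two passes: count, then stream), records are passed through
byte-identically, and mate pairing is preserved within every chunk.
Interleaved FASTQ is not accepted: exactly two mate files, or one file for
single-end data.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass
from typing import IO, Iterator

__all__ = [
    "ChunkPlan",
    "MalformedFastqError",
    "PairingError",
    "count_fastq_records",
    "chunk_boundaries",
    "stream_chunk",
    "write_chunks",
]

logger = logging.getLogger(__name__)


class MalformedFastqError(ValueError):
    """FASTQ file is not a well-formed stream of 4-line records."""


class PairingError(ValueError):
    """R1 and R2 disagree on record count; mates cannot be synchronized."""


@dataclass(frozen=True)
class ChunkPlan:
    """Balanced split of ``total_records`` into ``n_chunks`` contiguous runs.

    ``boundaries[i] = (start_record_index, record_count)``; counts differ by
    at most one, with the remainder going to the lowest-index chunks.
    """

    total_records: int
    n_chunks: int
    boundaries: tuple[tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.boundaries)


def _open_text(path: str | os.PathLike) -> IO[str]:
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def count_fastq_records(path: str | os.PathLike) -> int:
    """Number of 4-line FASTQ records in a (possibly gzipped) file.

    Validates that the line count is divisible by 4 and that every record
    header starts with ``@``.
    """
    n_lines = 0
    with _open_text(path) as fh:
        for i, line in enumerate(fh):
            if i % 4 == 0 and not line.startswith("@"):
                raise MalformedFastqError(
                    f"{path}: record header at line {i + 1} does not start with '@'"
                )
            n_lines += 1
    if n_lines % 4 != 0:
        raise MalformedFastqError(
            f"{path}: {n_lines} lines is not a multiple of 4"
        )
    return n_lines // 4


def chunk_boundaries(total_records: int, n_chunks: int) -> ChunkPlan:
    """Balanced chunk plan; extra records go to the lowest-index chunks.

    If ``n_chunks`` exceeds ``total_records`` (and records exist) the plan is
    capped at ``total_records`` single-record chunks, with a logged warning.
    """
    if total_records < 0:
        raise ValueError("total_records must be >= 0")
    if n_chunks < 1:
        raise ValueError("n_chunks must be >= 1")
    if total_records > 0 and n_chunks > total_records:
        logger.warning(
            "requested %d chunks for %d records; capping at %d non-empty chunks",
            n_chunks, total_records, total_records,
        )
        n_chunks = total_records
    if total_records == 0:
        return ChunkPlan(0, 1, ((0, 0),))
    base, extra = divmod(total_records, n_chunks)
    bounds = []
    start = 0
    for i in range(n_chunks):
        count = base + (1 if i < extra else 0)
        bounds.append((start, count))
        start += count
    return ChunkPlan(total_records, n_chunks, tuple(bounds))


def _records(fh: IO[str]) -> Iterator[str]:
    """Yield 4-line records (with trailing newlines) from an open FASTQ."""
    while True:
        lines = [fh.readline() for _ in range(4)]
        if not lines[0]:
            return
        if any(not ln for ln in lines[1:]):
            raise MalformedFastqError("truncated FASTQ record at end of file")
        yield "".join(lines)


def stream_chunk(
    r1_path: str | os.PathLike,
    r2_path: str | os.PathLike | None,
    plan: ChunkPlan,
    chunk_index: int,
) -> Iterator[tuple[str, str | None]]:
    """Yield ``(r1_record, r2_record)`` pairs for one chunk of the plan.

    Records are byte-identical to the source.  For single-end input pass
    ``r2_path=None``; the second element is then None.  Raises
    :class:`PairingError` before any output if mate counts disagree.
    """
    if not 0 <= chunk_index < len(plan.boundaries):
        raise IndexError(
            f"chunk_index {chunk_index} out of range for {len(plan.boundaries)}-chunk plan"
        )
    if r2_path is not None:
        n1 = count_fastq_records(r1_path)
        n2 = count_fastq_records(r2_path)
        if n1 != n2:
            raise PairingError(f"R1 has {n1} records but R2 has {n2}")
    start, count = plan.boundaries[chunk_index]
    with _open_text(r1_path) as fh1:
        fh2 = _open_text(r2_path) if r2_path is not None else None
        try:
            it1 = _records(fh1)
            it2 = _records(fh2) if fh2 is not None else None
            for _ in range(start):
                next(it1)
                if it2 is not None:
                    next(it2)
            for _ in range(count):
                r1 = next(it1)
                r2 = next(it2) if it2 is not None else None
                yield r1, r2
        finally:
            if fh2 is not None:
                fh2.close()


def write_chunks(
    r1_path: str | os.PathLike,
    r2_path: str | os.PathLike | None,
    n_chunks: int,
    outdir: str | os.PathLike,
) -> ChunkPlan:
    """Split mate files into ``n_chunks`` chunk files under ``outdir``.

    Emits ``chunk_<i>_R1.fastq`` (and ``_R2`` for paired input).  Returns
    the plan used.
    """
    os.makedirs(outdir, exist_ok=True)
    total = count_fastq_records(r1_path)
    plan = chunk_boundaries(total, n_chunks)
    for ci in range(len(plan)):
        p1 = os.path.join(outdir, f"chunk_{ci:04d}_R1.fastq")
        p2 = os.path.join(outdir, f"chunk_{ci:04d}_R2.fastq")
        with open(p1, "w") as o1:
            o2 = open(p2, "w") if r2_path is not None else None
            try:
                for rec1, rec2 in stream_chunk(r1_path, r2_path, plan, ci):
                    o1.write(rec1)
                    if o2 is not None and rec2 is not None:
                        o2.write(rec2)
            finally:
                if o2 is not None:
                    o2.close()
    return plan
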