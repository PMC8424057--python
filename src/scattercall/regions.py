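"""Static load balancing: partition a genome into contiguous regions.

Chromosomes differ in size by more than an order of magnitude, so each
contig is split into a number of near-equal contiguous spans averaging
40-50 Mb.  Every downstream stage (sorting, duplicate marking, shard
writing, per-region variant calling) uses this partition as its unit of
parallelism.  Spans are 1-based inclusive, matching SAM POS semantics;
BED export converts to 0-based half-open explicitly.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Region",
    "RegionTable",
    "RegionLookupError",
    "UNPLACED_REGION",
    "DEFAULT_TARGET_SIZE",
    "GRCH37_PRIMARY_CONTIGS",
    "build_regions",
    "region_histogram",
    "read_fai",
]

#: pseudo-region id for unmapped reads and reads on contigs absent from the table
UNPLACED_REGION = -1

#: default region target size in base pairs (gives ~40-50 Mb regions)
DEFAULT_TARGET_SIZE = 47_000_000

#: GRCh37/hg19 primary assembly contig lengths (chr1-22, X, Y, MT).
GRCH37_PRIMARY_CONTIGS: tuple[tuple[str, int], ...] = (
    ("1", 249_250_621),
    ("2", 243_199_373),
    ("3", 198_022_430),
    ("4", 191_154_276),
    ("5", 180_915_260),
    ("6", 171_115_067),
    ("7", 159_138_663),
    ("8", 146_364_022),
    ("9", 141_213_431),
    ("10", 135_534_747),
    ("11", 135_006_516),
    ("12", 133_851_895),
    ("13", 115_169_878),
    ("14", 107_349_540),
    ("15", 102_531_392),
    ("16", 90_354_753),
    ("17", 81_195_210),
    ("18", 78_077_248),
    ("19", 59_128_983),
    ("20", 63_025_520),
    ("21", 48_129_895),
    ("22", 51_304_566),
    ("X", 155_270_560),
    ("Y", 59_373_566),
    ("MT", 16_569),
)


class RegionLookupError(KeyError):
    """A (contig, position) pair cannot be assigned to any region."""


@dataclass(frozen=True, slots=True)
class Region:
    """One contiguous genomic span; coordinates 1-based inclusive."""

    region_id: int
    rname: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid region span [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


class RegionTable:
    """Ordered partition of the genome into regions, with O(log n) lookup."""

    def __init__(
        self, regions: Sequence[Region], contig_order: Sequence[tuple[str, int]]
    ) -> None:
        self.regions: tuple[Region, ...] = tuple(regions)
        self.contig_order: tuple[tuple[str, int], ...] = tuple(contig_order)
        self._lengths: dict[str, int] = dict(contig_order)
        # per-contig sorted region starts for binary search
        self._starts: dict[str, list[int]] = {}
        self._ids: dict[str, list[int]] = {}
        for r in self.regions:
            self._starts.setdefault(r.rname, []).append(r.start)
            self._ids.setdefault(r.rname, []).append(r.region_id)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def contig_length(self, rname: str) -> int:
        return self._lengths[rname]

    def assign_region(self, rname: str, pos: int) -> int:
        """Region id whose [start, end] contains ``pos`` on contig ``rname``.

        Raises :class:`RegionLookupError` for unknown contigs or positions
        outside [1, contig length].
        """
        starts = self._starts.get(rname)
        if starts is None:
            raise RegionLookupError(f"contig {rname!r} not in region table")
        if pos < 1 or pos > self._lengths[rname]:
            raise RegionLookupError(
                f"position {pos} outside [1, {self._lengths[rname]}] on {rname!r}"
            )
        i = bisect.bisect_right(starts, pos) - 1
        return self._ids[rname][i]

    def assign_region_clamped(self, rname: str, pos: int) -> int:
        """Like :meth:`assign_region` but clamps ``pos`` into the contig span.

        Used for routing by unclipped coordinates, which soft/hard clipping
        can push past a contig edge.
        """
        length = self._lengths.get(rname)
        if length is None:
            raise RegionLookupError(f"contig {rname!r} not in region table")
        return self.assign_region(rname, min(max(pos, 1), length))

    def region(self, region_id: int) -> Region:
        return self.regions[region_id]

    def contig_rank(self, rname: str) -> int:
        for i, (name, _) in enumerate(self.contig_order):
            if name == rname:
                return i
        raise RegionLookupError(f"contig {rname!r} not in region table")

    def mean_region_length(self) -> float:
        return sum(r.length for r in self.regions) / len(self.regions)

    def to_bed(self) -> str:
        """Region table as BED text (0-based, half-open)."""
        return "".join(
            f"{r.rname}\t{r.start - 1}\t{r.end}\tregion_{r.region_id}\n"
            for r in self.regions
        )

    def region_bed_line(self, region_id: int, pad: int = 0) -> str:
        """BED line for one region, optionally padded by ``pad`` bases each
        side (clamped to the contig span)."""
        r = self.regions[region_id]
        start = max(r.start - pad, 1)
        end = min(r.end + pad, self._lengths[r.rname])
        return f"{r.rname}\t{start - 1}\t{end}\n"


def build_regions(
    contig_lengths: Iterable[tuple[str, int]],
    target_size: int = DEFAULT_TARGET_SIZE,
) -> RegionTable:
    """Divide each contig into ``max(1, round(length / target_size))``
    near-equal contiguous spans and number them in genome order.

    The first ``length mod n`` spans of a contig take one extra base, so
    spans within a contig differ by at most one base.  Over the GRCh37
    primary contigs at the default target size this yields 65 regions
    averaging ~47.7 Mb.
    """
    contigs = list(contig_lengths)
    names = [n for n, _ in contigs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate contig name(s): {', '.join(dupes)}")
    regions: list[Region] = []
    rid = 0
    for name, length in contigs:
        if length <= 0:
            raise ValueError(f"non-positive length {length} for contig {name!r}")
        n = max(1, int(length / target_size + 0.5))  # round half up
        base, extra = divmod(length, n)
        start = 1
        for i in range(n):
            span = base + (1 if i < extra else 0)
            regions.append(Region(rid, name, start, start + span - 1))
            start += span
            rid += 1
    return RegionTable(regions, contigs)


def region_histogram(batches: Iterable) -> dict[int, int]:
    """Read counts per region over an iterable of ReadBatch-like objects."""
    out: dict[int, int] = {}
    for b in batches:
        if len(b):
            out[b.region_id] = out.get(b.region_id, 0) + len(b)
    return out


def read_fai(path: str) -> list[tuple[str, int]]:
    """Contig (name, length) pairs from a FASTA index (.fai) file."""
    out: list[tuple[str, int]] = []
    with open(path) as fh:
        for ln in fh:
            if not ln.strip():
                continue
            parts = ln.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed .fai line: {ln!r}")
            out.append((parts[0], int(parts[1])))
    return out
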