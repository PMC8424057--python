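"""Domain types for aligned reads and lossless SAM text parsing.

The in-memory unit of the pipeline is the key-value pair ``<POS : SAM line>``
with the contig name (RNAME) carried alongside, grouped per genomic region
into columnar batches.  The SAM *text* line is the canonical value: parsing
and re-serialising a record reproduces the input byte-exactly, including
auxiliary tags in their original order.  BAM containers are only produced at
shard-writing time (see :mod:`scattercall.shards`, which delegates to pysam).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

__all__ = [
    "ReadRecord",
    "KeyedRead",
    "ReadBatch",
    "SamHeader",
    "SamParseError",
    "BatchSealedError",
    "parse_sam_line",
    "format_sam_line",
    "to_keyed",
    "FLAG_PAIRED",
    "FLAG_UNMAPPED",
    "FLAG_MATE_UNMAPPED",
    "FLAG_REVERSE",
    "FLAG_MATE_REVERSE",
    "FLAG_READ1",
    "FLAG_READ2",
    "FLAG_SECONDARY",
    "FLAG_QCFAIL",
    "FLAG_DUPLICATE",
    "FLAG_SUPPLEMENTARY",
]

# SAM FLAG bits (SAMv1)
FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SECONDARY = 0x100
FLAG_QCFAIL = 0x200
FLAG_DUPLICATE = 0x400
FLAG_SUPPLEMENTARY = 0x800


class SamParseError(ValueError):
    """A SAM alignment line violates the SAMv1 text grammar."""


class BatchSealedError(RuntimeError):
    """Mutation was attempted on a sealed (immutable) read batch."""


@dataclass(frozen=True, slots=True)
class ReadRecord:
    """One parsed SAM alignment line: 11 mandatory fields plus raw tags.

    ``pos`` is the 1-based leftmost aligned base (0 iff no placement).
    ``tags`` are opaque strings preserved verbatim and in order, so that
    serialisation is byte-lossless.
    """

    qname: str
    flag: int
    rname: str
    pos: int
    mapq: int
    cigar: str
    rnext: str
    pnext: int
    tlen: int
    seq: str
    qual: str
    tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.flag < 0:
            raise SamParseError(f"negative FLAG {self.flag} for read {self.qname!r}")
        if self.pos < 0:
            raise SamParseError(f"negative POS {self.pos} for read {self.qname!r}")
        if (
            self.seq != "*"
            and self.qual != "*"
            and len(self.seq) != len(self.qual)
        ):
            raise SamParseError(
                f"SEQ/QUAL length mismatch for read {self.qname!r}: "
                f"{len(self.seq)} vs {len(self.qual)}"
            )

    # -- flag predicates ---------------------------------------------------
    @property
    def is_paired(self) -> bool:
        return bool(self.flag & FLAG_PAIRED)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def is_mate_unmapped(self) -> bool:
        return bool(self.flag & FLAG_MATE_UNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & FLAG_SECONDARY)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & FLAG_SUPPLEMENTARY)

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flag & FLAG_DUPLICATE)

    @property
    def is_primary(self) -> bool:
        return not (self.flag & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY))

    def mate_rank(self) -> int:
        """1 for first-of-pair, 2 for second-of-pair, 0 for unpaired."""
        if self.flag & FLAG_READ1:
            return 1
        if self.flag & FLAG_READ2:
            return 2
        return 0

    def tag_value(self, name: str) -> str | None:
        """Return the value part of tag ``name`` (e.g. ``"MC"``), or None."""
        prefix = name + ":"
        for t in self.tags:
            if t.startswith(prefix):
                return t.split(":", 2)[2]
        return None

    def with_flag(self, flag: int) -> "ReadRecord":
        return replace(self, flag=flag)


def parse_sam_line(line: str) -> ReadRecord:
    """Parse a non-header SAM alignment line into a :class:`ReadRecord`.

    Tags (field 12 onward) are kept verbatim.  Raises :class:`SamParseError`
    for fewer than 11 tab-separated fields or non-integer numeric fields.
    """
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 11:
        raise SamParseError(
            f"SAM alignment line has {len(fields)} fields; 11 are mandatory"
        )
    try:
        flag = int(fields[1])
        pos = int(fields[3])
        mapq = int(fields[4])
        pnext = int(fields[7])
        tlen = int(fields[8])
    except ValueError as exc:
        raise SamParseError(f"non-integer mandatory field: {exc}") from None
    return ReadRecord(
        qname=fields[0],
        flag=flag,
        rname=fields[2],
        pos=pos,
        mapq=mapq,
        cigar=fields[5],
        rnext=fields[6],
        pnext=pnext,
        tlen=tlen,
        seq=fields[9],
        qual=fields[10],
        tags=tuple(fields[11:]),
    )


def format_sam_line(rec: ReadRecord) -> str:
    """Serialise a record to a tab-delimited SAMv1 line (no newline).

    Inverse of :func:`parse_sam_line`: ``format(parse(line)) == line``.
    """
    fields = [
        rec.qname,
        str(rec.flag),
        rec.rname,
        str(rec.pos),
        str(rec.mapq),
        rec.cigar,
        rec.rnext,
        str(rec.pnext),
        str(rec.tlen),
        rec.seq,
        rec.qual,
    ]
    fields.extend(rec.tags)
    return "\t".join(fields)


@dataclass(frozen=True, slots=True)
class KeyedRead:
    """The ``<POS : SAM>`` key-value pair with RNAME carried alongside."""

    pos: int
    sam: str
    rname: str


def to_keyed(rec: ReadRecord) -> KeyedRead:
    """Convert a read into its key-value form; POS is the sort key."""
    return KeyedRead(pos=rec.pos, sam=format_sam_line(rec), rname=rec.rname)


class ReadBatch:
    """Columnar store of keyed reads for one region.

    Three parallel columns (``pos``: int, ``sam``: str, ``rname``: str) grow
    in lockstep until the batch is sealed; a sealed batch is immutable and
    transformations produce new batches.  ``to_arrow()`` exposes the sealed
    contents as a pyarrow RecordBatch with the same schema.
    """

    __slots__ = ("region_id", "_pos", "_sam", "_rname", "_sealed")

    def __init__(self, region_id: int) -> None:
        self.region_id = region_id
        self._pos: list[int] = []
        self._sam: list[str] = []
        self._rname: list[str] = []
        self._sealed = False

    # -- construction ------------------------------------------------------
    def append(self, k: KeyedRead) -> "ReadBatch":
        if self._sealed:
            raise BatchSealedError(
                f"batch for region {self.region_id} is sealed; appends rejected"
            )
        self._pos.append(k.pos)
        self._sam.append(k.sam)
        self._rname.append(k.rname)
        return self

    def seal(self) -> "ReadBatch":
        self._sealed = True
        return self

    @classmethod
    def from_keyed(cls, region_id: int, keyed: Iterable[KeyedRead]) -> "ReadBatch":
        b = cls(region_id)
        for k in keyed:
            b.append(k)
        return b.seal()

    # -- access ------------------------------------------------------------
    @property
    def sealed(self) -> bool:
        return self._sealed

    @property
    def pos(self) -> tuple[int, ...]:
        return tuple(self._pos)

    @property
    def sam(self) -> tuple[str, ...]:
        return tuple(self._sam)

    @property
    def rname(self) -> tuple[str, ...]:
        return tuple(self._rname)

    def __len__(self) -> int:
        return len(self._pos)

    def __iter__(self) -> Iterator[KeyedRead]:
        for p, s, r in zip(self._pos, self._sam, self._rname):
            yield KeyedRead(pos=p, sam=s, rname=r)

    def records(self) -> Iterator[ReadRecord]:
        for s in self._sam:
            yield parse_sam_line(s)

    def to_arrow(self):
        """Sealed contents as a pyarrow RecordBatch (pos:int64, sam/rname:str)."""
        import pyarrow as pa

        if not self._sealed:
            raise BatchSealedError("seal the batch before exporting to Arrow")
        return pa.record_batch(
            [
                pa.array(self._pos, type=pa.int64()),
                pa.array(self._sam, type=pa.string()),
                pa.array(self._rname, type=pa.string()),
            ],
            names=["pos", "sam", "rname"],
        )


@dataclass
class SamHeader:
    """SAM header lines preserved verbatim, queryable for @SQ and @RG info."""

    lines: list[str] = field(default_factory=list)

    @classmethod
    def from_text(cls, text: str) -> "SamHeader":
        return cls([ln for ln in text.splitlines() if ln.startswith("@")])

    def _tag_fields(self, record_type: str) -> Iterator[dict[str, str]]:
        for ln in self.lines:
            if ln.startswith(record_type):
                fields = ln.split("\t")[1:]
                yield {
                    f[:2]: f[3:] for f in fields if len(f) >= 3 and f[2] == ":"
                }

    def contig_lengths(self) -> list[tuple[str, int]]:
        """(name, length) pairs from @SQ lines, in header order."""
        out = []
        for d in self._tag_fields("@SQ"):
            if "SN" in d and "LN" in d:
                out.append((d["SN"], int(d["LN"])))
        return out

    def rg_to_lb(self) -> dict[str, str]:
        """Read-group ID → library (LB) mapping from @RG lines."""
        out: dict[str, str] = {}
        for d in self._tag_fields("@RG"):
            if "ID" in d:
                out[d["ID"]] = d.get("LB", "unknown")
        return out

    def to_text(self) -> str:
        return "\n".join(self.lines) + ("\n" if self.lines else "")

    @classmethod
    def for_contigs(
        cls,
        contigs: Iterable[tuple[str, int]],
        read_groups: Iterable[tuple[str, str]] = (),
        sort_order: str = "unsorted",
    ) -> "SamHeader":
        lines = [f"@HD\tVN:1.6\tSO:{sort_order}"]
        lines += [f"@SQ\tSN:{name}\tLN:{length}" for name, length in contigs]
        lines += [f"@RG\tID:{rg}\tLB:{lb}\tSM:sample1" for rg, lb in read_groups]
        return cls(lines)
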