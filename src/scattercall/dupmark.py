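"""Per-region coordinate sorting and Picard-compatible duplicate marking.

Duplicate marking identifies reads that arise from PCR amplification of the
same original DNA fragment.  Two paired-end reads are duplicates when, within
one library, both fragment ends share the same (contig, unclipped 5'
coordinate, strand); the *unclipped* coordinate undoes soft/hard clipping so
that duplicates with ragged alignments still collide.  Within each duplicate
group the candidate with the highest base-quality score is kept and all
others receive FLAG bit 0x400.  Fragments (unpaired reads, or reads whose
mate is unmapped) are keyed by their single end; a fragment colliding with
any *pair* end is always a duplicate, matching the convention that paired
evidence beats single-end evidence.

All tie-breaks are content-based (lexicographic by read name), so the
flagged set is invariant to input order and to how work is distributed
across regions or workers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .sam import (
    FLAG_DUPLICATE,
    FLAG_MATE_REVERSE,
    KeyedRead,
    ReadBatch,
    ReadRecord,
    format_sam_line,
    parse_sam_line,
)

__all__ = [
    "ClipProfile",
    "ReadEnd",
    "DuplicateKey",
    "PairCandidate",
    "CigarError",
    "DataIntegrityError",
    "ReconciliationError",
    "sort_region",
    "clip_profile",
    "unclipped_5prime",
    "mate_unclipped_5prime",
    "duplicate_score",
    "build_pair_candidates",
    "mark_duplicates",
    "apply_marks",
    "MIN_SCORED_QUALITY",
]

#: base qualities below this Phred value do not contribute to duplicate scores
MIN_SCORED_QUALITY = 15

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


class CigarError(ValueError):
    """CIGAR string contains an invalid token."""


class DataIntegrityError(ValueError):
    """Input records violate SAM pairing constraints."""


class ReconciliationError(ValueError):
    """A duplicate decision could not be matched back to any stored record."""


@dataclass(frozen=True, slots=True)
class ClipProfile:
    """Clipping summary of a CIGAR: leading/trailing S+H bases and the
    number of reference bases consumed (M/D/N/=/X)."""

    leading_clip: int
    trailing_clip: int
    ref_span: int


def clip_profile(cigar: str) -> ClipProfile:
    """Derive the clip profile from a CIGAR string (not ``"*"``)."""
    if cigar == "*" or not cigar:
        raise CigarError("cannot derive a clip profile from CIGAR '*'")
    ops = _CIGAR_RE.findall(cigar)
    if "".join(f"{n}{o}" for n, o in ops) != cigar:
        raise CigarError(f"invalid CIGAR string: {cigar!r}")
    leading = trailing = ref_span = 0
    seen_inner = False
    for n_str, op in ops:
        if op in "SH" and not seen_inner:
            leading += int(n_str)
        else:
            seen_inner = True
            if op in "MDN=X":
                ref_span += int(n_str)
    for n_str, op in reversed(ops):  # clips strictly after the last inner op
        if op in "SH":
            trailing += int(n_str)
        else:
            break
    if not seen_inner:  # all-clip CIGAR carries no alignment
        trailing = 0
    return ClipProfile(leading, trailing, ref_span)


#: one fragment end: (contig, unclipped 5' coordinate, strand "F"/"R")
ReadEnd = tuple[str, int, str]


def unclipped_5prime(rec: ReadRecord) -> ReadEnd | None:
    """The (contig, unclipped 5' coordinate, strand) of a read's end.

    Forward strand: POS minus leading clip.  Reverse strand: alignment end
    (POS + ref_span - 1) plus trailing clip.  Returns None — the read is
    excluded from duplicate keys, not an error — for unmapped, secondary or
    supplementary records or CIGAR ``"*"``.
    """
    if rec.is_unmapped or not rec.is_primary or rec.cigar == "*":
        return None
    cp = clip_profile(rec.cigar)
    if rec.is_reverse:
        return (rec.rname, rec.pos + cp.ref_span - 1 + cp.trailing_clip, "R")
    return (rec.rname, rec.pos - cp.leading_clip, "F")


def mate_unclipped_5prime(rec: ReadRecord) -> tuple[ReadEnd, bool]:
    """The mate's end inferred from this record's RNEXT/PNEXT and MC tag.

    Returns ``(end, clip_aware)``.  When the MC (mate CIGAR) tag is absent
    the mate's PNEXT is used clip-unaware and ``clip_aware`` is False, so
    callers can count a warning.
    """
    mate_rname = rec.rname if rec.rnext == "=" else rec.rnext
    mate_reverse = bool(rec.flag & FLAG_MATE_REVERSE)
    mc = rec.tag_value("MC")
    if mc is not None and mc != "*":
        cp = clip_profile(mc)
        if mate_reverse:
            return (mate_rname, rec.pnext + cp.ref_span - 1 + cp.trailing_clip, "R"), True
        return (mate_rname, rec.pnext - cp.leading_clip, "F"), True
    return (mate_rname, rec.pnext, "R" if mate_reverse else "F"), False


def duplicate_score(records: Sequence[ReadRecord]) -> int:
    """Sum of Phred base qualities >= 15 over one or two records.

    This is the de-facto Picard default scoring rule
    (SUM_OF_BASE_QUALITIES); a record with QUAL ``"*"`` contributes 0.
    """
    score = 0
    for rec in records:
        if rec.qual == "*":
            continue
        for ch in rec.qual:
            q = ord(ch) - 33
            if q >= MIN_SCORED_QUALITY:
                score += q
    return score


@dataclass(frozen=True, slots=True)
class DuplicateKey:
    """Grouping key for duplicate candidates.

    For pairs, ``end1 <= end2`` under (contig order, coordinate, strand) and
    ``orientation`` records the strands in that canonical order (FR/RF/FF/RR).
    Fragments carry a single end.
    """

    library: str
    kind: str  # "pair" | "fragment"
    end1: ReadEnd
    end2: ReadEnd | None = None
    orientation: str | None = None


@dataclass(frozen=True, slots=True)
class PairCandidate:
    """A scored duplicate candidate: one fragment or one read pair."""

    qname: str
    key: DuplicateKey
    score: int
    record_refs: tuple[ReadRecord, ...]


def _library_of(rec: ReadRecord, rg_lb: Mapping[str, str]) -> str:
    rg = rec.tag_value("RG")
    if rg is None:
        return "unknown"
    return rg_lb.get(rg, "unknown")


def _end_sort_key(end: ReadEnd, contig_rank: Mapping[str, int] | None):
    rname, coord, strand = end
    rank = contig_rank.get(rname, len(contig_rank)) if contig_rank is not None else 0
    return (rank, rname, coord, strand)


def build_pair_candidates(
    region_records: Iterable[ReadRecord],
    header_rg_lb: Mapping[str, str] | None = None,
    mate_info: Mapping[tuple[str, int], str] | None = None,
    contig_rank: Mapping[str, int] | None = None,
) -> tuple[list[PairCandidate], list[PairCandidate]]:
    """Group primary mapped records into pair and fragment candidates.

    Paired records with both mates mapped are joined by read name; when the
    mate record itself is present its end is computed exactly, otherwise it
    is inferred from the MC tag (``mate_info`` may supply mate CIGARs keyed
    by (qname, mate rank) as an override).  Unpaired reads and reads with an
    unmapped mate become fragments.  Secondary, supplementary and unmapped
    records are excluded entirely.

    Returns ``(pairs, fragments)``.  A read name with more than two primary
    records raises :class:`DataIntegrityError`.
    """
    rg_lb = header_rg_lb or {}
    by_qname: dict[str, list[ReadRecord]] = {}
    fragments: list[PairCandidate] = []
    pairs: list[PairCandidate] = []

    for rec in region_records:
        if rec.is_unmapped or not rec.is_primary:
            continue
        if rec.is_paired and not rec.is_mate_unmapped:
            by_qname.setdefault(rec.qname, []).append(rec)
        else:
            end = unclipped_5prime(rec)
            if end is None:
                continue
            fragments.append(
                PairCandidate(
                    qname=rec.qname,
                    key=DuplicateKey(_library_of(rec, rg_lb), "fragment", end),
                    score=duplicate_score([rec]),
                    record_refs=(rec,),
                )
            )

    for qname, recs in by_qname.items():
        if len(recs) > 2:
            raise DataIntegrityError(
                f"read name {qname!r} has {len(recs)} primary records"
            )
        ends: list[ReadEnd] = []
        if len(recs) == 2:
            e1, e2 = unclipped_5prime(recs[0]), unclipped_5prime(recs[1])
            if e1 is None or e2 is None:
                for rec in recs:
                    end = unclipped_5prime(rec)
                    if end is not None:
                        fragments.append(
                            PairCandidate(
                                qname=rec.qname,
                                key=DuplicateKey(
                                    _library_of(rec, rg_lb), "fragment", end
                                ),
                                score=duplicate_score([rec]),
                                record_refs=(rec,),
                            )
                        )
                continue
            ends = [e1, e2]
        else:
            # mate record not supplied: infer its end from MC/PNEXT
            rec = recs[0]
            own = unclipped_5prime(rec)
            if own is None:
                continue
            mc_override = None
            if mate_info is not None:
                mc_override = mate_info.get((qname, 3 - rec.mate_rank()))
            if mc_override is not None:
                mate_rname = rec.rname if rec.rnext == "=" else rec.rnext
                cp = clip_profile(mc_override)
                if rec.flag & FLAG_MATE_REVERSE:
                    mate_end: ReadEnd = (
                        mate_rname,
                        rec.pnext + cp.ref_span - 1 + cp.trailing_clip,
                        "R",
                    )
                else:
                    mate_end = (mate_rname, rec.pnext - cp.leading_clip, "F")
            else:
                mate_end, _ = mate_unclipped_5prime(rec)
            ends = [own, mate_end]
            recs = [rec]

        k1, k2 = (_end_sort_key(e, contig_rank) for e in ends)
        if k2 < k1:
            ends = [ends[1], ends[0]]
        orientation = ends[0][2] + ends[1][2]
        pairs.append(
            PairCandidate(
                qname=qname,
                key=DuplicateKey(
                    _library_of(recs[0], rg_lb), "pair", ends[0], ends[1], orientation
                ),
                score=duplicate_score(recs),
                record_refs=tuple(recs),
            )
        )
    return pairs, fragments


#: a duplicate decision: (read name, mate rank 0/1/2) of a record to flag
Decision = tuple[str, int]


def _candidate_decisions(c: PairCandidate) -> list[Decision]:
    if c.key.kind == "pair":
        if len(c.record_refs) == 2:
            return [(c.qname, r.mate_rank()) for r in c.record_refs]
        # mate inferred from MC: flag both mates by rank
        r = c.record_refs[0]
        return [(c.qname, r.mate_rank()), (c.qname, 3 - r.mate_rank())]
    return [(c.qname, c.record_refs[0].mate_rank())]


def mark_duplicates(
    pairs: Iterable[PairCandidate], fragments: Iterable[PairCandidate]
) -> set[Decision]:
    """Select duplicates among candidates of one routing region.

    Within each pair key group the highest-scoring pair is kept and every
    other pair's records are flagged.  A fragment whose (library, end)
    coincides with *any* pair end is flagged unconditionally; among
    fragment-only groups the highest-scoring fragment is kept.  Ties are
    broken by ascending read name (the kept candidate is the
    lexicographically smallest among the maximal scores), so results are
    independent of input order.
    """
    pairs = list(pairs)
    fragments = list(fragments)
    decisions: set[Decision] = set()

    pair_groups: dict[DuplicateKey, list[PairCandidate]] = {}
    for c in pairs:
        pair_groups.setdefault(c.key, []).append(c)
    for group in pair_groups.values():
        if len(group) == 1:
            continue
        keep = min(group, key=lambda c: (-c.score, c.qname))
        for c in group:
            if c is not keep:
                decisions.update(_candidate_decisions(c))

    # every end of every pair candidate beats fragments at the same position
    pair_end_index: set[tuple[str, ReadEnd]] = set()
    for c in pairs:
        pair_end_index.add((c.key.library, c.key.end1))
        assert c.key.end2 is not None
        pair_end_index.add((c.key.library, c.key.end2))

    frag_groups: dict[tuple[str, ReadEnd], list[PairCandidate]] = {}
    for c in fragments:
        fkey = (c.key.library, c.key.end1)
        if fkey in pair_end_index:
            decisions.update(_candidate_decisions(c))
        else:
            frag_groups.setdefault(fkey, []).append(c)
    for group in frag_groups.values():
        if len(group) == 1:
            continue
        keep = min(group, key=lambda c: (-c.score, c.qname))
        for c in group:
            if c is not keep:
                decisions.update(_candidate_decisions(c))
    return decisions


def sort_region(batch: ReadBatch) -> ReadBatch:
    """Coordinate-sort one region's batch: non-decreasing POS, ties broken
    by (qname, flag) ascending.  Returns a new sealed batch."""

    def key(k: KeyedRead):
        qname, flag, _ = k.sam.split("\t", 2)
        return (k.pos, qname, int(flag))

    return ReadBatch.from_keyed(batch.region_id, sorted(batch, key=key))


def apply_marks(
    batch: ReadBatch, decisions: set[Decision]
) -> tuple[ReadBatch, set[Decision]]:
    """Set FLAG bit 0x400 on records named by ``decisions``.

    Only the FLAG field of matched records changes; order and count are
    conserved.  Returns the new sealed batch and the subset of decisions
    that matched a record here, so the pipeline can verify that every
    decision was reconciled to exactly one storage region.
    """
    matched: set[Decision] = set()
    out = ReadBatch(batch.region_id)
    for k in batch:
        rec = parse_sam_line(k.sam)
        d = (rec.qname, rec.mate_rank())
        if d in decisions and rec.is_primary and not rec.is_unmapped:
            matched.add(d)
            if not rec.is_duplicate:
                rec = rec.with_flag(rec.flag | FLAG_DUPLICATE)
                out.append(KeyedRead(k.pos, format_sam_line(rec), k.rname))
                continue
        out.append(k)
    return out.seal(), matched
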