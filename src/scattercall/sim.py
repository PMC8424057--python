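"""Synthetic references and aligned paired-end reads with known truth.

Every pipeline stage is testable without downloads or an aligner: this
module fabricates a small multi-contig reference, paired-end reads with
known alignment positions, optional soft-clipped ends (placed so the
unclipped 5' coordinate is preserved — the property duplicate marking keys
on), and injected PCR-duplicate groups whose membership is recorded in a
truth table.  Sequencing errors are deliberately not simulated (alignment
is bypassed); base qualities are i.i.d. draws so duplicate scores are
almost surely distinct, and a degenerate quality distribution exercises the
tie-break path.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .sam import ReadRecord, SamHeader

__all__ = [
    "Reference",
    "TruthRow",
    "TruthTable",
    "ReadSet",
    "make_reference",
    "simulate_read_set",
    "emit_fastq",
    "emit_sam",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class Reference:
    """A synthetic reference: ordered contigs and their sequences."""

    contigs: list[tuple[str, int]]
    seqs: dict[str, str]

    def to_fasta(self, width: int = 70) -> str:
        out = []
        for name, _ in self.contigs:
            out.append(f">{name}\n")
            seq = self.seqs[name]
            for i in range(0, len(seq), width):
                out.append(seq[i : i + width] + "\n")
        return "".join(out)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_fasta())
        with open(path + ".fai", "w") as fh:
            # minimal .fai: name, length, offset, linebases, linewidth
            offset = 0
            for name, length in self.contigs:
                offset += len(name) + 2
                fh.write(f"{name}\t{length}\t{offset}\t70\t71\n")
                offset += length + (length + 69) // 70

    def gc_fraction(self, name: str) -> float:
        s = self.seqs[name]
        return (s.count("G") + s.count("C")) / len(s)


def make_reference(
    seed: int, contigs: Sequence[tuple[str, int]]
) -> Reference:
    """Uniform-base random reference; deterministic for a fixed seed."""
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seqs = {
        name: rng.choice(bases, size=length).tobytes().decode()
        for name, length in contigs
    }
    return Reference(list(contigs), seqs)


@dataclass(frozen=True)
class TruthRow:
    qname: str
    rname: str
    true_pos_r1: int  # unclipped 5' coordinate of R1 (forward)
    true_pos_r2: int  # unclipped 5' coordinate of R2 (reverse)
    strand_r1: str
    strand_r2: str
    dup_group_id: int | None
    is_seed_of_group: bool


@dataclass
class TruthTable:
    """Ground truth: one row per simulated read pair."""

    rows: list[TruthRow] = field(default_factory=list)

    def duplicate_qnames(self) -> set[str]:
        """Read names of non-seed duplicate-group members (the records a
        perfect marker flags)."""
        return {
            r.qname
            for r in self.rows
            if r.dup_group_id is not None and not r.is_seed_of_group
        }

    def expected_duplicate_count(self) -> int:
        """Sum over groups of (group size - 1) = number of flagged pairs."""
        return len(self.duplicate_qnames())

    def to_tsv(self) -> str:
        header = (
            "qname\trname\ttrue_pos_r1\ttrue_pos_r2\tstrand_r1\tstrand_r2"
            "\tdup_group_id\tis_seed_of_group\n"
        )
        lines = [
            f"{r.qname}\t{r.rname}\t{r.true_pos_r1}\t{r.true_pos_r2}"
            f"\t{r.strand_r1}\t{r.strand_r2}"
            f"\t{'' if r.dup_group_id is None else r.dup_group_id}"
            f"\t{int(r.is_seed_of_group)}\n"
            for r in self.rows
        ]
        return header + "".join(lines)


@dataclass
class ReadSet:
    """Simulated alignment records plus their generating truth."""

    records: list[ReadRecord]
    truth: TruthTable
    reference: Reference
    header: SamHeader


def _default_group_size(rng: np.random.Generator) -> int:
    """Truncated geometric (p = 0.5) duplicate-group size, 2..6."""
    return int(min(1 + rng.geometric(0.5), 6))


def simulate_read_set(
    reference: Reference,
    n_pairs: int,
    read_len: int = 100,
    insert_mean: float = 350.0,
    insert_sd: float = 50.0,
    dup_rate: float = 0.05,
    dup_group_size_dist: Callable[[np.random.Generator], int] | None = None,
    clip_prob: float = 0.0,
    seed: int = 0,
    qual_choices: Sequence[int] = tuple(range(20, 41)),
    max_clip: int = 10,
) -> ReadSet:
    """Simulate ``n_pairs`` original FR read pairs plus injected duplicates.

    Fragments are placed uniformly on contigs weighted by length.  With
    probability ``dup_rate`` an original fragment seeds a duplicate group;
    members copy the seed's coordinates and strands (and clipping pattern)
    but redraw base qualities, so duplicate scores differ almost surely.
    With probability ``clip_prob`` per read, a soft clip of 1..``max_clip``
    bases is applied at the 5' end with POS adjusted so the unclipped 5'
    coordinate is unchanged.  Records carry MC and RG tags and form valid
    proper pairs.
    """
    if not 0 <= dup_rate < 1:
        raise ValueError("dup_rate must be in [0, 1)")
    if read_len < 1 or insert_mean <= 0 or insert_sd < 0:
        raise ValueError("read parameters must be positive")
    group_size = dup_group_size_dist or _default_group_size
    rng = np.random.default_rng(seed)
    qual_choices = tuple(qual_choices)

    contigs = reference.contigs
    names = [n for n, _ in contigs]
    lengths = np.array([ln for _, ln in contigs], dtype=float)
    if min(lengths) < 2 * read_len:
        raise ValueError("every contig must be at least one fragment long")
    weights = lengths / lengths.sum()

    records: list[ReadRecord] = []
    truth = TruthTable()
    header = SamHeader.for_contigs(contigs, read_groups=[("rg1", "lib1")])
    pair_serial = 0

    def draw_quals() -> str:
        qs = rng.choice(qual_choices, size=read_len)
        return "".join(chr(int(q) + 33) for q in qs)

    def emit_pair(
        qname: str,
        rname: str,
        r1_pos: int,
        frag: int,
        dup_group_id: int | None,
        is_seed: bool,
        clip1: int,
        clip2: int,
    ) -> None:
        seq_full = reference.seqs[rname]
        r2_pos = r1_pos + frag - read_len
        seq1 = seq_full[r1_pos - 1 : r1_pos - 1 + read_len]
        seq2 = seq_full[r2_pos - 1 : r2_pos - 1 + read_len]
        # forward read: leading soft clip, POS shifts right by the clip
        if clip1:
            cigar1 = f"{clip1}S{read_len - clip1}M"
            sam_pos1 = r1_pos + clip1
        else:
            cigar1 = f"{read_len}M"
            sam_pos1 = r1_pos
        # reverse read: trailing soft clip, POS unchanged (5' end is rightmost)
        if clip2:
            cigar2 = f"{read_len - clip2}M{clip2}S"
        else:
            cigar2 = f"{read_len}M"
        sam_pos2 = r2_pos
        tags1 = (f"MC:Z:{cigar2}", "RG:Z:rg1")
        tags2 = (f"MC:Z:{cigar1}", "RG:Z:rg1")
        records.append(
            ReadRecord(
                qname=qname, flag=0x63, rname=rname, pos=sam_pos1, mapq=60,
                cigar=cigar1, rnext="=", pnext=sam_pos2, tlen=frag,
                seq=seq1, qual=draw_quals(), tags=tags1,
            )
        )
        records.append(
            ReadRecord(
                qname=qname, flag=0x93, rname=rname, pos=sam_pos2, mapq=60,
                cigar=cigar2, rnext="=", pnext=sam_pos1, tlen=-frag,
                seq=seq2, qual=draw_quals(), tags=tags2,
            )
        )
        truth.rows.append(
            TruthRow(
                qname=qname, rname=rname,
                true_pos_r1=r1_pos,
                true_pos_r2=r2_pos + read_len - 1,
                strand_r1="F", strand_r2="R",
                dup_group_id=dup_group_id, is_seed_of_group=is_seed,
            )
        )

    next_group_id = 0
    for _ in range(n_pairs):
        ci = int(rng.choice(len(names), p=weights))
        rname, clen = contigs[ci]
        for attempt in range(1000):
            frag = int(round(rng.normal(insert_mean, insert_sd)))
            frag = max(frag, 2 * read_len)
            if frag <= clen:
                break
        else:
            raise ValueError(
                f"cannot place a fragment of ~{insert_mean} bp on contig "
                f"{rname!r} of length {clen} after 1000 draws"
            )
        r1_pos = int(rng.integers(1, clen - frag + 2))

        is_group = rng.random() < dup_rate
        gid = next_group_id if is_group else None
        members = group_size(rng) if is_group else 1
        if is_group:
            next_group_id += 1
        first_row = len(truth.rows)
        for m in range(members):
            qname = f"sim{pair_serial:06d}"
            pair_serial += 1
            clip1 = int(rng.integers(1, max_clip + 1)) if rng.random() < clip_prob else 0
            clip2 = int(rng.integers(1, max_clip + 1)) if rng.random() < clip_prob else 0
            emit_pair(
                qname, rname, r1_pos, frag,
                dup_group_id=gid, is_seed=False,
                clip1=clip1, clip2=clip2,
            )
        if is_group:
            # the group's seed is the member a duplicate marker keeps: the
            # pair with the highest base-quality score (>= Q15 bases), ties
            # to the lexicographically smallest read name
            def pair_score(row_idx: int) -> int:
                r1, r2 = records[2 * row_idx], records[2 * row_idx + 1]
                return sum(
                    q - 33
                    for rec in (r1, r2)
                    for q in map(ord, rec.qual)
                    if q - 33 >= 15
                )

            member_rows = range(first_row, first_row + members)
            seed_row = min(
                member_rows, key=lambda i: (-pair_score(i), truth.rows[i].qname)
            )
            truth.rows[seed_row] = dataclasses.replace(
                truth.rows[seed_row], is_seed_of_group=True
            )
    return ReadSet(records=records, truth=truth, reference=reference, header=header)


def emit_fastq(read_set: ReadSet, r1_path: str, r2_path: str) -> int:
    """Write the read set as paired FASTQ (reads in sequencing orientation).

    Reverse-strand records are reverse-complemented back to the orientation
    the sequencer saw.  Returns the number of pairs written.
    """
    n = 0
    with open(r1_path, "w") as o1, open(r2_path, "w") as o2:
        it = iter(read_set.records)
        for r1, r2 in zip(it, it):
            for rec, out in ((r1, o1), (r2, o2)):
                seq, qual = rec.seq, rec.qual
                if rec.is_reverse:
                    seq, qual = _revcomp(seq), qual[::-1]
                mate = "/1" if rec.mate_rank() == 1 else "/2"
                out.write(f"@{rec.qname}{mate}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def emit_sam(read_set: ReadSet, path: str | None = None) -> str:
    """The read set as SAM text (header + records); optionally written out."""
    from .sam import format_sam_line

    text = read_set.header.to_text() + "".join(
        format_sam_line(r) + "\n" for r in read_set.records
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def write_simulation(
    outdir: str,
    seed: int,
    contigs: Sequence[tuple[str, int]],
    n_pairs: int,
    dup_rate: float,
    clip_prob: float = 0.0,
    **kwargs,
) -> ReadSet:
    """One-stop emission of reference, SAM, FASTQ and truth TSV files."""
    os.makedirs(outdir, exist_ok=True)
    ref = make_reference(seed, contigs)
    rs = simulate_read_set(
        ref, n_pairs, dup_rate=dup_rate, clip_prob=clip_prob, seed=seed + 1,
        **kwargs,
    )
    ref.write(os.path.join(outdir, "reference.fasta"))
    emit_sam(rs, os.path.join(outdir, "reads.sam"))
    emit_fastq(
        rs, os.path.join(outdir, "reads_R1.fastq"), os.path.join(outdir, "reads_R2.fastq")
    )
    with open(os.path.join(outdir, "truth.tsv"), "w") as fh:
        fh.write(rs.truth.to_tsv())
    return rs
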