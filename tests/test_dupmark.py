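import random

import pytest

from conftest import make_fragments, oracle_flagged_qnames
from scattercall import sim
from scattercall.dupmark import (
    CigarError,
    DataIntegrityError,
    apply_marks,
    build_pair_candidates,
    clip_profile,
    duplicate_score,
    mark_duplicates,
    sort_region,
    unclipped_5prime,
)
from scattercall.sam import (
    FLAG_DUPLICATE,
    ReadBatch,
    ReadRecord,
    parse_sam_line,
    to_keyed,
)


def rec(qname="r", flag=0, rname="c1", pos=100, cigar="10M", qual=None,
        rnext="*", pnext=0, seq=None, tags=()):
    n = sum(int(x[:-1]) for x in
            __import__("re").findall(r"\d+[MIS=X]", cigar)) if cigar != "*" else 4
    seq = seq or "A" * n
    qual = qual or chr(30 + 33) * n
    return ReadRecord(qname, flag, rname, pos, 60, cigar, rnext, pnext, 0, seq, qual, tuple(tags))


def pair(qname, pos1, pos2, cigar1="10M", cigar2="10M", q1=30, q2=30, rname="c1"):
    """A proper FR pair with uniform per-mate quality."""
    def qual(c, q):
        n = sum(int(x[:-1]) for x in __import__("re").findall(r"\d+[MIS=X]", c))
        return chr(q + 33) * n
    r1 = rec(qname, 0x63, rname, pos1, cigar1, qual=qual(cigar1, q1),
             rnext="=", pnext=pos2, tags=(f"MC:Z:{cigar2}",))
    r2 = rec(qname, 0x93, rname, pos2, cigar2, qual=qual(cigar2, q2),
             rnext="=", pnext=pos1, tags=(f"MC:Z:{cigar1}",))
    return [r1, r2]


class TestClipProfile:
    @pytest.mark.parametrize(
        "cigar,expected",
        [
            ("100M", (0, 0, 100)),
            ("10S90M", (10, 0, 90)),
            ("50M10D40M5S", (0, 5, 100)),      # D consumes reference
            ("5H3S90M2S1H", (8, 3, 90)),
            ("20M100N30M", (0, 0, 150)),       # N consumes reference
            ("10M5I10M", (0, 0, 20)),          # I does not
        ],
    )
    def test_profiles(self, cigar, expected):
        cp = clip_profile(cigar)
        assert (cp.leading_clip, cp.trailing_clip, cp.ref_span) == expected

    @pytest.mark.parametrize("bad", ["*", "", "10Q", "M10", "10"])
    def test_invalid_cigar(self, bad):
        with pytest.raises(CigarError):
            clip_profile(bad)


class TestUnclipped5Prime:
    def test_forward_no_clipping(self):
        assert unclipped_5prime(rec(pos=1000, cigar="100M")) == ("c1", 1000, "F")

    def test_forward_leading_clip(self):
        assert unclipped_5prime(rec(pos=1000, cigar="10S90M")) == ("c1", 990, "F")

    def test_reverse_trailing_clip(self):
        r = rec(flag=0x10, pos=1000, cigar="90M10S")
        assert unclipped_5prime(r) == ("c1", 1099, "R")  # 1000 + 90 - 1 + 10

    @pytest.mark.parametrize("flag,cigar", [(0x4, "10M"), (0x100, "10M"),
                                            (0x800, "10M"), (0, "*")])
    def test_exclusions_return_none(self, flag, cigar):
        assert unclipped_5prime(rec(flag=flag, cigar=cigar)) is None


class TestDuplicateScore:
    def test_uniform_q30(self):
        assert duplicate_score([rec(cigar="10M", qual=chr(30 + 33) * 10)]) == 300

    def test_only_qualities_at_least_15_count(self):
        qual = "".join(chr(q + 33) for q in (10, 20, 14, 15))
        assert duplicate_score([rec(cigar="4M", seq="ACGT", qual=qual)]) == 35

    def test_pair_additivity(self):
        a = rec(cigar="10M", qual=chr(30 + 33) * 10)
        qual = "".join(chr(q + 33) for q in (10, 20, 14, 15))
        b = rec(cigar="4M", seq="ACGT", qual=qual)
        assert duplicate_score([a, b]) == 335

    def test_star_qual_contributes_zero(self):
        assert duplicate_score([rec(cigar="4M", seq="ACGT", qual="*")]) == 0


class TestSortRegion:
    @staticmethod
    def _batch(records):
        return ReadBatch.from_keyed(0, [to_keyed(r) for r in records])

    def test_sorts_by_pos(self):
        b = self._batch([rec(pos=5), rec(pos=1), rec(pos=3)])
        assert sort_region(b).pos == (1, 3, 5)

    def test_tie_break_by_qname(self):
        b = self._batch([rec("b", pos=7), rec("a", pos=7)])
        out = sort_region(b)
        assert [s.split("\t")[0] for s in out.sam] == ["a", "b"]

    def test_empty_batch(self):
        out = sort_region(ReadBatch(0).seal())
        assert len(out) == 0 and out.sealed


class TestBuildPairCandidates:
    def test_proper_pair_one_candidate(self):
        pairs, frags = build_pair_candidates(pair("p", 100, 300))
        assert len(pairs) == 1 and not frags
        c = pairs[0]
        assert c.key.kind == "pair"
        assert c.key.end1 == ("c1", 100, "F")
        assert c.key.end2 == ("c1", 309, "R")
        assert c.key.orientation == "FR"

    def test_mate_unmapped_becomes_fragment(self):
        r = rec("f", 0x1 | 0x8 | 0x40, pos=50, cigar="10M")
        pairs, frags = build_pair_candidates([r])
        assert not pairs and len(frags) == 1
        assert frags[0].key.kind == "fragment"

    def test_supplementary_and_secondary_excluded(self):
        recs = pair("p", 100, 300) + [rec("p", 0x63 | 0x800, pos=700)]
        pairs, frags = build_pair_candidates(recs)
        assert len(pairs) == 1 and not frags

    def test_three_primaries_is_integrity_error(self):
        recs = pair("p", 100, 300) + [rec("p", 0x63, pos=700)]
        with pytest.raises(DataIntegrityError):
            build_pair_candidates(recs)

    def test_lone_mate_uses_mc_tag(self):
        # only R1 present; mate end must come from MC + PNEXT
        full_pairs, _ = build_pair_candidates(pair("p", 100, 300, cigar2="5S5M"))
        lone_pairs, _ = build_pair_candidates(pair("p", 100, 300, cigar2="5S5M")[:1])
        assert lone_pairs[0].key == full_pairs[0].key


class TestMarkDuplicates:
    def test_single_pair_unflagged(self):
        p, f = build_pair_candidates(pair("p", 100, 300))
        assert mark_duplicates(p, f) == set()

    def test_lower_scoring_pair_flagged(self):
        recs = pair("a", 100, 300, q1=30, q2=30) + pair("b", 100, 300, q1=20, q2=20)
        p, f = build_pair_candidates(recs)
        decisions = mark_duplicates(p, f)
        assert {q for q, _ in decisions} == {"b"}
        assert decisions == {("b", 1), ("b", 2)}

    def test_clipped_duplicate_collides(self):
        # same unclipped 5' ends despite clipping: 95+5=100 and identical R ends
        recs = pair("a", 100, 300) + pair("b", 105, 300, cigar1="5S5M", cigar2="5M5S")
        p, f = build_pair_candidates(recs)
        assert len({c.key for c in p}) == 1
        assert {q for q, _ in mark_duplicates(p, f)} == {"b"}

    def test_fragment_at_pair_end_always_flagged(self):
        recs = pair("p", 100, 300, q1=10, q2=10)
        frag = rec("f", 0x1 | 0x8 | 0x40, pos=100, cigar="10M",
                   qual=chr(40 + 33) * 10)  # higher score than the pair
        p, f = build_pair_candidates(recs + [frag])
        assert ("f", 1) in mark_duplicates(p, f)

    def test_fragment_only_group_keeps_best(self):
        f1 = rec("f1", 0, pos=100, cigar="10M", qual=chr(40 + 33) * 10)
        f2 = rec("f2", 0, pos=100, cigar="10M", qual=chr(20 + 33) * 10)
        p, f = build_pair_candidates([f1, f2])
        assert mark_duplicates(p, f) == {("f2", 0)}

    def test_score_tie_broken_by_ascending_qname(self):
        recs = pair("zz", 100, 300) + pair("aa", 100, 300)  # equal scores
        p, f = build_pair_candidates(recs)
        assert {q for q, _ in mark_duplicates(p, f)} == {"zz"}


class TestApplyMarks:
    @staticmethod
    def _batch(records):
        return ReadBatch.from_keyed(0, [to_keyed(r) for r in records])

    def test_empty_decisions_byte_identical(self):
        b = self._batch(pair("p", 100, 300))
        out, matched = apply_marks(b, set())
        assert out.sam == b.sam and matched == set()

    def test_one_decision_flips_only_flag_field(self):
        recs = pair("a", 100, 300) + pair("b", 100, 300, q1=20, q2=20)
        b = self._batch(recs)
        out, matched = apply_marks(b, {("b", 1), ("b", 2)})
        assert matched == {("b", 1), ("b", 2)}
        changed = [
            (old, new) for old, new in zip(b.sam, out.sam) if old != new
        ]
        assert len(changed) == 2
        for old, new in changed:
            of, nf = old.split("\t"), new.split("\t")
            assert int(nf[1]) == int(of[1]) | FLAG_DUPLICATE
            assert of[:1] + of[2:] == nf[:1] + nf[2:]

    def test_count_and_order_conserved(self):
        recs = pair("a", 100, 300) + pair("b", 100, 300)
        b = self._batch(recs)
        out, _ = apply_marks(b, {("b", 1), ("b", 2)})
        assert len(out) == len(b)
        assert [s.split("\t")[0] for s in out.sam] == [s.split("\t")[0] for s in b.sam]


def _flagged_qnames(records, rg_lb=None):
    pairs, frags = build_pair_candidates(records, rg_lb)
    return {q for q, _ in mark_duplicates(pairs, frags)}


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_regions(self, seed, small_reference):
        rs = sim.simulate_read_set(
            small_reference, n_pairs=150, dup_rate=0.15, clip_prob=0.3,
            seed=seed,
        )
        records = make_fragments(rs.records, every=4)
        rg_lb = rs.header.rg_to_lb()
        assert _flagged_qnames(records, rg_lb) == oracle_flagged_qnames(
            records, rg_lb, [n for n, _ in small_reference.contigs]
        )

    def test_degenerate_qualities_all_tie(self, small_reference):
        rs = sim.simulate_read_set(
            small_reference, n_pairs=100, dup_rate=0.3, clip_prob=0.0,
            seed=3, qual_choices=[30],
        )
        rg_lb = rs.header.rg_to_lb()
        assert _flagged_qnames(rs.records, rg_lb) == oracle_flagged_qnames(
            rs.records, rg_lb, [n for n, _ in small_reference.contigs]
        )


class TestInvariants:
    def test_permutation_invariance(self, clipped_read_set):
        records = list(clipped_read_set.records)
        rg_lb = clipped_read_set.header.rg_to_lb()
        base = _flagged_qnames(records, rg_lb)
        rng = random.Random(5)
        for _ in range(3):
            rng.shuffle(records)
            assert _flagged_qnames(records, rg_lb) == base

    def test_idempotence(self, clipfree_read_set):
        rs = clipfree_read_set
        rg_lb = rs.header.rg_to_lb()
        pairs, frags = build_pair_candidates(rs.records, rg_lb)
        decisions = mark_duplicates(pairs, frags)
        b = ReadBatch.from_keyed(0, [to_keyed(r) for r in rs.records])
        marked, _ = apply_marks(b, decisions)
        # second run on marked output: same decisions, no byte changes
        pairs2, frags2 = build_pair_candidates(marked.records(), rg_lb)
        decisions2 = mark_duplicates(pairs2, frags2)
        assert decisions2 == decisions
        marked2, _ = apply_marks(marked, decisions2)
        assert marked2.sam == marked.sam

    def test_ground_truth_recovery_exact(self, clipfree_read_set):
        rs = clipfree_read_set
        flagged = _flagged_qnames(rs.records, rs.header.rg_to_lb())
        truth = rs.truth.duplicate_qnames()
        assert truth, "fixture must contain duplicate groups"
        assert flagged == truth  # recall = precision = 1.0
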