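import os
import re
import stat

import pytest

from scattercall import sim
from scattercall.regions import build_regions
from scattercall.sam import ReadRecord

# ---------------------------------------------------------------------------
# Independent brute-force duplicate-marking oracle.
#
# Deliberately re-derives clipping, ends, keys and scores with its own
# minimal code (dict hashing, no sorting, no batching, no region routing) so
# it shares no code path with scattercall.dupmark.
# ---------------------------------------------------------------------------

_CIG = re.compile(r"(\d+)([A-Z=])")


def _oracle_end(rec: ReadRecord):
    ops = _CIG.findall(rec.cigar)
    lead = trail = span = 0
    i = 0
    while i < len(ops) and ops[i][1] in "SH":
        lead += int(ops[i][0])
        i += 1
    j = len(ops) - 1
    while j >= 0 and ops[j][1] in "SH":
        trail += int(ops[j][0])
        j -= 1
    for n, op in ops:
        if op in "MDN=X":
            span += int(n)
    if rec.flag & 0x10:
        return (rec.rname, rec.pos + span - 1 + trail, "R")
    return (rec.rname, rec.pos - lead, "F")


def _oracle_score(recs):
    total = 0
    for r in recs:
        if r.qual != "*":
            total += sum(q - 33 for q in map(ord, r.qual) if q - 33 >= 15)
    return total


def _oracle_lib(rec: ReadRecord, rg_lb):
    for t in rec.tags:
        if t.startswith("RG:"):
            return rg_lb.get(t.split(":", 2)[2], "unknown")
    return "unknown"


def oracle_flagged_qnames(records, rg_lb=None, contig_order=None):
    """Brute-force duplicate marking: returns the set of flagged read names."""
    rg_lb = rg_lb or {}
    rank = {c: i for i, c in enumerate(contig_order)} if contig_order else {}

    def end_key(e):
        return (rank.get(e[0], len(rank)), e[0], e[1], e[2])

    primaries = [
        r for r in records
        if not (r.flag & (0x4 | 0x100 | 0x800))
    ]
    by_name = {}
    frags = []
    for r in primaries:
        if (r.flag & 0x1) and not (r.flag & 0x8):
            by_name.setdefault(r.qname, []).append(r)
        else:
            frags.append(r)

    pair_groups = {}
    pair_ends = set()
    for qname, recs in by_name.items():
        if len(recs) != 2:
            continue
        lib = _oracle_lib(recs[0], rg_lb)
        e = sorted((_oracle_end(recs[0]), _oracle_end(recs[1])), key=end_key)
        key = (lib, e[0], e[1], e[0][2] + e[1][2])
        pair_groups.setdefault(key, []).append((qname, _oracle_score(recs)))
        pair_ends.add((lib, e[0]))
        pair_ends.add((lib, e[1]))

    flagged = set()
    for group in pair_groups.values():
        if len(group) > 1:
            keep = min(group, key=lambda t: (-t[1], t[0]))
            flagged |= {q for q, _ in group if q != keep[0]}

    frag_groups = {}
    for r in frags:
        lib = _oracle_lib(r, rg_lb)
        key = (lib, _oracle_end(r))
        if key in pair_ends:
            flagged.add(r.qname)
        else:
            frag_groups.setdefault(key, []).append((r.qname, _oracle_score([r])))
    for group in frag_groups.values():
        if len(group) > 1:
            keep = min(group, key=lambda t: (-t[1], t[0]))
            flagged |= {q for q, _ in group if q != keep[0]}
    return flagged


# ---------------------------------------------------------------------------
# Shared fixtures
# ---------------------------------------------------------------------------

SIM_CONTIGS = [("c1", 120_000), ("c2", 60_000)]


@pytest.fixture(scope="session")
def small_reference():
    return sim.make_reference(11, SIM_CONTIGS)


@pytest.fixture(scope="session")
def small_table():
    # 50 kb regions: c1 -> 2 regions (60 kb each), c2 -> 1 region
    return build_regions(SIM_CONTIGS, target_size=50_000)


@pytest.fixture(scope="session")
def clipfree_read_set(small_reference):
    return sim.simulate_read_set(
        small_reference, n_pairs=400, dup_rate=0.1, clip_prob=0.0, seed=7
    )


@pytest.fixture(scope="session")
def clipped_read_set(small_reference):
    return sim.simulate_read_set(
        small_reference, n_pairs=400, dup_rate=0.1, clip_prob=0.25, seed=8
    )


def make_fragments(records, every=5):
    """Turn every ``every``-th pair into a lone fragment (mate 'unmapped').

    Drops the R2 record and rewrites R1's flags so it reads as a mapped read
    with an unmapped mate.
    """
    out = []
    it = iter(records)
    for i, (r1, r2) in enumerate(zip(it, it)):
        if i % every == 0:
            flag = (r1.flag | 0x8) & ~(0x2 | 0x20)
            out.append(r1.with_flag(flag))
        else:
            out.extend([r1, r2])
    return out


def _write_stub_caller(script):
    """A stand-in caller script (synthetic): emits two fixed VCF records
    positioned inside the queried region."""
    script.write_text(
        "#!/bin/bash\n"
        "bed=$3; vcf=$4\n"
        "chrom=$(cut -f1 $bed); start=$(cut -f2 $bed)\n"
        "{\n"
        "echo '##fileformat=VCFv4.2'\n"
        "echo '##contig=<ID=c1,length=120000>'\n"
        "echo '##contig=<ID=c2,length=60000>'\n"
        "printf '#CHROM\\tPOS\\tID\\tREF\\tALT\\tQUAL\\tFILTER\\tINFO\\n'\n"
        "printf '%s\\t%s\\t.\\tA\\tT\\t30\\tPASS\\t.\\n' $chrom $((start+5))\n"
        "printf '%s\\t%s\\t.\\tG\\tC\\t30\\tPASS\\t.\\n' $chrom $((start+9))\n"
        "} > $vcf\n"
    )
    script.chmod(script.stat().st_mode | stat.S_IEXEC)
    return str(script)


@pytest.fixture()
def stub_caller(tmp_path):
    return _write_stub_caller(tmp_path / "stub_caller.sh")


@pytest.fixture(scope="session")
def stub_caller_session(tmp_path_factory):
    return _write_stub_caller(tmp_path_factory.mktemp("stub") / "stub_caller.sh")
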