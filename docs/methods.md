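# Methods

This note documents the models, rules and numerical choices behind
`scattercall`, and what the synthetic-data tests do and do not demonstrate
about real sequencing data.

## Read model

The unit of data is the key-value pair `<POS : SAM line>` with RNAME carried
alongside. The SAM *text* line is the canonical value: `parse_sam_line` /
`format_sam_line` are exact inverses, auxiliary tags are opaque strings kept
verbatim and in order, and every transformation that does not deliberately
edit a field (only duplicate marking edits FLAG) is byte-preserving. Reads
are grouped per region into columnar batches (`pos: int64`, `sam: string`,
`rname: string`); a sealed batch is immutable and can be exported as a
pyarrow RecordBatch with that schema. The store is in-process: the contract
(immutable columnar batches per region) is what downstream stages rely on,
not any particular shared-memory transport. BAM is produced only at
shard-writing time, through pysam; BAM/CRAM binary parsing is out of scope.

Unmapped reads (FLAG 0x4), reads with RNAME `*`, and reads on contigs
missing from the region table are carried through to an "unplaced"
pseudo-region: they are preserved and counted, but excluded from sorting
keys and duplicate marking, mirroring how downstream callers treat them.
Base qualities are assumed Phred+33.

## Static region partition

Each contig of length *L* is split into `n = max(1, round(L / T))`
contiguous spans (round half up), the first `L mod n` spans one base longer,
so spans within a contig differ by at most one base. The default target
*T* = 47,000,000 bp was chosen because, over the embedded GRCh37 primary
contig lengths (chr1–22, X, Y, MT), it produces 65 regions with a mean
length of 47.6 Mb — in the middle of the 40–50 Mb band this load-balancing
scheme aims for. The per-contig *count* rule (rather than a fixed span
length) is what guarantees near-equal regions inside each chromosome.
Region spans are 1-based inclusive, matching SAM POS; BED export converts
to 0-based half-open explicitly. Lookup is a binary search over region
starts, checked in tests against a linear-scan oracle on 10,000 random
positions. Partition exactness (no gap, no overlap, full coverage) is
asserted over the whole table.

Dynamic, read-density-based balancing and N-gap-aware boundaries are
deliberately not implemented: static spans keep region assignment a pure
function of (contig, POS).

## FASTQ chunking

Paired FASTQ is split by record index into `n` chunks whose sizes differ by
at most one record, the remainder going to the lowest-index chunks —
deterministic and maximally balanced. Chunking is two-pass (count, then
stream); records pass through byte-identically and mates stay synchronized
by index. Requesting more chunks than records caps the plan at one record
per chunk with a warning. Interleaved FASTQ is rejected; exactly two mate
files (or one single-end file) are accepted.

## Duplicate marking

The algorithm follows Picard MarkDuplicates semantics:

- **Ends.** A read end is (contig, unclipped 5′ coordinate, strand).
  Forward: `POS − leading_clip`; reverse: `POS + ref_span − 1 +
  trailing_clip`, with `ref_span = Σ M/D/N/=/X`. Secondary (0x100),
  supplementary (0x800) and unmapped records are excluded entirely; a CIGAR
  of `*` excludes a record from keys (it passes through unmarked).
- **Keys.** Pairs (both mates mapped, primary): (library, end1, end2,
  orientation), ends in canonical order by (contig order, coordinate,
  strand), orientation being the strands in that order (FR/RF/FF/RR).
  Fragments (unpaired or mate unmapped): (library, end). Library comes from
  the RG tag via the @RG→LB header mapping, falling back to "unknown".
- **Score.** Sum of base qualities ≥ 15 over both mates (the de-facto
  Picard default); `*` qualities contribute 0.
- **Selection.** Per pair-key group keep the arg-max score; flag the rest.
  A fragment whose (library, end) coincides with *any* pair end is flagged
  unconditionally (paired evidence beats single-end evidence); among
  fragment-only groups keep the arg-max. Ties break by ascending read name.
- **Marking.** Decisions are (read name, mate rank) tuples; applying them
  sets FLAG |= 0x400 and changes nothing else. Marking is idempotent (the
  0x400 bit is ignored when grouping) and permutation-invariant (all
  tie-breaks are content-based).

When only one mate of a pair is at hand, the mate's end is inferred from
the MC (mate CIGAR) tag; without MC, PNEXT is used clip-unaware — exact for
unclipped mates, and the pipeline counts such fallbacks. Optical-duplicate
detection (tile/x/y parsing) is not implemented; all duplicates are treated
as PCR duplicates. Records are flagged, never dropped.

**Region routing.** For marking, a pair is processed in the region
containing its smaller canonical end; a fragment in the region containing
its own end (coordinates clamped to the contig span, since clipping can
push an unclipped coordinate past an edge). Because all members of one
duplicate group share both end coordinates, every group is complete in
exactly one routing region — per-region marking is provably equivalent to
global marking. Decisions are then reconciled back to each record's storage
region by read name; an unmatched decision is an error, not a warning.

**Sorting.** Within a region, records are ordered by POS with ties broken
by (read name, FLAG). The tie-break is a design choice — any deterministic
content-based order suffices — made so output never depends on input order.
Concatenating regions in table order yields a globally coordinate-sorted
stream.

## Sharding, calling, merging

Every region becomes an indexed BAM shard whose header carries the full
sequence dictionary (so mate references on other contigs remain valid);
empty regions produce valid empty shards so callers can be launched
uniformly. A pre-existing sorted BAM can be split the same way, placing
each read by POS (overlap-based fetches are filtered back to containment).
Caller integration is purely declarative: a command template with
placeholders, one subprocess per region, at most `max_parallel` at a time.
Failures are recorded per region with their exit code and do not stop other
regions; manifest statuses make reruns resumable.

Merging takes the header from the first per-region VCF, verifies
`##contig` lines are consistent across inputs, and sorts records by
(contig order of the region table, POS, REF, ALT). By default regions are
unpadded, so region VCFs cannot overlap and the merged record count is the
sum of the inputs. With `--pad B` each region's BED is extended by B bases
per side for callers sensitive to edge truncation; at merge time records
outside their own region's span are dropped and exact (contig, POS, REF,
ALT) duplicates collapse, restoring partition semantics. gVCF inputs are
concatenated without the span filter (reference blocks straddle
boundaries) and flagged as such. Merging operates on VCF text lines:
the operation is pure line bookkeeping and per-record bytes from each
caller are preserved exactly.

## Parallelism contract

Regions are the unit of parallelism; within-region work is sequential. The
worker pool is a thread pool and the contract is *artifact invariance*:
every shard and the merged VCF are byte-identical for 1 or N workers and
across reruns, because per-region computation is deterministic and results
are assembled in region order. No distributed engine is involved; the
contract, not the engine, is the design object.

## Synthetic data

The generator fabricates what the tests need and nothing more:

- uniform-base references (GC ≈ 0.5) over arbitrary contig tables;
- FR proper pairs with fragment length ~ Normal(350, 50) truncated below at
  two read lengths, placed uniformly on contigs weighted by length;
  read length 100, MAPQ 60, MC and RG tags, one library;
- duplicate groups injected at rate 0.05 by default (0.1 in most tests),
  group sizes from a truncated geometric distribution (p = 0.5, max 6) —
  small groups dominate real PCR duplication, and the marking logic is
  size-agnostic;
- base qualities i.i.d. uniform on Phred 20–40, so group members' scores
  are almost surely distinct; a degenerate single-value distribution
  exercises the tie-break path;
- optional soft clips of 1–10 bases applied at the 5′ end with POS adjusted
  so the unclipped 5′ coordinate is preserved — the keystone property
  (checked record-by-record in tests) that makes duplicate-recovery
  assertions meaningful under clipping.

A group's truth "seed" is the member a correct marker keeps: the pair with
the highest base-quality score, ties to the smallest read name. This makes
"flagged set = non-seed members" an exact expectation rather than a
statistical one.

Not emulated: sequencing errors and indels (alignment is bypassed, so
aligner-induced key ambiguity never arises), optical duplicate geometry,
multiple libraries/read groups per file, secondary/supplementary
alignments, coverage gradients, and real genome repeat structure. Passing
tests therefore demonstrate the *logic* — key construction, selection,
routing, conservation, ordering, invariance — under clean alignments, not
robustness to aligner artifacts on real data. The Picard conformance
harness (run automatically when a `picard` executable is present) is the
bridge to an external implementation.

## Problem sizes and tolerances

All checks are exact (set equality, byte equality, integer conservation);
no numerical tolerances are involved anywhere. Test and acceptance problem
sizes are chosen to keep the whole suite in seconds while exercising every
code path: oracle-equivalence uses 50 seeded regions of ~300–400 records
each on a 180 kb two-contig genome (collision-dense because positions are
drawn from a small space), ground-truth recovery uses 3,000 pairs, and the
end-to-end invariance runs use 3 regions at a 50 kb target. The marking
algorithm is O(n log n) in reads per region and has no size-dependent
behavior beyond hash-group sizes, so small dense regions are the stringent
test of the grouping logic.
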