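# scattercall

Desk-scale scatter-gather pre-processing for short-read variant calling.

Whole-genome variant-calling workflows spend much of their time in three
pre-processing steps between the aligner and the caller: coordinate sorting,
PCR-duplicate marking, and the bookkeeping needed to run a variant caller on
many genomic regions in parallel. Cluster frameworks solve this with
distributed engines; `scattercall` implements the same *architecture* —
paired FASTQ chunking, a columnar `<POS : SAM>` key-value read model, static
region-based load balancing of the genome, per-region sorting and
Picard-compatible duplicate marking, region-sharded BAM emission, pluggable
per-region variant calling, and VCF merging — as an ordinary Python library
and CLI that is fully testable on synthetic data, with no downloads and no
aligner required.

It is aimed at pipeline developers who want the scatter-gather contract
(regions processed independently, artifacts invariant to worker count and
input order) in a form they can run, test and extend at a desk.

## The method

**Static load balancing.** Each contig of length *L* is divided into
`max(1, round(L / T))` contiguous near-equal spans, with the default target
*T* = 47 Mb. Over the GRCh37 primary contigs (chr1–22, X, Y, MT, embedded as
constants) this yields **65 regions** with mean length **47.6 Mb**, inside
the 40–50 Mb band the design aims for. Regions are 1-based inclusive spans;
every read is routed to the unique region containing its POS.

**Duplicate marking.** Within one library, two read pairs are PCR duplicates
when both fragment ends share the same (contig, unclipped 5′ coordinate,
strand). The unclipped 5′ coordinate undoes soft/hard clipping:

- forward strand: `POS − leading_clip`
- reverse strand: `POS + ref_span − 1 + trailing_clip`

where `ref_span` counts reference-consuming CIGAR operations (M/D/N/=/X).
Candidates are scored by the Picard default rule — the sum of base qualities
≥ 15 over both mates — and within each key group the highest-scoring
candidate is kept while all others receive FLAG 0x400. Fragments (unpaired
reads or reads with an unmapped mate) are keyed by their single end; a
fragment colliding with any *pair* end is flagged unconditionally. All ties
break lexicographically by read name, so the flagged set is a pure function
of record content. A pair is processed in the region containing its smaller
canonical end, which makes every duplicate group complete in exactly one
region and the whole computation embarrassingly parallel.

**Scatter-gather calling.** Each region becomes a coordinate-sorted, indexed
BAM shard carrying the full sequence dictionary. Any caller that supports
region-restricted calling plugs in through a command template with `{bam}`,
`{ref}`, `{region_bed}`, `{vcf}` (and `{threads}`) placeholders; per-region
VCFs are merged into one VCF sorted by (contig order, POS), with optional
region padding and exact-duplicate removal at merge time.

## Worked example

Simulate reads with injected duplicate groups, preprocess, call with a stub
caller script, and merge:

```
$ scattercall simulate --contigs c1:120000,c2:60000 --pairs 500 \
      --dup-rate 0.1 --seed 42 --outdir simdata
wrote 1178 records (589 pairs, 89 true duplicate pairs) to simdata

$ scattercall preprocess --input simdata/reads.sam \
      --fai simdata/reference.fasta.fai --target-size 50000 \
      --workers 4 --outdir shards
1178 records, 1178 placed, 178 duplicate decisions; manifest in shards

$ scattercall call --manifest shards/manifest.json \
      --caller-template './stub_caller.sh {bam} {ref} {region_bed} {vcf}' \
      --ref simdata/reference.fasta --fai simdata/reference.fasta.fai \
      --target-size 50000 --max-parallel 2 --outdir calls
3 regions done, 0 failed

$ scattercall merge --manifest shards/manifest.json \
      --fai simdata/reference.fasta.fai --target-size 50000 --out merged.vcf
6 records written to merged.vcf
```

The simulator injected 89 duplicate *pairs*, and preprocessing emitted 178
duplicate decisions — one per mate of each flagged pair, i.e. exactly the 89
redundant pairs and nothing else (`shards/preprocess_report.json` carries
the per-region read counts and the conservation check). The 50 kb target
splits the 120 kb + 60 kb toy genome into 3 regions; the stub caller emits 2
records per region, so the merged VCF holds 6.

The same steps are available as library calls (`scattercall.sim`,
`scattercall.pipeline.preprocess`, `scattercall.shards`); `scattercall run`
drives the whole chain, optionally starting from FASTQ with
`chunk` + an external aligner command.

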