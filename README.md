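# ovsize

Reference-free genome size estimation from long-read overlaps.

Genome size is needed before many long-read analyses even start —
assemblers ask for it, and computing sequencing depth or downsampling a
run requires it. k-mer-based estimators built for short reads struggle
with the error rates of Oxford Nanopore and PacBio data. `ovsize`
instead estimates genome size directly from how often randomly sampled
reads overlap each other: under uniform read placement on a genome of
size *GS*, a query read *q* overlaps a target read *t* by at least *OT*
bases with probability

    P = (ℓ(q) + ℓ(t) − 2·OT + 1) / (GS − ℓ(q)),

so the expected number of targets overlapping *q* is
|T∖{q}| · (ℓ(q) + ℓ̄ − 2·OT + 1) / (GS − ℓ(q)). Inverting this at the
*observed* overlap count gives a genome-size estimate per query read,

    GS(q) = ℓ(q) + |T∖{q}| · (ℓ(q) + ℓ̄ − 2·OT + 1) / count(q),

and the final estimate is the **median** of the defined per-read
estimates, with an expected range taken from their 15th–65th
percentiles. Reads with no overlaps (undefined estimates) are counted
and excluded. Overlap evidence comes either from a minimap2 all-vs-all
run (`ava-ont`/`ava-pb`, minimum chaining score = *OT*) or from any
precomputed PAF file.

The package also ships a simulator that places reads uniformly on a
genome of known size, computes exact ground-truth overlap counts, and
emits perfect PAF records — so the entire pipeline is testable and
calibratable with no external data. See `docs/methods.md` for the full
model, its assumptions, and known failure modes (notably non-uniform
depth, which drives underestimates).

## Worked example

Simulate a 1 Mbp circular genome sequenced into 15 000 reads of
1 kbp, with perfect overlap evidence, then estimate its size back:

```sh
ovsize simulate --genome-size 1000000 --n-reads 15000 --seed 11 \
    --paf-out demo.paf --reads-out demo_reads.fa --genome-out demo_genome.fa
ovsize estimate demo_reads.fa --paf-in demo.paf --seed 11
```

which prints

```json
{
  "genome_size": 1001555.5555555555,
  "ci_low": 819636.3636363636,
  "ci_high": 1126625.0,
  "ci_note": "expected range: 15th-65th percentile of per-read estimates",
  "n_zero_overlap": 0,
  "n_used": 5000,
  "n_query": 5000,
  "strategy": "2set",
  "seed": 11,
  "ot": 100,
  "min_read_length": 0,
  "platform": "ont",
  "filter_internal": false,
  "use_min_ref": false,
  "version": "0.1.0"
}
```

The median of 5 000 per-read estimates lands on 1 001 556 bp — a
relative error of +0.16% against the simulated truth of 1 Mbp — and the
true size sits inside the reported 15th–65th percentile expected range.
All 5 000 sampled query reads had at least one overlap, so none were
excluded. Every parameter, including the sampling seed, is echoed in
the report, making any run reproducible from its own output.

On real reads, skip `--paf-in` and `ovsize estimate reads.fastq.gz`
will run minimap2 itself (`--platform pacbio` switches the preset; `-F`
filters contained reads, recommended for repeat-rich genomes;
`--output-format plain` prints just the size for pipeline use).
`ovsize calibrate` re-derives the percentile range from a directory of
per-read estimate TSVs plus a truth table.

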