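# Methods

## The model

Genome size is inferred from how often randomly sampled long reads
overlap each other. Suppose a genome of size *GS* has been sequenced
into reads placed uniformly at random. Fix a target read *t* of length
ℓ(t) at a known position, and drop a query read *q* of length ℓ(q)
uniformly over its *GS* − ℓ(q) possible start positions. The two reads
share at least *OT* bases exactly when *q*'s start lands in an interval
of size ℓ(q) + ℓ(t) − 2·*OT* + 1, so

    P(overlap ≥ OT) = (ℓ(q) + ℓ(t) − 2·OT + 1) / (GS − ℓ(q)),

clamped to [0, 1]; positions near the ends of a linear genome shrink
the interval slightly, and this edge effect is deliberately ignored
(it is a sub-percent correction at typical genome/read-length ratios,
and the simulator's circular mode removes it entirely for testing).

Summing over a target set *T* (excluding *q* itself, so the same read
pool can serve as both sets) gives the expected overlap count

    E[count(q)] = |T∖{q}| · (ℓ(q) + ℓ̄_{T∖{q}} − 2·OT + 1) / (GS − ℓ(q)),

where ℓ̄_{T∖{q}} is the mean target length with *q* left out. Observing
a count and solving for *GS* yields a per-read estimate

    GS(q) = ℓ(q) + |T∖{q}| · (ℓ(q) + ℓ̄_{T∖{q}} − 2·OT + 1) / count(q).

A read with no overlaps gives an undefined estimate (the count is a
denominator); such reads are tallied and excluded rather than mapped to
infinity. The overall estimate is the **median** of the defined
per-read estimates — robust both to zero-overlap dropouts and to reads
from unusually deep regions. The reported range is a percentile
interval of the same estimates, by default the 15th–65th (see
"Expected range" below).

The inversion is exact in the noiseless limit: substituting the
expected count back into the per-read formula returns
ℓ(q) + (GS − ℓ(q)) = GS identically, which the test suite asserts at
floating-point tolerance.

### Assumptions

- Reads are placed uniformly (no amplification bias, no depth spikes).
  Plasmids or rRNA operons at very high copy number violate this and
  drive underestimates, because sampled reads then mostly come from the
  small high-depth replicon; the method does not correct for it.
- Overlaps arise from genomic adjacency, not repeats. The optional
  internal-match filter (below) mitigates, but does not remove,
  repeat-induced overlaps in large genomes.
- Every true overlap of at least *OT* bases is observed. With a real
  aligner, low-quality reads break this assumption, reduce counts, and
  inflate the estimate.

## Parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| `n_query` (|Q|) | 5 000 | per-read estimates computed; median taken over these |
| `n_target` (|T|) | 10 000 | overlap partners per query; controls count magnitude |
| `ot` (OT) | 100 bp | minimum overlap; also the aligner's min chaining score |
| `strategy` | `2set` | disjoint Q/T; `ava` uses one shared set |
| `min_read_length` | 0 | drop shorter reads before sampling (off by default) |
| `filter_internal` | off | discard containments before counting |
| `seed` | 42 | read sampling; echoed in every report |

*OT* is a single knob serving both the model and the aligner by
construction (minimap2 `-m`), so the evidence and the expectation
formula cannot drift apart. Larger |T| tightens each per-read estimate
(more Bernoulli trials); larger |Q| tightens the median. The defaults
suit bacterial-scale genomes at typical long-read depths; much larger
genomes need proportionally larger sets to keep expected counts well
above zero.

## Overlap evidence

Counting is over **distinct read pairs**, not alignment records: a
chained or split alignment can emit several PAF records for one pair,
which would bias counts upward. Each unordered pair {a, b} contributes
at most 1 to a query's count; self-pairs contribute 0; records are
normalized so the Q-side read is treated as the query, making counts
invariant to which set served as the aligner's reference. Records
joining two queries or two targets (possible when the reference is
swapped) are discarded with a diagnostic counter.

Containments ("internal matches") are classified by the standard
end-overhang test on strand-normalized coordinates: a read is contained
when both of its unaligned overhangs fit within the partner's (within a
tolerance, default 0). Filtering them is off by default and recommended
for repeat-rich eukaryotic genomes.

The external backend shells out to `minimap2 -x ava-ont|ava-pb -m OT`.
For two-set runs `--dual=yes` is passed: the ava presets otherwise
report each pair in only one lexicographic name orientation, which
silently halves Q–T evidence when query and reference are distinct
files (verified to cause a ~2× size overestimate before the fix).

## The simulator

The generator emulates the model's own sampling process: read lengths
from a fixed or clipped-lognormal model, start positions uniform,
strands uniform, and — when sequences are requested — a uniform-random
genome with substitution errors only. Ground-truth overlap counts come
from interval arithmetic (a sorted sweep with an O(n²) reference kept
for oracle tests), and each truly overlapping pair can be emitted as a
perfect PAF record whose coordinates derive from the interval
intersection.

It does **not** emulate: realistic error profiles (indels in
particular, which is why the aligner integration test uses error-free
reads), chimeric reads, repeats, or non-uniform depth. Passing tests
therefore demonstrate the statistical machinery is correct under the
model's assumptions, not that estimates on real runs reach any
particular accuracy.

### Circular mode and the exact expectation

A circular genome removes edge effects, but shifts the position count:
a circle of circumference *C* offers *C* admissible starts, whereas the
model's denominator *GS* − ℓ(q) counts linear placements. The overlap
statistics on the circle therefore equal the linear model's at genome
size *C* + ℓ(q) exactly, and the expectation tests compare against that
equivalent size (at the scales tested the difference is ~1%, which is
systematic and would otherwise sit right at the edge of a 3-standard-
error band). The flip side is that the estimator applied to circular
simulations converges to *C* + ℓ(q) — a +0.1% bias at the
parameter-recovery scale, far inside its 5% band. Linear mode is
retained to demonstrate the edge-effect undershoot, which shrinks as
*GS*/ℓ grows.

## Expected range

Per-read estimates give a natural dispersion measure. The reported
range is the [L, L+50]th percentile interval of the defined estimates,
constrained to contain the median (L ≤ 50 ≤ L+50). The calibration scan
(`ovsize calibrate` / `calibrate_confidence_range`) sweeps L over a
grid and returns the value maximizing the fraction of samples whose
true size falls inside the interval; ties prefer the centered range
(L = 25 for width 50), then the smaller L. The shipped default of
15–65 reflects the right-skew of per-read estimates on real data
(counts in the denominator skew estimates upward); on the idealized
simulator battery the skew is mild and the scan typically returns the
centered range with full coverage. The range is an *expected range*,
not a formal confidence interval.

## Numerical choices

- Percentiles use linear interpolation between closest order
  statistics (numpy's default); at n ≥ 5 000 estimates, alternative
  quantile conventions differ by well under a percent.
- Undefined per-read estimates are a typed sentinel (`None`), never a
  float, so they cannot leak into quantiles.
- The overlap probability is clamped to [0, 1]; reads shorter than *OT*
  raise a domain error before estimation rather than producing a
  negative interval.
- ℓ̄_{T∖{q}} under `ava` is computed from a precomputed total length in
  O(1) per query as (Σℓ(t) − ℓ(q)) / (|T| − 1); under `2set` it is
  simply ℓ̄_T.
- Reservoir sampling (Algorithm R) draws one combined sample in a
  single pass, then shuffles and splits it into Q and T, so arbitrarily
  large files stream in constant memory and disjointness is guaranteed.
  Sampling is uniform over the whole file, not a prefix.
- Duplicate read ids are rejected outright: counting keys on ids.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run entirely on simulated
data at desk scale: oracle-equivalence over 50 instances of up to a few
hundred reads; the expectation check at 2 000 reads on a 100 kbp
circle; parameter recovery at |T| = 10 000, |Q| = 5 000 on a 1 Mbp
circle (20 replicates in the suite, 10 in the acceptance script); the
calibration battery on 100–200 samples of 20–60 kbp at ~10× coverage.
These sizes give standard errors comfortably below the asserted bands
while keeping a full run in tens of seconds.

## Known limitations

- Heterogeneous coverage (plasmid amplification, rRNA depth spikes) is
  an acknowledged failure mode, not corrected.
- No ploidy awareness; a diploid genome's size is estimated on the
  haploid-equivalent read pool the overlaps reflect.
- The aligner path inherits minimap2's sensitivity floor; overlaps near
  *OT* on noisy reads are under-detected, biasing estimates upward on
  low-quality runs.
- The percentile range is calibrated, not probabilistic; its coverage
  on data violating the uniformity assumptions is an empirical matter.
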