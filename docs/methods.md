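# Methods

## Coverage accounting

A paired-end fragment has outer insert size `2L + I`: two sequenced reads of
length `L` and an unsequenced inter-read gap `I` (negative if the reads
overlap). Sequence coverage counts sequenced bases, `N·L/G`; physical
(clonal) coverage counts fragments spanning a position. Two physical-coverage
conventions circulate and differ exactly by a factor of two:

* **read-based** `C = N·(2L+I)/G`, with `N` the number of aligned *reads* —
  each fragment counted once per read;
* **fragment-based** — one count per pair, `C_phys = C_seq·insert/(2L)`.

Published design numbers mix the two (power analyses are typically
fragment-based; per-lane coverage tables often read-based), so the package
exposes both as separately named functions and never silently defaults.
Reported coverages are rounded half away from zero, reproducing the familiar
design points 107× → 161× (300-bp insert, 2×100), 30× → 163× (900 bp,
2×83) and 12.57× → 38× (313.9 bp, 2×104, read-based).

## Detection power

A somatic event at fragment frequency `a` (purity/2 when heterozygous,
purity when homozygous) is detected when at least `t` of the `C` fragments
crossing the breakpoint derive from the variant allele:

    P(detect) = 1 − Σ_{k=0}^{t−1} C(C, k) a^k (1 − a)^(C − k)

`detection_power` evaluates this with the scipy binomial survival function;
the test suite checks it against direct pmf summation to 1e−12 over a
`C ≤ 200` grid. A Poisson-tail variant (`model="poisson"`, mean `C·a`) is
available for sensitivity analysis; it converges to the binomial for small
`a`. Non-integer coverages are rounded half away from zero because `C` is a
fragment count. `required_physical_coverage` inverts the model by
exponential bracketing plus bisection, exploiting monotonicity in `C`. The
support threshold `t` is always an explicit parameter (common operating
points are 8 and 10), never a hard-coded constant.

## Alignment records and normalisation

All downstream logic operates on whole fragments, so the I/O layer pairs SAM
records by query name and emits one record per primary pair; side *a* is the
lexicographically smaller `(chrom, pos)` end. "Insert size" is the outer
span (1-based inclusive, leftmost to rightmost mapped base), 0 exactly for
inter-chromosomal pairs. Coordinates are 1-based inclusive internally; BED
and BEDPE outputs convert to 0-based half-open. Records flagged as PCR
duplicates are excluded from every coverage and calling computation by
default (duplicate *detection* is upstream's job).

The insert-size "range" of a sample is the empirical 0.5–99.5% quantile
interval rather than min–max, which a single chimeric pair would destroy;
the quantiles are configurable, including strict min–max.

Downsampling to a fixed mapped-read budget selects whole pairs uniformly
without replacement (read-level selection would orphan mates and starve the
discordant-pair callers); the target is still expressed in reads, each pair
contributing two. The draw is a pure function of (input, seed), the output
count is exact, and a 1000-seed experiment in the test suite checks per-pair
inclusion frequencies against the binomial band (3.5σ per pair,
family-wise-adjusted across the 100 pairs tested).

## Simulator

The simulator emits mapped coordinates directly — no sequences, no aligner —
because the callers consume mapped positions only. Fragment left ends are
uniform over the genome (read depth assumed evenly distributed; no GC
model), inserts are normal(mean, sd) truncated below at `2L`, and the
fragment count per sample is `round(coverage · G / insert_mean)`. Defaults
describe a long-insert lane: 2×83 reads, 900 ± 64 bp inserts, 70× physical
coverage, purity 0.5.

Event semantics:

* A fragment crossing an event locus in the tumor carries the variant with
  probability `purity·0.5` (het) or `purity` (hom).
* Variant fragments spanning a **translocation** junction become discordant
  pairs, one read at each partner locus with the configured orientation. A
  junction landing inside a read would really produce a clipped read, not a
  cleanly mapped pair; such fragments are dropped (split-read evidence is
  out of scope), retaining a fraction ≈ `(insert − 2L)/insert` of crossing
  variant fragments — ≈ 0.82 at the defaults. Cross-validation tests
  account for this geometry.
* **Copy-number events** scale sampling density over their span by the
  mixture copy number `(2(1−purity) + purity·cn_tumor)/2`, with
  `cn_tumor = 2 + copy_change·(1 het, 2 hom)` floored at zero;
  `copy_change` is per-haplotype (het loss −1 ⇒ one lost copy; hom −1 at
  purity 1 ⇒ homozygous deletion, zero fragments starting inside the span).
  Deletions additionally emit junction fragments that jump the deleted
  interval, producing the long-spanning pairs measured by the boundary
  anomalous-pair ratio.

Because the per-sample fragment budget is fixed, removing density inside a
deletion redistributes it genome-wide; after per-sample mean normalisation
this biases the log2 ratio toward zero by `log2(G/W)` where `W` is the
density-weighted genome size. The validation experiments therefore keep
events to ≤ 2% of the simulated genome, where the bias is ≈ 0.01 — the same
consideration applies to real mean-normalised data when aneuploidy is
extensive. Events may not overlap (within one mean insert); overlapping
configurations are rejected.

What the simulator does *not* model — GC bias, mappability, duplicates,
base errors, clipped reads, subclonal structure beyond a single purity —
bounds what passing tests show: they validate the calling logic and its
statistics under the stated sampling model, not robustness to real-data
artefacts.

## Translocation calling

Windows are sized at `multiplier ×` the normal insert range (default 3),
floored at 1 kb to guard against degenerate near-constant profiles, and
tiled per chromosome. A pair is discordant evidence if inter-chromosomal,
or co-chromosomal with outer span above the normal `range_high` **and**
mates at least two windows apart — the ~0.5% insert-tail pairs by
construction exceed `range_high` but stay within adjacent windows, carry no
rearrangement information at window resolution, and would otherwise
chain-merge into spurious diagonal clusters.

Discordant pairs are grouped by their unordered window pair; groups adjacent
(≤ 1 window) on both sides merge, so support straddling a window boundary —
or arriving from the two reciprocal directions of one event — yields one
canonical call. Support is counted in pairs by default; `count_units="reads"`
doubles it for the reading of the thresholds in which each mate counts. Tiers:
primary ≥ 8, rescue ≥ 4 (rescue ≤ primary enforced). Any cluster linked by
one or more germline discordant pairs is removed outright; reported calls
are somatic with zero germline support. Per side the reported window is the
support-dominant one and the strand is the majority strand (ties → `+`).
Calls render as `strand:chrom:pos|strand:chrom:pos` breakpoint strings
(window starts, canonical side order, ASCII minus).

## CNV calling

Clonal coverage is the number of concordant fragments whose outer span
overlaps each window (2 kb tiling by default; a sliding step ≤ window is
supported), computed with a difference-array sweep and normalised by the
sample's genome-wide mean (enforced to 1 within 1e−9). Discordant pairs are
excluded from depth — they are junction evidence. The per-window statistic
is `log2((t+ε)/(n+ε))` with ε = 1e−6 of the normalised mean; windows with
zero normal depth are masked, and zero tumor depth is flagged `depth_zero`
rather than masked.

Segments are maximal same-sign runs with `|log2| ≥ 0.75` and at least 5
windows (10 kb) — run-merging only, no HMM or CBS, which is sufficient at
this operating point: a clonal single-copy loss sits at −1.0 and is called,
a 50%-purity heterozygous loss sits at `log2(0.75) = −0.415` and is
deliberately not. Segment `start`/`end` are window-start coordinates (end =
start of the window after the run) so `length = end − start` is a multiple
of the step; seeded 60× experiments recover the two mixture values within
±0.05. The boundary anomalous-pair ratio is, over pairs with a read within
one mean insert of either segment boundary, the anomalous fraction; zero
eligible pairs yield a missing value, not zero.

## DLRS

The derivative log ratio spread — `sd(point-to-point differences)/√2`, an
array-CGH noise measure — is computed after smoothing each chromosome with
a centred moving average (19 kb default, NaN-aware, width rounded to an odd
number of windows) and resampling one point per 80 kb (defaults follow
common array practice; both are configurable, and smoothing 0 disables).
Differences never span a chromosome boundary; the sample sd (ddof = 1) is
used. For i.i.d. Gaussian noise of sd σ the statistic recovers σ (the √2
removes the doubling of variance under differencing), verified to 5% at
10 000 points; it is invariant under constant shifts and insensitive to
genuine copy-number steps, which contribute single outlier differences.

## Validation experiments and problem sizes

`liwgs.benchmarks` packages the seeded end-to-end experiments used by both
the test suite and `scripts/acceptance.py`, at desk-scale problem sizes:
junction detection over 300–500 replicates of a 40-kb two-chromosome genome
at 160× (checked against the analytic power inside a 99% binomial band);
translocation recall and false-primary counts over 10–20 seeds of a 1-Mb
genome at 60×; CNV log2 recovery as the average over 6 seeds of a 150-kb
het loss in a 10-Mb genome at 60×; DLRS and downsampling closed-form
checks. Each experiment runs in seconds to ~1 minute on one CPU.

## Known limitations

* Breakpoints are resolved to windows (~1 kb), not bases; no split-read or
  assembly refinement, no inversion/duplication classification.
* Power entries reported for specific patient datasets are functions of the
  exact coverage accounting of those pipelines and are not reproduced here;
  the binomial tail is this package's documented, oracle-tested model.
* Mean normalisation assumes most of the genome is copy-neutral; highly
  aneuploid genomes compress all log2 ratios toward zero.
* The simulator's fidelity limits are listed above; in particular duplicate
  flags are honoured by the callers but never generated by the simulator.
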