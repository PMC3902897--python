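# liwgs

Design arithmetic, power modelling, simulation and somatic variant calling
for **long-insert whole-genome sequencing (LI-WGS)** tumor/normal studies.

Shallow WGS of long inserts (~900–1000 bp) buys *physical* coverage cheaply:
every DNA fragment spans its whole insert, including the unsequenced gap
between the two reads, so a breakpoint-crossing fragment is detectable as an
anomalous read pair even at low sequence coverage. This package implements
the computational side of that design end to end:

* **`liwgs.coverage_power`** — coverage conversions and detection power.
  With read length *L*, outer insert *2L + I* and genome size *G*,
  sequence coverage is *N·L/G* and physical coverage *N·(2L+I)/G* for *N*
  aligned reads. Both published accounting conventions are kept: the
  fragment-based conversion *C_phys = C_seq·insert/(2L)* and the read-based
  *C_phys = C_seq·insert/L*. Power to detect a somatic event present in a
  fraction *a* of fragments (*a* = purity/2 for a heterozygous event), with
  at least *t* supporting anomalous pairs out of *C* breakpoint-crossing
  fragments, is the binomial tail
  *P = 1 − Σₖ₌₀^{t−1} C(C,k)·aᵏ·(1−a)^{C−k}*.
* **`liwgs.alignment_io`** — read-pair records (SAM text or an internal TSV
  dialect), insert-size profiling, and seeded pair-preserving downsampling to
  an exact mapped-read target.
* **`liwgs.simulator`** — tumor/normal fragment simulation at configurable
  purity, insert distribution and physical coverage, with implanted
  translocations and copy-number events and a machine-readable truth list.
* **`liwgs.sv_caller`** — somatic translocation calling: windows sized at 3×
  the normal sample's insert-size range, clustering of discordant pairs by
  window pair, two support tiers (primary ≥ 8 pairs, rescue ≥ 4), and
  germline filtering.
* **`liwgs.cnv_caller`** — CNV segments from clonal-coverage log2 ratios in
  2-kb windows (|log2| ≥ 0.75), the boundary anomalous-pair ratio, and the
  DLRS noise statistic (sd of point-to-point differences / √2, 19-kb
  smoothing, 80-kb point spacing).

## Worked example

How much sequencing does a 50%-cellularity tumor need before a heterozygous
rearrangement is detectable with ten anomalous pairs at 0.99 power?

```sh
$ liwgs power --cellularity 0.5 --min-support 10 --target-power 0.99 \
      --read-length 83 --insert 900
a       min_support     seq_coverage    phys_coverage   power
0.2500  10      12.91   70      0.990061
```

The event frequency *a* is 0.25 (half the cellularity); 70 fragments must
cross the breakpoint, which a 900-bp-insert 2×83 library reaches at only
~13× sequence coverage.

A full simulated run — one clonal translocation t(1;2) and a 40-kb
heterozygous deletion at purity 1, 60× physical coverage on a 1-Mb toy
genome (`demo.yaml` below):

```sh
$ liwgs end2end --config demo.yaml --seed 1
{"coverage": 60.0, "genome_size": 1000000, "primary": 8, "purity": 1.0, "record": "run", "rescue": 4, "seed": 1, "window_size": 1000}
{"breakpoints": ["+:1:99001|-:1:140001", "+:1:249001|+:2:250001"], "calls": 2, "detected": 1, "false_calls": 0, "recall": 1.0, "record": "translocations", "truth": 1}
{"detected": 1, "log2": [-1.0377, -0.9781], "recall": 1.0, "record": "cnvs", "segments": 2, "truth": 1}
```

The translocation is recovered as the breakpoint pair
`+:1:249001|+:2:250001`; the deletion is seen twice, as a depth loss
(segments with log2 ≈ −1, i.e. one copy of two) and as an intra-chromosomal
discordant-pair cluster linking its two boundaries (`+:1:99001|-:1:140001`),
which the summary scores against the truth rather than as a false call.

```yaml
# demo.yaml
seed: 1
genome: {"1": 500000, "2": 500000}
read_length: 83
insert_mean: 900
insert_sd: 64
purity: 1.0
coverage: 60
events:
  - kind: translocation
    a: ["1", 250000]
    b: ["2", 250000]
    zygosity: hom
  - kind: cnv
    span: ["1", 100000, 140000]
    copy_change: -1
    zygosity: het
```

Other subcommands: `liwgs simulate`, `liwgs profile`, `liwgs downsample`,
`liwgs call-trl`, `liwgs call-cnv`, `liwgs dlrs` — see `--help` on each.

## Documentation

The model assumptions, parameter choices and known limitations are described
in [docs/methods.md](docs/methods.md).
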