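"""Tumor/normal read-pair simulator with implanted translocations and CNVs.

The simulator emits mapped fragment coordinates directly -- no sequence, no
aligner -- because the downstream callers operate purely on mapped positions.
A sample is a set of fragments whose left ends fall uniformly over the genome
(no GC model: depth is assumed evenly distributed), with outer insert lengths
drawn from a normal distribution truncated below at ``2 * read_length``.

The tumor sample is a mixture: a fraction ``purity`` of fragments derive from
tumor cells, and within tumor cells a heterozygous event sits on one of the
two haplotypes. Hence a fragment crossing an event locus carries the variant
with probability ``purity * 0.5`` (het) or ``purity`` (hom) -- the event
frequency ``a`` of the power model.

* Translocations: a variant fragment whose insert spans the junction is
  emitted as a discordant pair, one read at each partner locus with the
  orientation configured on the event. A junction falling *inside* a read
  (rather than in the inter-read gap or between the reads' spans) would in
  reality yield a clipped read, not a cleanly mapped discordant pair; such
  fragments are dropped rather than modelling clipping. With insert ``S`` and
  read length ``L`` this retains a fraction ``~ (S - 2L) / S`` of
  junction-crossing variant fragments.
* Copy-number events: fragment sampling density over the event span is scaled
  by the mixture copy number ``(2 (1 - purity) + purity * cn_tumor) / 2``
  where ``cn_tumor = 2 + copy_change * (1 for het, 2 for hom)``, floored at
  zero. ``copy_change`` is the per-haplotype change: a het loss of one copy is
  ``(copy_change=-1, het)``; a clonal homozygous deletion is
  ``(copy_change=-1, hom)`` at purity 1. Deletions additionally emit junction
  fragments: a variant fragment crossing the left boundary of the deleted span
  re-enters the reference at the right boundary, producing a long-spanning
  (anomalous) pair -- the signal read by the boundary anomalous-pair ratio.

The total fragment count per sample is fixed at
``round(target_phys_coverage * genome_size / insert_mean)`` regardless of
events, mirroring a fixed amount of sequencing; large deleted fractions
therefore slightly inflate coverage elsewhere, exactly as in a real
mean-normalised experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .alignment_io import InsertSizeProfile, ReadPairRecord
from .errors import ConfigError

__all__ = [
    "SvEvent",
    "SimulationConfig",
    "SimulationResult",
    "simulate_pair_set",
    "count_junction_discordant",
]


@dataclass(frozen=True)
class SvEvent:
    """An implanted somatic event (simulation truth).

    ``kind`` is ``"translocation"`` (junction joining ``breakpoint_a`` to
    ``breakpoint_b`` with per-side strands in ``orientation``) or ``"cnv"``
    (``span`` = (chrom, start, end), 1-based inclusive, with per-haplotype
    ``copy_change``).
    """

    kind: str
    breakpoint_a: tuple[str, int] | None = None
    breakpoint_b: tuple[str, int] | None = None
    span: tuple[str, int, int] | None = None
    copy_change: int = 0
    zygosity: str = "het"
    orientation: tuple[str, str] = ("+", "+")

    def __post_init__(self) -> None:
        if self.kind not in ("translocation", "cnv"):
            raise ConfigError(f"unknown event kind: {self.kind!r}")
        if self.zygosity not in ("het", "hom"):
            raise ConfigError(f"zygosity must be 'het' or 'hom', got {self.zygosity!r}")
        if self.kind == "translocation":
            if self.breakpoint_a is None or self.breakpoint_b is None:
                raise ConfigError("translocation events need breakpoint_a and breakpoint_b")
        else:
            if self.span is None:
                raise ConfigError("cnv events need a span")
            if self.span[1] >= self.span[2]:
                raise ConfigError("cnv span start must be < end")

    def variant_fraction(self, purity: float) -> float:
        """Probability that a tumor-sample fragment at this locus carries the variant."""
        return purity * (0.5 if self.zygosity == "het" else 1.0)

    def density_weight(self, purity: float) -> float:
        """Relative fragment-sampling density over a CNV span (diploid = 1)."""
        mult = 1 if self.zygosity == "het" else 2
        cn_tumor = max(0.0, 2.0 + self.copy_change * mult)
        return (2.0 * (1.0 - purity) + purity * cn_tumor) / 2.0


@dataclass
class SimulationConfig:
    """Study conditions for one simulated tumor/normal pair.

    Defaults describe a long-insert library normalised to one flowcell lane:
    2 x 83 reads, 900 +/- 64 bp inserts, 70x fragment-based physical coverage,
    50% tumor cellularity.
    """

    chrom_lengths: dict[str, int]
    read_length: int = 83
    insert_mean: float = 900.0
    insert_sd: float = 64.0
    purity: float = 0.5
    target_phys_coverage: float = 70.0
    events: list[SvEvent] = field(default_factory=list)
    seed: int = 0

    @property
    def genome_size(self) -> int:
        return sum(self.chrom_lengths.values())

    def validate(self) -> None:
        if not self.chrom_lengths:
            raise ConfigError("chrom_lengths must not be empty")
        for chrom, length in self.chrom_lengths.items():
            if length < 10 * self.insert_mean:
                raise ConfigError(
                    f"chromosome {chrom} ({length} bp) shorter than 10 x insert_mean"
                )
        if not 0.0 <= self.purity <= 1.0:
            raise ConfigError("purity must be in [0, 1]")
        if self.target_phys_coverage < 0:
            raise ConfigError("target_phys_coverage must be non-negative")
        self._check_event_geometry()

    def _check_event_geometry(self) -> None:
        # events must not interact: spans disjoint, breakpoints outside spans
        # and separated by at least one insert_mean
        margin = int(self.insert_mean)
        loci: list[tuple[str, int, int]] = []
        for ev in self.events:
            if ev.kind == "cnv":
                chrom, start, end = ev.span
                if chrom not in self.chrom_lengths:
                    raise ConfigError(f"cnv span on unknown chromosome {chrom!r}")
                loci.append((chrom, start - margin, end + margin))
            else:
                for chrom, pos in (ev.breakpoint_a, ev.breakpoint_b):
                    if chrom not in self.chrom_lengths:
                        raise ConfigError(f"breakpoint on unknown chromosome {chrom!r}")
                    loci.append((chrom, pos - margin, pos + margin))
        loci.sort()
        for (c1, s1, e1), (c2, s2, e2) in zip(loci, loci[1:]):
            if c1 == c2 and s2 <= e1:
                raise ConfigError("implanted events overlap (within one insert_mean); unsupported")


@dataclass
class SimulationResult:
    tumor: list[ReadPairRecord]
    normal: list[ReadPairRecord]
    truth: list[SvEvent]


def _weighted_intervals(
    config: SimulationConfig, purity: float
) -> list[tuple[str, int, int, float]]:
    """Partition the genome into (chrom, start, end, density-weight) pieces."""
    spans_by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for ev in config.events:
        if ev.kind == "cnv" and purity > 0:
            chrom, start, end = ev.span
            spans_by_chrom.setdefault(chrom, []).append((start, end, ev.density_weight(purity)))
    out: list[tuple[str, int, int, float]] = []
    for chrom, length in config.chrom_lengths.items():
        cursor = 1
        for start, end, w in sorted(spans_by_chrom.get(chrom, [])):
            if start > cursor:
                out.append((chrom, cursor, start - 1, 1.0))
            out.append((chrom, start, end, w))
            cursor = end + 1
        if cursor <= length:
            out.append((chrom, cursor, length, 1.0))
    return out


def _sample_sample(
    rng: np.random.Generator,
    config: SimulationConfig,
    sample: str,
    purity: float,
) -> list[ReadPairRecord]:
    n_frag = int(round(config.target_phys_coverage * config.genome_size / config.insert_mean))
    if n_frag == 0:
        return []
    L = config.read_length
    intervals = _weighted_intervals(config, purity)
    chroms = [iv[0] for iv in intervals]
    starts = np.array([iv[1] for iv in intervals], dtype=np.int64)
    lens = np.array([iv[2] - iv[1] + 1 for iv in intervals], dtype=np.int64)
    weights = np.array([iv[3] for iv in intervals], dtype=float)
    p = weights * lens
    total = p.sum()
    if total <= 0:
        raise ConfigError("all sampling weight removed by events")
    p /= total

    idx = rng.choice(len(intervals), size=n_frag, p=p)
    offs = np.floor(rng.random(n_frag) * lens[idx]).astype(np.int64)
    left = starts[idx] + offs
    ins = np.rint(rng.normal(config.insert_mean, config.insert_sd, n_frag)).astype(np.int64)
    ins = np.maximum(ins, 2 * L)  # truncate: no overlapping-pair geometry
    chrom_code = idx  # interval index; map to chrom later
    chrom_of = np.array([chroms[i] for i in range(len(intervals))])
    chrom_len = np.array([config.chrom_lengths[c] for c in chroms], dtype=np.int64)
    # keep fragments inside their chromosome
    left = np.minimum(left, chrom_len[chrom_code] - ins + 1)
    left = np.maximum(left, 1)

    # default: concordant forward/reverse pair on one chromosome
    frag_chrom = chrom_of[chrom_code]
    pos_a = left.copy()
    pos_b = left + ins - L
    chrom_b = frag_chrom.copy()
    strand_a = np.full(n_frag, "+", dtype="<U1")
    strand_b = np.full(n_frag, "-", dtype="<U1")
    insert_out = ins.copy()
    alive = np.ones(n_frag, dtype=bool)

    if purity > 0:
        # junction-crossing variant fragments at translocations and deletions
        u_variant = rng.random(n_frag)
        u_order_used = np.zeros(n_frag, dtype=bool)  # guard against double assignment
        for ev in config.events:
            v = ev.variant_fraction(purity)
            if v <= 0:
                continue
            if ev.kind == "translocation":
                (ca, pa), (cb, pb) = ev.breakpoint_a, ev.breakpoint_b
                cross = (frag_chrom == ca) & (left <= pa) & (left + ins - 1 >= pa + 1)
            elif ev.copy_change < 0:
                ca, s, e = ev.span
                pa, cb, pb = s - 1, ca, e + 1  # junction: base s-1 joined to base e+1
                cross = (frag_chrom == ca) & (left <= pa) & (left + ins - 1 >= pa + 1)
            else:
                continue
            cross &= alive & ~u_order_used
            variant = cross & (u_variant < v)
            u_order_used |= cross
            if not variant.any():
                continue
            d = pa - left[variant] + 1  # bases on the a side of the junction
            rem = ins[variant] - d
            ok = (d >= L) & (rem >= L)  # junction inside a read -> drop (clipped in reality)
            vi = np.flatnonzero(variant)
            alive[vi[~ok]] = False
            vi = vi[ok]
            rem = rem[ok]
            if ev.kind == "translocation":
                sa, sb = ev.orientation
                if sb == "+":
                    new_pos_b = pb + rem - L
                else:
                    new_pos_b = pb - rem + 1
                new_pos_b = np.maximum(new_pos_b, 1)
                chrom_b[vi] = cb
                pos_b[vi] = new_pos_b
                strand_a[vi] = sa
                strand_b[vi] = sb
                if cb == ca:
                    span = np.maximum(pos_b[vi] + L - 1, pos_a[vi] + L - 1) - np.minimum(
                        pos_a[vi], pos_b[vi]
                    ) + 1
                    insert_out[vi] = span
                else:
                    insert_out[vi] = 0
            else:
                # deletion junction: pair spans the deleted interval
                pos_b[vi] = pb + rem - L
                insert_out[vi] = pos_b[vi] + L - 1 - pos_a[vi] + 1

    keep = np.flatnonzero(alive)
    records: list[ReadPairRecord] = []
    append = records.append
    fc = frag_chrom
    for i in keep:
        ca, cb = fc[i], chrom_b[i]
        a, b = int(pos_a[i]), int(pos_b[i])
        sa, sb = strand_a[i], strand_b[i]
        if (ca, a) > (cb, b):
            ca, cb, a, b, sa, sb = cb, ca, b, a, sb, sa
        append(
            ReadPairRecord(
                fragment_id=f"{sample}:{i:08d}",
                sample=sample,
                chrom_a=ca,
                pos_a=a,
                strand_a=sa,
                chrom_b=cb,
                pos_b=b,
                strand_b=sb,
                mapq=60,
                insert_size=int(insert_out[i]),
                is_duplicate=False,
                is_mapped=True,
            )
        )
    return records


def simulate_pair_set(config: SimulationConfig) -> SimulationResult:
    """Simulate a tumor/normal fragment set and return it with the truth list.

    The normal sample carries no somatic events. Identical configs (including
    the seed) produce identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    normal = _sample_sample(rng, config, "normal", purity=0.0)
    tumor = _sample_sample(rng, config, "tumor", purity=config.purity)
    return SimulationResult(tumor=tumor, normal=normal, truth=list(config.events))


def count_junction_discordant(
    pairs: list[ReadPairRecord] | Iterator[ReadPairRecord],
    event: SvEvent,
    normal_profile: InsertSizeProfile,
) -> int:
    """Count discordant pairs whose mates flank a translocation junction.

    A pair counts when one read maps within one mean insert of
    ``breakpoint_a``, the other within one mean insert of ``breakpoint_b``,
    and the pair is anomalous (inter-chromosomal, or outer span beyond the
    normal insert range).
    """
    if event.kind != "translocation":
        raise ConfigError("count_junction_discordant expects a translocation event")
    (ca, pa), (cb, pb) = event.breakpoint_a, event.breakpoint_b
    w = normal_profile.mean
    hi = normal_profile.range_high
    n = 0
    for p in pairs:
        if not (p.is_interchromosomal or p.insert_size > hi):
            continue
        near_a1 = p.chrom_a == ca and abs(p.pos_a - pa) <= w
        near_b1 = p.chrom_b == cb and abs(p.pos_b - pb) <= w
        near_a2 = p.chrom_b == ca and abs(p.pos_b - pa) <= w
        near_b2 = p.chrom_a == cb and abs(p.pos_a - pb) <= w
        if (near_a1 and near_b1) or (near_a2 and near_b2):
            n += 1
    return n
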