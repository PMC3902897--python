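"""Seeded validation experiments linking the simulator, callers and models.

Each function runs the full pipeline -- simulate, profile, call, measure --
at a fixed study condition and returns the measured quantities. They back
both the acceptance-style tests and the reproduction script; problem sizes
are desk-scale (megabase genomes) so each experiment completes in seconds to
a couple of minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import alignment_io as aio
from . import cnv_caller as cnv
from . import simulator as sim
from . import sv_caller as svc

__all__ = [
    "junction_detection_successes",
    "sv_recall_experiment",
    "event_free_false_calls",
    "germline_filter_removes_call",
    "cnv_recovery_experiment",
    "downsample_inclusion_frequencies",
]


def _seed(base: int, offset: int, i: int) -> int:
    return (base * 1009 + offset * 101 + i) % (2**31 - 1)


def junction_detection_successes(
    n_reps: int,
    base_seed: int,
    *,
    purity: float = 0.5,
    coverage: float = 160.0,
    min_support: int = 10,
) -> int:
    """Replicates of a heterozygous junction; counts replicates with at least
    ``min_support`` discordant pairs flanking the breakpoints.

    The empirical success fraction is the quantity the binomial power model
    predicts as ``detection_power(purity / 2, coverage, min_support)`` (up to
    the clipped-fragment geometry the simulator applies).
    """
    event = sim.SvEvent(
        kind="translocation",
        breakpoint_a=("1", 10_000),
        breakpoint_b=("2", 10_000),
        zygosity="het",
    )
    successes = 0
    for i in range(n_reps):
        cfg = sim.SimulationConfig(
            chrom_lengths={"1": 20_000, "2": 20_000},
            purity=purity,
            target_phys_coverage=coverage,
            events=[event],
            seed=_seed(base_seed, 1, i),
        )
        res = sim.simulate_pair_set(cfg)
        prof = aio.insert_profile(res.normal)
        if sim.count_junction_discordant(res.tumor, event, prof) >= min_support:
            successes += 1
    return successes


@dataclass
class SvRecallResult:
    n_seeds: int
    detected: int
    false_primary_calls: int

    @property
    def recall(self) -> float:
        return self.detected / self.n_seeds


def _trl_scenario(seed: int, purity: float, coverage: float):
    event = sim.SvEvent(
        kind="translocation",
        breakpoint_a=("1", 250_000),
        breakpoint_b=("2", 250_000),
        zygosity="hom",
    )
    cfg = sim.SimulationConfig(
        chrom_lengths={"1": 500_000, "2": 500_000},
        purity=purity,
        target_phys_coverage=coverage,
        events=[event],
        seed=seed,
    )
    return cfg, event


def sv_recall_experiment(
    n_seeds: int,
    base_seed: int,
    *,
    purity: float = 1.0,
    coverage: float = 60.0,
) -> SvRecallResult:
    """Recall of one implanted homozygous translocation per seeded replicate,
    and the number of primary-tier calls not matching the truth."""
    detected = 0
    false_calls = 0
    for i in range(n_seeds):
        cfg, event = _trl_scenario(_seed(base_seed, 2, i), purity, coverage)
        res = sim.simulate_pair_set(cfg)
        prof = aio.insert_profile(res.normal)
        calls = svc.call_translocations(res.tumor, res.normal, prof, genome=cfg.chrom_lengths)
        w = svc.window_size_from_profile(prof)
        matching = [c for c in calls if _matches(c, event, w)]
        if any(c.tier == "primary" for c in matching):
            detected += 1
        false_calls += sum(1 for c in calls if c.tier == "primary" and not _matches(c, event, w))
    return SvRecallResult(n_seeds=n_seeds, detected=detected, false_primary_calls=false_calls)


def _matches(call: svc.TranslocationCall, event: sim.SvEvent, w: int) -> bool:
    (ca, pa), (cb, pb) = event.breakpoint_a, event.breakpoint_b

    def near(window, chrom, pos):
        return window[0] == chrom and window[1] - w <= pos <= window[2] + w

    return (near(call.window_a, ca, pa) and near(call.window_b, cb, pb)) or (
        near(call.window_a, cb, pb) and near(call.window_b, ca, pa)
    )


def event_free_false_calls(
    n_seeds: int,
    base_seed: int,
    *,
    purity: float = 0.5,
    coverage: float = 70.0,
) -> int:
    """Primary-tier somatic calls on event-free tumor/normal simulations."""
    total = 0
    for i in range(n_seeds):
        cfg = sim.SimulationConfig(
            chrom_lengths={"1": 500_000, "2": 500_000},
            purity=purity,
            target_phys_coverage=coverage,
            events=[],
            seed=_seed(base_seed, 3, i),
        )
        res = sim.simulate_pair_set(cfg)
        prof = aio.insert_profile(res.normal)
        calls = svc.call_translocations(res.tumor, res.normal, prof, genome=cfg.chrom_lengths)
        total += sum(1 for c in calls if c.tier == "primary")
    return total


def germline_filter_removes_call(base_seed: int) -> bool:
    """True when one germline pair linking a called window pair removes the
    otherwise-identical somatic call."""
    cfg, event = _trl_scenario(_seed(base_seed, 4, 0), purity=1.0, coverage=60.0)
    res = sim.simulate_pair_set(cfg)
    prof = aio.insert_profile(res.normal)
    calls = svc.call_translocations(res.tumor, res.normal, prof, genome=cfg.chrom_lengths)
    if len(calls) != 1:
        return False
    c = calls[0]
    linking = aio.ReadPairRecord(
        fragment_id="germ",
        sample="normal",
        chrom_a=c.window_a[0],
        pos_a=(c.window_a[1] + c.window_a[2]) // 2,
        strand_a="+",
        chrom_b=c.window_b[0],
        pos_b=(c.window_b[1] + c.window_b[2]) // 2,
        strand_b="+",
        insert_size=0,
    )
    filtered = svc.call_translocations(
        res.tumor, list(res.normal) + [linking], prof, genome=cfg.chrom_lengths
    )
    return not any(_same_windows(f, c) for f in filtered)


def _same_windows(a: svc.TranslocationCall, b: svc.TranslocationCall) -> bool:
    return {a.window_a, a.window_b} == {b.window_a, b.window_b}


@dataclass
class CnvRecoveryResult:
    mean_log2: float
    loss_called: bool  # any loss segment overlapping the implanted span
    n_segments: int  # all segments genome-wide, summed over replicates


def cnv_recovery_experiment(
    purity: float,
    base_seed: int,
    *,
    n_seeds: int = 6,
    coverage: float = 60.0,
    genome_size: int = 10_000_000,
    span: tuple[int, int] = (4_000_000, 4_150_000),
    threshold: float = 0.75,
    min_windows: int = 5,
) -> CnvRecoveryResult:
    """Heterozygous single-copy loss at the given purity; measures the mean
    log2 ratio over windows inside the implanted span (one insert of margin
    from each boundary) and whether the 0.75 threshold calls it.

    Expected log2 is ``log2(1 - purity/2)``: -1.0 for a clonal loss, -0.415
    at 50% purity. A single replicate's span mean carries ~0.03 of sampling
    noise at these sizes, so the default averages six replicates.
    """
    event = sim.SvEvent(
        kind="cnv", span=("1", span[0], span[1]), copy_change=-1, zygosity="het"
    )
    means = []
    called = False
    n_segments = 0
    for i in range(n_seeds):
        cfg = sim.SimulationConfig(
            chrom_lengths={"1": genome_size},
            purity=purity,
            target_phys_coverage=coverage,
            events=[event],
            seed=_seed(base_seed, 5, i),
        )
        res = sim.simulate_pair_set(cfg)
        prof = aio.insert_profile(res.normal)
        tt = cnv.clonal_coverage_track(res.tumor, cfg.chrom_lengths, max_span=prof.range_high)
        nt = cnv.clonal_coverage_track(res.normal, cfg.chrom_lengths, max_span=prof.range_high)
        ratio = cnv.log2_ratio_track(tt, nt)
        track = ratio["1"]
        margin = int(cfg.insert_mean)
        lo = -(-(span[0] + margin - 1) // track.step)  # first window start >= span lo + margin
        hi = (span[1] - margin - track.window_size) // track.step  # last window end <= span hi - margin
        means.append(float(np.nanmean(track.log2[lo : hi + 1])))
        segments = cnv.call_cnv_segments(ratio, threshold, min_windows)
        n_segments += len(segments)
        called = called or any(
            s.direction == "loss" and s.start <= span[1] and s.end >= span[0] for s in segments
        )
    return CnvRecoveryResult(
        mean_log2=float(np.mean(means)), loss_called=called, n_segments=n_segments
    )


def downsample_inclusion_frequencies(
    base_seed: int,
    *,
    n_pairs: int = 100,
    target_reads: int = 50,
    n_seeds: int = 1000,
) -> np.ndarray:
    """Per-pair inclusion frequency over seeded downsampling draws; uniform
    selection makes each frequency concentrate at target/(2 n_pairs)."""
    pairs = [
        aio.ReadPairRecord(
            fragment_id=str(i),
            sample="s",
            chrom_a="1",
            pos_a=1000 + i,
            strand_a="+",
            chrom_b="1",
            pos_b=1800 + i,
            strand_b="-",
            insert_size=900,
        )
        for i in range(n_pairs)
    ]
    counts = np.zeros(n_pairs)
    for i in range(n_seeds):
        kept = aio.downsample(pairs, target_reads, seed=_seed(base_seed, 6, i))
        for rec in kept:
            counts[int(rec.fragment_id)] += 1
    return counts / n_seeds
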