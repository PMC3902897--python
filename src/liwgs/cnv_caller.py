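"""Copy-number calling from clonal-coverage log2 ratios, plus DLRS.

Depth is measured as *clonal* (physical) coverage: the number of concordant
fragments whose outer span overlaps each 2-kb window, mean-normalised per
sample so tumor and normal are comparable regardless of sequencing depth. The
per-window statistic is ``log2(tumor / normal)`` of the normalised values; a
CNV segment is a maximal run of consecutive same-sign windows with
``|log2| >= threshold`` (default 0.75). Simple run-merging is used rather
than an HMM or CBS: with a 0.75 threshold a clonal single-copy loss
(log2 = -1) is called while a 50%-purity heterozygous loss (log2 ~ -0.415)
is not, which is the intended operating point.

Segment coordinates follow the convention ``start`` = first window start,
``end`` = last window start + window size, so ``length = end - start`` is a
multiple of the window step.

DLRS (derivative log ratio spread), borrowed from array CGH quality control,
is the standard deviation of point-to-point differences of the log2 track
divided by sqrt(2) -- an estimate of per-point noise that is insensitive to
true copy-number structure. The track is smoothed with a centred moving
average (default 19 kb) and resampled (default one point per 80 kb) before
differencing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alignment_io import InsertSizeProfile, ReadPairRecord
from .annotate import GeneIndex, split_flagged
from .errors import EmptyTrackError, InsufficientDataError, ValidationError

__all__ = [
    "CoverageTrack",
    "RatioTrack",
    "CnvSegment",
    "DlrsResult",
    "clonal_coverage_track",
    "log2_ratio_track",
    "call_cnv_segments",
    "boundary_anomalous_ratio",
    "dlrs",
    "annotate_genes",
]


def n_windows(chrom_length: int, step: int) -> int:
    """Number of tiled windows starting at 1, 1+step, ... within a chromosome."""
    return (chrom_length - 1) // step + 1


@dataclass
class CoverageTrack:
    """Per-window clonal coverage for one chromosome.

    ``raw`` counts fragments overlapping each window; ``values`` is ``raw``
    divided by the genome-wide mean raw count of the sample (so the mean of
    ``values`` across the whole sample is 1).
    """

    chrom: str
    window_size: int
    step: int
    raw: np.ndarray
    values: np.ndarray


@dataclass
class RatioTrack:
    """Per-window log2 tumor/normal ratio; NaN where the normal has no depth."""

    chrom: str
    window_size: int
    step: int
    log2: np.ndarray
    depth_zero: np.ndarray  # tumor raw == 0 (large negative log2 via pseudo-count)


@dataclass(frozen=True)
class CnvSegment:
    """A contiguous run of same-sign supra-threshold windows."""

    chrom: str
    start: int
    end: int
    direction: str  # "gain" | "loss"
    log2_ratio: float
    n_windows: int
    boundary_anomalous_ratio: float | None = None
    depth_zero: bool = False
    genes: tuple[str, ...] = ()
    flagged_genes: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DlrsResult:
    value: float
    n_points: int
    point_spacing: int
    smoothing_window: int


def clonal_coverage_track(
    pairs: Iterable[ReadPairRecord],
    genome: Mapping[str, int],
    window_size: int = 2000,
    step: int | None = None,
    max_span: float | None = None,
) -> dict[str, CoverageTrack]:
    """Count fragments overlapping sliding windows and mean-normalise.

    Only co-chromosomal mapped pairs contribute; pairs with outer span above
    ``max_span`` (typically the normal insert range high) are excluded --
    discordant pairs are breakpoint evidence, not depth. Normalisation uses
    the genome-wide mean raw count across all chromosomes of the sample.
    """
    if window_size <= 0:
        raise ValidationError("window_size must be positive")
    step = step or window_size
    if step > window_size:
        raise ValidationError("step must not exceed window_size")
    counts = {
        chrom: np.zeros(n_windows(length, step) + 1, dtype=np.int64)
        for chrom, length in genome.items()
    }
    total = 0
    for p in pairs:
        if not p.is_mapped or p.is_duplicate or p.is_interchromosomal or p.insert_size <= 0:
            continue
        if max_span is not None and p.insert_size > max_span:
            continue
        diff = counts.get(p.chrom_a)
        if diff is None:
            continue
        left = p.pos_a
        right = p.pos_a + p.insert_size - 1
        nw = diff.size - 1
        w_lo = max(0, -(-(left - window_size) // step))  # ceil division
        w_hi = min(nw - 1, (right - 1) // step)
        if w_lo > w_hi:
            continue
        diff[w_lo] += 1
        diff[w_hi + 1] -= 1
        total += 1
    if total == 0:
        raise EmptyTrackError("no concordant fragments; cannot build coverage track")
    raw = {chrom: np.cumsum(diff[:-1]) for chrom, diff in counts.items()}
    mean_raw = sum(r.sum() for r in raw.values()) / sum(r.size for r in raw.values())
    return {
        chrom: CoverageTrack(
            chrom=chrom,
            window_size=window_size,
            step=step,
            raw=r,
            values=r / mean_raw,
        )
        for chrom, r in raw.items()
    }


def log2_ratio_track(
    tumor: Mapping[str, CoverageTrack],
    normal: Mapping[str, CoverageTrack],
    pseudo: float = 1e-6,
) -> dict[str, RatioTrack]:
    """Per-window ``log2((tumor + pseudo) / (normal + pseudo))`` on normalised
    values; windows where the normal has zero raw depth are masked (NaN).

    The pseudo-count (default 1e-6 of the normalised mean of 1) keeps
    homozygous-deletion windows finite; they are flagged via ``depth_zero``.
    """
    if set(tumor) != set(normal):
        raise ValidationError("tumor and normal tracks cover different chromosomes")
    out: dict[str, RatioTrack] = {}
    for chrom in tumor:
        t, n = tumor[chrom], normal[chrom]
        if t.window_size != n.window_size or t.step != n.step or t.raw.size != n.raw.size:
            raise ValidationError(f"window grid mismatch on chromosome {chrom}")
        with np.errstate(divide="ignore"):
            ratio = np.log2((t.values + pseudo) / (n.values + pseudo))
        ratio[n.raw == 0] = np.nan
        out[chrom] = RatioTrack(
            chrom=chrom,
            window_size=t.window_size,
            step=t.step,
            log2=ratio,
            depth_zero=t.raw == 0,
        )
    return out


def call_cnv_segments(
    ratio_tracks: Mapping[str, RatioTrack],
    threshold: float = 0.75,
    min_windows: int = 5,
) -> list[CnvSegment]:
    """Maximal runs of consecutive windows with ``|log2| >= threshold`` and a
    common sign, at least ``min_windows`` long; reported with the mean log2
    over the run."""
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    segments: list[CnvSegment] = []
    for chrom, track in ratio_tracks.items():
        x = track.log2
        sign = np.zeros(x.size, dtype=np.int8)
        with np.errstate(invalid="ignore"):
            sign[x >= threshold] = 1
            sign[x <= -threshold] = -1
        i = 0
        while i < sign.size:
            if sign[i] == 0:
                i += 1
                continue
            j = i
            while j + 1 < sign.size and sign[j + 1] == sign[i]:
                j += 1
            if j - i + 1 >= min_windows:
                # start/end are window-start positions (end = start of the
                # window following the run), so length = end - start
                start = i * track.step + 1
                end = j * track.step + track.window_size + 1
                segments.append(
                    CnvSegment(
                        chrom=chrom,
                        start=start,
                        end=end,
                        direction="gain" if sign[i] > 0 else "loss",
                        log2_ratio=float(np.nanmean(x[i : j + 1])),
                        n_windows=j - i + 1,
                        depth_zero=bool(track.depth_zero[i : j + 1].any()),
                    )
                )
            i = j + 1
    segments.sort(key=lambda s: (s.chrom, s.start))
    return segments


def boundary_anomalous_ratio(
    segment: CnvSegment,
    tumor_pairs: Iterable[ReadPairRecord],
    normal_profile: InsertSizeProfile,
    flank: float | None = None,
) -> float | None:
    """Fraction of anomalous pairs among all pairs with a read within
    ``flank`` (default: mean insert) of either segment boundary.

    Returns None when no pair marks the boundary -- an absent measurement, not
    a zero.
    """
    flank = normal_profile.mean if flank is None else flank
    if flank <= 0:
        raise ValidationError("flank must be positive")
    hi = normal_profile.range_high
    total = 0
    anomalous = 0
    for p in tumor_pairs:
        if not p.is_mapped or p.is_duplicate:
            continue
        near = (
            (p.chrom_a == segment.chrom and min(abs(p.pos_a - segment.start), abs(p.pos_a - segment.end)) <= flank)
            or (p.chrom_b == segment.chrom and min(abs(p.pos_b - segment.start), abs(p.pos_b - segment.end)) <= flank)
        )
        if not near:
            continue
        total += 1
        if p.is_interchromosomal or p.insert_size > hi:
            anomalous += 1
    if total == 0:
        return None
    return anomalous / total


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centred moving average that ignores NaNs (window shrinks at edges)."""
    if width <= 1:
        return x
    mask = np.isfinite(x)
    filled = np.where(mask, x, 0.0)
    kernel = np.ones(width)
    num = np.convolve(filled, kernel, mode="same")
    den = np.convolve(mask.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def dlrs(
    ratio_tracks: Mapping[str, RatioTrack] | RatioTrack,
    point_spacing: int = 80_000,
    smoothing_window: int = 19_000,
) -> DlrsResult:
    """Derivative log ratio spread of a log2 track.

    Each chromosome's track is smoothed by a centred moving average of width
    ``smoothing_window`` (0 disables smoothing), resampled at one point per
    ``point_spacing``, and successive within-chromosome differences are
    pooled; the result is their sample standard deviation divided by sqrt(2).
    """
    if isinstance(ratio_tracks, RatioTrack):
        ratio_tracks = {ratio_tracks.chrom: ratio_tracks}
    diffs: list[np.ndarray] = []
    total_points = 0
    for track in ratio_tracks.values():
        stride = max(1, int(round(point_spacing / track.step)))
        width = int(round(smoothing_window / track.step)) if smoothing_window else 0
        if width % 2 == 0 and width > 0:
            width -= 1  # centred average needs odd width
        smoothed = _moving_average(track.log2, width) if width > 1 else track.log2
        points = smoothed[::stride]
        points = points[np.isfinite(points)]
        total_points += points.size
        if points.size >= 2:
            diffs.append(np.diff(points))
    if total_points < 3 or not diffs:
        raise InsufficientDataError("DLRS requires at least 3 resampled points")
    d = np.concatenate(diffs)
    if d.size < 2:
        raise InsufficientDataError("DLRS requires at least 2 point-to-point differences")
    return DlrsResult(
        value=float(np.std(d, ddof=1) / math.sqrt(2.0)),
        n_points=int(total_points),
        point_spacing=point_spacing,
        smoothing_window=smoothing_window,
    )


def annotate_genes(
    segments: Sequence[CnvSegment],
    genes: str | Path | Iterable[tuple[str, int, int, str]],
    flag_list: set[str] | None = None,
) -> list[CnvSegment]:
    """Attach gene names overlapping each segment span; genes in ``flag_list``
    are additionally flagged."""
    index = GeneIndex.from_bed(genes) if isinstance(genes, (str, Path)) else GeneIndex(genes)
    out = []
    for seg in segments:
        hit = index.overlapping(seg.chrom, seg.start, seg.end - 1)
        out.append(replace(seg, genes=tuple(hit), flagged_genes=split_flagged(hit, flag_list)))
    return out
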