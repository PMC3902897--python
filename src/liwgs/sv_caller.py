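"""Somatic translocation calling from discordant read-pair clusters.

The tumor genome is tiled with windows sized from the *normal* sample's
insert-size distribution (default 3x the empirical insert range, floored at
1 kb). A pair is discordant evidence when its mates map to different
chromosomes, or to the same chromosome with an outer span beyond the normal
range and at least two windows apart (short over-long pairs that stay within
adjacent windows are insert-size tail, not rearrangement evidence, and cannot
be resolved at window granularity anyway).

Discordant pairs are grouped by the unordered pair of windows their two reads
fall in; groups whose windows are adjacent on both sides are merged into one
cluster, so a junction whose support straddles a window boundary is still one
call (and the two reciprocal directions of one event canonicalise to a single
call). Clusters reaching the primary support threshold (default 8 pairs) are
tier ``primary``; those reaching the rescue threshold (default 4) are tier
``rescue``. Any cluster linked by even one germline discordant pair is
removed: reported calls are somatic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from collections import Counter, defaultdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .alignment_io import InsertSizeProfile, ReadPairRecord
from .annotate import GeneIndex, split_flagged
from .errors import ConfigError, ValidationError

__all__ = [
    "TranslocationCall",
    "window_size_from_profile",
    "make_windows",
    "call_translocations",
    "format_breakpoint",
    "annotate_genes",
]

WINDOW_FLOOR = 1000  # bp; guards against degenerate near-constant insert profiles


@dataclass(frozen=True)
class TranslocationCall:
    """A clustered pair of discordant windows (1-based inclusive bounds)."""

    window_a: tuple[str, int, int]
    window_b: tuple[str, int, int]
    strand_a: str
    strand_b: str
    n_tumor_support: int
    n_germline_support: int
    tier: str
    genes: tuple[str, ...] = ()
    flagged_genes: tuple[str, ...] = ()


def window_size_from_profile(
    profile: InsertSizeProfile, multiplier: float = 3.0, floor: int = WINDOW_FLOOR
) -> int:
    """Window size = multiplier x (insert-size range of the normal data)."""
    if multiplier <= 0:
        raise ValidationError("multiplier must be positive")
    width = profile.range_width
    size = int(round(multiplier * width))
    if width == 0:
        warnings.warn("degenerate insert profile (zero range); using floor window size", stacklevel=2)
    return max(size, floor)


def make_windows(
    genome: Mapping[str, int],
    normal_profile: InsertSizeProfile,
    multiplier: float = 3.0,
    floor: int = WINDOW_FLOOR,
) -> list[tuple[str, int, int]]:
    """Non-overlapping tiling windows over the genome; the last window of each
    chromosome is truncated at the chromosome end."""
    size = window_size_from_profile(normal_profile, multiplier, floor)
    windows: list[tuple[str, int, int]] = []
    for chrom, length in genome.items():
        start = 1
        while start <= length:
            windows.append((chrom, start, min(start + size - 1, length)))
            start += size
    return windows


def _is_discordant(rec: ReadPairRecord, range_high: float, wsize: int) -> bool:
    if rec.is_interchromosomal:
        return True
    if rec.insert_size <= range_high:
        return False
    idx_a = (rec.pos_a - 1) // wsize
    idx_b = (rec.pos_b - 1) // wsize
    return abs(idx_b - idx_a) >= 2


def _cluster_key(rec: ReadPairRecord, wsize: int):
    a = (rec.chrom_a, (rec.pos_a - 1) // wsize, rec.strand_a)
    b = (rec.chrom_b, (rec.pos_b - 1) // wsize, rec.strand_b)
    if (a[0], a[1]) > (b[0], b[1]):
        a, b = b, a
    return a, b


def _merge_adjacent(groups: dict) -> list[list]:
    """Union groups whose windows are adjacent (<= 1 apart) on both sides."""
    keys = sorted(groups)
    parent = {k: k for k in keys}

    def find(k):
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    by_chrompair = defaultdict(list)
    for k in keys:
        (ca, ia, _sa), (cb, ib, _sb) = k
        by_chrompair[(ca, cb)].append(k)
    for ks in by_chrompair.values():
        ks.sort(key=lambda k: (k[0][1], k[1][1]))
        for i, k1 in enumerate(ks):
            for k2 in ks[i + 1 :]:
                if k2[0][1] - k1[0][1] > 1:
                    break
                if abs(k2[1][1] - k1[1][1]) <= 1:
                    r1, r2 = find(k1), find(k2)
                    if r1 != r2:
                        parent[r2] = r1
    clusters = defaultdict(list)
    for k in keys:
        clusters[find(k)].append(k)
    return list(clusters.values())


def call_translocations(
    tumor: Iterable[ReadPairRecord],
    normal: Iterable[ReadPairRecord],
    normal_profile: InsertSizeProfile,
    *,
    genome: Mapping[str, int],
    primary: int = 8,
    rescue: int = 4,
    multiplier: float = 3.0,
    floor: int = WINDOW_FLOOR,
    count_units: str = "pairs",
) -> list[TranslocationCall]:
    """Cluster discordant tumor pairs into somatic translocation calls.

    ``primary``/``rescue`` are the two support tiers; support is counted in
    pairs by default (``count_units="reads"`` doubles each pair's
    contribution, for the reading of the thresholds in which each mate counts
    separately). Clusters with any linking germline pair are removed. Each
    retained cluster is reported once with ``window_a`` the lexicographically
    smaller side.
    """
    if rescue > primary:
        raise ConfigError("rescue threshold must not exceed primary threshold")
    if count_units not in ("pairs", "reads"):
        raise ValidationError("count_units must be 'pairs' or 'reads'")
    unit = 1 if count_units == "pairs" else 2
    wsize = window_size_from_profile(normal_profile, multiplier, floor)
    hi = normal_profile.range_high

    tumor_groups: dict = defaultdict(list)
    for rec in tumor:
        if not rec.is_mapped or rec.is_duplicate:
            continue
        if _is_discordant(rec, hi, wsize):
            tumor_groups[_cluster_key(rec, wsize)].append(rec)
    if not tumor_groups:
        return []
    germline_keys: Counter = Counter()
    for rec in normal:
        if not rec.is_mapped or rec.is_duplicate:
            continue
        if _is_discordant(rec, hi, wsize):
            germline_keys[_cluster_key(rec, wsize)] += 1

    calls: list[TranslocationCall] = []
    for cluster in _merge_adjacent(tumor_groups):
        support_recs = [r for k in cluster for r in tumor_groups[k]]
        n_support = len(support_recs) * unit
        if n_support < rescue:
            continue
        n_germ = sum(
            cnt
            for gk, cnt in germline_keys.items()
            if any(_keys_adjacent(gk, tk) for tk in cluster)
        ) * unit
        if n_germ > 0:
            continue  # germline-supported: not somatic
        # dominant window per side; majority strand, ties -> '+'
        side_a = Counter((r.chrom_a, (r.pos_a - 1) // wsize) for r in support_recs)
        side_b = Counter((r.chrom_b, (r.pos_b - 1) // wsize) for r in support_recs)
        (ca, ia), _ = side_a.most_common(1)[0]
        (cb, ib), _ = side_b.most_common(1)[0]
        sa = _majority([r.strand_a for r in support_recs])
        sb = _majority([r.strand_b for r in support_recs])
        wa = (ca, ia * wsize + 1, min((ia + 1) * wsize, genome[ca]))
        wb = (cb, ib * wsize + 1, min((ib + 1) * wsize, genome[cb]))
        if (wa[0], wa[1]) > (wb[0], wb[1]):
            wa, wb, sa, sb = wb, wa, sb, sa
        calls.append(
            TranslocationCall(
                window_a=wa,
                window_b=wb,
                strand_a=sa,
                strand_b=sb,
                n_tumor_support=n_support,
                n_germline_support=0,
                tier="primary" if n_support >= primary else "rescue",
            )
        )
    calls.sort(key=lambda c: (c.window_a, c.window_b))
    return calls


def _keys_adjacent(k1, k2) -> bool:
    (c1a, i1a, _), (c1b, i1b, _) = k1
    (c2a, i2a, _), (c2b, i2b, _) = k2
    return c1a == c2a and c1b == c2b and abs(i1a - i2a) <= 1 and abs(i1b - i2b) <= 1


def _majority(strands: Sequence[str]) -> str:
    plus = sum(1 for s in strands if s == "+")
    return "+" if plus >= len(strands) - plus else "-"


def format_breakpoint(call: TranslocationCall) -> str:
    """Render a call as ``strand:chrom:pos|strand:chrom:pos`` with ``pos`` the
    window start of each side (canonical side order, ASCII minus)."""
    a = (call.window_a, call.strand_a)
    b = (call.window_b, call.strand_b)
    if (a[0][0], a[0][1]) > (b[0][0], b[0][1]):
        a, b = b, a
    return "|".join(f"{strand}:{w[0]}:{w[1]}" for w, strand in (a, b))


def annotate_genes(
    calls: Sequence[TranslocationCall],
    genes: str | Path | Iterable[tuple[str, int, int, str]],
    flag_list: set[str] | None = None,
) -> list[TranslocationCall]:
    """Attach gene names overlapping either window of each call; genes in
    ``flag_list`` (e.g. a COSMIC census) are additionally flagged."""
    index = GeneIndex.from_bed(genes) if isinstance(genes, (str, Path)) else GeneIndex(genes)
    out = []
    for call in calls:
        hit = sorted(
            set(index.overlapping(*call.window_a)) | set(index.overlapping(*call.window_b))
        )
        out.append(
            replace(call, genes=tuple(hit), flagged_genes=split_flagged(hit, flag_list))
        )
    return out
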