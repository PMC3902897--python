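"""Paired-end alignment I/O, insert-size profiling and seeded downsampling.

Records are whole fragments (read pairs), not individual reads: all downstream
logic -- discordant-pair clustering, clonal-coverage depth, boundary ratios --
needs both mates. Two on-disk dialects are supported:

* SAM text (read and written through :mod:`pysam`); pairing is reconstructed
  by query name, secondary/supplementary/unmapped records are skipped;
* an internal tab-separated dialect with one fragment per line, mirroring
  :class:`ReadPairRecord` (lossless round-trip, convenient for fixtures).

Coordinates are 1-based inclusive throughout (SAM convention). "Insert size"
is the outer fragment span, leftmost mapped base to rightmost mapped base,
equal to ``2L + I`` for a concordant pair; it is 0 exactly when the mates map
to different chromosomes.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pysam

from .errors import EmptyProfileError, InfeasibleError, ParseError, ValidationError

__all__ = [
    "ReadPairRecord",
    "InsertSizeProfile",
    "read_pairs",
    "write_pairs",
    "insert_profile",
    "downsample",
]

_TSV_COLUMNS = (
    "fragment_id",
    "sample",
    "chrom_a",
    "pos_a",
    "strand_a",
    "chrom_b",
    "pos_b",
    "strand_b",
    "mapq",
    "insert_size",
    "is_duplicate",
    "is_mapped",
)


@dataclass(slots=True)
class ReadPairRecord:
    """One aligned fragment: the two primary alignments of a read pair.

    Side *a* is the lexicographically smaller ``(chrom, pos)`` end so that a
    fragment has one canonical representation. ``insert_size`` is the outer
    span in bases (0 for inter-chromosomal pairs).
    """

    fragment_id: str
    sample: str
    chrom_a: str
    pos_a: int
    strand_a: str
    chrom_b: str
    pos_b: int
    strand_b: str
    mapq: int = 60
    insert_size: int = 0
    is_duplicate: bool = False
    is_mapped: bool = True

    @property
    def is_interchromosomal(self) -> bool:
        return self.chrom_a != self.chrom_b


@dataclass(frozen=True)
class InsertSizeProfile:
    """Summary of the outer insert-size distribution of a sample.

    ``range_low``/``range_high`` are empirical quantiles (default 0.5% and
    99.5%) rather than the raw min/max, which is unstable under outliers; the
    difference ``range_high - range_low`` is the "insert size range" from
    which translocation windows are sized.
    """

    n_pairs: int
    median: float
    mean: float
    sd: float
    range_low: float
    range_high: float

    @property
    def range_width(self) -> float:
        return self.range_high - self.range_low


# ---------------------------------------------------------------------------
# reading


def _detect_format(path: Path) -> str:
    if path.suffix.lower() == ".sam":
        return "sam"
    if path.suffix.lower() in (".tsv", ".pairs", ".txt"):
        return "tsv"
    with open(path) as fh:
        first = fh.readline()
    return "sam" if first.startswith("@") else "tsv"


def _pair_record(a: pysam.AlignedSegment, b: pysam.AlignedSegment, sample: str) -> ReadPairRecord:
    def endpoints(seg: pysam.AlignedSegment) -> tuple[str, int, int, str]:
        start = seg.reference_start + 1  # 1-based leftmost
        end = seg.reference_end if seg.reference_end is not None else seg.reference_start + 1
        return seg.reference_name, start, end, "-" if seg.is_reverse else "+"

    ca, sa, ea, stra = endpoints(a)
    cb, sb, eb, strb = endpoints(b)
    if (ca, sa) > (cb, sb):
        (ca, sa, ea, stra), (cb, sb, eb, strb) = (cb, sb, eb, strb), (ca, sa, ea, stra)
    if ca == cb:
        insert = max(ea, eb) - min(sa, sb) + 1  # outer span, 1-based inclusive
        if a.template_length:
            insert = max(insert, abs(a.template_length))
    else:
        insert = 0
    return ReadPairRecord(
        fragment_id=a.query_name,
        sample=sample,
        chrom_a=ca,
        pos_a=sa,
        strand_a=stra,
        chrom_b=cb,
        pos_b=sb,
        strand_b=strb,
        mapq=min(a.mapping_quality, b.mapping_quality),
        insert_size=insert,
        is_duplicate=a.is_duplicate or b.is_duplicate,
        is_mapped=True,
    )


def _read_sam(path: Path, sample: str) -> Iterator[ReadPairRecord]:
    pending: dict[str, pysam.AlignedSegment] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_secondary or aln.is_supplementary:
                continue
            if aln.is_unmapped or aln.mate_is_unmapped or not aln.is_paired:
                continue
            mate = pending.pop(aln.query_name, None)
            if mate is None:
                pending[aln.query_name] = aln
            else:
                yield _pair_record(mate, aln, sample)
    for name in pending:
        warnings.warn(f"orphan mate skipped: {name}", stacklevel=2)


def _read_tsv(path: Path) -> Iterator[ReadPairRecord]:
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != len(_TSV_COLUMNS):
                raise ParseError(f"{path}:{lineno}: expected {len(_TSV_COLUMNS)} fields, got {len(row)}")
            try:
                yield ReadPairRecord(
                    fragment_id=row[0],
                    sample=row[1],
                    chrom_a=row[2],
                    pos_a=int(row[3]),
                    strand_a=row[4],
                    chrom_b=row[5],
                    pos_b=int(row[6]),
                    strand_b=row[7],
                    mapq=int(row[8]),
                    insert_size=int(row[9]),
                    is_duplicate=row[10] == "1",
                    is_mapped=row[11] == "1",
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc


def read_pairs(
    path: str | Path,
    *,
    min_mapq: int = 0,
    drop_duplicates: bool = True,
    sample: str | None = None,
    fmt: str | None = None,
) -> Iterator[ReadPairRecord]:
    """Stream fragment records from a SAM or internal TSV file.

    One record per primary read pair passing the filters; unmapped, secondary
    and supplementary alignments are skipped, orphan mates raise a warning and
    are dropped. ``sample`` overrides the sample label (default: file stem for
    SAM; the stored column for TSV).
    """
    path = Path(path)
    fmt = fmt or _detect_format(path)
    if fmt == "sam":
        stream: Iterator[ReadPairRecord] = _read_sam(path, sample or path.stem)
    elif fmt == "tsv":
        stream = _read_tsv(path)
        if sample is not None:
            stream = (replace(r, sample=sample) for r in stream)
    else:
        raise ValidationError(f"unknown format: {fmt!r}")
    for rec in stream:
        if rec.mapq < min_mapq:
            continue
        if drop_duplicates and rec.is_duplicate:
            continue
        yield rec


# ---------------------------------------------------------------------------
# writing


def write_pairs(
    path: str | Path,
    pairs: Iterable[ReadPairRecord],
    *,
    genome: Mapping[str, int] | None = None,
    read_length: int = 100,
    fmt: str | None = None,
) -> None:
    """Write fragment records as SAM text (two reads per pair, coordinate
    sorted; requires ``genome`` for the @SQ header) or internal TSV."""
    path = Path(path)
    fmt = fmt or ("sam" if path.suffix.lower() == ".sam" else "tsv")
    if fmt == "tsv":
        with open(path, "w", newline="") as fh:
            fh.write("#" + "\t".join(_TSV_COLUMNS) + "\n")
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            for r in pairs:
                w.writerow(
                    [
                        r.fragment_id,
                        r.sample,
                        r.chrom_a,
                        r.pos_a,
                        r.strand_a,
                        r.chrom_b,
                        r.pos_b,
                        r.strand_b,
                        r.mapq,
                        r.insert_size,
                        int(r.is_duplicate),
                        int(r.is_mapped),
                    ]
                )
        return
    if fmt != "sam":
        raise ValidationError(f"unknown format: {fmt!r}")
    if genome is None:
        raise ValidationError("writing SAM requires a genome (chromosome lengths) for @SQ lines")
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": int(length)} for chrom, length in genome.items()],
    }
    tids = {chrom: i for i, chrom in enumerate(genome)}
    segments: list[pysam.AlignedSegment] = []
    sam_header = pysam.AlignmentHeader.from_dict(header)
    for r in pairs:
        tlen = r.insert_size if r.chrom_a == r.chrom_b else 0
        for first, (chrom, pos, strand, mchrom, mpos, mstrand, stlen) in enumerate(
            [
                (r.chrom_a, r.pos_a, r.strand_a, r.chrom_b, r.pos_b, r.strand_b, tlen),
                (r.chrom_b, r.pos_b, r.strand_b, r.chrom_a, r.pos_a, r.strand_a, -tlen),
            ]
        ):
            seg = pysam.AlignedSegment(sam_header)
            seg.query_name = r.fragment_id
            seg.reference_id = tids[chrom]
            seg.reference_start = pos - 1
            seg.mapping_quality = r.mapq
            seg.cigarstring = f"{read_length}M"
            seg.next_reference_id = tids[mchrom]
            seg.next_reference_start = mpos - 1
            seg.template_length = stlen
            flag = 0x1  # paired
            flag |= 0x40 if first == 0 else 0x80
            if strand == "-":
                flag |= 0x10
            if mstrand == "-":
                flag |= 0x20
            if r.is_duplicate:
                flag |= 0x400
            seg.flag = flag
            segments.append(seg)
    segments.sort(key=lambda s: (s.reference_id, s.reference_start))
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for seg in segments:
            out.write(seg)


# ---------------------------------------------------------------------------
# profiling and downsampling


def insert_profile(
    pairs: Iterable[ReadPairRecord],
    quantiles: tuple[float, float] = (0.005, 0.995),
) -> InsertSizeProfile:
    """Insert-size profile over co-chromosomal mapped pairs.

    ``quantiles`` define the empirical insert-size range used downstream for
    window sizing and concordance; pass ``(0.0, 1.0)`` for a strict min-max
    range.
    """
    lo, hi = quantiles
    if not 0.0 <= lo < hi <= 1.0:
        raise ValidationError("quantiles must satisfy 0 <= low < high <= 1")
    sizes = np.array(
        [p.insert_size for p in pairs if p.is_mapped and not p.is_interchromosomal and p.insert_size > 0],
        dtype=float,
    )
    if sizes.size == 0:
        raise EmptyProfileError("no co-chromosomal mapped pairs to profile")
    qlow, qhigh = np.quantile(sizes, [lo, hi])
    return InsertSizeProfile(
        n_pairs=int(sizes.size),
        median=float(np.median(sizes)),
        mean=float(sizes.mean()),
        sd=float(sizes.std(ddof=1)) if sizes.size > 1 else 0.0,
        range_low=float(qlow),
        range_high=float(qhigh),
    )


def downsample(
    pairs: Sequence[ReadPairRecord],
    target_mapped_reads: int,
    seed: int,
) -> list[ReadPairRecord]:
    """Select whole pairs uniformly without replacement to hit an exact
    mapped-read target.

    The target is expressed in reads (each retained pair contributes two) and
    must be even. Selection is pair-preserving so downstream discordant-pair
    logic keeps both mates; output preserves input order and is a pure
    function of (input, seed).
    """
    if target_mapped_reads < 0 or target_mapped_reads % 2 != 0:
        raise ValidationError("target_mapped_reads must be a non-negative even integer")
    mapped_idx = [i for i, p in enumerate(pairs) if p.is_mapped]
    n_keep = target_mapped_reads // 2
    if n_keep > len(mapped_idx):
        raise InfeasibleError(
            f"requested {target_mapped_reads} reads but only {2 * len(mapped_idx)} mapped reads available"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(mapped_idx), size=n_keep, replace=False)
    keep = sorted(mapped_idx[i] for i in chosen)
    return [pairs[i] for i in keep]
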