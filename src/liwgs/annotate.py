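"""Gene-interval loading and overlap lookup shared by both callers."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .errors import ParseError

__all__ = ["read_bed", "read_gene_list", "GeneIndex"]


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Parse a BED file of gene intervals into (chrom, start, end, name)
    tuples, keeping BED's 0-based half-open coordinates."""
    out: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED line has fewer than 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if end <= start:
                raise ParseError(f"{path}:{lineno}: BED end must exceed start")
            name = fields[3] if len(fields) > 3 else f"{fields[0]}:{start}-{end}"
            out.append((fields[0], start, end, name))
    return out


def read_gene_list(path: str | Path) -> set[str]:
    """Read a plain-text gene list (one symbol per line) for flagging."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


class GeneIndex:
    """Interval index over gene annotations, queried in 1-based inclusive
    genomic coordinates."""

    def __init__(self, intervals: Iterable[tuple[str, int, int, str]]):
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end, name in intervals:
            # BED half-open [start, end) -> 1-based inclusive [start+1, end]
            self._trees.setdefault(chrom, IntervalTree()).addi(start + 1, end + 1, name)

    @classmethod
    def from_bed(cls, path: str | Path) -> "GeneIndex":
        return cls(read_bed(path))

    def overlapping(self, chrom: str, start: int, end: int) -> list[str]:
        """Gene names overlapping [start, end] (1-based inclusive), sorted."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.overlap(start, end + 1)})


def split_flagged(genes: Sequence[str], flag_list: set[str] | None) -> tuple[str, ...]:
    """Subset of ``genes`` present in ``flag_list`` (order preserved)."""
    if not flag_list:
        return ()
    return tuple(g for g in genes if g in flag_list)
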