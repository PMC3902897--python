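"""Physical-coverage and detection-power models for paired-end library design.

A paired-end library sequenced at read length ``L`` with outer insert size
``2L + I`` (``I`` the unsequenced inter-read gap) gives two distinct notions of
coverage over a genome of size ``G``:

* sequence coverage -- average number of *sequenced* bases over a position,
  ``N * L / G`` for ``N`` aligned reads;
* physical (clonal) coverage -- average number of DNA *fragments* whose outer
  span (including the gap) crosses a position.

Because a fragment spans the whole insert, long-insert libraries buy physical
coverage cheaply: every breakpoint-crossing fragment whose mates straddle the
junction is detectable as an anomalous pair, so the power to see a somatic
event scales with physical, not sequence, coverage.

Two accounting conventions for physical coverage are in circulation and both
are kept here, explicitly named, because published design numbers mix them:

* read-based: ``C = N * (2L + I) / G`` with ``N`` counting individual aligned
  reads, so each fragment is counted once per read (twice per pair);
* fragment-based: one fragment per pair, ``C = N_pairs * (2L + I) / G``, i.e.
  half the read-based value; equivalently ``C_phys = C_seq * insert / (2L)``.

Detection power uses a binomial tail: of the ``C`` fragments crossing a
breakpoint, each derives from the variant-bearing allele with probability
``a`` (the event frequency; ``a = purity / 2`` for a heterozygous somatic
event), and the event is detected when at least ``t`` anomalous pairs are
observed:

    P(detect) = 1 - sum_{k=0}^{t-1} C(C, k) a^k (1 - a)^(C - k)

A Poisson-tail variant (mean ``C * a``) is available for sensitivity
analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .errors import InvalidDesignError, UnattainablePowerError, ValidationError

__all__ = [
    "LibraryDesign",
    "PowerQuery",
    "physical_coverage",
    "sequence_coverage",
    "phys_from_seq_fragment",
    "phys_from_seq_read_based",
    "expected_event_frequency",
    "detection_power",
    "required_physical_coverage",
    "round_half_away",
]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero.

    Used for reporting coverages: a coverage is a fragment count, and the
    printed design numbers round 160.5 up to 161.
    """
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class LibraryDesign:
    """A paired-end sequencing library design.

    Parameters
    ----------
    read_length:
        Bases sequenced per read (``L``).
    insert_size:
        Outer fragment length in bases, ``2L + I``.
    genome_size:
        Haploid genome size in bases (``G``).
    insert_sd:
        Standard deviation of the insert-size distribution (informational;
        not used by the deterministic conversions).
    """

    read_length: int
    insert_size: float
    genome_size: float
    insert_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise InvalidDesignError("read_length must be positive")
        if self.insert_size <= 0:
            raise InvalidDesignError("insert_size must be positive")
        if self.genome_size <= 0:
            raise InvalidDesignError("genome_size must be positive")

    @property
    def inter_read_gap(self) -> float:
        """Unsequenced bases between the two reads (``I = insert - 2L``).

        Negative for overlapping read pairs; the coverage conversions remain
        defined either way.
        """
        return self.insert_size - 2 * self.read_length


@dataclass(frozen=True)
class PowerQuery:
    """One detection-power question: event frequency, coverage, support cutoff."""

    event_frequency: float
    physical_coverage: float
    min_support: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.event_frequency <= 1.0:
            raise ValidationError("event_frequency must be in [0, 1]")
        if self.min_support < 1:
            raise ValidationError("min_support must be >= 1")
        if self.physical_coverage < 0:
            raise ValidationError("physical_coverage must be non-negative")

    def power(self, model: str = "binomial") -> float:
        return detection_power(
            self.event_frequency, self.physical_coverage, self.min_support, model=model
        )


def physical_coverage(n_aligned_reads: float, design: LibraryDesign) -> float:
    """Read-based physical coverage ``C = N (2L + I) / G`` for N aligned reads."""
    if n_aligned_reads < 0:
        raise ValidationError("n_aligned_reads must be non-negative")
    return n_aligned_reads * design.insert_size / design.genome_size


def sequence_coverage(n_aligned_reads: float, design: LibraryDesign) -> float:
    """Sequence coverage ``N * L / G`` for N aligned reads."""
    if n_aligned_reads < 0:
        raise ValidationError("n_aligned_reads must be non-negative")
    return n_aligned_reads * design.read_length / design.genome_size


def phys_from_seq_fragment(seq_coverage: float, design: LibraryDesign) -> float:
    """Fragment-based conversion: each pair contributes 2L sequenced bases and
    one insert-long fragment, so ``C_phys = C_seq * insert / (2L)``."""
    if seq_coverage < 0:
        raise ValidationError("seq_coverage must be non-negative")
    return seq_coverage * design.insert_size / (2 * design.read_length)


def phys_from_seq_read_based(seq_coverage: float, design: LibraryDesign) -> float:
    """Read-based conversion ``C_phys = C_seq * insert / L`` (each read of a
    pair counted once; exactly twice the fragment-based value)."""
    if seq_coverage < 0:
        raise ValidationError("seq_coverage must be non-negative")
    return seq_coverage * design.insert_size / design.read_length


def expected_event_frequency(tumor_cellularity: float) -> float:
    """Expected fragment-level frequency of a heterozygous somatic event.

    A heterozygous event sits on one of the two tumor haplotypes, so its
    expected frequency among breakpoint-crossing fragments is half the tumor
    cell content of the sample.
    """
    if not 0.0 <= tumor_cellularity <= 1.0:
        raise ValidationError("tumor_cellularity must be in [0, 1]")
    return tumor_cellularity / 2.0


def detection_power(
    event_frequency: float,
    physical_coverage: float,
    min_support: int = 10,
    *,
    model: str = "binomial",
) -> float:
    """Probability that >= ``min_support`` of the breakpoint-crossing
    fragments derive from the variant allele.

    ``physical_coverage`` is rounded half away from zero to an integer
    fragment count. ``model`` selects the binomial tail (default) or a
    Poisson approximation with mean ``C * a``.
    """
    if not 0.0 <= event_frequency <= 1.0:
        raise ValidationError("event_frequency must be in [0, 1]")
    if min_support < 1:
        raise ValidationError("min_support must be >= 1")
    if physical_coverage < 0:
        raise ValidationError("physical_coverage must be non-negative")
    c = round_half_away(physical_coverage)
    if model == "binomial":
        return float(stats.binom.sf(min_support - 1, c, event_frequency))
    if model == "poisson":
        return float(stats.poisson.sf(min_support - 1, c * event_frequency))
    raise ValidationError(f"unknown power model: {model!r}")


def required_physical_coverage(
    event_frequency: float,
    min_support: int = 10,
    target_power: float = 0.99,
    *,
    model: str = "binomial",
    max_coverage: int = 10**9,
) -> int:
    """Smallest integer physical coverage reaching ``target_power``.

    Inverse of :func:`detection_power` in its coverage argument; found by
    exponential bracketing followed by bisection (power is nondecreasing in
    coverage).
    """
    if event_frequency <= 0.0:
        raise UnattainablePowerError("event_frequency must be positive to attain power")
    if event_frequency > 1.0:
        raise ValidationError("event_frequency must be in (0, 1]")
    if not 0.0 < target_power < 1.0:
        raise ValidationError("target_power must be in (0, 1)")
    if min_support < 1:
        raise ValidationError("min_support must be >= 1")

    lo = min_support  # below this the power is exactly zero
    if detection_power(event_frequency, lo, min_support, model=model) >= target_power:
        return lo
    hi = lo
    while detection_power(event_frequency, hi, min_support, model=model) < target_power:
        hi *= 2
        if hi > max_coverage:
            raise UnattainablePowerError(
                f"target power {target_power} not reached below coverage {max_coverage}"
            )
    # invariant: power(lo) < target <= power(hi)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if detection_power(event_frequency, mid, min_support, model=model) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi
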