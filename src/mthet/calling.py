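"""Minor-variant calling from per-position allele counts.

A heteroplasmic call at a position is the second-most frequent base surviving
a cascade of filters designed for deep-coverage amplicon data:

1. total coverage at the position >= ``min_total_coverage`` (default 200);
2. minor-allele fraction >= the analytical threshold (default 1%);
3. minor-allele reads >= ``min_variant_reads`` (default 40);
4. minor-allele strand balance within ``max_balance_ratio`` (default 2.5);
5. major/minor mean quality difference <= ``max_score_balance`` (default 10,
   applied only when per-base quality summaries are present);
6. minor fraction >= the reporting threshold (default 2%) to be *reported*.

Frequencies are fractions of the total position coverage over all four
bases, not of major+minor only.

The strand-balance statistic defaults to the minor allele's forward/reverse
odds normalised by the major allele's odds, so that amplicon-wide strand
imbalance (both alleles skewed the same way) does not reject a genuine
variant while a one-direction minor under a balanced major does fail.  The
raw max/min of the minor allele's strand counts is available with
``balance_mode="minor_only"``.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

from .reference import GENOME_LENGTH, check_np

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

#: call statuses, in cascade order
STATUS_REPORTED = "reported"
STATUS_BELOW_REPORTING = "below_reporting"
STATUS_INSUFFICIENT = "insufficient_coverage"


def _failed(name: str) -> str:
    return f"failed_filter:{name}"


@dataclass(frozen=True)
class AlleleCounts:
    """Forward/reverse read counts for the four bases at one sample-position."""

    sample_id: str
    np: int
    fwd: Mapping[str, int]
    rev: Mapping[str, int]
    #: optional mean quality score per base (0-40 scale)
    quality: Mapping[str, float] | None = None

    def __post_init__(self):
        check_np(self.np)
        for base in BASES:
            if self.fwd.get(base, 0) < 0 or self.rev.get(base, 0) < 0:
                raise ValueError(
                    f"negative read count at np {self.np} for sample {self.sample_id}"
                )

    def count(self, base: str) -> int:
        return self.fwd.get(base, 0) + self.rev.get(base, 0)

    @property
    def total(self) -> int:
        return sum(self.count(b) for b in BASES)


@dataclass(frozen=True)
class FilterConfig:
    """Filter stack settings; defaults follow the deep-coverage protocol."""

    analytical_threshold: float = 0.01
    min_variant_reads: int = 40
    min_total_coverage: int = 200
    max_balance_ratio: float = 2.5
    max_score_balance: float = 10.0
    reporting_threshold: float = 0.02
    excluded_positions: frozenset[int] = frozenset({310, 3107})
    balance_mode: str = "major_normalized"

    def __post_init__(self):
        if not 0 < self.analytical_threshold <= self.reporting_threshold < 0.5:
            raise ValueError(
                "need 0 < analytical_threshold <= reporting_threshold < 0.5, got "
                f"{self.analytical_threshold} and {self.reporting_threshold}"
            )
        if self.min_variant_reads < 1:
            raise ValueError("min_variant_reads must be >= 1")
        if self.min_total_coverage < self.min_variant_reads:
            raise ValueError("min_total_coverage must be >= min_variant_reads")
        if self.max_balance_ratio <= 0:
            raise ValueError("max_balance_ratio must be positive")
        if self.balance_mode not in ("major_normalized", "minor_only"):
            raise ValueError(f"unknown balance_mode {self.balance_mode!r}")

    #: coverage needed so the read-count filter still permits calls at the
    #: reporting threshold (2000 at defaults)
    @property
    def reporting_floor_coverage(self) -> float:
        return self.min_variant_reads / self.reporting_threshold

    def replace(self, **kw) -> "FilterConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class VariantCall:
    """Outcome of calling one sample-position."""

    sample_id: str
    np: int
    status: str
    total_coverage: int
    major_allele: str | None = None
    major_freq: float = 0.0
    minor_allele: str | None = None
    minor_freq: float = 0.0
    minor_fwd: int = 0
    minor_rev: int = 0

    @property
    def reported(self) -> bool:
        return self.status == STATUS_REPORTED

    @property
    def minor_pct(self) -> float:
        return 100.0 * self.minor_freq


@dataclass(frozen=True)
class DetectionFloor:
    """Effective minimum detectable minor fraction at one sample-position."""

    sample_id: str
    np: int
    floor: float
    adequate_for_reporting: bool


def frequencies(counts: AlleleCounts) -> dict[str, float]:
    """Per-base fractions of total position coverage; they sum to 1."""
    total = counts.total
    if total == 0:
        raise ValueError(
            f"zero coverage at np {counts.np} for sample {counts.sample_id}"
        )
    return {b: counts.count(b) / total for b in BASES}


def strand_balance_ratio(
    counts: AlleleCounts, major: str, minor: str, mode: str = "major_normalized"
) -> float:
    """Strand-balance statistic for the minor allele (>= 1; inf = one-sided).

    ``minor_only``: max/min of the minor allele's forward vs reverse counts.
    ``major_normalized``: the minor allele's fwd/rev odds divided by the major
    allele's, folded to >= 1.  A minor allele observed on a single strand is
    infinite (fails any cutoff) under both modes.
    """
    nf, nr = counts.fwd.get(minor, 0), counts.rev.get(minor, 0)
    if nf == 0 or nr == 0:
        return math.inf
    if mode == "minor_only":
        return max(nf, nr) / min(nf, nr)
    mf, mr = counts.fwd.get(major, 0), counts.rev.get(major, 0)
    if mf == 0 or mr == 0:
        # degenerate major strand distribution: fall back to the raw ratio
        return max(nf, nr) / min(nf, nr)
    odds = (nf / nr) / (mf / mr)
    return max(odds, 1.0 / odds)


def call_position(counts: AlleleCounts, cfg: FilterConfig | None = None) -> VariantCall:
    """Apply the filter cascade to one sample-position."""
    cfg = cfg or FilterConfig()
    total = counts.total
    if counts.np in cfg.excluded_positions:
        return VariantCall(counts.sample_id, counts.np, _failed("excluded"), total)
    if total == 0:
        return VariantCall(counts.sample_id, counts.np, STATUS_INSUFFICIENT, 0)

    freqs = frequencies(counts)
    ranked = sorted(BASES, key=lambda b: (-freqs[b], b))
    major, minor = ranked[0], ranked[1]
    if freqs[major] == freqs[minor]:
        logger.info(
            "major-allele tie at np %d for sample %s (%s/%s at %.4f); "
            "breaking lexicographically",
            counts.np, counts.sample_id, major, minor, freqs[major],
        )
    common = dict(
        sample_id=counts.sample_id,
        np=counts.np,
        total_coverage=total,
        major_allele=major,
        major_freq=freqs[major],
        minor_allele=minor,
        minor_freq=freqs[minor],
        minor_fwd=counts.fwd.get(minor, 0),
        minor_rev=counts.rev.get(minor, 0),
    )

    if total < cfg.min_total_coverage:
        return VariantCall(status=_failed("min_total_coverage"), **common)
    if freqs[minor] < cfg.analytical_threshold:
        return VariantCall(status=_failed("analytical_threshold"), **common)
    if counts.count(minor) < cfg.min_variant_reads:
        return VariantCall(status=_failed("min_variant_reads"), **common)
    ratio = strand_balance_ratio(counts, major, minor, cfg.balance_mode)
    if ratio > cfg.max_balance_ratio:
        return VariantCall(status=_failed("balance_ratio"), **common)
    if counts.quality is not None:
        dq = abs(counts.quality.get(major, 0.0) - counts.quality.get(minor, 0.0))
        if dq > cfg.max_score_balance:
            return VariantCall(status=_failed("score_balance"), **common)
    if freqs[minor] < cfg.reporting_threshold:
        return VariantCall(status=STATUS_BELOW_REPORTING, **common)
    return VariantCall(status=STATUS_REPORTED, **common)


def detection_floor(counts: AlleleCounts, cfg: FilterConfig | None = None) -> DetectionFloor:
    """max(analytical threshold, min reads / coverage) for one sample-position.

    A position is coverage-adequate for reporting when that floor does not
    exceed the reporting threshold, i.e. coverage >= min_variant_reads /
    reporting_threshold (2000 reads at the defaults).
    """
    cfg = cfg or FilterConfig()
    total = counts.total
    if total == 0:
        return DetectionFloor(counts.sample_id, counts.np, math.inf, False)
    floor = max(cfg.analytical_threshold, cfg.min_variant_reads / total)
    return DetectionFloor(
        counts.sample_id, counts.np, floor, floor <= cfg.reporting_threshold
    )
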