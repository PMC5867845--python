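"""Assumed substitution-error profiling across a sample set.

The estimator is deliberately conservative: at each position of each sample,
every base call making up at most 50% of the reads there is assumed to be an
error (true heteroplasmy below 50% is knowingly included, inflating the
estimate).  Per-position rates sum those assumed-error calls across samples
and divide by the summed coverage; average rates pool all positions.  Rates
are reported in percent.

The hotspot report ranks the highest per-position rates for each nucleotide,
attaches the flanking sequence context from the reference, and flags motifs
(polyA/polyC runs, GGT) known to drive alignment- and chemistry-related
error spikes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import BASES, AlleleCounts, FilterConfig
from .reference import GENOME_LENGTH, PLACEHOLDER_NP, MtReference, motif_flags

logger = logging.getLogger(__name__)

_BASE_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass
class ErrorProfile:
    """Per-position and average assumed substitution-error rates.

    ``numerators[i, b]`` holds assumed-error calls of base b at position i+1
    summed over samples; ``denominators[i]`` the summed coverage.  Positions
    with zero pooled coverage have undefined rates and are excluded from
    averages.
    """

    numerators: np.ndarray  # (16569, 4)
    denominators: np.ndarray  # (16569,)
    n_samples: int
    excluded_positions: frozenset[int] = frozenset({PLACEHOLDER_NP})

    def rate(self, np_: int, base: str) -> float:
        """Assumed error rate in percent for one base at one position."""
        den = self.denominators[np_ - 1]
        if den == 0:
            return float("nan")
        return 100.0 * self.numerators[np_ - 1, _BASE_IDX[base]] / den

    def average_rates(self) -> dict[str, float]:
        """Pooled rate per base in percent (all positions, all samples)."""
        den = self.denominators.sum()
        if den == 0:
            return {b: float("nan") for b in BASES}
        return {b: 100.0 * self.numerators[:, i].sum() / den for b, i in _BASE_IDX.items()}

    def per_position(self) -> pd.DataFrame:
        """DataFrame of rates in percent: np, rate_A..rate_T, coverage."""
        with np.errstate(divide="ignore", invalid="ignore"):
            rates = 100.0 * self.numerators / self.denominators[:, None]
        df = pd.DataFrame(rates, columns=[f"rate_{b}" for b in BASES])
        df.insert(0, "np", np.arange(1, GENOME_LENGTH + 1))
        df["coverage"] = self.denominators
        return df

    def undefined_positions(self) -> np.ndarray:
        """Positions with zero pooled coverage (rates undefined there)."""
        zero = np.flatnonzero(self.denominators == 0) + 1
        return np.array([p for p in zero if p not in self.excluded_positions])

    def positions_exceeding(self, threshold_pct: float) -> list[tuple[int, str, float]]:
        """(np, base, rate) for rates above a percentage threshold."""
        out = []
        with np.errstate(divide="ignore", invalid="ignore"):
            rates = 100.0 * self.numerators / self.denominators[:, None]
        idx = np.argwhere(rates > threshold_pct)
        for i, j in idx:
            out.append((int(i) + 1, BASES[j], float(rates[i, j])))
        return sorted(out, key=lambda r: -r[2])


@dataclass(frozen=True)
class HotspotRow:
    np: int
    base: str
    rate_pct: float
    ref_base: str
    adjacent_sequence: str
    motifs: frozenset[str]


@dataclass
class HotspotReport:
    rows: list[HotspotRow]
    motif_fractions: dict[str, float]
    above_reporting_threshold: list[tuple[int, str, float]] = field(default_factory=list)

    def for_base(self, base: str) -> list[HotspotRow]:
        return [r for r in self.rows if r.base == base]


@dataclass(frozen=True)
class CoverageAssessment:
    per_sample: pd.DataFrame  # sample_id, n_positions_below_floor, mean_coverage
    cohort_fraction_adequate: float
    mean_coverage: float
    floor_coverage: float


def error_rates(
    pileups: Iterable[AlleleCounts],
    excluded_positions: frozenset[int] = frozenset({PLACEHOLDER_NP}),
) -> ErrorProfile:
    """Aggregate assumed error rates over an iterable of sample pileups.

    The <=50% cut is applied per sample per position *before* summation; a
    sample-position with zero coverage contributes nothing.
    """
    num = np.zeros((GENOME_LENGTH, 4), dtype=np.int64)
    den = np.zeros(GENOME_LENGTH, dtype=np.int64)
    samples: set[str] = set()
    for counts in pileups:
        samples.add(counts.sample_id)
        if counts.np in excluded_positions:
            continue
        total = counts.total
        if total == 0:
            continue
        i = counts.np - 1
        den[i] += total
        for b in BASES:
            nb = counts.count(b)
            if 2 * nb <= total:  # the <=50% "assumed error" rule
                num[i, _BASE_IDX[b]] += nb
    return ErrorProfile(num, den, len(samples), excluded_positions)


def hotspots(
    profile: ErrorProfile,
    reference: MtReference,
    depth: Mapping[str, int] | int = None,
    reporting_threshold_pct: float = 2.0,
) -> HotspotReport:
    """Rank the highest per-position rates for each base with motif context.

    ``depth`` is the number of top rates kept per base (default 25 for A, G,
    T and 35 for C, extending the C list the way a >2%-inclusive cut does).
    Warns about positions whose rate exceeds the reporting threshold: calls
    at such positions need scrutiny even though balance/quality filters
    usually reject them.
    """
    if depth is None:
        depth = {"A": 25, "C": 35, "G": 25, "T": 25}
    elif isinstance(depth, int):
        depth = {b: depth for b in BASES}
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = 100.0 * profile.numerators / profile.denominators[:, None]
    rates = np.nan_to_num(rates, nan=0.0)
    rows: list[HotspotRow] = []
    for b, j in _BASE_IDX.items():
        order = np.argsort(-rates[:, j], kind="stable")[: depth[b]]
        for i in order:
            np_ = int(i) + 1
            if rates[i, j] <= 0 or np_ in profile.excluded_positions:
                continue
            ctx = reference.adjacent_sequence(np_)
            rows.append(
                HotspotRow(np_, b, float(rates[i, j]), reference.base(np_), ctx, motif_flags(ctx))
            )
    n = len(rows)
    fractions = {
        flag: (sum(1 for r in rows if flag in r.motifs) / n if n else float("nan"))
        for flag in ("polyA", "polyC", "GGT")
    }
    above = profile.positions_exceeding(reporting_threshold_pct)
    if above:
        logger.warning(
            "%d position/base rates exceed the %.1f%% reporting threshold: %s",
            len(above), reporting_threshold_pct,
            ", ".join(f"np {p} {b} {r:.2f}%" for p, b, r in above[:10]),
        )
    return HotspotReport(rows, fractions, above)


def coverage_assessment(
    pileups: Iterable[AlleleCounts],
    cfg: FilterConfig | None = None,
) -> CoverageAssessment:
    """Depth-of-coverage adequacy for reporting at the minor-allele threshold.

    The floor is min_variant_reads / reporting_threshold reads (2000 at
    defaults): below it, the read-count filter forbids calls at the reporting
    threshold regardless of signal.
    """
    cfg = cfg or FilterConfig()
    floor = cfg.reporting_floor_coverage
    below: dict[str, int] = {}
    total_cov: dict[str, int] = {}
    n_obs: dict[str, int] = {}
    for counts in pileups:
        sid = counts.sample_id
        t = counts.total
        below[sid] = below.get(sid, 0) + (1 if t < floor else 0)
        total_cov[sid] = total_cov.get(sid, 0) + t
        n_obs[sid] = n_obs.get(sid, 0) + 1
    per_sample = pd.DataFrame(
        {
            "sample_id": sorted(below),
            "n_positions_below_floor": [below[s] for s in sorted(below)],
            "mean_coverage": [total_cov[s] / n_obs[s] for s in sorted(below)],
        }
    )
    n_total = sum(n_obs.values())
    n_below = sum(below.values())
    return CoverageAssessment(
        per_sample,
        (n_total - n_below) / n_total if n_total else float("nan"),
        sum(total_cov.values()) / n_total if n_total else float("nan"),
        floor,
    )
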