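"""Cohort summary statistics and Welch comparisons of heteroplasmy rates.

Frequency sets are assembled per classification label, one observation per
reported sample-slot: every reported slot of a shared site, the carrier's two
slots of a differentiating site, and the single slot of a random site.
Non-detections are excluded, never imputed as zero.  Values are percentages.
Group comparisons use the Welch unequal-variance two-sample t-test with
Welch-Satterthwaite degrees of freedom and two-sided p-values.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .classify import (
    DIFFERENTIATING,
    RANDOM,
    SHARED,
    ClassifiedSite,
    SiteComparison,
)

LABELS = (SHARED, DIFFERENTIATING, RANDOM)


@dataclass(frozen=True)
class FrequencySet:
    """Minor-variant percentages for one classification label."""

    label: str
    values: tuple[float, ...]

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if self.values else float("nan")


@dataclass(frozen=True)
class WelchResult:
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def frequency_sets(classified: Iterable[ClassifiedSite]) -> dict[str, FrequencySet]:
    """Assemble the shared/differentiating/random frequency sets.

    Shared sites contribute every reported slot; differentiating sites the
    carrier's two tissues; random sites their single reported slot.  The
    three sets partition the reported observations of classified sites.
    """
    values: dict[str, list[float]] = {label: [] for label in LABELS}
    for site in classified:
        if site.label not in values:
            continue  # unclassifiable sites contribute nothing
        for slot in site.reported_slots():
            if site.label == DIFFERENTIATING and not slot.startswith(site.carrier):
                continue
            values[site.label].append(site.minor_pct[slot])
    return {
        label: FrequencySet(label, tuple(vals)) for label, vals in values.items()
    }


def welch_test(a: FrequencySet, b: FrequencySet) -> WelchResult:
    """Welch two-sample t-test between two frequency sets (two-sided)."""
    for fs in (a, b):
        if fs.n < 2:
            raise ValueError(
                f"frequency set {fs.label!r} has {fs.n} observation(s); need >= 2"
            )
    xa, xb = np.asarray(a.values), np.asarray(b.values)
    res = stats.ttest_ind(xa, xb, equal_var=False)
    va, vb = xa.var(ddof=1) / a.n, xb.var(ddof=1) / b.n
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return WelchResult(
        float(res.statistic), float(df), float(res.pvalue),
        a.mean, b.mean, a.n, b.n,
    )


def band_summary(
    comparisons: Sequence[SiteComparison],
    classified: Iterable[ClassifiedSite] = (),
) -> dict:
    """Tissue-band, fold-difference and carrier tallies for differentiating sites."""
    n = len(comparisons)
    diff_sites = [s for s in classified if s.label == DIFFERENTIATING]
    out = {
        "n_sites": n,
        "both_below_10pct": sum(1 for c in comparisons if c.band == "both<10%"),
        "both_above_10pct": sum(1 for c in comparisons if c.band == "both>10%"),
        "mixed_band": sum(1 for c in comparisons if c.band == "mixed"),
        "buccal_higher": sum(1 for c in comparisons if c.buccal_higher),
        "fold_below_2": sum(1 for c in comparisons if c.fold_difference < 2),
        "fold_2_to_3": sum(1 for c in comparisons if 2 <= c.fold_difference <= 3),
        "fold_above_3": sum(1 for c in comparisons if c.fold_difference > 3),
    }
    if diff_sites:
        out["carrier"] = {
            "mother": sum(1 for s in diff_sites if s.carrier == "mother"),
            "child": sum(1 for s in diff_sites if s.carrier == "child"),
        }
    return out


def cohort_report(classified: Sequence[ClassifiedSite], comparisons: Sequence[SiteComparison]) -> dict:
    """Frequency-set means/sizes plus all three pairwise Welch comparisons."""
    sets = frequency_sets(classified)
    report: dict = {
        "frequency_sets": {
            label: {"n": fs.n, "mean_pct": fs.mean} for label, fs in sets.items()
        },
        "welch": {},
        "bands": band_summary(comparisons, classified),
    }
    pairs = [(SHARED, DIFFERENTIATING), (SHARED, RANDOM), (DIFFERENTIATING, RANDOM)]
    for la, lb in pairs:
        a, b = sets[la], sets[lb]
        if a.n >= 2 and b.n >= 2:
            res = welch_test(a, b)
            report["welch"][f"{la}_vs_{lb}"] = {
                "t": res.t_statistic,
                "df": res.degrees_of_freedom,
                "p": res.p_value,
                "mean_a": res.mean_a,
                "mean_b": res.mean_b,
                "n_a": res.n_a,
                "n_b": res.n_b,
            }
        else:
            report["welch"][f"{la}_vs_{lb}"] = None
    return report
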