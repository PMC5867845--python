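"""Synthetic cohort generator: germline bottleneck, tissue segregation, and
deep-coverage read sampling with substitution noise.

The transmission model is deliberately the simplest one generating the
statistical structure the analysis assumes:

* a founder (mother germline) minor-variant frequency is drawn per seeded
  site;
* the child's germline frequency is one binomial segregation through an
  effective bottleneck of ``bottleneck_size`` mtDNA copies (empirical
  estimates of the human germline bottleneck range from a mean near 9 under
  variable-size models up to ~30-35 copies; the default uses the small end,
  which produces the pronounced mother-child drift deep sequencing reveals);
* each individual's two tissue frequencies are one further binomial
  segregation with tissue-specific effective sizes — buccal smaller than
  blood by default, reproducing the higher and more variable heteroplasmy
  levels seen in buccal cells;
* reads are multinomial draws at lognormal coverage: each read reports its
  true allele with probability 1-e and otherwise one of the other three
  bases uniformly, with e the per-base substitution error (default 0.05%,
  the order of magnitude of deep-sequencing error on this platform);
  forward/reverse strands split symmetrically-binomially, with an optional
  bias knob to exercise the strand-balance filter, and an optional
  position->multiplier overlay to plant error hotspots.

Identical configurations (including the seed) produce identical output.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import BASES, AlleleCounts
from .fixtures import fixtures_from_tables  # re-exported: table-driven fixtures
from .reference import GENOME_LENGTH, MtReference

__all__ = [
    "SimConfig",
    "SimResult",
    "simulate_cohort",
    "bottleneck_frequencies",
    "expected_label",
    "fixtures_from_tables",
]

SLOT_SHORT = {"mother_buccal": "MBu", "mother_blood": "MBl",
              "child_buccal": "CBu", "child_blood": "CBl"}


@dataclass(frozen=True)
class SimConfig:
    """Cohort-simulation settings (defaults emulate the study conditions)."""

    n_families: int = 39
    bottleneck_size: int = 9
    tissue_drift_size: int = 500
    #: effective segregation size for buccal tissue; None = same as blood
    buccal_drift_size: int | None = 150
    #: seeded heteroplasmic sites per family
    sites_per_family: int = 2
    #: founder minor-variant frequency drawn uniformly from this range
    founder_freq_range: tuple[float, float] = (0.02, 0.5)
    error_rate_per_base: float = 5e-4
    coverage_median: float = 24_000.0
    coverage_sigma: float = 0.5
    #: forward-strand excess probability (0 = symmetric)
    strand_bias: float = 0.0
    seed: int = 0
    #: positions simulated; None = the whole 16,569-position genome
    positions: tuple[int, ...] | None = None
    #: np -> error-rate multiplier, for planting hotspots
    hotspot_overlay: Mapping[int, float] | None = None
    excluded_positions: frozenset[int] = frozenset({310, 3107})

    def __post_init__(self):
        if min(self.n_families, self.bottleneck_size, self.tissue_drift_size,
               self.sites_per_family) < 1:
            raise ValueError("sizes must be >= 1")
        lo, hi = self.founder_freq_range
        if not 0 <= lo <= hi <= 1:
            raise ValueError("founder_freq_range must lie in [0, 1]")
        if not 0 <= self.error_rate_per_base < 1:
            raise ValueError("error_rate_per_base must lie in [0, 1)")
        if abs(self.strand_bias) >= 0.5:
            raise ValueError("strand_bias must lie in (-0.5, 0.5)")

    def replace(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class SimResult:
    """Simulated pileup (TSV-dialect DataFrame), manifest, and ground truth."""

    pileup: pd.DataFrame
    manifest: list[dict]
    truth: list[dict]
    config: SimConfig

    def allele_counts(self) -> Iterator[AlleleCounts]:
        cols = {b: (f"{b}_fwd", f"{b}_rev") for b in BASES}
        for row in self.pileup.itertuples(index=False):
            d = row._asdict()
            yield AlleleCounts(
                d["sample_id"], int(d["np"]),
                {b: int(d[cols[b][0]]) for b in BASES},
                {b: int(d[cols[b][1]]) for b in BASES},
            )


def bottleneck_frequencies(
    founder: float, n_offspring: int, bottleneck_size: int, rng: np.random.Generator
) -> np.ndarray:
    """Post-bottleneck germline frequencies for replicate offspring.

    One binomial segregation: k ~ Binomial(N, founder), frequency k/N.  The
    drift is unbiased (mean = founder) with variance founder(1-founder)/N.
    """
    return rng.binomial(bottleneck_size, founder, size=n_offspring) / bottleneck_size


def expected_label(tissue_freqs: Mapping[str, float], threshold: float = 0.02) -> str | None:
    """Idealized classification of a site from its four true tissue frequencies."""
    m = sum(1 for s in ("mother_buccal", "mother_blood") if tissue_freqs[s] >= threshold)
    c = sum(1 for s in ("child_buccal", "child_blood") if tissue_freqs[s] >= threshold)
    if m + c == 0:
        return None
    if m >= 1 and c >= 1:
        return "shared"
    if (m, c) in ((2, 0), (0, 2)):
        return "differentiating"
    return "random"


def _multinomial_by_base(
    rng: np.random.Generator, cov: np.ndarray, probs: np.ndarray
) -> np.ndarray:
    """Vectorized multinomial over 4 bases: counts[i, b] ~ Mult(cov[i], probs[i])."""
    n_pos = cov.shape[0]
    counts = np.zeros((n_pos, 4), dtype=np.int64)
    remaining = cov.copy()
    prob_left = np.ones(n_pos)
    for j in range(3):
        p = np.where(prob_left > 0, np.clip(probs[:, j] / np.maximum(prob_left, 1e-300), 0, 1), 0)
        counts[:, j] = rng.binomial(remaining, p)
        remaining -= counts[:, j]
        prob_left -= probs[:, j]
    counts[:, 3] = remaining
    return counts


def simulate_cohort(cfg: SimConfig, reference: MtReference | None = None) -> SimResult:
    """Generate a mother-child-pair cohort under the bottleneck/drift model."""
    reference = reference or MtReference.load()
    rng = np.random.default_rng(cfg.seed)

    if cfg.positions is None:
        positions = np.array(
            [p for p in range(1, GENOME_LENGTH + 1) if p not in cfg.excluded_positions]
        )
    else:
        positions = np.array(sorted(set(cfg.positions) - cfg.excluded_positions))
    pos_index = {p: i for i, p in enumerate(positions)}
    n_pos = positions.size
    ref_bases = np.array([BASES.index(reference.base(int(p))) if reference.base(int(p)) in BASES else 0
                          for p in positions])

    err = np.full(n_pos, cfg.error_rate_per_base)
    if cfg.hotspot_overlay:
        for np_, mult in cfg.hotspot_overlay.items():
            if np_ in pos_index:
                err[pos_index[np_]] *= mult
    err = np.clip(err, 0.0, 0.75)

    manifest: list[dict] = []
    truth: list[dict] = []
    frames: list[pd.DataFrame] = []
    n_bu = cfg.buccal_drift_size or cfg.tissue_drift_size

    for fam_i in range(cfg.n_families):
        fam = f"F{fam_i + 1:02d}"
        seeded = rng.choice(positions, size=min(cfg.sites_per_family, n_pos), replace=False)
        lo, hi = cfg.founder_freq_range
        founders = rng.uniform(lo, hi, size=seeded.size)
        child_germ = rng.binomial(cfg.bottleneck_size, founders) / cfg.bottleneck_size

        site_info = []
        for p, f0, fc in zip(seeded, founders, child_germ):
            i = pos_index[int(p)]
            alt_choices = [j for j in range(4) if j != ref_bases[i]]
            minor = int(rng.choice(alt_choices))
            freqs = {
                "mother_buccal": rng.binomial(n_bu, f0) / n_bu,
                "mother_blood": rng.binomial(cfg.tissue_drift_size, f0) / cfg.tissue_drift_size,
                "child_buccal": rng.binomial(n_bu, fc) / n_bu,
                "child_blood": rng.binomial(cfg.tissue_drift_size, fc) / cfg.tissue_drift_size,
            }
            site_info.append((int(p), minor, freqs))
            truth.append(
                {
                    "family_id": fam,
                    "np": int(p),
                    "minor_allele": BASES[minor],
                    "founder_freq": float(f0),
                    "child_germline_freq": float(fc),
                    "tissue_freqs": {k: float(v) for k, v in freqs.items()},
                    "expected_label": expected_label(freqs),
                }
            )

        for slot, short in SLOT_SHORT.items():
            sid = f"{fam}-{short}"
            manifest.append(
                {
                    "sample_id": sid,
                    "family_id": fam,
                    "role": slot.split("_")[0],
                    "tissue": slot.split("_")[1],
                }
            )
            cov = np.maximum(
                rng.lognormal(np.log(cfg.coverage_median), cfg.coverage_sigma, n_pos).astype(np.int64),
                1,
            )
            # true allele mix per position
            x = np.zeros((n_pos, 4))
            x[np.arange(n_pos), ref_bases] = 1.0
            for p, minor, freqs in site_info:
                i = pos_index[p]
                f = freqs[slot]
                x[i, :] = 0.0
                x[i, ref_bases[i]] = 1.0 - f
                x[i, minor] += f
            # sequencing error: report true base w.p. 1-e, else uniform other
            probs = x * (1.0 - err[:, None]) + (1.0 - x) * (err[:, None] / 3.0)
            counts = _multinomial_by_base(rng, cov, probs)
            fwd = rng.binomial(counts, 0.5 + cfg.strand_bias)
            rev = counts - fwd
            frame = {"sample_id": sid, "np": positions}
            for j, b in enumerate(BASES):
                frame[f"{b}_fwd"] = fwd[:, j]
                frame[f"{b}_rev"] = rev[:, j]
            frames.append(pd.DataFrame(frame))

    pileup = pd.concat(frames, ignore_index=True)
    pileup.insert(2, "ref", [reference.base(int(p)) for p in pileup["np"]])
    return SimResult(pileup, manifest, truth, cfg)
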