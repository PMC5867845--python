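"""Profile per-position substitution error on a simulated deep-coverage
cohort with planted hotspots.

Simulates 20 heteroplasmy-free samples over the first 2,000 genome positions
with a 0.05% per-base error rate, multiplies the error 40x at three
positions adjacent to C-runs, and shows that the profiler's hotspot ranking
finds exactly those positions and flags their motif context.
"""
from mthet import MtReference, SimConfig, error_rates, hotspots, simulate_cohort

reference = MtReference.load()
planted = {297: 40.0, 302: 40.0, 316: 40.0}  # positions flanked by C-runs
cfg = SimConfig(
    n_families=5,
    sites_per_family=1,
    founder_freq_range=(0.0, 0.0),  # noise only; no true heteroplasmy
    error_rate_per_base=5e-4,
    coverage_median=8000,
    positions=tuple(range(1, 2001)),
    hotspot_overlay=planted,
    seed=12,
)
sim = simulate_cohort(cfg)
profile = error_rates(sim.allele_counts())

avg = profile.average_rates()
print("average assumed substitution error (percent of base calls):")
for b in "ACGT":
    print(f"  rCRS>{b}: {avg[b]:.4f}%")

report = hotspots(profile, reference, depth=3)
print("\ntop hotspot positions per base (rate %, flanking context, motifs):")
for row in sorted(report.rows, key=lambda r: -r.rate_pct)[:8]:
    motifs = ",".join(sorted(row.motifs)) or "-"
    print(f"  np {row.np:>5}  {row.base}  {row.rate_pct:6.3f}%  "
          f"{row.adjacent_sequence:<16} {motifs}")

found = {row.np for row in report.rows}
print(f"\nplanted hotspots {sorted(planted)} recovered: "
      f"{sorted(found & set(planted))}")
print(
    "\nThe per-base averages near 0.013% (they sum to the 0.05% injected\n"
    "per-read error) are the background noise floor, far below the 2%\n"
    "reporting threshold.  The planted positions stand out an order of\n"
    "magnitude above it, sitting next to homopolymeric C context.  On real\n"
    "data true heteroplasmy below 50% also enters this conservative\n"
    "estimate, deliberately inflating the profile rather than missing noise."
)
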