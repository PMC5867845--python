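"""Germline-bottleneck drift: why mother and child heteroplasmy frequencies
diverge, and how the bottleneck size controls it.

Pushes a 30% founder heteroplasmy through bottlenecks of different effective
sizes (10,000 replicate transmissions each) and prints the drift statistics
against the binomial closed form, plus how often the variant fixes or is
lost outright in a single generation.
"""
import numpy as np

from mthet import bottleneck_frequencies

rng = np.random.default_rng(8)
founder = 0.30
reps = 10_000

print(f"founder frequency {founder:.0%}, {reps} replicate transmissions\n")
print(f"{'bottleneck N':>12} {'mean child freq':>16} {'sd (obs)':>10} "
      f"{'sd (theory)':>12} {'lost':>7} {'fixed':>7}")
for N in (1, 3, 9, 35, 200):
    freqs = bottleneck_frequencies(founder, reps, N, rng)
    sd_theory = np.sqrt(founder * (1 - founder) / N)
    print(f"{N:>12} {freqs.mean():>15.3f} {freqs.std():>10.3f} "
          f"{sd_theory:>12.3f} {(freqs == 0).mean():>6.1%} {(freqs == 1).mean():>6.1%}")

print(
    "\nDrift is unbiased (the mean stays at the founder frequency) but its\n"
    "spread scales as sqrt(f(1-f)/N): a bottleneck near 9 copies routinely\n"
    "moves a 30% variant by +/-15 points in one generation - and can fix or\n"
    "lose it - which is exactly what makes heteroplasmy informative for\n"
    "distinguishing maternal relatives."
)
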