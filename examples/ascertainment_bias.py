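"""How discovery bias inflates the apparent frequency of disease mutations.

A recessive lethal mutation is only recognised clinically once an affected
homozygote is seen, which is far more likely for mutations that happen to
drift to higher frequencies — especially in populations with consanguinity.
This script simulates a pool of CpG-transition sites (the most mutable
class, u = 1.12e-7) under the out-of-Africa demography, then asks: what
fraction of those mutations would a discovery study find, and how much higher
is the mean frequency of the discovered subset?
"""

import numpy as np

from lethalpop import (
    AscertainmentConfig,
    SiteConfig,
    ascertainment_experiment,
    p_ascertain,
    rescaled_tennessen,
    simulate_site,
)

# pool of present-day European frequencies for CpG transitions
model = rescaled_tennessen(1.0)  # the unrescaled history behind the reference table
cfg = SiteConfig(u=1.12e-7, sigma=0.57, rate_mode="lognormal",
                 replicates=20_000, seed=7)
pool = simulate_site(model, cfg).q_EUR.to_numpy()
print(f"simulated {pool.size:,} CpG-transition sites: mean q = {pool.mean():.3g}, "
      f"{np.mean(pool > 0):.1%} segregating")

print(f"\n{'study n_a':>10} {'F_a':>6} {'P(ascertained)':>15} {'fold q_a/q_u':>13}")
rng = np.random.default_rng(1)
for n_a, F_a in [(10_000, 1 / 16), (10_000, 1 / 8), (100_000, 1 / 8), (500_000, 1 / 8)]:
    res = ascertainment_experiment(pool, AscertainmentConfig(n_a=n_a, F_a=F_a), rng)
    print(f"{n_a:>10,} {F_a:>6.4f} {res.P_asc:>15.4f} {res.fold:>13.1f}")

print("\nLarger or more inbred discovery studies ascertain more mutations")
print("(reference: 0.015 -> 0.186 across these designs for CpG transitions),")
print("and the more complete the discovery, the smaller the upward bias in")
print("the mean frequency of known mutations (reference fold 27.6 -> 5.2).")
print(f"\nClosed form at the mean frequency: P_asc(q=7.1e-6, F=1/16, n=10^4) = "
      f"{p_ascertain(7.10e-6, 1 / 16, 10_000):.2e}")
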