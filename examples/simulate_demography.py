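"""Forward-simulate a recessive lethal site through the out-of-Africa
demography and compare the present-day European frequency with theory.

Runs 20,000 replicates (a few minutes' worth at full precision takes ~400k;
this is a quick look) of a single site at the mean exonic mutation rate with
lognormal rate heterogeneity, under the mutation-rate-rescaled two-population
demographic model: 10*Ne burn-in, African size change, out-of-Africa split
with a European bottleneck, two-stage European growth and two-way gene flow.
"""

import numpy as np

from lethalpop import (
    MSBParams,
    SelectionParams,
    SiteConfig,
    equivalent_constant_N,
    mean_freq_finite_exact,
    rescaled_tennessen,
    simulate_site,
)

model = rescaled_tennessen()
print(f"model: {model.name}")
print(f"  burn-in: {model.burnin_generations:,} generations at Ne = {model.burnin_ne:,}")
print(f"  explicit history: {model.history_length:,.0f} generations, "
      f"split {model.split_gen:,.0f} generations ago")

cfg = SiteConfig(u=1.5e-8, sigma=0.57, rate_mode="lognormal",
                 replicates=20_000, seed=42)
df = simulate_site(model, cfg, SelectionParams(s=1.0, h=0.0))

mean = df.q_EUR.mean()
se = df.q_EUR.std() / np.sqrt(len(df))
nei = mean_freq_finite_exact(MSBParams(u=cfg.u, s=1.0, N=20_000))

print(f"\nreplicates: {len(df):,}  (u = {cfg.u:g}, lognormal spread sigma = {cfg.sigma})")
print(f"mean European frequency  : {mean:.3g} +/- {se:.2g}   (reference value 7.10e-6)")
print(f"segregating in Europe    : {df.segregating.mean():.1%} of replicates")
print(f"mean African frequency   : {df.q_AFR.mean():.3g}")
print(f"ratio to constant-N=20k  : {mean / nei:.2f}   (reference ~1.33)")
print(f"equivalent constant size : {equivalent_constant_N(mean, cfg.u, 1.0):,} diploids "
      "(reference 35,651)")
print("\nRecent growth lets lethal recessives drift slightly higher than the")
print("long-term effective size would suggest, but the mean stays ~17x below")
print("the infinite-population equilibrium of 1.22e-4.")
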