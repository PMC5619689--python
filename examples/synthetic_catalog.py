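"""Build a synthetic disease-variant catalog and test it against expectation.

Generates per-class frequency pools under a small constant-size demography,
assembles a 417-SNV catalog in two 'worlds' — null (catalog mutations are a
fair draw from all mutations) and ascertained (catalog mutations are ones a
100,000-person discovery study with F = 1/8 would have found) — applies the
QC filters, and compares each class's observed mean sample frequency with its
simulated null distribution.  The ascertained world reproduces the study's
headline pattern: observed means sit above expectation, more so for less
mutable classes.
"""

import numpy as np

from lethalpop import (
    AscertainmentConfig,
    MUTATION_CLASSES,
    SiteConfig,
    apply_site_filters,
    constant_size_model,
    generate_catalog,
    mean_freq_test,
    simulate_site,
)

model = constant_size_model(8_000)
pools = {}
for i, cls in enumerate(MUTATION_CLASSES.values()):
    cfg = SiteConfig(u=cls.rate, sigma=0.57, replicates=20_000, seed=100 + i)
    pools[cls.name] = simulate_site(model, cfg).q_EUR.to_numpy()
    print(f"pool {cls.name:>9} (u={cls.rate:.3g}): mean q = {pools[cls.name].mean():.3g}")

chroms = 65_762
asc = AscertainmentConfig(n_a=100_000, F_a=1 / 8, sample_chromosomes=chroms)

for world in ("null", "ascertained"):
    catalog = generate_catalog(pools, world=world, asc_cfg=asc, AN=chroms,
                               rng=np.random.default_rng(5))
    kept, report = apply_site_filters(catalog)
    print(f"\n=== {world} world: {len(catalog)} variants, QC removed {report} ===")
    print(f"{'class':>9} {'K':>4} {'observed':>10} {'expected':>10} {'fold':>6} {'p':>8}")
    rng = np.random.default_rng(6)
    for cls in MUTATION_CLASSES:
        sub = kept[kept.mutation_class == cls]
        res = mean_freq_test((sub.AC / sub.AN).to_numpy(), pools[cls],
                             chroms=chroms, R=2_000, rng=rng, mutation_class=cls)
        print(f"{cls:>9} {res.K:>4} {res.observed_mean:>10.3g} "
              f"{res.expected_mean:>10.3g} {res.fold:>6.2f} {res.p_two_tailed:>8.3g}")

print("\nIn the null world most catalog variants are invisible in the sample")
print("(frequencies are tiny), folds scatter around 1 and p-values are")
print("unremarkable.  In the ascertained world every class is inflated, and")
print("the inflation is strongest for the least mutable classes — discovery")
print("bias alone produces the observed-vs-expected pattern.")
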