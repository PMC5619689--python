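"""Gene-level simulation: compound heterozygotes as homozygote-equivalents.

When any two lethal alleles of the same gene fail to complement, the combined
frequency of all lethal alleles in the gene follows single-locus dynamics
with the summed mutation rate U = sum(u_j).  This script simulates a gene
with eight known lethal sites, places an 'observed' combined frequency in the
simulated distribution, and reports the two-tailed empirical p-value and the
fraction of simulations in which no allele would be seen in an exome sample.
"""

import numpy as np

from lethalpop import (
    GeneConfig,
    constant_size_model,
    gene_level_test,
    simulate_gene,
)

site_rates = (1.12e-7, 9.59e-9, 9.59e-9, 6.18e-9, 6.18e-9, 3.76e-9, 3.76e-9, 3.76e-9)
model = constant_size_model(8_000)
cfg = GeneConfig(site_rates=site_rates, sigma=0.57, replicates=1_000, seed=11)

df = simulate_gene(model, cfg)
print(f"gene with {len(site_rates)} lethal sites, summed mean rate "
      f"U = {sum(site_rates):.3g}")
print(f"1,000 simulations: mean combined frequency {df.q_EUR.mean():.3g}, "
      f"{df.segregating.mean():.1%} segregating")

observed = 5e-4  # a gene whose known lethal alleles sum to 5e-4 in the sample
res = gene_level_test(observed, df.q_EUR.to_numpy(), gene="EXAMPLE",
                      rng=np.random.default_rng(3))
print(f"\nobserved combined sample frequency : {observed:g}")
print(f"expected (simulated) mean          : {res.expected_mean:.3g}")
print(f"two-tailed empirical p-value       : {res.p_two_tailed:.3g}")
print(f"zero-allele fraction in simulations: {res.zero_fraction:.2f}")
print("\nWith 1,000 simulations the smallest reportable p-value is 2/1001;")
print("genes whose observed combined frequency exceeds every simulation are")
print("reported as p < 0.004 (r = 1 band).")
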