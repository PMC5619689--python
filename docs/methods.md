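# Methods

`lethalpop` models the population genetics of mutations that cause recessive,
lethal Mendelian disease: how frequent such mutations should be under
mutation–selection balance, how demographic history and mutation-rate
heterogeneity shape that expectation, and how clinical discovery bias
distorts the set of mutations we actually know about. This note records the
models, the defaults and why they were chosen, the numerical design of the
simulator, and what the synthetic data can and cannot establish.

## The selection model

Every analysis assumes a bi-allelic site with wild-type allele A and
deleterious allele a, genotype fitnesses

    w_AA = 1,   w_Aa = 1 − h·s,   w_aa = 1 − s,

one-way recurrent mutation A→a at rate `u` per gamete per generation, and no
back-mutation. The headline case is the recessive lethal: `s = 1`, `h = 0`.
Gene-level analyses treat all lethal alleles of a gene as one pooled allele
class: compound heterozygotes are assumed as unfit as homozygotes (no
complementation), which makes the pooled frequency follow single-locus
dynamics with the summed rate `U = Σ u_j`.

## Analytic module (`analytic`)

Closed forms for constant-size populations, h = 0 only:

* infinite population: q* = √(u/s);
* finite diploid size N (diffusion): q̄ = Γ(2Nu + ½)/(√(2Ns)·Γ(2Nu)),
  σ²_q = u/s − q̄²; for 2Nu ≪ 1, q̄ ≈ u·√(2πN/s).

The exact mean is evaluated in log-gamma space (`scipy.special.gammaln`)
because 2Nu spans many orders of magnitude across use cases and Γ(2Nu)
overflows already at 2Nu ≈ 100 in double precision. `equivalent_constant_N`
inverts the low-2Nu mean, N = q̄²s/(2πu²): it answers "what constant
population size would produce this mean frequency", and raises for
q̄ ≥ √(u/s), where no finite size can. Functions raise for h ≠ 0 rather than
silently approximating — there is no comparably standard closed form with
dominance, and the simulator covers that case. Violated approximation
preconditions (2Nu > 0.1 for the low-mutation form) warn instead of raising,
since exploratory sweeps legitimately cross the boundary.

## Demographic model (`demography`)

The reference history is the two-population (African/European) out-of-Africa
model of Tennessen et al. (2012), built on Gravel et al. (2011): an ancestral
population of 7,310 diploids, growth to 14,474 at 5,920 generations before
present, a European split 2,040 generations ago through a bottleneck of
1,861, a second bottleneck to 1,032 with slow growth (0.307%/generation)
from 920 generations ago, accelerated growth (1.95%/generation, Africa
1.66%) from 204.6 generations ago, and symmetric migration (1.5e-4 per
generation between Africa and the out-of-Africa branch, 2.5e-5 thereafter).
These base parameters ship as a versioned JSON file
(`lethalpop/data/tennessen2012.json`) rather than constants in code.

That model was inferred assuming a mutation rate of 2.36e-8 per bp per
generation; direct pedigree estimates are about half that. Because
polymorphism data identify only the products N·u, m·N and ratios t/N,
adopting the lower rate means **rescaling**: sizes and durations multiplied
by c, per-generation rates (growth, migration) divided by c, preserving each
epoch's cumulative effect. The default is c = 2.36/1.2 ≈ 1.9667, which
reproduces the published rescaled African-change time of 11,643 generations;
the burn-in/ancestral size is pinned to the published 14,328 diploids at the
default c (the published value is not exactly 7,310·c for any single c; we
follow the printed numbers and expose both knobs). Derived present-day sizes
are ≈983k (Europe) and ≈847k (Africa) diploids — within 2.5% of c×512,000 and
c×424,000; the small gap is inherited from rounding in the published growth
rates, which we keep as primary parameters.

Epochs are half-open intervals [start, end) in generations before present;
nominal sizes may be fractional and are rounded to the nearest integer
generation by generation, exactly as the simulator consumes them.
`variant_model` builds stronger-growth variants (present European size
multiplied 2–10×, with the final growth rate re-solved; or growth starting
immediately at the bottleneck exit), and `constant_size_model` wraps a
single constant population for oracle comparisons.

## Forward simulator (`simulate`)

Each replicate is one site (or pooled gene) evolving through: a burn-in of
10·Ne generations at the burn-in size starting from the wild-type fixed
(long enough that segregating-allele statistics equilibrate well before the
first demographic event), then the explicit history. Per generation the
order of events is **mutation → selection → migration → drift**:

1. mutation: q_m = q + (1 − q)·M, applied deterministically to the gamete
   pool — at M·2N ≪ 1 this is distributionally indistinguishable from
   sampling mutation events, and drift sampling follows immediately;
2. viability selection on random-union genotypes:
   q_s = [q_m²(1−s) + q_m(1−q_m)(1−hs)] / w̄; the degenerate corner w̄ = 0
   (q_m = 1, s = 1) resolves to q_s = 0, i.e. a population consisting solely
   of lethal homozygotes loses the allele;
3. migration: deterministic symmetric mixing
   q_i ← (1−m)q_i + m·q_j once per generation;
4. drift: allele count ~ Binomial(2N_next, q_s) at the offspring
   generation's (rounded) size.

The split is instantaneous: both daughter populations inherit the ancestral
frequency, and drift immediately proceeds at their own sizes.

**Mutation-rate heterogeneity.** Within a mutation class, per-site rates
vary (sequence context beyond the dinucleotide, replication timing, …). Each
replicate draws its rate M from a lognormal,
log10 M ~ Normal(log10 u − (σ²/2)·ln 10, σ²), mean-preserving by
construction (E[M] = u); σ defaults to 0.57 log10 units. Gene-level runs
draw each site's u_j independently and sum.

**Event-driven implementation.** At human mutation rates a replicate spends
the overwhelming majority of its ~155,000 generations with zero copies of
the allele. The engine therefore separates *dormant* replicates (zero copies
in every population) from *active* ones. A dormant replicate's waiting time
to its next mutation arrival is sampled exactly: the probability of staying
dormant through a set of generations is Π_t (1−q_s0)^{2N_t} =
exp(log(1−q_s0)·Σ_t 2N_t), so one standard-exponential draw plus a binary
search of the cumulative-2N array yields the exact arrival generation, even
through size changes; the arriving copy count is a zero-truncated binomial
(inverse-CDF over k ≤ 12; the neglected tail is < 1e-12 at these rates).
With two populations, independent per-population arrival times are drawn and
the earlier one wakes the replicate (exact, because for a dormant replicate
migration mixes two equal frequencies and the two populations' arrival
processes are independent). Active replicates are updated with vectorised
binomial draws each generation. This is a sampling scheme for the same
process, not an approximation; `tests/test_simulator.py` verifies
distributional agreement with naive generation-by-generation iteration, and
an exact 21-state Markov-chain oracle (2N = 20, scaled-up u) pins the
stationary mean to within 2%.

**Treatment scenario.** Modern medicine is modelled as s → 0 in the final
`treatment_generations` generations (default window 3 when used).
`paired_treatment_comparison` runs the shared history once, snapshots the
state and the RNG state three generations before present, and finishes twice
(s as configured vs s = 0) — a paired design with common random histories,
so the contrast is not swamped by between-run noise. Replicates are split
into groups to give independent repetitions of the comparison.

**Determinism.** All randomness flows from one seed through numpy
`SeedSequence` spawning; identical config + seed gives identical output, and
multi-part runs give each part an independent child seed.

## Ascertainment model (`ascertainment`)

A recessive lethal mutation is discovered only when an affected (aa)
homozygote is observed. With inbreeding coefficient F, genotype
probabilities are P(aa) = F·q + (1−F)q², P(Aa) = (1−F)·2q(1−q), remainder
AA; a survey of n_a unrelated individuals therefore ascertains the mutation
with probability P_asc = 1 − (1 − P(aa))^{n_a}, increasing in q, F and n_a.
Evaluation uses `expm1`/`log1p` since P(aa) is ~1e-7 in the regime of
interest.

`ascertainment_experiment` applies this to a pool of simulated population
frequencies: each mutation is marked discovered by a single Bernoulli draw
with the closed-form probability (distributionally identical to sampling
n_a genotypes and orders of magnitude faster; an explicit genotype-sampling
mode is retained for validation), all frequencies are Poisson-sampled to a
modern reference panel of 65,762 chromosomes, and the mean sample frequency
of the discovered subset (q_a) is compared with the mean over all mutations
(q_u). The fold q_a/q_u is the discovery bias. Because P_asc rises with the
mutation rate (higher-rate classes sit at higher frequencies), the bias is
largest for the least mutable classes — the inverse fold-vs-rate ordering
that the package's catalog-level tests reproduce qualitatively.

The reference discovery-bias table is reproduced from pools generated under
the **unrescaled** Tennessen history with lognormal rates: that is the
setting that matches the published table cell-for-cell (verified for all
ten CpG-transition cells), whereas rescaled-model pools give systematically
~2× higher discovery probabilities and ~2× lower folds. The experiment API
is pool-agnostic, so either demography can be fed in.

## Comparison statistics (`compare`)

Sample allele counts are Poisson(q·2n) truncated at 2n — the standard
rare-allele approximation to binomial sampling of 2n chromosomes; 2n
defaults to 65,762 (= 2×32,881 covered individuals). For a class with K
observed mutations, the null distribution of the class mean is built by
drawing K pool frequencies and Poisson-sampling each, R times. The empirical
two-tailed p-value is

    p = min(1, 2·min(n_ge + 1, n_le + 1)/(R + 1)),

with ties counted as extreme. When the observed mean lies above the null
median — the only regime in which small p-values are reported here — this
equals the one-sided doubled form 2(r+1)/(R+1) with r the number of null
means at least as large; taking the smaller tail and capping at 1 makes the
test properly two-sided and calibrated at its nominal level under the null
(verified by a calibration test at the 5% level). Gene-level comparisons do
the same with R simulated combined frequencies (the smallest reportable p
at R = 1000 is 2/1001, hence the "p < 0.004" band when r = 1), and also
report the fraction of simulations with an empty sample. Fisher's combined
probability test (−2Σln p against χ²_{2k}) aggregates genes via
`scipy.stats`.

The fold reported by `mean_freq_test` divides the observed mean by the
*mean* of the null means; using the median instead would raise folds by the
mean/median ratio of the null (a few percent at the Ks used here, larger
for very small K).

## Synthetic catalogs (`catalog`)

`generate_catalog` emulates the statistical structure of a hand-curated set
of reported recessive-lethal SNVs with exome frequencies: per class it draws
population frequencies from a simulated pool (either fairly — the "null"
world — or restricted by the discovery model — the "ascertained" world),
Poisson-samples allele counts at AN chromosomes, attaches a sequence context
consistent with the class, and injects QC artifacts at configurable
fractions (homozygote carriers 3/417, low coverage 29/417, CpG-island flags
on 12/122 CpG transitions — mirroring the real set's filter yield: 417 →
385 after homozygote and coverage filters, → 373 after the CpG-island
exclusion). Mutation classes come from the immediate context:
CpG iff ref C is followed by G or ref G preceded by C (strand-symmetric);
transition iff A↔G or C↔T; class rates default to the pedigree estimates
CpGti 1.12e-7, CpGtv 9.59e-9, nonCpGti 6.18e-9, nonCpGtv 3.76e-9 (CpG
transitions ~17× the mean of the rest).

The default composition (122/25/145/125 over CpGti/CpGtv/nonCpGti/nonCpGtv)
is **synthetic**: only the CpGti share (29.3% of 417) is reported for the
real set; the split of the remainder is a package choice favouring
transitions, as disease catalogs do, and is config. What passing tests on
these catalogs show is that the *pipeline* behaves correctly (null catalogs
are calibrated; ascertained catalogs reproduce the inverse fold-vs-rate
ordering); they cannot validate the real set's composition, its true
frequencies, gene assignments, or any clinical-curation step, and linkage,
population substructure, genotyping error and coverage-frequency
correlations present in real exome data are not modelled.

## Replicate counts and tolerances

The replicate-level standard deviation of the present-day European frequency
at u = 1.5e-8 is ≈7e-5 — an order of magnitude above the mean of ≈7e-6,
because the distribution is a spike at 0 plus rare high-frequency
excursions. Monte-Carlo standard errors of the mean are therefore
≈ 10/√R relative: ~1.6% at the 400,000 replicates used for the headline
mean (and ~3.2% on the equivalent constant N, which scales as the square of
the mean), ~4.5% at the 50,000-replicate scale. Pool-level ascertainment
quantities are much better behaved (P_asc has SE < 1% at 60,000 draws; the
fold's SE is a few percent, driven by the ~1,500 ascertained mutations).
The default acceptance-script scale (400k/150k/120k replicates for the three
runs) keeps every Monte-Carlo standard error several times smaller than the
loosest published precision of the corresponding quantity; the test suite
uses the same 400k run plus 60k-replicate pools. Reaching ±2.5% (2σ) on the
headline mean — what a ±5% band on the equivalent constant N demands — would
require ~2×10⁶ replicates, which is the scale the original analyses used.

## Known limitations

* Single bi-allelic site; no linkage, recombination, background selection,
  or interference between genes. Gene-level pooling assumes complete
  non-complementation and ignores undiscovered lethal sites in the gene, so
  simulated gene-level expectations are upper bounds.
* The European sample is treated as panmictic; substructure (Wahlund
  excess of homozygotes) would lower real expectations further.
* Migration rates for the rescaled history are taken from the underlying
  published model (they are config, not re-inferred).
* The ascertainment model describes a single idealised discovery study per
  mutation and excludes compound-heterozygote ascertainment, pedigree
  structure and publication history.
* Poisson sampling of allele counts is a rare-allele approximation; at
  q approaching 1 it undercounts relative to binomial sampling (irrelevant
  at disease-allele frequencies).
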