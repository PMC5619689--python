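"""Observed-vs-expected comparison statistics for disease-allele catalogs.

Simulated population frequencies are matched to an exome-style sample by
Poisson sampling of allele counts (count ~ Poisson(q * 2n), truncated at 2n).
For a mutation class with K observed mutations, the null distribution of the
class mean sample frequency is built by repeatedly drawing K population
frequencies from the simulated pool and Poisson-sampling each; the observed
mean is then placed in that distribution with an empirical two-tailed
p-value p = min(1, 2 * min(n_ge + 1, n_le + 1) / (R + 1)), where n_ge / n_le
count null means at least as large / small as the observed one.  Whenever the
observed mean exceeds the null median — the regime of interest for inflated
disease-allele frequencies — this is exactly 2 (r + 1) / (R + 1) with r the
number of null means >= the observed mean, and the capped, two-sided form is
calibrated at its nominal level under the null.

Gene-level comparisons place an observed combined (summed) allele frequency
in the distribution of Poisson-sampled simulated combined frequencies, also
reporting the fraction of simulations where no allele would have been seen in
the sample.  Fisher's combined probability test aggregates per-gene p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ClassComparison",
    "GeneComparison",
    "sample_allele_count",
    "empirical_two_tailed_p",
    "mean_freq_test",
    "gene_level_test",
    "fisher_combined",
]

#: 2 x 32,881: twice the mean number of covered individuals in the reference
#: exome sample, the default number of chromosomes for sample frequencies.
DEFAULT_CHROMOSOMES = 65_762


@dataclass(frozen=True)
class ClassComparison:
    """Observed vs simulated mean sample frequency for one mutation class."""

    mutation_class: str
    K: int
    observed_mean: float
    expected_mean: float
    fold: float
    p_two_tailed: float
    null_means: np.ndarray

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")


@dataclass(frozen=True)
class GeneComparison:
    """Observed vs simulated combined lethal-allele frequency for one gene."""

    gene: str
    observed_combined_freq: float
    expected_mean: float
    p_two_tailed: float
    zero_fraction: float
    null_freqs: np.ndarray


def sample_allele_count(q, chroms: int, rng: np.random.Generator):
    """Sample allele count(s) in ``chroms`` chromosomes at population
    frequency ``q``: Poisson(q * chroms), truncated at chroms."""
    if chroms < 2:
        raise ValueError("chroms must be >= 2")
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("q must be in [0, 1]")
    return np.minimum(rng.poisson(q * chroms), chroms)


def empirical_two_tailed_p(observed: float, null: np.ndarray) -> float:
    """Capped empirical two-tailed p-value of ``observed`` within ``null``.

    p = min(1, 2 * min(n_ge + 1, n_le + 1) / (R + 1)); ties count as extreme
    on both sides.
    """
    null = np.asarray(null, dtype=float)
    R = null.size
    if R < 1:
        raise ValueError("null distribution must be non-empty")
    n_ge = int(np.count_nonzero(null >= observed))
    n_le = int(np.count_nonzero(null <= observed))
    return min(1.0, 2.0 * (min(n_ge, n_le) + 1) / (R + 1))


def mean_freq_test(
    observed_freqs,
    sim_pool,
    chroms: int = DEFAULT_CHROMOSOMES,
    R: int = 100_000,
    rng: np.random.Generator | None = None,
    mutation_class: str = "",
) -> ClassComparison:
    """Compare a class's observed mean sample frequency with simulation.

    ``observed_freqs``: the K observed sample frequencies of the class;
    ``sim_pool``: simulated population frequencies for the class (much larger
    than K).  Builds R null means, each the average of K pool draws
    Poisson-sampled at ``chroms`` chromosomes, and reports the fold increase
    (observed mean over null-mean average) and the empirical two-tailed p.
    """
    if rng is None:
        rng = np.random.default_rng()
    obs = np.asarray(observed_freqs, dtype=float)
    K = obs.size
    if K == 0:
        raise ValueError("need at least one observed mutation (K >= 1)")
    pool = np.asarray(sim_pool, dtype=float)
    if pool.size < K:
        raise ValueError("simulation pool smaller than the observed set")
    if R < 1:
        raise ValueError("R must be >= 1")

    draws = pool[rng.integers(0, pool.size, size=(R, K))]
    counts = np.minimum(rng.poisson(draws * chroms), chroms)
    null_means = counts.mean(axis=1) / chroms

    observed_mean = float(obs.mean())
    expected_mean = float(null_means.mean())
    return ClassComparison(
        mutation_class=mutation_class,
        K=K,
        observed_mean=observed_mean,
        expected_mean=expected_mean,
        fold=observed_mean / expected_mean if expected_mean > 0 else float("inf"),
        p_two_tailed=empirical_two_tailed_p(observed_mean, null_means),
        null_means=null_means,
    )


def gene_level_test(
    observed_combined: float,
    gene_sims,
    chroms: int = DEFAULT_CHROMOSOMES,
    rng: np.random.Generator | None = None,
    gene: str = "",
) -> GeneComparison:
    """Compare a gene's observed combined lethal-allele sample frequency with
    simulated combined frequencies (one per gene-level replicate).

    Each simulated population frequency is Poisson-sampled at ``chroms``;
    ``zero_fraction`` is the share of simulations in which no deleterious
    allele would have been seen in the sample at all.
    """
    if rng is None:
        rng = np.random.default_rng()
    sims = np.asarray(gene_sims, dtype=float)
    if sims.size == 0:
        raise ValueError("need at least one gene-level simulation")
    counts = sample_allele_count(sims, chroms, rng)
    null = counts / chroms
    return GeneComparison(
        gene=gene,
        observed_combined_freq=float(observed_combined),
        expected_mean=float(null.mean()),
        p_two_tailed=empirical_two_tailed_p(float(observed_combined), null),
        zero_fraction=float(np.mean(counts == 0)),
        null_freqs=null,
    )


def fisher_combined(p_values) -> tuple[float, float]:
    """Fisher's combined probability test across independent p-values.

    Returns (statistic, combined p) with statistic = -2 sum(ln p), referred to
    a chi-square distribution with 2k degrees of freedom.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]; cap empirical p's upstream")
    stat, combined = stats.combine_pvalues(p, method="fisher")
    return float(stat), float(combined)
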