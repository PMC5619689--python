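"""Discovery (ascertainment) bias for recessive lethal mutations.

A recessive disease mutation can only be recognised clinically if at least
one affected homozygote is observed.  In a discovery population with average
inbreeding coefficient F, a mutation at population frequency q produces
homozygotes with probability P(aa) = F q + (1 - F) q^2, so a survey of n
unrelated individuals ascertains it with probability

    P_asc = 1 - (1 - P(aa))^n = 1 - [(1 - q)(1 + q - F q)]^n,

an increasing function of q, F and n.  Because P_asc increases with q, the
mutations that have been discovered are a frequency-biased sample of all
existing ones: ``ascertainment_experiment`` quantifies that bias over a pool
of simulated population frequencies, reporting the ascertained fraction and
the fold increase of the mean (Poisson-sampled) sample frequency of the
ascertained subset over the mean across the whole pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compare import sample_allele_count

__all__ = [
    "AscertainmentConfig",
    "AscertainmentSummary",
    "genotype_probs",
    "p_ascertain",
    "ascertainment_experiment",
]


@dataclass(frozen=True)
class AscertainmentConfig:
    """Putative discovery-study design.

    ``n_a``: individuals surveyed; ``F_a``: their average inbreeding
    coefficient (1/16 = offspring of first cousins); ``sample_chromosomes``:
    2n of the modern reference panel used to estimate sample frequencies
    afterwards (default matches 32,881 sequenced individuals).
    """

    n_a: int
    F_a: float
    sample_chromosomes: int = 65_762

    def __post_init__(self) -> None:
        if self.n_a < 1:
            raise ValueError("n_a must be >= 1")
        if not 0.0 <= self.F_a <= 1.0:
            raise ValueError("F_a must be in [0, 1]")
        if self.sample_chromosomes < 2:
            raise ValueError("sample_chromosomes must be >= 2")


@dataclass(frozen=True)
class AscertainmentSummary:
    """Outcome of one simulated discovery experiment over a frequency pool.

    ``fold`` is q_a / q_u (mean sample frequency of ascertained mutations over
    the mean across all mutations); NaN when nothing was ascertained.
    """

    P_asc: float
    q_u: float
    q_a: float
    fold: float
    n_pool: int
    n_ascertained: int


def genotype_probs(q, F):
    """Genotype probabilities (P(AA), P(Aa), P(aa)) at deleterious-allele
    frequency ``q`` under inbreeding coefficient ``F``."""
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("q must be in [0, 1]")
    if np.any((np.asarray(F) < 0) | (np.asarray(F) > 1)):
        raise ValueError("F must be in [0, 1]")
    p = 1.0 - q
    paa = F * q + (1.0 - F) * q * q
    pab = (1.0 - F) * 2.0 * q * p
    return 1.0 - pab - paa, pab, paa


def p_ascertain(q, F, n):
    """Probability that a survey of ``n`` unrelated individuals with
    inbreeding coefficient ``F`` contains at least one aa homozygote.

    Evaluated as -expm1(n log1p(-P(aa))) for accuracy at the tiny P(aa)
    typical of lethal recessives.  Vectorised over ``q``.
    """
    if np.any(np.asarray(n) < 1):
        raise ValueError("n must be >= 1")
    _, _, paa = genotype_probs(q, F)
    return -np.expm1(n * np.log1p(-paa))


def ascertainment_experiment(
    freqs,
    cfg: AscertainmentConfig,
    rng: np.random.Generator,
    mode: str = "bernoulli",
) -> AscertainmentSummary:
    """Simulate mutation discovery over a pool of population frequencies.

    Each mutation is marked ascertained either by one Bernoulli draw with the
    closed-form probability (``mode='bernoulli'``, the default) or by
    explicitly sampling the number of homozygotes among ``cfg.n_a`` surveyed
    genotypes (``mode='genotype'``); the two are distributionally identical,
    the second existing for validation.  All frequencies (ascertained or not)
    are then Poisson-sampled down to ``cfg.sample_chromosomes`` chromosomes,
    and the mean sample frequencies q_u (all) and q_a (ascertained subset)
    are compared.
    """
    q = np.asarray(freqs, dtype=float)
    if q.ndim != 1 or q.size == 0:
        raise ValueError("freqs must be a non-empty 1-d array of frequencies")
    if mode == "bernoulli":
        ascertained = rng.random(q.size) < p_ascertain(q, cfg.F_a, cfg.n_a)
    elif mode == "genotype":
        _, _, paa = genotype_probs(q, cfg.F_a)
        ascertained = rng.binomial(cfg.n_a, paa) > 0
    else:
        raise ValueError(f"mode must be 'bernoulli' or 'genotype', got {mode!r}")

    counts = sample_allele_count(q, cfg.sample_chromosomes, rng)
    sample_freq = counts / cfg.sample_chromosomes
    q_u = float(sample_freq.mean())
    n_asc = int(ascertained.sum())
    if n_asc == 0:
        q_a = float("nan")
        fold = float("nan")
    else:
        q_a = float(sample_freq[ascertained].mean())
        fold = q_a / q_u if q_u > 0 else float("nan")
    return AscertainmentSummary(
        P_asc=n_asc / q.size,
        q_u=q_u,
        q_a=q_a,
        fold=fold,
        n_pool=q.size,
        n_ascertained=n_asc,
    )
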