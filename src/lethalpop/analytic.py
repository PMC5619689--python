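"""Closed-form mutation-selection balance for recessive deleterious alleles.

Two classical results are implemented for a bi-allelic site with genotype
fitnesses w_AA = 1, w_Aa = 1 - h*s, w_aa = 1 - s and one-way mutation at rate
``u`` per gamete per generation:

* Wright's deterministic equilibrium in an infinite population,
  q = sqrt(u/s) for a fully recessive allele (h = 0).
* Nei's diffusion results for a finite Wright-Fisher population of diploid
  size N: the mean frequency  q̄ = Γ(2Nu + 1/2) / (sqrt(2Ns) Γ(2Nu))  and the
  variance  σ_q² = u/s − q̄².  In the low population-mutation-rate regime
  (2Nu << 1) the mean reduces to  q̄ ≈ u sqrt(2πN/s).

Only the fully recessive closed forms are available (no analytic theory is
implemented for h > 0); functions raise for h != 0 rather than silently
approximating.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy.special import gammaln

__all__ = [
    "MSBParams",
    "eq_freq_infinite",
    "mean_freq_finite_exact",
    "var_freq_finite",
    "mean_freq_low_mut",
    "equivalent_constant_N",
]

#: 2Nu above which the low-mutation approximation is considered unreliable.
_LOW_MUT_WARN_THRESHOLD = 0.1


@dataclass(frozen=True)
class MSBParams:
    """Parameters of a single-site mutation-selection balance model.

    Parameters
    ----------
    u
        Per-base-pair, per-generation mutation rate toward the deleterious
        allele (a probability; 0 < u < 1).
    s
        Selection coefficient against the deleterious homozygote
        (0 < s <= 1; s = 1 means recessive lethal).
    h
        Dominance coefficient; heterozygote fitness is 1 - h*s.  The closed
        forms implemented here require h = 0.
    N
        Diploid effective population size (finite-population formulas only).
    """

    u: float
    s: float = 1.0
    h: float = 0.0
    N: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.u < 1.0:
            raise ValueError(f"mutation rate u must be in (0, 1), got {self.u}")
        if not 0.0 < self.s <= 1.0:
            raise ValueError(f"selection coefficient s must be in (0, 1], got {self.s}")
        if self.h < 0.0:
            raise ValueError(f"dominance coefficient h must be >= 0, got {self.h}")
        if self.N is not None and self.N < 1:
            raise ValueError(f"population size N must be >= 1, got {self.N}")

    def _require_recessive(self, what: str) -> None:
        if self.h != 0.0:
            raise ValueError(
                f"{what} is only available for fully recessive alleles (h = 0); "
                f"got h = {self.h}. Use the simulator for h > 0."
            )

    def _require_N(self, what: str) -> int:
        if self.N is None:
            raise ValueError(f"{what} requires a finite population size N")
        return self.N


def eq_freq_infinite(params: MSBParams) -> float:
    """Deterministic equilibrium frequency q = sqrt(u/s) in an infinite population."""
    params._require_recessive("the infinite-population equilibrium")
    return math.sqrt(params.u / params.s)


def mean_freq_finite_exact(params: MSBParams) -> float:
    """Nei's mean frequency of a recessive deleterious allele in a finite population.

    q̄ = Γ(2Nu + 1/2) / (sqrt(2Ns) Γ(2Nu)), evaluated in log-gamma space so
    that arbitrarily large 2Nu does not overflow.
    """
    params._require_recessive("Nei's finite-population mean")
    N = params._require_N("Nei's finite-population mean")
    theta = 2.0 * N * params.u
    log_qbar = gammaln(theta + 0.5) - gammaln(theta) - 0.5 * math.log(2.0 * N * params.s)
    return float(math.exp(log_qbar))


def var_freq_finite(params: MSBParams) -> float:
    """Variance of the frequency, σ_q² = u/s − q̄² (Nei's diffusion result)."""
    qbar = mean_freq_finite_exact(params)
    return params.u / params.s - qbar * qbar


def mean_freq_low_mut(params: MSBParams) -> float:
    """Low-mutation-rate (2Nu << 1) approximation q̄ = u sqrt(2πN/s).

    Warns (but still evaluates) when 2Nu exceeds 0.1, where the approximation
    degrades.
    """
    params._require_recessive("the low-mutation-rate mean")
    N = params._require_N("the low-mutation-rate mean")
    theta = 2.0 * N * params.u
    if theta > _LOW_MUT_WARN_THRESHOLD:
        warnings.warn(
            f"2Nu = {theta:.3g} > {_LOW_MUT_WARN_THRESHOLD}; the low-mutation "
            "approximation q̄ = u*sqrt(2πN/s) may be inaccurate",
            stacklevel=2,
        )
    return params.u * math.sqrt(2.0 * math.pi * N / params.s)


def equivalent_constant_N(qbar: float, u: float, s: float = 1.0) -> int:
    """Constant diploid size whose low-2Nu mean frequency equals ``qbar``.

    Inverts q̄ = u sqrt(2πN/s) to N = q̄² s / (2π u²), rounded to the nearest
    integer.  Raises if ``qbar`` is at or above the infinite-population
    equilibrium sqrt(u/s), where no finite size can produce it under the
    low-mutation approximation.
    """
    if qbar <= 0 or u <= 0 or s <= 0:
        raise ValueError("qbar, u and s must all be positive")
    if qbar >= math.sqrt(u / s):
        raise ValueError(
            f"mean frequency {qbar:.3g} >= sqrt(u/s) = {math.sqrt(u / s):.3g}: "
            "no finite constant population size matches it under the low-2Nu "
            "approximation"
        )
    return round(qbar * qbar * s / (2.0 * math.pi * u * u))
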