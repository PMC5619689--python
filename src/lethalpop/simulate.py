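"""Forward Wright-Fisher simulation of recessive lethal disease alleles.

Single bi-allelic site (or a pooled class of lethal alleles in one gene)
evolving under one-way recurrent mutation, viability selection, symmetric
migration and binomial drift, through a demographic history
(:mod:`lethalpop.demography`).  Genotype fitnesses are w_AA = 1,
w_Aa = 1 - h*s, w_aa = 1 - s; per generation the order of events is
mutation -> selection -> migration -> drift.  Simulations start with the
wild-type allele fixed and run a 10*Ne burn-in at the burn-in size before the
explicit demographic history.

Mutation-rate heterogeneity across sites is modelled by drawing each
replicate's rate M from a lognormal distribution,
log10 M ~ Normal(log10 u - (sigma^2/2) ln 10, sigma^2), whose mean is exactly
the class rate u.

Implementation note: at these mutation rates a replicate spends most of its
history with zero copies of the deleterious allele.  The engine therefore
keeps "dormant" replicates (no copies anywhere) out of the per-generation
arithmetic and schedules their next mutation arrival exactly: the probability
that a dormant replicate stays dormant through a set of generations is
prod_t (1 - q0)^(2N_t) = exp(log(1-q0) * sum_t 2N_t), so arrival generations
can be found by searching a cumulative-population-size array with a standard
exponential draw.  This is an exact sampling of the same process, not an
approximation; a test verifies distributional agreement with the naive
per-generation update.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demography import DemographicModel, size_at

__all__ = [
    "SelectionParams",
    "SiteConfig",
    "GeneConfig",
    "draw_mutation_rate",
    "wf_step",
    "migrate",
    "apply_treatment",
    "simulate_site",
    "simulate_gene",
    "paired_treatment_comparison",
]

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class SelectionParams:
    """Selection against the deleterious allele.

    ``treatment_generations`` forces s = 0 in that many final generations,
    emulating fully effective modern treatment of the disease.
    """

    s: float = 1.0
    h: float = 0.0
    treatment_generations: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 1.0:
            raise ValueError(f"s must be in [0, 1], got {self.s}")
        if self.h < 0.0 or self.h * self.s > 1.0:
            raise ValueError(f"need h >= 0 and h*s <= 1, got h={self.h}, s={self.s}")
        if self.treatment_generations < 0:
            raise ValueError("treatment_generations must be >= 0")


@dataclass(frozen=True)
class SiteConfig:
    """Configuration of a single-site simulation batch.

    ``u`` is the class mean mutation rate; with ``rate_mode='lognormal'`` each
    replicate draws its own rate M (spread ``sigma`` in log10 units, mean
    preserved), with ``'fixed'`` every replicate uses u exactly.
    """

    u: float
    sigma: float = 0.57
    rate_mode: str = "lognormal"
    replicates: int = 10_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.u <= 0:
            raise ValueError("mutation rate u must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.rate_mode not in ("fixed", "lognormal"):
            raise ValueError(f"rate_mode must be 'fixed' or 'lognormal', got {self.rate_mode!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class GeneConfig:
    """Gene-level simulation: per-site mean rates are drawn lognormally and
    summed into a total rate U per replicate (compound heterozygotes are
    assumed as fit as homozygotes, so the pooled-allele frequency follows the
    single-site machinery with rate U)."""

    site_rates: tuple[float, ...]
    sigma: float = 0.57
    rate_mode: str = "lognormal"
    replicates: int = 1_000
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "site_rates", tuple(self.site_rates))
        if len(self.site_rates) == 0:
            raise ValueError("gene-level simulation requires at least one site rate")
        if any(u <= 0 for u in self.site_rates):
            raise ValueError("all site rates must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def draw_mutation_rate(u: float, sigma: float, rng: np.random.Generator, size=None):
    """Draw site mutation rate(s) M with E[M] = u.

    log10 M ~ Normal(log10 u - (sigma^2 / 2) ln 10, sigma^2); the offset makes
    the arithmetic mean of M equal to u.  ``sigma = 0`` returns u exactly.
    """
    if u <= 0:
        raise ValueError("u must be positive")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return u if size is None else np.full(size, u, dtype=float)
    mu10 = math.log10(u) - sigma * sigma * _LN10 / 2.0
    return 10.0 ** rng.normal(mu10, sigma, size)


def _post_selection_freq(q_m, s: float, h: float):
    """Deleterious-allele frequency after viability selection on
    random-union genotypes at post-mutation frequency ``q_m``.

    The w̄ = 0 corner (q_m = 1 with s = 1) resolves to 0: every carrier is a
    lethal homozygote, so the allele is gone next generation.
    """
    q_m = np.asarray(q_m, dtype=float)
    p = 1.0 - q_m
    w_het = 1.0 - h * s
    w_hom = 1.0 - s
    het = q_m * p * w_het
    num = het + q_m * q_m * w_hom
    wbar = p * p + 2.0 * het + q_m * q_m * w_hom
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(wbar > 0.0, num / np.where(wbar > 0.0, wbar, 1.0), 0.0)
    return np.clip(out, 0.0, 1.0)


def wf_step(q, N_next: int, M, sel: SelectionParams, rng: np.random.Generator):
    """One Wright-Fisher generation: mutation, selection, binomial drift.

    Vectorised over ``q`` (and ``M`` if array-valued); returns the frequency
    in the next generation of 2*N_next chromosomes.
    """
    if N_next < 1:
        raise ValueError("N_next must be >= 1")
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    q_m = q + (1.0 - q) * np.asarray(M, dtype=float)
    q_s = _post_selection_freq(q_m, sel.s, sel.h)
    n2 = 2 * int(N_next)
    return rng.binomial(n2, q_s) / n2


def migrate(q_afr, q_eur, m_af_eu: float, m_eu_af: float):
    """Deterministic symmetric gene flow applied once per generation.

    ``m_af_eu`` is the fraction of the African population replaced by
    European migrants and vice versa; q_i' = (1 - m_i) q_i + m_i q_j.
    """
    for m in (m_af_eu, m_eu_af):
        if not 0.0 <= m < 0.5:
            raise ValueError(f"migration rates must be in [0, 0.5), got {m}")
    q_afr = np.asarray(q_afr, dtype=float)
    q_eur = np.asarray(q_eur, dtype=float)
    return (
        (1.0 - m_af_eu) * q_afr + m_af_eu * q_eur,
        (1.0 - m_eu_af) * q_eur + m_eu_af * q_afr,
    )


def apply_treatment(sel: SelectionParams, total_generations: int) -> np.ndarray:
    """Per-generation selection schedule s(t), indexed by generations before
    present (t = 0 is the last generation): s(t) = 0 for the final
    ``sel.treatment_generations`` generations, ``sel.s`` otherwise."""
    k = sel.treatment_generations
    if k > total_generations:
        raise ValueError("treatment_generations exceeds the simulated span")
    sched = np.full(total_generations, sel.s, dtype=float)
    sched[:k] = 0.0
    return sched


# ---------------------------------------------------------------------------
# engine internals
# ---------------------------------------------------------------------------


def _ztrunc_binomial(n2: int, q: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Binomial(n2, q) conditioned on being >= 1, vectorised over q.

    Inverse-CDF over k = 1..kmax; with the tiny n2*q arising here the
    neglected tail beyond kmax carries probability < 1e-12.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    pmf = np.exp(n2 * np.log1p(-q))  # P(X = 0)
    tail = 1.0 - pmf
    u = rng.random(q.size) * tail
    extra = np.zeros(q.size, dtype=np.int64)
    cum = np.zeros(q.size)
    ratio = q / (1.0 - q)
    kmax = min(n2, 12)
    for k in range(1, kmax + 1):
        pmf = pmf * ((n2 - k + 1) / k) * ratio
        cum += pmf
        extra += u >= cum
    return np.minimum(extra + 1, n2)


def _lineage_sizes(model: DemographicModel, times: np.ndarray, population: str) -> np.ndarray:
    """Diploid sizes along ``times`` (generations before present), with the
    burn-in size for times at/after the start of explicit history."""
    hist = model.history_length
    out = np.empty(times.size, dtype=np.int64)
    for i, t in enumerate(times):
        out[i] = model.burnin_ne if t >= hist else size_at(model, population, float(t))
    return out


class _WakeScheduler:
    """Exact arrival times for dormant replicates.

    ``cums`` is one cumulative 2N array per population (summed along the
    stage's step order); a dormant replicate's first mutation arrival in a
    population is the first step where the cumulative hazard
    |log(1-q0)| * (cum[g] - cum[g_from]) exceeds a standard exponential draw.
    """

    def __init__(self, cums: list[np.ndarray], L: np.ndarray, rng: np.random.Generator):
        self.cums = cums
        self.L = L
        self.rng = rng
        self.n_steps = len(cums[0])
        self.buckets: dict[int, list] = {}

    def schedule(self, idx: np.ndarray, g_from: int) -> None:
        if idx.size == 0:
            return
        inv = -1.0 / self.L[idx]
        wake = np.full(idx.size, self.n_steps, dtype=np.int64)
        arrive = []
        for cum in self.cums:
            base = cum[g_from] if g_from >= 0 else 0.0
            target = base + self.rng.exponential(size=idx.size) * inv
            g = np.searchsorted(cum, target, side="left")
            g = np.maximum(g, g_from + 1)
            arrive.append(g)
            wake = np.minimum(wake, g)
        ok = wake < self.n_steps
        if not ok.any():
            return
        flags = [(g[ok] == wake[ok]) for g in arrive]
        buckets = self.buckets
        if len(self.cums) == 1:
            for i, w in zip(idx[ok], wake[ok]):
                buckets.setdefault(int(w), []).append((int(i), True, False))
        else:
            for i, w, fa, fe in zip(idx[ok], wake[ok], flags[0], flags[1]):
                buckets.setdefault(int(w), []).append((int(i), bool(fa), bool(fe)))

    def pop(self, g: int):
        return self.buckets.pop(g, None)


def _run_single_pop(counts, denom, M, qs0, L, n2_steps, s, h, rng, active):
    """Event-driven run of one population across ``n2_steps`` (child 2N per
    step).  Mutates ``counts`` in place; returns (denom, active)."""
    n_steps = n2_steps.size
    if n_steps == 0:
        return denom, active
    sched = _WakeScheduler([np.cumsum(n2_steps, dtype=float)], L, rng)
    sched.schedule(np.flatnonzero(counts == 0), -1)
    binom = rng.binomial
    for g in range(n_steps):
        n2c = int(n2_steps[g])
        if active.size:
            q = counts[active] * (1.0 / denom)
            qm = q + (1.0 - q) * M[active]
            qs = _post_selection_freq(qm, s, h)
            cn = binom(n2c, qs)
            counts[active] = cn
            dead = cn == 0
            if dead.any():
                sched.schedule(active[dead], g)
                active = active[~dead]
        woke = sched.pop(g)
        if woke:
            idx = np.fromiter((w[0] for w in woke), dtype=np.int64, count=len(woke))
            counts[idx] = _ztrunc_binomial(n2c, qs0[idx], rng)
            active = np.concatenate((active, idx))
        denom = n2c
    return denom, active


def _run_two_pop(cA, cE, denomA, denomE, M, qs0, L, n2A, n2E, mig, s, h, rng, active):
    """Event-driven two-population stage (AFR, EUR) with migration."""
    n_steps = n2A.size
    if n_steps == 0:
        return denomA, denomE, active
    sched = _WakeScheduler(
        [np.cumsum(n2A, dtype=float), np.cumsum(n2E, dtype=float)], L, rng
    )
    dormant = np.flatnonzero((cA == 0) & (cE == 0))
    sched.schedule(dormant, -1)
    binom = rng.binomial
    for g in range(n_steps):
        n2a = int(n2A[g])
        n2e = int(n2E[g])
        if active.size:
            a = active
            qA = cA[a] * (1.0 / denomA)
            qE = cE[a] * (1.0 / denomE)
            Ma = M[a]
            qsA = _post_selection_freq(qA + (1.0 - qA) * Ma, s, h)
            qsE = _post_selection_freq(qE + (1.0 - qE) * Ma, s, h)
            mg = mig[g]
            if mg > 0.0:
                qsA, qsE = (1.0 - mg) * qsA + mg * qsE, (1.0 - mg) * qsE + mg * qsA
            na = binom(n2a, qsA)
            ne = binom(n2e, qsE)
            cA[a] = na
            cE[a] = ne
            dead = (na == 0) & (ne == 0)
            if dead.any():
                sched.schedule(a[dead], g)
                active = a[~dead]
        woke = sched.pop(g)
        if woke:
            idx = np.fromiter((w[0] for w in woke), dtype=np.int64, count=len(woke))
            in_a = np.fromiter((w[1] for w in woke), dtype=bool, count=len(woke))
            in_e = np.fromiter((w[2] for w in woke), dtype=bool, count=len(woke))
            if in_a.any():
                ia = idx[in_a]
                cA[ia] = _ztrunc_binomial(n2a, qs0[ia], rng)
            if in_e.any():
                ie = idx[in_e]
                cE[ie] = _ztrunc_binomial(n2e, qs0[ie], rng)
            active = np.concatenate((active, idx))
        denomA = n2a
        denomE = n2e
    return denomA, denomE, active


def _build_schedule(model: DemographicModel, stop_at: int):
    """Per-step child-generation sizes (and migration) for the whole run.

    Steps run from the oldest generation toward the present; returns
    (pre_n2, postA_n2, postE_n2, post_mig, split, T_total).  For single
    population models the post arrays are empty and split = stop_at.
    """
    T_hist = int(round(model.history_length))
    T_total = T_hist + model.burnin_generations
    split = int(round(model.split_gen)) if model.split_gen is not None else stop_at
    if not 0 <= stop_at <= split:
        raise ValueError("stop_at must lie in the final (most recent) phase")
    pre_times = np.arange(T_total - 1, split - 1, -1)
    # burn-in portion is constant: avoid per-generation lookups there
    n_burn = np.count_nonzero(pre_times >= T_hist)
    pre_n2 = np.empty(pre_times.size, dtype=np.int64)
    pre_n2[:n_burn] = 2 * model.burnin_ne
    pre_n2[n_burn:] = 2 * _lineage_sizes(model, pre_times[n_burn:], "ANC")
    if model.split_gen is not None:
        post_times = np.arange(split - 1, stop_at - 1, -1)
        postA = 2 * _lineage_sizes(model, post_times, "AFR")
        postE = 2 * _lineage_sizes(model, post_times, "EUR")
        mig = np.array([model.migration_at(float(t)) for t in post_times])
    else:
        postA = postE = np.empty(0, dtype=np.int64)
        mig = np.empty(0)
    return pre_n2, postA, postE, mig, split, T_total


def _tail_schedule(model: DemographicModel, stop_at: int):
    """Sizes/migration for the final ``stop_at`` generations (plain steps)."""
    times = np.arange(stop_at - 1, -1, -1)
    two_pop = model.split_gen is not None
    if two_pop:
        n2A = 2 * _lineage_sizes(model, times, "AFR")
        n2E = 2 * _lineage_sizes(model, times, "EUR")
        mig = np.array([model.migration_at(float(t)) for t in times])
    else:
        n2A = n2E = 2 * _lineage_sizes(model, times, "ANC")
        mig = np.zeros(times.size)
    return n2A, n2E, mig, two_pop


def _simulate_engine(model, M, sel, rng, stop_at=0):
    """Run all replicates from fixed wild-type to ``stop_at`` generations
    before present; returns (q_AFR, q_EUR) float arrays (equal for
    single-population models)."""
    M = np.asarray(M, dtype=float)
    qs0 = _post_selection_freq(M, sel.s, sel.h)
    L = np.log1p(-qs0)
    pre_n2, postA, postE, mig, split, _ = _build_schedule(model, stop_at)

    counts = np.zeros(M.size, dtype=np.int64)
    active = np.empty(0, dtype=np.int64)
    denom = 2 * model.burnin_ne
    denom, active = _run_single_pop(
        counts, denom, M, qs0, L, pre_n2, sel.s, sel.h, rng, active
    )
    if model.split_gen is None:
        q = counts / denom
        return q, q.copy()
    cA = counts
    cE = counts.copy()
    denomA, denomE, active = _run_two_pop(
        cA, cE, denom, denom, M, qs0, L, postA, postE, mig, sel.s, sel.h, rng, active
    )
    return cA / denomA, cE / denomE


def _plain_tail(qA, qE, n2A, n2E, mig, M, s_sched, h, rng, two_pop):
    """Naive vectorised Wright-Fisher steps for the last few generations
    (used for the treatment window, where s changes)."""
    for g in range(n2A.size):
        s = s_sched[g]
        qsA = _post_selection_freq(qA + (1.0 - qA) * M, s, h)
        if two_pop:
            qsE = _post_selection_freq(qE + (1.0 - qE) * M, s, h)
            mg = mig[g]
            if mg > 0.0:
                qsA, qsE = (1.0 - mg) * qsA + mg * qsE, (1.0 - mg) * qsE + mg * qsA
            qA = rng.binomial(int(n2A[g]), qsA) / n2A[g]
            qE = rng.binomial(int(n2E[g]), qsE) / n2E[g]
        else:
            qA = rng.binomial(int(n2A[g]), qsA) / n2A[g]
            qE = qA
    return qA, qE


def _draw_rates(cfg, rng: np.random.Generator) -> np.ndarray:
    if isinstance(cfg, GeneConfig):
        rates = np.zeros(cfg.replicates)
        for u_j in cfg.site_rates:
            if cfg.rate_mode == "lognormal":
                rates += draw_mutation_rate(u_j, cfg.sigma, rng, cfg.replicates)
            else:
                rates += u_j
        return rates
    if cfg.rate_mode == "lognormal":
        return np.asarray(draw_mutation_rate(cfg.u, cfg.sigma, rng, cfg.replicates))
    return np.full(cfg.replicates, cfg.u, dtype=float)


def _results_frame(M, qA, qE) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "replicate": np.arange(M.size),
            "drawn_rate": M,
            "q_AFR": qA,
            "q_EUR": qE,
            "segregating": qE > 0,
        }
    )


def _simulate(model, cfg, sel, rng):
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    M = _draw_rates(cfg, rng)
    k = sel.treatment_generations
    qA, qE = _simulate_engine(model, M, sel, rng, stop_at=k)
    if k:
        n2A, n2E, mig, two_pop = _tail_schedule(model, k)
        s_sched = np.zeros(k)  # treatment: s -> 0 in the final generations
        qA, qE = _plain_tail(qA, qE, n2A, n2E, mig, M, s_sched, sel.h, rng, two_pop)
    return _results_frame(M, qA, qE)


def simulate_site(
    model: DemographicModel,
    cfg: SiteConfig,
    sel: SelectionParams = SelectionParams(),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate ``cfg.replicates`` independent sites to the present.

    Returns a DataFrame with columns ``replicate``, ``drawn_rate``,
    ``q_AFR``, ``q_EUR`` and ``segregating`` (q_EUR > 0); for
    single-population models the two frequency columns coincide.
    """
    return _simulate(model, cfg, sel, rng)


def simulate_gene(
    model: DemographicModel,
    cfg: GeneConfig,
    sel: SelectionParams = SelectionParams(),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate the combined frequency of all lethal alleles in one gene.

    Each replicate draws a rate per site, sums them into a total rate U
    (``drawn_rate`` column) and runs the single-locus machinery with U; the
    returned frequencies are the summed frequency of all lethal alleles,
    treating compound heterozygotes as equivalent to homozygotes.
    """
    return _simulate(model, cfg, sel, rng)


def paired_treatment_comparison(
    model: DemographicModel,
    cfg: SiteConfig,
    sel: SelectionParams = SelectionParams(),
    treatment_generations: int = 3,
    n_groups: int = 1,
    rng: np.random.Generator | None = None,
    return_replicates: bool = False,
):
    """Paired with/without-treatment comparison sharing one history.

    Replicates are simulated once to ``treatment_generations`` before present,
    then finished twice from identical state and RNG state: once with the
    original s, once with s = 0 (treatment).  Replicates are split into
    ``n_groups`` independent groups; per group the mean European frequencies
    of the two endings and the relative increase (%) are reported.  With
    ``return_replicates`` the per-replicate control and treated European
    frequencies are returned alongside the per-group table.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if n_groups < 1 or cfg.replicates < n_groups:
        raise ValueError("need 1 <= n_groups <= replicates")
    M = _draw_rates(cfg, rng)
    qA, qE = _simulate_engine(model, M, sel, rng, stop_at=treatment_generations)
    n2A, n2E, mig, two_pop = _tail_schedule(model, treatment_generations)

    state = rng.bit_generator.state
    s_on = np.full(treatment_generations, sel.s)
    _, qE_control = _plain_tail(
        qA.copy(), qE.copy(), n2A, n2E, mig, M, s_on, sel.h, rng, two_pop
    )
    rng_t = np.random.default_rng()
    rng_t.bit_generator.state = state
    s_off = np.zeros(treatment_generations)
    _, qE_treated = _plain_tail(
        qA.copy(), qE.copy(), n2A, n2E, mig, M, s_off, sel.h, rng_t, two_pop
    )

    groups = np.array_split(np.arange(cfg.replicates), n_groups)
    rows = []
    for gi, idx in enumerate(groups):
        mc = float(qE_control[idx].mean())
        mt = float(qE_treated[idx].mean())
        rows.append(
            {
                "group": gi,
                "n_replicates": idx.size,
                "mean_control": mc,
                "mean_treated": mt,
                "relative_increase_pct": 100.0 * (mt - mc) / mc if mc > 0 else float("nan"),
            }
        )
    table = pd.DataFrame(rows)
    if return_replicates:
        return table, qE_control, qE_treated
    return table
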