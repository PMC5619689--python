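"""Two-population (African/European) demographic histories for the simulator.

The demographic model used throughout is the Tennessen et al. (2012)
out-of-Africa history, rescaled for a lower mutation rate: Tennessen's
parameters were inferred assuming u = 2.36e-8 per bp per generation, whereas
direct pedigree estimates are about half that (1.2e-8, Kong et al. 2012).
Because only the compound parameters N*u and t/N (and m*N) are identified by
polymorphism data, halving the assumed mutation rate means multiplying all
population sizes and epoch durations by c = 2.36/1.2 and dividing all
per-generation rates (growth, migration) by c.  With the default c the
African size change falls 11,643 generations before present and the burn-in
population size is 14,328 diploids.

Time is measured in discrete generations before present; an epoch covers the
half-open interval [start_gen, end_gen) with start_gen > end_gen >= 0.
Populations are labelled ``ANC`` (the single ancestral population, which is
also the burn-in population), ``AFR`` and ``EUR``.  Nominal sizes may be
non-integral; :func:`size_at` rounds to the nearest integer generation by
generation, which is also what the simulator uses.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from importlib import resources

__all__ = [
    "Epoch",
    "MigrationPhase",
    "DemographicModel",
    "DEFAULT_RESCALE",
    "base_tennessen_params",
    "rescaled_tennessen",
    "variant_model",
    "constant_size_model",
    "size_at",
    "load_model",
    "save_model",
]

#: Default rescale factor: ratio of Tennessen's assumed mutation rate
#: (2.36e-8) to the pedigree-based estimate (1.2e-8).
DEFAULT_RESCALE = 2.36 / 1.2

#: Burn-in / ancestral diploid size used with the default rescale factor.
_DEFAULT_BURNIN_NE = 14_328


@dataclass(frozen=True)
class Epoch:
    """One population's size history over [start_gen, end_gen).

    ``n_start`` is the diploid size at ``start_gen`` (the older boundary);
    with ``growth`` r > 0 the size at time t (generations before present) is
    n_start * exp(r * (start_gen - t)), i.e. exponential growth toward the
    present. ``growth = 0`` gives a constant epoch.
    """

    population: str
    start_gen: float
    end_gen: float
    n_start: float
    growth: float = 0.0

    def __post_init__(self) -> None:
        if self.population not in ("ANC", "AFR", "EUR"):
            raise ValueError(f"unknown population label {self.population!r}")
        if not self.start_gen > self.end_gen >= 0:
            raise ValueError(
                f"epoch must satisfy start_gen > end_gen >= 0, got "
                f"[{self.start_gen}, {self.end_gen})"
            )
        if self.n_start < 0.5:
            raise ValueError("population size must round to at least 1 diploid")

    def size_at(self, t: float) -> int:
        """Diploid size at generation ``t`` before present, rounded."""
        if not self.end_gen <= t < self.start_gen:
            raise ValueError(f"t={t} outside epoch [{self.start_gen}, {self.end_gen})")
        n = self.n_start * math.exp(self.growth * (self.start_gen - t))
        return max(1, round(n))

    def size_at_end(self) -> float:
        """Nominal (unrounded) size at the epoch's younger boundary."""
        return self.n_start * math.exp(self.growth * (self.start_gen - self.end_gen))


@dataclass(frozen=True)
class MigrationPhase:
    """Symmetric AFR<->EUR migration rate m over [start_gen, end_gen)."""

    start_gen: float
    end_gen: float
    rate: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate < 0.5:
            raise ValueError(f"migration rate must be in [0, 0.5), got {self.rate}")
        if not self.start_gen > self.end_gen >= 0:
            raise ValueError("migration phase must satisfy start_gen > end_gen >= 0")


@dataclass(frozen=True)
class DemographicModel:
    """Piecewise demographic history with an optional two-population phase.

    ``split_gen`` is the generation (before present) at which EUR splits from
    the ancestral lineage; ``None`` describes a single-population model.
    ``burnin_generations`` defaults to 10 * burnin_ne when left at 0.
    """

    epochs: tuple[Epoch, ...]
    split_gen: float | None
    migration: tuple[MigrationPhase, ...] = ()
    burnin_ne: int = _DEFAULT_BURNIN_NE
    burnin_generations: int = 0
    rescale_factor: float = 1.0
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.burnin_ne < 1:
            raise ValueError("burnin_ne must be >= 1")
        if self.burnin_generations == 0:
            object.__setattr__(self, "burnin_generations", 10 * self.burnin_ne)
        span = self.history_length
        if self.split_gen is not None and not 0 < self.split_gen <= span:
            raise ValueError("split_gen must lie within the modelled time span")
        for pop in ("ANC", "AFR", "EUR"):
            self._check_tiling(pop)

    def _check_tiling(self, population: str) -> None:
        eps = [e for e in self.epochs if e.population == population]
        eps.sort(key=lambda e: -e.start_gen)
        for a, b in zip(eps, eps[1:]):
            if not math.isclose(a.end_gen, b.start_gen, abs_tol=1e-9):
                raise ValueError(
                    f"epochs for {population} do not tile time: gap/overlap between "
                    f"{a.end_gen} and {b.start_gen}"
                )

    @property
    def history_length(self) -> float:
        """Generations of explicit history (excluding burn-in)."""
        return max(e.start_gen for e in self.epochs)

    @property
    def total_generations(self) -> int:
        """Burn-in plus explicit history, in generations."""
        return int(round(self.history_length)) + self.burnin_generations

    def epochs_for(self, population: str) -> list[Epoch]:
        out = [e for e in self.epochs if e.population == population]
        out.sort(key=lambda e: -e.start_gen)
        return out

    def migration_at(self, t: float) -> float:
        for phase in self.migration:
            if phase.end_gen <= t < phase.start_gen:
                return phase.rate
        return 0.0

    def rescaled(self, k: float) -> "DemographicModel":
        """Generic rescaling: sizes and times * k, per-generation rates / k."""
        if k <= 0:
            raise ValueError("rescale factor must be positive")
        epochs = tuple(
            Epoch(e.population, e.start_gen * k, e.end_gen * k, e.n_start * k, e.growth / k)
            for e in self.epochs
        )
        migration = tuple(
            MigrationPhase(p.start_gen * k, p.end_gen * k, p.rate / k) for p in self.migration
        )
        burnin_ne = max(1, round(self.burnin_ne * k))
        return replace(
            self,
            epochs=epochs,
            migration=migration,
            split_gen=None if self.split_gen is None else self.split_gen * k,
            burnin_ne=burnin_ne,
            burnin_generations=10 * burnin_ne,
            rescale_factor=self.rescale_factor * k,
        )

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "name": self.name,
            "rescale_factor": self.rescale_factor,
            "burnin_ne": self.burnin_ne,
            "burnin_generations": self.burnin_generations,
            "split_gen": self.split_gen,
            "epochs": [
                {
                    "population": e.population,
                    "start_gen": e.start_gen,
                    "end_gen": e.end_gen,
                    "n_start": e.n_start,
                    "growth": e.growth,
                }
                for e in self.epochs
            ],
            "migration": [
                {"start_gen": p.start_gen, "end_gen": p.end_gen, "rate": p.rate}
                for p in self.migration
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicModel":
        return cls(
            epochs=tuple(Epoch(**e) for e in d["epochs"]),
            split_gen=d.get("split_gen"),
            migration=tuple(MigrationPhase(**p) for p in d.get("migration", [])),
            burnin_ne=d["burnin_ne"],
            burnin_generations=d.get("burnin_generations", 0),
            rescale_factor=d.get("rescale_factor", 1.0),
            name=d.get("name", "custom"),
        )


def base_tennessen_params() -> dict:
    """The packaged, unrescaled Tennessen et al. (2012) parameter set."""
    with resources.files("lethalpop.data").joinpath("tennessen2012.json").open() as fh:
        return json.load(fh)


def _build_tennessen(params: dict, c: float, burnin_ne: int | None) -> DemographicModel:
    t_af = round(params["T_african_growth"] * c)
    t_split = round(params["T_split"] * c)
    t_eu2 = round(params["T_european_second"] * c)
    t_grow = round(params["T_recent_growth"] * c)
    n_anc = params["N_ancestral"] * c
    n_afr = params["N_african"] * c
    n_b = params["N_bottleneck"] * c
    n_eu2 = params["N_european_second"] * c
    r_eu_early = params["r_european_early"] / c
    r_eu_recent = params["r_european_recent"] / c
    r_af_recent = params["r_african_recent"] / c

    if burnin_ne is None:
        if math.isclose(c, DEFAULT_RESCALE):
            burnin_ne = _DEFAULT_BURNIN_NE
        else:
            burnin_ne = max(1, round(n_anc))
    # Size of EUR at the onset of accelerated growth, for epoch continuity.
    n_eu_mid = n_eu2 * math.exp(r_eu_early * (t_eu2 - t_grow))

    epochs = (
        # Ancestral lineage from the African size change to the split; the
        # preceding burn-in (10 * burnin_ne generations at burnin_ne) is
        # implicit in the model rather than an explicit epoch.
        Epoch("ANC", t_af, t_split, n_afr),
        # African lineage after the split: constant, then recent growth.
        Epoch("AFR", t_split, t_grow, n_afr),
        Epoch("AFR", t_grow, 0, n_afr, r_af_recent),
        # European lineage: bottleneck, slow growth, accelerated growth.
        Epoch("EUR", t_split, t_eu2, n_b),
        Epoch("EUR", t_eu2, t_grow, n_eu2, r_eu_early),
        Epoch("EUR", t_grow, 0, n_eu_mid, r_eu_recent),
    )
    migration = (
        MigrationPhase(t_split, t_eu2, params["m_ancestral_european"] / c),
        MigrationPhase(t_eu2, 0, params["m_african_european"] / c),
    )
    return DemographicModel(
        epochs=epochs,
        split_gen=t_split,
        migration=migration,
        burnin_ne=burnin_ne,
        burnin_generations=10 * burnin_ne,
        rescale_factor=c,
        name=f"tennessen_rescaled_c={c:.6g}",
    )


def rescaled_tennessen(
    c: float = DEFAULT_RESCALE,
    *,
    burnin_ne: int | None = None,
    params: dict | None = None,
) -> DemographicModel:
    """Tennessen et al. (2012) two-population model rescaled by factor ``c``.

    Sizes and epoch durations are multiplied by ``c`` and per-generation
    growth/migration rates divided by ``c``, preserving each epoch's
    cumulative effect.  With the default ``c`` = 2.36/1.2 the African size
    change falls 11,643 generations ago and the burn-in size is pinned to the
    published 14,328 diploids; pass ``burnin_ne`` to override.
    """
    if c <= 0:
        raise ValueError(f"rescale factor must be positive, got {c}")
    return _build_tennessen(params or base_tennessen_params(), c, burnin_ne)


def variant_model(
    base: DemographicModel,
    end_size_multiplier: float,
    growth_style: str = "staged",
) -> DemographicModel:
    """Stronger-recent-growth variants of a two-population model.

    ``staged`` keeps all epoch boundaries and multiplies the present-day
    European size by ``end_size_multiplier``, re-solving the final growth
    rate.  ``immediate`` replaces the post-bottleneck European history with a
    single exponential epoch running from the bottleneck exit to the (possibly
    multiplied) present size.
    """
    if end_size_multiplier < 1:
        raise ValueError("end_size_multiplier must be >= 1")
    if growth_style not in ("staged", "immediate"):
        raise ValueError(f"growth_style must be 'staged' or 'immediate', got {growth_style!r}")

    eur = base.epochs_for("EUR")
    if not eur:
        raise ValueError("variant_model requires a model with a EUR lineage")
    last = eur[-1]
    present = last.size_at_end() * end_size_multiplier

    others = tuple(e for e in base.epochs if e.population != "EUR")
    if growth_style == "staged":
        rate = math.log(present / last.n_start) / (last.start_gen - last.end_gen)
        new_eur = tuple(eur[:-1]) + (replace(last, growth=rate),)
    else:
        bottleneck = eur[0]
        exit_gen = bottleneck.end_gen
        n_exit = eur[1].n_start if len(eur) > 1 else bottleneck.size_at_end()
        rate = math.log(present / n_exit) / exit_gen
        new_eur = (bottleneck, Epoch("EUR", exit_gen, 0, n_exit, rate))
    return replace(
        base,
        epochs=others + new_eur,
        name=f"{base.name}_x{end_size_multiplier:g}_{growth_style}",
    )


def constant_size_model(N: int, history_generations: int = 1) -> DemographicModel:
    """Single constant-size population with a 10N-generation burn-in."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return DemographicModel(
        epochs=(Epoch("ANC", float(history_generations), 0.0, float(N)),),
        split_gen=None,
        burnin_ne=N,
        burnin_generations=10 * N,
        rescale_factor=1.0,
        name=f"constant_N={N}",
    )


def size_at(model: DemographicModel, population: str, t: float) -> int:
    """Diploid size of ``population`` at generation ``t`` before present.

    Before the split, AFR and EUR queries fall back to the ancestral lineage.
    Times inside the burn-in return the burn-in size.  Rounds nominal sizes to
    the nearest integer, generation by generation.
    """
    history = model.history_length
    if t >= history:
        if t < history + model.burnin_generations + 1:
            return model.burnin_ne
        raise ValueError(f"t={t} is before the start of the simulation")
    pops = [population]
    if model.split_gen is not None and t >= model.split_gen and population in ("AFR", "EUR"):
        pops = ["ANC"]
    elif population in ("AFR", "EUR") and model.split_gen is None:
        pops = ["ANC"]
    for pop in pops:
        for e in model.epochs_for(pop):
            if e.end_gen <= t < e.start_gen:
                return e.size_at(t)
    raise ValueError(f"no epoch covers population {population!r} at t={t}")


def load_model(path) -> DemographicModel:
    with open(path) as fh:
        return DemographicModel.from_dict(json.load(fh))


def save_model(model: DemographicModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)
        fh.write("\n")
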