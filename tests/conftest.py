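"""Shared fixtures: the expensive simulation runs are session-scoped and
reused across test modules so each demographic scenario is simulated once.

All fixture seeds are fixed, so results are deterministic; computed arrays
are additionally cached under scratch/ (ignored scratch space) to spare
repeated local runs — a cold cache reproduces byte-identical arrays.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lethalpop import (
    GeneConfig,
    SelectionParams,
    SiteConfig,
    constant_size_model,
    paired_treatment_comparison,
    rescaled_tennessen,
    simulate_gene,
    simulate_site,
)

settings.register_profile(
    "lethalpop",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("lethalpop")

_CACHE = Path(__file__).resolve().parent.parent / "scratch" / "test_cache"


def _cached_arrays(name: str, compute) -> dict[str, np.ndarray]:
    """Disk-cache deterministic (fixed-seed) fixture arrays between runs."""
    path = _CACHE / f"{name}.npz"
    if path.exists():
        with np.load(path) as d:
            return {k: d[k] for k in d.files}
    out = compute()
    try:
        _CACHE.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(path, **out)
    except OSError:
        pass
    return out


@pytest.fixture(scope="session")
def tennessen_model():
    return rescaled_tennessen()


def _group_table(q_control: np.ndarray, q_treated: np.ndarray, n_groups: int) -> pd.DataFrame:
    rows = []
    for gi, idx in enumerate(np.array_split(np.arange(q_control.size), n_groups)):
        mc = float(q_control[idx].mean())
        mt = float(q_treated[idx].mean())
        rows.append({"group": gi, "n_replicates": idx.size, "mean_control": mc,
                     "mean_treated": mt,
                     "relative_increase_pct": 100.0 * (mt - mc) / mc})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def tennessen_run(tennessen_model):
    """Rescaled-demography run at u = 1.5e-8 (lognormal rates, h = 0) with a
    paired treatment branch over the final 3 generations, split into 10
    groups; returns (per-group DataFrame, overall control mean, per-replicate
    control frequencies)."""

    def compute():
        cfg = SiteConfig(u=1.5e-8, sigma=0.57, rate_mode="lognormal",
                         replicates=400_000, seed=20170928)
        _, q_control, q_treated = paired_treatment_comparison(
            tennessen_model, cfg, SelectionParams(), treatment_generations=3,
            n_groups=10, return_replicates=True,
        )
        return {"q_control": q_control, "q_treated": q_treated}

    d = _cached_arrays("tennessen_u1.5e-8_R400k_seed20170928", compute)
    pairs = _group_table(d["q_control"], d["q_treated"], 10)
    return pairs, float(d["q_control"].mean()), d["q_control"]


@pytest.fixture(scope="session")
def het_run_mean(tennessen_model):
    """Mean q_EUR under a 1% heterozygote fitness effect (h = 0.01)."""

    def compute():
        cfg = SiteConfig(u=1.5e-8, sigma=0.57, rate_mode="lognormal",
                         replicates=60_000, seed=1006915)
        df = simulate_site(tennessen_model, cfg, SelectionParams(h=0.01))
        return {"q": df.q_EUR.to_numpy()}

    return float(_cached_arrays("tennessen_h0.01_R60k_seed1006915", compute)["q"].mean())


@pytest.fixture(scope="session")
def class_pools():
    """European population-frequency pools for the four mutation classes
    under the unrescaled demography (the setting behind the discovery-bias
    table), lognormal rates."""

    def compute():
        model = rescaled_tennessen(1.0)
        pools = {}
        for i, (cls, u) in enumerate(
            [("CpGti", 1.12e-7), ("CpGtv", 9.59e-9), ("nonCpGti", 6.18e-9),
             ("nonCpGtv", 3.76e-9)]
        ):
            cfg = SiteConfig(u=u, sigma=0.57, rate_mode="lognormal",
                             replicates=60_000, seed=417_000 + i)
            pools[cls] = simulate_site(model, cfg).q_EUR.to_numpy()
        return pools

    return _cached_arrays("class_pools_c1_R60k", compute)


@pytest.fixture(scope="session")
def constant_pool_5k():
    """Constant N = 5,000 equilibrium frequencies at fixed u = 1e-7."""

    def compute():
        cfg = SiteConfig(u=1e-7, sigma=0.0, rate_mode="fixed",
                         replicates=30_000, seed=5_000)
        return {"q": simulate_site(constant_size_model(5_000), cfg).q_EUR.to_numpy()}

    return _cached_arrays("constant_N5000_R30k", compute)["q"]


@pytest.fixture(scope="session")
def gene_pool_20k():
    """Constant N = 20,000 gene-level run: ten sites at fixed 3.76e-9 each,
    so the pooled mutation rate is U = 3.76e-8."""

    def compute():
        cfg = GeneConfig(site_rates=(3.76e-9,) * 10, rate_mode="fixed",
                         replicates=30_000, seed=20_000)
        return {"q": simulate_gene(constant_size_model(20_000), cfg).q_EUR.to_numpy()}

    return _cached_arrays("gene_N20000_R30k", compute)["q"]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
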