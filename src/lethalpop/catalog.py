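"""Synthetic variant catalogs with the statistical structure of a curated
exome-frequency study of recessive lethal mutations.

Each catalog row is one reported disease SNV: its immediate sequence context
(previous base, ref, alt, next base), the mutation class derived from that
context, a CpG-island flag, an allele count AC out of AN genotyped
chromosomes, a homozygote count, and the fraction of individuals covered to
at least 15x.  Frequencies are drawn from simulated population-frequency
pools per mutation class — either directly (``world='null'``: the catalog is
a fair sample of all mutations) or restricted to mutations a discovery study
would have found (``world='ascertained'``, via the inbreeding-based
ascertainment model) — and Poisson-sampled into allele counts.  Configurable
fractions of rows carry homozygotes or low coverage so the QC filters have
work to do.

Mutation classes and their default per-generation rates (pedigree estimates):
CpG transitions 1.12e-7, CpG transversions 9.59e-9, non-CpG transitions
6.18e-9, non-CpG transversions 3.76e-9 — CpG transitions are ~17-fold more
mutable than the average of the other three classes.

The default class composition is synthetic: 29.3% of 417 rows are CpGti as
reported for the real curated set, and the remaining 295 are split across the
other classes in rough proportion to how disease-mutation catalogs are
populated (transitions enriched); the real per-class counts are figure-level
data not reprinted in text.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .ascertainment import AscertainmentConfig, p_ascertain

__all__ = [
    "MutationClass",
    "MUTATION_CLASSES",
    "DEFAULT_CLASS_COUNTS",
    "classify_mutation_type",
    "generate_catalog",
    "apply_site_filters",
    "CATALOG_COLUMNS",
]

_BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass(frozen=True)
class MutationClass:
    """A named mutation category with its mean per-generation rate."""

    name: str
    rate: float

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("mutation rate must be positive")


#: The four context classes with pedigree-study rates (per bp per generation).
MUTATION_CLASSES: dict[str, MutationClass] = {
    "CpGti": MutationClass("CpGti", 1.12e-7),
    "CpGtv": MutationClass("CpGtv", 9.59e-9),
    "nonCpGti": MutationClass("nonCpGti", 6.18e-9),
    "nonCpGtv": MutationClass("nonCpGtv", 3.76e-9),
}

#: Synthetic default composition of a 417-SNV catalog (see module docstring):
#: CpGti = 29.3% of 417; the split of the remainder is a package choice.
DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "CpGti": 122,
    "CpGtv": 25,
    "nonCpGti": 145,
    "nonCpGtv": 125,
}

CATALOG_COLUMNS = [
    "variant_id",
    "gene",
    "prev_base",
    "ref",
    "alt",
    "next_base",
    "cgi_flag",
    "mutation_class",
    "AC",
    "AN",
    "n_hom",
    "frac_cov15",
    "pop_freq",
]


def classify_mutation_type(prev: str, ref: str, alt: str, next_: str) -> str:
    """Mutation class from the immediate sequence context.

    A site is CpG context iff ref C is followed by G or ref G is preceded by C
    (strand-symmetric); a change is a transition iff it swaps A<->G or C<->T.
    """
    for b in (prev, ref, alt, next_):
        if b not in _BASES:
            raise ValueError(f"invalid base {b!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    cpg = (ref == "C" and next_ == "G") or (ref == "G" and prev == "C")
    ti = (ref, alt) in _TRANSITIONS
    return ("CpG" if cpg else "nonCpG") + ("ti" if ti else "tv")


def _contexts_by_class() -> dict[str, list[tuple[str, str, str, str]]]:
    out: dict[str, list] = {name: [] for name in MUTATION_CLASSES}
    for prev, ref, alt, next_ in product(_BASES, repeat=4):
        if ref == alt:
            continue
        out[classify_mutation_type(prev, ref, alt, next_)].append((prev, ref, alt, next_))
    return out


_CONTEXTS = _contexts_by_class()


def generate_catalog(
    freq_pools: dict[str, np.ndarray],
    class_counts: dict[str, int] | None = None,
    world: str = "null",
    asc_cfg: AscertainmentConfig | None = None,
    AN: int = 65_762,
    n_hom_fraction: float = 3 / 417,
    low_cov_fraction: float = 29 / 417,
    cgi_fraction: float = 12 / 122,
    n_genes: int = 32,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate a synthetic variant catalog from per-class frequency pools.

    ``world='null'`` draws each class's population frequencies directly from
    its pool; ``world='ascertained'`` keeps a pool mutation with probability
    equal to its discovery probability under ``asc_cfg`` and draws from the
    survivors, emulating a catalog assembled from clinically discovered
    mutations.  Allele counts are Poisson(q * AN) truncated at AN.
    ``cgi_fraction`` of CpGti rows are flagged as CpG-island sites;
    homozygote-carrying and low-coverage rows are injected disjointly at the
    given fractions.
    """
    if rng is None:
        rng = np.random.default_rng()
    counts = dict(class_counts or DEFAULT_CLASS_COUNTS)
    unknown = set(counts) - set(MUTATION_CLASSES)
    if unknown:
        raise ValueError(f"unknown mutation classes {sorted(unknown)}")
    if world not in ("null", "ascertained"):
        raise ValueError(f"world must be 'null' or 'ascertained', got {world!r}")
    if world == "ascertained" and asc_cfg is None:
        raise ValueError("world='ascertained' requires asc_cfg")

    rows = []
    vid = 0
    for cls, K in counts.items():
        if K == 0:
            continue
        pool = np.asarray(freq_pools.get(cls, ()), dtype=float)
        if pool.size == 0:
            raise ValueError(f"empty frequency pool for class {cls}")
        if world == "ascertained":
            keep = rng.random(pool.size) < p_ascertain(pool, asc_cfg.F_a, asc_cfg.n_a)
            if not keep.any():
                raise ValueError(
                    f"no mutations of class {cls} were ascertained; enlarge the pool "
                    "or the discovery study"
                )
            pool = pool[keep]
        q = pool[rng.integers(0, pool.size, size=K)]
        ac = np.minimum(rng.poisson(q * AN), AN)
        ctx = [_CONTEXTS[cls][i] for i in rng.integers(0, len(_CONTEXTS[cls]), size=K)]
        genes = rng.integers(0, n_genes, size=K)
        for j in range(K):
            prev, ref, alt, next_ = ctx[j]
            rows.append(
                {
                    "variant_id": f"var{vid:05d}",
                    "gene": f"GENE{genes[j] + 1:02d}",
                    "prev_base": prev,
                    "ref": ref,
                    "alt": alt,
                    "next_base": next_,
                    "cgi_flag": False,
                    "mutation_class": cls,
                    "AC": int(ac[j]),
                    "AN": AN,
                    "n_hom": 0,
                    "frac_cov15": 0.0,
                    "pop_freq": q[j],
                }
            )
            vid += 1
    df = pd.DataFrame(rows, columns=CATALOG_COLUMNS)
    n = len(df)

    # disjoint QC injections: homozygote carriers, low coverage, CGI flags
    n_hom = round(n_hom_fraction * n)
    n_low = round(low_cov_fraction * n)
    cpgti_idx = df.index[df.mutation_class == "CpGti"].to_numpy()
    n_cgi = round(cgi_fraction * cpgti_idx.size)
    perm = rng.permutation(n)
    hom_idx = perm[:n_hom]
    low_idx = perm[n_hom : n_hom + n_low]
    remaining_cpgti = np.setdiff1d(cpgti_idx, perm[: n_hom + n_low], assume_unique=False)
    cgi_idx = rng.permutation(remaining_cpgti)[:n_cgi]

    df["frac_cov15"] = rng.uniform(0.82, 1.0, size=n)
    df.loc[df.index[low_idx], "frac_cov15"] = rng.uniform(0.2, 0.8, size=n_low)
    df.loc[df.index[hom_idx], "n_hom"] = 1
    df.loc[cgi_idx, "cgi_flag"] = True
    df["frac_cov15"] = df["frac_cov15"].round(4)
    return df


def apply_site_filters(
    records: pd.DataFrame,
    min_cov_frac: float = 0.8,
    exclude_homozygous: bool = True,
    exclude_cgi_cpgti: bool = True,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Quality-control filters applied to a variant catalog.

    Removes rows with any homozygote carrier (healthy homozygotes contradict
    the lethal-recessive annotation), rows where fewer than ``min_cov_frac``
    of individuals reached 15x coverage, and CpG-transition rows inside CpG
    islands (unmethylated, so the elevated CpGti rate does not apply).
    Returns the surviving rows and a per-rule removal report; each removed
    row is attributed to the first rule it fails, so the counts sum to the
    number removed.
    """
    remaining = records
    report = {"homozygous": 0, "coverage": 0, "cgi_cpgti": 0}
    if exclude_homozygous:
        bad = remaining["n_hom"] > 0
        report["homozygous"] = int(bad.sum())
        remaining = remaining[~bad]
    bad = remaining["frac_cov15"] < min_cov_frac
    report["coverage"] = int(bad.sum())
    remaining = remaining[~bad]
    if exclude_cgi_cpgti:
        bad = (remaining["mutation_class"] == "CpGti") & remaining["cgi_flag"]
        report["cgi_cpgti"] = int(bad.sum())
        remaining = remaining[~bad]
    return remaining.copy(), report
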