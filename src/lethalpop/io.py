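"""TSV/JSON plumbing: result tables, catalogs, run metadata, seed splitting.

All tabular artifacts are tab-separated with a header line and ``.`` for
missing values; every run writes a JSON metadata sidecar recording the
parameters, the seed and the package version, so outputs are reproducible
and diffable.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import CATALOG_COLUMNS, classify_mutation_type

__all__ = [
    "write_tsv",
    "read_tsv",
    "write_catalog",
    "read_catalog",
    "write_metadata",
    "spawn_seeds",
]

MISSING = "."


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[MISSING])


def write_catalog(df: pd.DataFrame, path) -> None:
    write_tsv(df[CATALOG_COLUMNS], path)


def read_catalog(path) -> pd.DataFrame:
    """Read and validate a variant-catalog TSV.

    Raises ValueError naming the file, line and field for the first
    malformed record encountered.
    """
    df = read_tsv(path)
    missing_cols = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required column(s) {missing_cols}")
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            cls = classify_mutation_type(
                row["prev_base"], row["ref"], row["alt"], row["next_base"]
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{line}: field 'ref/alt/context': {exc}") from None
        if cls != row["mutation_class"]:
            raise ValueError(
                f"{path}:{line}: field 'mutation_class': stated {row['mutation_class']!r} "
                f"but context implies {cls!r}"
            )
        if not 0 <= row["AC"] <= row["AN"]:
            raise ValueError(f"{path}:{line}: field 'AC': must satisfy 0 <= AC <= AN")
        if row["n_hom"] < 0:
            raise ValueError(f"{path}:{line}: field 'n_hom': must be >= 0")
    return df


def write_metadata(path, *, seed, command: str, params: dict) -> None:
    from . import __version__

    meta = {
        "command": command,
        "seed": seed,
        "params": params,
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    Path(path).write_text(json.dumps(meta, indent=1, default=str) + "\n")


def sidecar_path(out_path) -> Path:
    p = Path(out_path)
    return p.with_suffix(p.suffix + ".meta.json")


def spawn_seeds(seed: int | None, n: int) -> list[np.random.SeedSequence]:
    """Split one user seed into ``n`` independent child seed sequences.

    All randomness in a multi-part run flows from a single seed through this
    documented splitting scheme (numpy SeedSequence.spawn).
    """
    return np.random.SeedSequence(seed).spawn(n)
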