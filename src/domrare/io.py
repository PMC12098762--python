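"""Readers and writers for the tabular interchange formats.

All tables are delimited text (TSV by default) with header rows and "."
decimal separators.  ``write_tables(read_tables(...))`` is an identity on
canonicalized tables.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import pandas as pd

from .types import (
    TRAITS,
    SchemaError,
    validate_plots,
    validate_traits,
    validate_trees,
)

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class Tables:
    """The three interchange tables plus derived bookkeeping."""

    plots: pd.DataFrame
    trees: pd.DataFrame
    traits: pd.DataFrame
    unknown_species: tuple[str, ...] = ()


def _read_one(path: str, sep: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise SchemaError(f"input file not found: {path}")
    return pd.read_csv(path, sep=sep)


def read_tables(
    plots_path: str, trees_path: str, traits_path: str, sep: str = "\t"
) -> Tables:
    """Read and validate the plot, tree and trait tables.

    Species present in the tree table but absent from the trait table are
    flagged in ``Tables.unknown_species`` (trait lookup later falls back to
    the genus mean or drops them).
    """
    plots = validate_plots(_read_one(plots_path, sep))
    trees = validate_trees(_read_one(trees_path, sep))
    traits = validate_traits(_read_one(traits_path, sep))
    unknown = sorted(set(trees["species"]) - set(traits["species"]))
    return Tables(plots, trees, traits, tuple(unknown))


def write_tables(tables: Tables, out_dir: str, sep: str = "\t") -> dict[str, str]:
    """Write the three tables under ``out_dir``; returns the file map."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "plots": os.path.join(out_dir, "plots.tsv"),
        "trees": os.path.join(out_dir, "trees.tsv"),
        "traits": os.path.join(out_dir, "traits.tsv"),
    }
    tables.plots.to_csv(paths["plots"], sep=sep, index=False, float_format=_FLOAT_FMT)
    tables.trees.to_csv(paths["trees"], sep=sep, index=False, float_format=_FLOAT_FMT)
    tables.traits.to_csv(paths["traits"], sep=sep, index=False, float_format=_FLOAT_FMT)
    return paths


def write_frame(frame: pd.DataFrame, path: str, sep: str = "\t") -> str:
    """Write any result frame with the package's canonical float format."""
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    frame.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)
    return path


def write_manifest(manifest: dict, path: str) -> str:
    """Write a JSON run manifest with stable key order."""
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def resolve_names(
    raw_names: list[str], synonym_map: dict[str, str] | None = None
) -> tuple[list[str], float]:
    """Map raw species names through a synonym table.

    Names found in ``synonym_map`` are replaced by their accepted form;
    everything else passes through unchanged.  Returns the resolved list and
    the fraction of names that were remapped.  Full taxonomic resolution
    (The Plant List / GBIF backbone style) is out of scope; a simple synonym
    map stands in for it.
    """
    synonym_map = synonym_map or {}
    resolved = [synonym_map.get(n, n) for n in raw_names]
    mapped = sum(1 for n in raw_names if n in synonym_map)
    fraction = mapped / len(raw_names) if raw_names else 0.0
    return resolved, fraction
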