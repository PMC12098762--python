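"""Rank-abundance classification of locally dominant and rare species.

Within each plot, species are ranked by abundance (stem counts by default).
Plots with 6–19 species contribute their top two and bottom two species as
dominant and rare; plots with 20 or more species contribute the top and
bottom ``pct`` percent (k = floor(S·pct/100), never below two).  A plot
whose rarest species still makes up more than 10% of its stems is excluded
outright — its rare species are not clearly distinguishable in abundance
from its dominants.  Selection percentages of 5 and 15 are supported for
sensitivity analyses.

Ties at a rank boundary are broken deterministically but *per plot*: by a
hash of (plot id, species id), with the species id itself as the final
disambiguator.  A fixed global tie order (e.g. alphabetical) would pick the
same species out of every plot's pool of 1-stem ties, quietly importing
that species' trait values into the rare group across an entire biome and
biasing downstream contrasts; the per-plot hash keeps classification
reproducible while favouring no species systematically.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd

from .types import DominanceAssignment

SMALL_PLOT_MAX = 19     # 6..19 species: top/bottom two
MIN_SPECIES = 6
RAREST_SHARE_LIMIT = 0.10


def tie_break_keys(plot_id: object, species: np.ndarray) -> np.ndarray:
    """Deterministic per-(plot, species) tie-break keys (uint64).

    Shared by the classifier and by reference implementations so both
    resolve rank-boundary ties identically.
    """
    return np.array([
        int.from_bytes(
            hashlib.blake2b(f"{plot_id}|{s}".encode(),
                            digest_size=8).digest(), "big")
        for s in species
    ], dtype=np.uint64)


def selection_count(n_species: int, pct: float = 10.0) -> int:
    """k for a plot of ``n_species``: 2 for 6–19 species, else
    max(2, floor(S*pct/100))."""
    if n_species <= SMALL_PLOT_MAX:
        return 2
    return max(2, int(np.floor(n_species * pct / 100.0)))


def classify_plot(
    plot_trees: pd.DataFrame,
    pct: float = 10.0,
    abundance_basis: str = "stems",
) -> DominanceAssignment:
    """Classify one plot's species into dominant and rare sets.

    ``plot_trees`` holds one plot's rows (``species``, ``stems`` and, when
    ``abundance_basis='basal_area'``, a ``basal_area`` column).  The
    rarest-species exclusion is always evaluated on stem shares, whatever
    the ranking basis.
    """
    plot_id = plot_trees["plot_id"].iloc[0] if len(plot_trees) else None
    n = len(plot_trees)
    if n < MIN_SPECIES:
        return DominanceAssignment(plot_id, (), (), True, "too_few_species")

    stems = plot_trees["stems"].to_numpy(dtype=float)
    if stems.min() / stems.sum() > RAREST_SHARE_LIMIT:
        return DominanceAssignment(plot_id, (), (), True, "rarest_gt_10pct")

    abundance = (plot_trees["basal_area"] if abundance_basis == "basal_area"
                 else plot_trees["stems"]).to_numpy(dtype=float)
    species = plot_trees["species"].to_numpy()
    k = selection_count(n, pct)

    # sort keys: abundance, then the per-plot hash, then id; rares are
    # drawn among non-dominant species so a tie group spanning both rank
    # boundaries can never put one species in both sets
    keys = tie_break_keys(plot_id, species)
    order_id = np.lexsort((species, keys))
    dom_order = order_id[np.argsort(-abundance[order_id], kind="stable")]
    rare_order = order_id[np.argsort(abundance[order_id], kind="stable")]
    dominant = tuple(species[dom_order[:k]])
    dom_set = set(dominant)
    rare = tuple(sp for sp in species[rare_order] if sp not in dom_set)[:k]
    return DominanceAssignment(plot_id, dominant, rare)


def classify_all(
    trees: pd.DataFrame,
    plots: pd.DataFrame,
    pct: float = 10.0,
    abundance_basis: str = "stems",
    temperate_subsample: tuple[int, int] | None = None,
) -> tuple[dict, dict]:
    """Classify every plot; returns (assignments, info).

    ``assignments`` maps plot_id → DominanceAssignment for retained plots.
    ``temperate_subsample = (n, seed)`` first draws a uniform random sample
    of n temperate plots (the analysis uses such a subsample to balance
    the biome sizes); sampled ids are recorded in ``info``.
    """
    plots = plots.copy()
    info: dict = {"temperate_subsample": None, "excluded": {}}
    if temperate_subsample is not None:
        n_sub, seed = temperate_subsample
        temp_ids = plots.loc[plots["biome"] == "temperate", "plot_id"]
        if len(temp_ids) > n_sub:
            rng = np.random.default_rng(seed)
            keep = rng.choice(temp_ids.to_numpy(), size=n_sub, replace=False)
            keep_set = set(keep)
            plots = plots[(plots["biome"] != "temperate")
                          | plots["plot_id"].isin(keep_set)]
            info["temperate_subsample"] = sorted(keep_set)

    plot_ids = set(plots["plot_id"])
    assignments: dict = {}
    for pid, grp in trees.groupby("plot_id", sort=True):
        if pid not in plot_ids:
            continue
        a = classify_plot(grp, pct=pct, abundance_basis=abundance_basis)
        if a.excluded:
            info["excluded"][pid] = a.exclusion_reason
        else:
            assignments[pid] = a
    return assignments, info


def bootstrap_subsample_check(
    full_contrasts: pd.DataFrame,
    sub_contrasts: pd.DataFrame,
    traits: list[str],
    n_boot: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Does a subsample represent the full biome?

    Bootstraps the subsample's per-trait mean contrast D and checks whether
    the full set's mean lies inside the central 95% bootstrap interval.
    Returns one row per trait with the interval and a coverage flag.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if full_contrasts.empty or sub_contrasts.empty:
        raise ValueError("contrast sets must be nonempty")
    rng = np.random.default_rng(seed)
    rows = []
    for t in traits:
        col = f"d_{t}"
        sub = sub_contrasts[col].dropna().to_numpy()
        full_mean = full_contrasts[col].mean()
        idx = rng.integers(0, len(sub), size=(n_boot, len(sub)))
        boots = sub[idx].mean(axis=1)
        lo, hi = np.quantile(boots, [0.025, 0.975])
        rows.append({
            "trait": t, "full_mean": full_mean, "boot_lo": lo, "boot_hi": hi,
            "covered": bool(lo <= full_mean <= hi),
        })
    return pd.DataFrame(rows)
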