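"""Marginal-preserving community null models.

The robustness null randomizes the plot×species stem-count matrix of a
biome while keeping both margins fixed — every plot keeps its total number
of trees, every species keeps its total number of individuals — which
severs the link between a species' traits and where it is locally dominant
without touching either abundance structure.  Tables are drawn with
Patefield's sequential conditional algorithm (the classic r2dtable
sampler): individuals are allocated at random conditional on both margins,
i.e. tables follow the multivariate hypergeometric null of Fisher's exact
test.  The draw is exact — no burn-in or mixing diagnostics are needed.

For each replicate the dominance classification is re-run and the
dominant/rare group trait values are summarized three ways — mean, median
and interquartile range — and the pairwise overlap of the three statistics'
replicate distributions is reported.  Trait values travel with the
species: after randomization, a species' trait row is looked up exactly as
in the observed data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .contrast import StandardizedTraits
from .dominance import classify_plot
from .types import MAIN_BIOMES, TRAITS

STATISTICS = ("mean", "median", "iqr")


def fixed_margin_randomize(
    matrix: np.ndarray, seed: int | np.random.Generator
) -> np.ndarray:
    """Random non-negative integer matrix with the input's margins.

    Row sums (trees per plot) and column sums (individuals per species)
    are conserved exactly; tables follow the fixed-margin hypergeometric
    null (all arrangements of individuals equally likely).  An empty matrix comes back empty; a
    single-row or single-column matrix is fully constrained and comes
    back unchanged.
    """
    m = np.asarray(matrix)
    if m.size == 0:
        return m.copy()
    if (m < 0).any():
        raise ValueError("matrix must be non-negative")
    rows = m.sum(axis=1)
    cols = m.sum(axis=0)
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) \
        else seed
    if m.shape[0] == 1 or m.shape[1] == 1:
        return m.copy()
    return sps.random_table(rows, cols).rvs(
        method="patefield", random_state=rng).astype(m.dtype)


def _matrix_from_trees(trees: pd.DataFrame) -> tuple[np.ndarray, list, list]:
    pivot = trees.pivot_table(index="plot_id", columns="species",
                              values="stems", fill_value=0, aggfunc="sum")
    return pivot.to_numpy(), list(pivot.index), list(pivot.columns)


def _trees_from_matrix(
    matrix: np.ndarray, plot_ids: list, species: list, division: pd.Series
) -> pd.DataFrame:
    rows, cols = np.nonzero(matrix)
    sp = np.asarray(species, dtype=object)[cols]
    return pd.DataFrame({
        "plot_id": np.asarray(plot_ids, dtype=object)[rows],
        "species": sp,
        "stems": matrix[rows, cols],
        "division": division.reindex(sp).to_numpy(),
    })


def _group_summaries(
    trees: pd.DataFrame, ztraits: StandardizedTraits, pct: float
) -> tuple[pd.DataFrame, int]:
    """Classify each plot of a randomized table and summarize group trait
    values under mean, median and IQR; returns (summaries, n_excluded)."""
    frame = ztraits.frame
    by_species = frame.groupby("species")[list(TRAITS)].mean()
    rows = []
    n_excluded = 0
    for pid, grp in trees.groupby("plot_id", sort=True):
        a = classify_plot(grp, pct=pct)
        if a.excluded:
            n_excluded += 1
            continue
        for group, members in (("dom", a.dominant_set), ("rare", a.rare_set)):
            tv = by_species.reindex(list(members)).dropna(how="all")
            if tv.empty:
                continue
            for stat in STATISTICS:
                if stat == "mean":
                    vals = tv.mean()
                elif stat == "median":
                    vals = tv.median()
                else:
                    vals = tv.quantile(0.75) - tv.quantile(0.25)
                rows.append({"plot_id": pid, "group": group, "stat": stat,
                             **{t: vals[t] for t in TRAITS}})
    return pd.DataFrame(rows), n_excluded


def overlap_coefficient(
    a: np.ndarray, b: np.ndarray, n_bins: int | None = None
) -> float:
    """Overlapping coefficient of two samples' frequency distributions,
    estimated from shared-bin histograms (1 = identical, 0 = disjoint).
    Bin count defaults to Sturges' rule on the smaller sample."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        return float("nan")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:
        return 1.0
    if n_bins is None:
        n_bins = int(np.ceil(np.log2(min(len(a), len(b))) + 1))
    edges = np.linspace(lo, hi, n_bins + 1)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    return float(np.minimum(pa / pa.sum(), pb / pb.sum()).sum())


@dataclass
class NullEnsemble:
    biome: str
    n_reps: int
    #: replicate-level summaries: rep, group, stat, one column per trait
    #: (across-plot mean of the plot-level statistic)
    replicates: pd.DataFrame
    #: pairwise overlap of the three statistics' plot-level frequency
    #: distributions pooled over replicates, per group, averaged over traits
    overlap: pd.DataFrame
    excluded_per_rep: list[int]


def null_ensemble(
    plots: pd.DataFrame,
    trees: pd.DataFrame,
    ztraits: StandardizedTraits,
    biome: str,
    n_reps: int = 100,
    seed: int = 0,
    pct: float = 10.0,
) -> NullEnsemble:
    """Run the fixed-margin null for one biome.

    Each replicate randomizes the biome's plot×species matrix, re-runs the
    dominance classifier (plots falling below six species in a replicate
    are excluded by the standard rule and counted), and records the
    across-plot mean of the plot-level group statistic for each of mean,
    median and IQR.  Identical seeds give identical ensembles.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    biome_plots = set(plots.loc[plots["biome"] == biome, "plot_id"])
    sub = trees[trees["plot_id"].isin(biome_plots)]
    matrix, plot_ids, species = _matrix_from_trees(sub)
    division = sub.drop_duplicates("species").set_index("species")["division"]
    rng = np.random.default_rng(seed)

    rep_rows = []
    pooled_parts = []
    excluded = []
    for rep in range(n_reps):
        rand = fixed_margin_randomize(matrix, rng)
        rtrees = _trees_from_matrix(rand, plot_ids, species, division)
        summaries, n_exc = _group_summaries(rtrees, ztraits, pct)
        excluded.append(n_exc)
        if summaries.empty:
            continue
        pooled_parts.append(summaries)
        agg = summaries.groupby(["group", "stat"])[list(TRAITS)].mean()
        for (group, stat), vals in agg.iterrows():
            rep_rows.append({"rep": rep, "group": group, "stat": stat,
                             **{t: vals[t] for t in TRAITS}})
    replicates = pd.DataFrame(rep_rows)
    pooled = (pd.concat(pooled_parts, ignore_index=True)
              if pooled_parts else pd.DataFrame())

    # overlap of the three statistics' plot-level frequency distributions,
    # pooled over replicates
    overlap_rows = []
    for group in ("dom", "rare"):
        for s1, s2 in (("mean", "median"), ("mean", "iqr"), ("median", "iqr")):
            vals = []
            for t in TRAITS:
                if pooled.empty:
                    vals.append(float("nan"))
                    continue
                a = pooled.query("group == @group and stat == @s1")[t]
                b = pooled.query("group == @group and stat == @s2")[t]
                vals.append(overlap_coefficient(a.to_numpy(), b.to_numpy()))
            overlap_rows.append({"group": group, "stat_a": s1, "stat_b": s2,
                                 "overlap": float(np.nanmean(vals))})
    return NullEnsemble(biome, n_reps, replicates,
                        pd.DataFrame(overlap_rows), excluded)


def main_biome_ensembles(
    plots, trees, ztraits, n_reps: int = 100, seed: int = 0,
    biomes: tuple[str, ...] = MAIN_BIOMES,
) -> dict[str, NullEnsemble]:
    """The null ensemble for each of the five main biomes, with per-biome
    seeds derived from one master seed."""
    rng = np.random.default_rng(seed)
    out = {}
    for b in biomes:
        out[b] = null_ensemble(plots, trees, ztraits, b, n_reps,
                               seed=int(rng.integers(2**31 - 1)))
    return out
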