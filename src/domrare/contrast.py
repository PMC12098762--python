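"""Trait transformation and the dominant-minus-rare contrast statistic.

Raw trait values are natural-log transformed (damping outliers) and
z-scored per trait over the full tree-level population of the filtered,
classified dataset, so every trait lives in pooled standard-deviation
units and contrasts are comparable across biomes.  For each plot, the
median z-value over the dominant species and over the rare species is
taken (the median, so unequal group sizes cannot distort the statistic),
and the contrast is

    D = median_z(dominant) - median_z(rare)      [s.d. units]

per trait.  The per-plot gymnosperm percentage of each group and the
groups' scores on the trait PCA axes ride along as extra responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import TRAITS, ValidationError


@dataclass(frozen=True)
class StandardizedTraits:
    """Z-scored trait table plus the standardization constants.

    ``frame`` carries species (and plot_id where intraspecific values
    exist), division, and one z-scored column per trait; ``log_mean`` and
    ``log_sd`` are the per-trait constants of the log layer, kept so new
    values can be projected onto the same scale.
    """

    frame: pd.DataFrame
    log_mean: pd.Series
    log_sd: pd.Series


def standardize_traits(
    traits: pd.DataFrame, population: pd.Index | None = None
) -> StandardizedTraits:
    """Log-transform and z-score the raw trait table.

    ``population`` optionally restricts the rows over which the mean and
    standard deviation of each log trait are computed (the analysis
    population); the transform itself is applied to every row.
    """
    out = traits.copy()
    for t in TRAITS:
        bad = out.index[out[t].notna() & (out[t] <= 0)]
        if len(bad):
            raise ValidationError(
                f"non-positive value for trait {t!r} "
                f"(species {out.loc[bad[0], 'species']!r})"
            )
    logs = np.log(out[list(TRAITS)].astype(float))
    pop = logs if population is None else logs.loc[population]
    mean = pop.mean()
    sd = pop.std(ddof=0)
    zero = sd.index[(sd == 0) | sd.isna()]
    if len(zero):
        raise ValidationError(f"zero variance for trait {zero[0]!r}")
    out[list(TRAITS)] = (logs - mean) / sd
    return StandardizedTraits(out, mean, sd)


def _genus(species: str) -> str:
    return str(species).split(" ")[0].split("_sp")[0]


def lookup_group_traits(
    ztraits: StandardizedTraits,
    plot_id: object,
    species: tuple[str, ...],
) -> pd.DataFrame:
    """Z-trait rows for a plot's species, with fallbacks.

    Preference order per species: the (species, plot) row when
    intraspecific values exist; else the species' mean z-row; else the mean
    over congeneric species (trees identified to genus only); species with
    no usable values are dropped (callers count them).
    """
    frame = ztraits.frame
    cols = list(TRAITS)
    rows = []
    has_plot = "plot_id" in frame.columns
    by_species = frame.groupby("species")[cols].mean()
    for sp in species:
        if has_plot:
            hit = frame[(frame["species"] == sp) & (frame["plot_id"] == plot_id)]
            if len(hit):
                rows.append((sp, hit[cols].iloc[0]))
                continue
        if sp in by_species.index:
            rows.append((sp, by_species.loc[sp]))
            continue
        congeners = by_species[by_species.index.map(_genus) == _genus(sp)]
        if len(congeners):
            rows.append((sp, congeners.mean()))
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame({sp: r for sp, r in rows}).T[cols]


def build_contrasts(
    plots: pd.DataFrame,
    trees: pd.DataFrame,
    ztraits: StandardizedTraits,
    assignments: dict,
) -> pd.DataFrame:
    """Per-plot contrast table: one row per retained plot.

    Columns: plot covariates, then per trait ``dom_<t>``, ``rare_<t>`` and
    ``d_<t> = dom - rare``, plus the gymnosperm percentage of each group
    and its difference.  PCA scores are attached separately
    (:func:`attach_pca_scores`).
    """
    cols = list(TRAITS)
    members = pd.DataFrame(
        [
            (a.plot_id, sp, group)
            for a in assignments.values()
            for group, sset in (("dom", a.dominant_set), ("rare", a.rare_set))
            for sp in sset
        ],
        columns=["plot_id", "species", "group"],
    )
    if members.empty:
        return pd.DataFrame()

    frame = ztraits.frame
    if "plot_id" in frame.columns:
        merged = members.merge(
            frame[["plot_id", "species", *cols]], on=["plot_id", "species"],
            how="left",
        )
    else:
        merged = members.merge(frame[["species", *cols]], on="species", how="left")
    # fallbacks: species mean z-row, then congeneric mean
    missing = merged[cols[0]].isna()
    if missing.any():
        by_species = frame.groupby("species")[cols].mean()
        fill = merged.loc[missing, "species"].map(
            lambda s: by_species.loc[s] if s in by_species.index else None
        )
        ok = fill.notna()
        if ok.any():
            merged.loc[fill[ok].index, cols] = pd.DataFrame(
                list(fill[ok]), index=fill[ok].index
            )
        missing = merged[cols[0]].isna()
    if missing.any():
        by_species = frame.groupby("species")[cols].mean()
        genus_mean = by_species.groupby(by_species.index.map(_genus)).mean()
        fill = merged.loc[missing, "species"].map(
            lambda s: genus_mean.loc[_genus(s)]
            if _genus(s) in genus_mean.index else None
        )
        ok = fill.notna()
        if ok.any():
            merged.loc[fill[ok].index, cols] = pd.DataFrame(
                list(fill[ok]), index=fill[ok].index
            )

    med = merged.groupby(["plot_id", "group"])[cols].median()
    division = trees.drop_duplicates("species").set_index("species")["division"]
    merged["is_gym"] = merged["species"].map(division).eq("gymnosperm")
    gym = 100.0 * merged.groupby(["plot_id", "group"])["is_gym"].mean()

    wide = med.unstack("group")
    out = pd.DataFrame(index=wide.index)
    for group in ("dom", "rare"):
        for t in TRAITS:
            out[f"{group}_{t}"] = wide[(t, group)]
        out[f"gym_pct_{group}"] = gym.unstack("group")[group]
    for t in TRAITS:
        out[f"d_{t}"] = out[f"dom_{t}"] - out[f"rare_{t}"]
    out["d_gym_pct"] = out["gym_pct_dom"] - out["gym_pct_rare"]

    meta_cols = ["plot_id", "biome", "mat_c", "wai", "area_ha", "age",
                 "elevation_m"]
    out = (plots[meta_cols].merge(out, left_on="plot_id", right_index=True,
                                  how="inner")
           .sort_values("plot_id").reset_index(drop=True))
    return out


def attach_pca_scores(contrasts: pd.DataFrame, pca) -> pd.DataFrame:
    """Add PC1/PC2 scores of each group's median trait vector and their
    dominant-minus-rare differences (``d_pc1``, ``d_pc2``)."""
    out = contrasts.copy()
    for group in ("dom", "rare"):
        vecs = out[[f"{group}_{t}" for t in TRAITS]].to_numpy(dtype=float)
        scores = pca.transform(vecs)
        out[f"pc1_{group}"] = scores[:, 0]
        out[f"pc2_{group}"] = scores[:, 1]
    out["d_pc1"] = out["pc1_dom"] - out["pc1_rare"]
    out["d_pc2"] = out["pc2_dom"] - out["pc2_rare"]
    return out


def biome_mean_absolute_difference(
    contrasts: pd.DataFrame, biome: str
) -> float:
    """Mean |D| pooled over the ten traits and a biome's plots; NaN for an
    empty biome.  The analysis uses this to compare contrast magnitude
    across biomes on one scale."""
    sub = contrasts[contrasts["biome"] == biome]
    if sub.empty:
        return float("nan")
    d = sub[[f"d_{t}" for t in TRAITS]].to_numpy(dtype=float)
    return float(np.nanmean(np.abs(d)))
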