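"""Shared domain types and table schemas.

Forest-inventory data moves through the pipeline as three pandas DataFrames
with fixed schemas:

``plots``
    one row per plot: ``plot_id, lat, lon, area_ha, year, age, elevation_m,
    biome, mat_c, wai``.
``trees``
    one row per (plot, species) occurrence: ``plot_id, species, stems,
    division``.
``traits``
    one row per species or per (species, plot): ``species, [plot_id]``, the
    ten trait columns, ``division``.

``mat_c`` is mean annual temperature in degrees Celsius; ``wai`` is the
water-availability index (mean annual precipitation over potential
evapotranspiration, dimensionless; <1 arid, >1 humid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: The ten functional traits, in canonical column order.  Units of the raw
#: layer are the traits' native units (m, m, mm2/mg, um, m, g/cm3, mm,
#: mg/g, ratio, mg); analysis layers are natural-log and z-score.
TRAITS: tuple[str, ...] = (
    "height",
    "rooting_depth",
    "sla",
    "conduit_diameter",
    "crown_diameter",
    "wood_density",
    "bark_thickness",
    "leaf_n",
    "leaf_np",
    "seed_mass",
)

#: The six forest biome labels.
BIOMES: tuple[str, ...] = (
    "tropical_moist",
    "tropical_dry",
    "tropical_conifer",
    "temperate",
    "temperate_conifer",
    "boreal",
)

#: The five "main" biomes: the six minus tropical_conifer, which the
#: plot-level analyses exclude for its small sample.
MAIN_BIOMES: tuple[str, ...] = tuple(b for b in BIOMES if b != "tropical_conifer")

DIVISIONS: tuple[str, ...] = ("angiosperm", "gymnosperm")

PLOT_COLUMNS: tuple[str, ...] = (
    "plot_id", "lat", "lon", "area_ha", "year", "age",
    "elevation_m", "biome", "mat_c", "wai",
)
TREE_COLUMNS: tuple[str, ...] = ("plot_id", "species", "stems", "division")


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A table row violates a domain invariant."""


@dataclass(frozen=True)
class DominanceAssignment:
    """Per-plot outcome of the rank-abundance classifier.

    ``dominant_set`` and ``rare_set`` are disjoint species tuples; an
    excluded plot carries empty sets and a reason in
    {"none", "rarest_gt_10pct", "too_few_species"}.
    """

    plot_id: object
    dominant_set: tuple[str, ...]
    rare_set: tuple[str, ...]
    excluded: bool = False
    exclusion_reason: str = "none"

    def __post_init__(self) -> None:
        if set(self.dominant_set) & set(self.rare_set):
            raise ValidationError(
                f"plot {self.plot_id}: dominant and rare sets overlap"
            )
        if self.excluded and (self.dominant_set or self.rare_set):
            raise ValidationError(
                f"plot {self.plot_id}: excluded plot must carry empty sets"
            )

    @property
    def k_dom(self) -> int:
        return len(self.dominant_set)

    @property
    def k_rare(self) -> int:
        return len(self.rare_set)


@dataclass
class FilterReport:
    """Ordered attrition record: one (name, n_before, n_after) per step."""

    steps: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, name: str, n_before: int, n_after: int) -> None:
        if n_after > n_before:
            raise ValidationError("filter cannot add rows")
        self.steps.append((name, n_before, n_after))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "filter": name,
                "n_before": nb,
                "n_after": na,
                "fraction_removed": 0.0 if nb == 0 else (nb - na) / nb,
            }
            for name, nb, na in self.steps
        ]
        return pd.DataFrame(
            rows, columns=["filter", "n_before", "n_after", "fraction_removed"]
        )


def validate_plots(plots: pd.DataFrame) -> pd.DataFrame:
    """Check the plot-table schema and invariants; returns the frame."""
    for col in PLOT_COLUMNS:
        if col not in plots.columns:
            raise SchemaError(f"plot table missing required column {col!r}")
    bad = plots.index[plots["area_ha"] <= 0]
    if len(bad):
        raise ValidationError(f"non-positive plot area at row {bad[0]}")
    bad = plots.index[plots["wai"] < 0]
    if len(bad):
        raise ValidationError(f"negative water-availability index at row {bad[0]}")
    bad = plots.index[plots["age"] < 0]
    if len(bad):
        raise ValidationError(f"negative forest age at row {bad[0]}")
    unknown = set(plots["biome"]) - set(BIOMES)
    if unknown:
        raise ValidationError(f"unknown biome label(s): {sorted(unknown)}")
    if plots["plot_id"].duplicated().any():
        raise ValidationError("duplicate plot_id in plot table")
    return plots


def validate_trees(trees: pd.DataFrame) -> pd.DataFrame:
    """Check the tree/abundance table schema and invariants."""
    for col in TREE_COLUMNS:
        if col not in trees.columns:
            raise SchemaError(f"tree table missing required column {col!r}")
    bad = trees.index[trees["stems"] < 1]
    if len(bad):
        raise ValidationError(f"stems < 1 at row {bad[0]}")
    if trees.duplicated(["plot_id", "species"]).any():
        raise ValidationError("duplicate (plot_id, species) in tree table")
    unknown = set(trees["division"]) - set(DIVISIONS)
    if unknown:
        raise ValidationError(f"unknown division label(s): {sorted(unknown)}")
    return trees


def validate_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Check the trait-table schema; raw trait values must be positive."""
    if "species" not in traits.columns:
        raise SchemaError("trait table missing required column 'species'")
    for col in TRAITS:
        if col not in traits.columns:
            raise SchemaError(f"trait table missing required column {col!r}")
    for col in TRAITS:
        bad = traits.index[traits[col].notna() & (traits[col] <= 0)]
        if len(bad):
            raise ValidationError(
                f"non-positive raw value for trait {col!r} at row {bad[0]} "
                f"(species {traits.loc[bad[0], 'species']!r})"
            )
    key = ["species", "plot_id"] if "plot_id" in traits.columns else ["species"]
    if traits.duplicated(key).any():
        raise ValidationError(f"duplicate {tuple(key)} in trait table")
    return traits
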