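import math

import numpy as np
import pandas as pd
import pytest

import domrare as dr
from domrare.contrast import (
    StandardizedTraits,
    biome_mean_absolute_difference,
    build_contrasts,
    lookup_group_traits,
    standardize_traits,
)
from domrare.types import TRAITS, DominanceAssignment, ValidationError


def _trait_table(values_by_species: dict[str, float]) -> pd.DataFrame:
    """All ten traits share the same per-species value (keeps hand
    computation one-dimensional)."""
    df = pd.DataFrame({"species": list(values_by_species)})
    for t in TRAITS:
        df[t] = list(values_by_species.values())
    df["division"] = "angiosperm"
    return df


class TestStandardize:
    def test_two_point_population_is_plus_minus_one(self):
        st = standardize_traits(_trait_table({"a": 1.0, "b": math.e**2}))
        # logs {0, 2}: mean 1, sd 1 -> z = {-1, +1}
        assert st.frame[TRAITS[0]].tolist() == pytest.approx([-1.0, 1.0])
        assert st.log_mean[TRAITS[0]] == pytest.approx(1.0)
        assert st.log_sd[TRAITS[0]] == pytest.approx(1.0)

    def test_population_moments(self, small_dataset):
        _, _, _, traits, _ = small_dataset
        st = standardize_traits(traits)
        z = st.frame[list(TRAITS)]
        assert np.allclose(z.mean(), 0.0, atol=1e-9)
        assert np.allclose(z.std(ddof=0), 1.0, atol=1e-9)

    def test_constant_trait_rejected(self):
        with pytest.raises(ValidationError, match="zero variance"):
            standardize_traits(_trait_table({"a": 2.0, "b": 2.0}))

    def test_non_positive_rejected(self):
        tbl = _trait_table({"a": 1.0, "b": 2.0})
        tbl.loc[0, "sla"] = -1.0
        with pytest.raises(ValidationError, match="sla"):
            standardize_traits(tbl)

    def test_restricted_population_sets_the_scale(self):
        tbl = _trait_table({"a": 1.0, "b": math.e**2, "c": math.e**10})
        st = standardize_traits(tbl, population=pd.Index([0, 1]))
        assert st.frame[TRAITS[0]].iloc[:2].tolist() == pytest.approx([-1, 1])
        assert st.frame[TRAITS[0]].iloc[2] == pytest.approx(9.0)


class TestGroupLookup:
    def test_genus_fallback_uses_congeneric_mean(self):
        st = standardize_traits(_trait_table({
            "Picea abies": 1.0, "Picea glauca": math.e**2,
            "Fagus sylvatica": math.e,
        }))
        out = lookup_group_traits(st, "p", ("Picea obovata",))
        # Picea mean of z-values; z for the two Picea rows straddle their mean
        expect = st.frame.loc[[0, 1], TRAITS[0]].mean()
        assert out[TRAITS[0]].iloc[0] == pytest.approx(expect)

    def test_unknown_species_dropped(self):
        st = standardize_traits(_trait_table({"Picea abies": 1.0,
                                              "Fagus sylvatica": math.e}))
        out = lookup_group_traits(st, "p", ("Quercus robur",))
        assert out.empty


def _manual_dataset():
    """Two plots, six species, trait values engineered so medians are
    hand-computable: z-values equal log(raw) exactly under sd-1 scaling."""
    plots = pd.DataFrame({
        "plot_id": ["p1", "p2"], "lat": 0.0, "lon": 0.0, "area_ha": 0.1,
        "year": 2000, "age": 50, "elevation_m": 100.0,
        "biome": ["temperate", "boreal"], "mat_c": [9.0, 0.0],
        "wai": [1.0, 1.5],
    })
    sp = list("ABCDEF")
    trees = pd.concat([
        pd.DataFrame({"plot_id": p, "species": sp,
                      "stems": [30, 20, 10, 5, 2, 1],
                      "division": ["gymnosperm", "angiosperm"] * 3})
        for p in ("p1", "p2")
    ], ignore_index=True)
    traits = _trait_table(dict(zip(sp, np.exp([2.0, 1.0, 0.5, -0.5, -1.0,
                                               -2.0]))))
    traits["division"] = ["gymnosperm", "angiosperm"] * 3
    return plots, trees, traits


class TestBuildContrasts:
    def test_difference_and_gym_percentage(self):
        plots, trees, traits = _manual_dataset()
        st = standardize_traits(traits)
        assignments = {p: DominanceAssignment(p, ("A", "B"), ("E", "F"))
                       for p in ("p1", "p2")}
        out = build_contrasts(plots, trees, st, assignments)
        t0 = TRAITS[0]
        z = st.frame.set_index("species")[t0]
        expect = (z[["A", "B"]].mean() - z[["E", "F"]].mean())
        assert out[f"d_{t0}"].tolist() == pytest.approx([expect, expect])
        # dominant set {A gym, B angio} -> 50%; rare {E gym, F angio} -> 50%
        assert out["gym_pct_dom"].tolist() == pytest.approx([50.0, 50.0])
        assert out["d_gym_pct"].tolist() == pytest.approx([0.0, 0.0])

    def test_swapping_labels_negates_d(self):
        plots, trees, traits = _manual_dataset()
        st = standardize_traits(traits)
        fwd = {p: DominanceAssignment(p, ("A", "B"), ("E", "F"))
               for p in ("p1", "p2")}
        rev = {p: DominanceAssignment(p, ("E", "F"), ("A", "B"))
               for p in ("p1", "p2")}
        d_fwd = build_contrasts(plots, trees, st, fwd)
        d_rev = build_contrasts(plots, trees, st, rev)
        for t in TRAITS:
            assert d_fwd[f"d_{t}"].to_numpy() == pytest.approx(
                -d_rev[f"d_{t}"].to_numpy())

    def test_raw_scale_change_leaves_d_unchanged(self):
        plots, trees, traits = _manual_dataset()
        assignments = {p: DominanceAssignment(p, ("A", "B"), ("E", "F"))
                       for p in ("p1", "p2")}
        d1 = build_contrasts(plots, trees, standardize_traits(traits),
                             assignments)
        scaled = traits.copy()
        scaled[TRAITS[0]] = scaled[TRAITS[0]] * 1000.0  # e.g. unit change
        d2 = build_contrasts(plots, trees, standardize_traits(scaled),
                             assignments)
        assert d1[f"d_{TRAITS[0]}"].to_numpy() == pytest.approx(
            d2[f"d_{TRAITS[0]}"].to_numpy())

    def test_trait_identical_groups_give_zero(self):
        plots, trees, traits = _manual_dataset()
        # make C, D carbon copies of A, B: the groups differ in identity
        # but not in trait values, so every D must vanish
        for t in TRAITS:
            traits.loc[traits["species"] == "C", t] = \
                traits.loc[traits["species"] == "A", t].to_numpy()
            traits.loc[traits["species"] == "D", t] = \
                traits.loc[traits["species"] == "B", t].to_numpy()
        st = standardize_traits(traits)
        assignments = {"p1": DominanceAssignment("p1", ("A", "B"),
                                                 ("C", "D"))}
        out = build_contrasts(plots, trees, st, assignments)
        for t in TRAITS:
            assert out[f"d_{t}"].iloc[0] == pytest.approx(0.0, abs=1e-12)


class TestBiomeMeanAbsoluteDifference:
    def test_absolute_value_pooling(self):
        df = pd.DataFrame({"biome": ["temperate", "temperate"]})
        for t in TRAITS:
            df[f"d_{t}"] = [0.2, -0.2]
        assert biome_mean_absolute_difference(df, "temperate") \
            == pytest.approx(0.2)
        assert math.isnan(biome_mean_absolute_difference(df, "boreal"))

    def test_scales_with_coupling_strength(self):
        base = dr.homogeneous_config(400, mat_span=(5, 15))
        vals = []
        for beta in (0.3, 0.6):
            cfg = base.with_coupling(dr.constant_coupling("height", beta))
            res = dr.run_pipeline(cfg, seed=5, null_reps=0)
            vals.append(res.contrasts["d_height"].mean())
        assert vals[1] > vals[0] > 0
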