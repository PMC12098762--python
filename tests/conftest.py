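import numpy as np
import pandas as pd
import pytest

import domrare as dr
from domrare.types import TRAITS


@pytest.fixture(scope="session")
def small_dataset():
    """A modest default-structure synthetic inventory shared across tests."""
    cfg = dr.GeneratorConfig().scaled(60)
    plots, trees, traits, truth = dr.generate(cfg, seed=7)
    return cfg, plots, trees, traits, truth


@pytest.fixture(scope="session")
def small_run():
    """A full pipeline run on a small neutral inventory."""
    cfg = dr.GeneratorConfig().scaled(60)
    return dr.run_pipeline(cfg, seed=7, null_reps=0, wilcoxon_min_plots=30)


@pytest.fixture()
def tiny_tables():
    """Three hand-written plots with eight species, fully valid."""
    plots = pd.DataFrame({
        "plot_id": ["p1", "p2", "p3"],
        "lat": [45.0, 46.0, 47.0],
        "lon": [7.0, 8.0, 9.0],
        "area_ha": [0.05, 0.10, 0.25],
        "year": [2000, 2005, 2010],
        "age": [60, 40, 120],
        "elevation_m": [300.0, 800.0, 1500.0],
        "biome": ["temperate", "temperate", "boreal"],
        "mat_c": [9.0, 8.0, 1.0],
        "wai": [1.2, 1.0, 1.6],
    })
    species = [f"sp{i}" for i in range(1, 9)]
    rows = []
    counts = {"p1": [30, 20, 10, 5, 2, 1], "p2": [25, 12, 8, 6, 3, 1],
              "p3": [40, 18, 9, 7, 2, 1]}
    for pid, cc in counts.items():
        for sp, c in zip(species[:6] if pid != "p3" else species[2:], cc):
            rows.append({"plot_id": pid, "species": sp, "stems": c,
                         "division": "gymnosperm" if sp in ("sp7", "sp8")
                         else "angiosperm"})
    trees = pd.DataFrame(rows)
    rng = np.random.default_rng(0)
    traits = pd.DataFrame({"species": species})
    for t in TRAITS:
        traits[t] = np.exp(rng.normal(1.0, 0.5, size=len(species)))
    traits["division"] = ["gymnosperm" if s in ("sp7", "sp8")
                          else "angiosperm" for s in species]
    return plots, trees, traits
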