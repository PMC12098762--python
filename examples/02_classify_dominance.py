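"""Classify locally dominant and rare species from rank-abundance curves.

Plots with 6-19 species contribute their two most and two least abundant
species; richer plots the top and bottom 10%.  A plot whose rarest species
still holds >10% of its stems is excluded — its rare species are not
clearly rare.
"""

import pandas as pd

import domrare as dr
from domrare.dominance import classify_plot

# a hand-built plot: six species, steep abundance curve
plot = pd.DataFrame({
    "plot_id": "demo",
    "species": ["Fagus sylvatica", "Picea abies", "Abies alba",
                "Acer pseudoplatanus", "Sorbus aucuparia", "Taxus baccata"],
    "stems": [38, 21, 9, 4, 2, 1],
    "division": ["angiosperm", "gymnosperm", "gymnosperm",
                 "angiosperm", "angiosperm", "gymnosperm"],
})
a = classify_plot(plot)
print("dominant:", ", ".join(a.dominant_set))
print("rare:    ", ", ".join(a.rare_set))
print("The two ends of the rank-abundance curve; every trait contrast "
      "downstream\ncompares these two sets within the same plot.\n")

# the exclusion rule on a flat community
flat = plot.assign(stems=[7, 7, 7, 7, 7, 7])
b = classify_plot(flat)
print(f"flat community excluded: {b.excluded} "
      f"(reason: {b.exclusion_reason})")
print("With every species at 7/42 ≈ 17% of stems, 'rare' species are not "
      "distinguishable\nfrom dominants, so the plot is dropped.\n")

# whole-dataset classification with the temperate subsample
plots, trees, traits, _ = dr.generate(dr.GeneratorConfig().scaled(100),
                                      seed=7)
assignments, info = dr.classify_all(trees, plots,
                                    temperate_subsample=(50, 1))
print(f"classified {len(assignments)} plots; "
      f"{len(info['excluded'])} excluded; "
      f"temperate biome subsampled to "
      f"{len(info['temperate_subsample'])} plots")
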