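"""Compute per-plot trait contrasts D and test them per biome.

Traits are log-transformed and z-scored over all tree-level occurrences,
then summarized per plot as the dominant-group median minus the rare-group
median: D > 0 means the locally dominant species carry higher trait values
than the locally rare ones, in pooled standard-deviation units.
"""

import domrare as dr

# couple height to dominance so there is a real signal to find
config = dr.GeneratorConfig().scaled(150).with_coupling(
    dr.constant_coupling("height", beta=0.6))
result = dr.run_pipeline(config, seed=11, null_reps=0,
                         wilcoxon_min_plots=50)

c = result.contrasts
print(f"{len(c)} plots with contrasts\n")
print("mean contrast D per trait (s.d. units):")
for t in dr.TRAITS:
    print(f"  {t:18s} {c[f'd_{t}'].mean():+.3f}")
print("\nHeight stands out because the generator made tall species "
      "locally dominant;\nthe other traits move only through their "
      "correlation with height.")

wil = result.wilcoxon.query("~skipped and response == 'd_height'")
print("\nsigned-rank test of D_height per biome:")
print(wil[["biome", "n", "w", "p"]].to_string(index=False))
print("\nSmall p-values: within those biomes the dominant species are "
      "systematically\ntaller than the rare species in the same plot.")

for biome in ("tropical_moist", "temperate_conifer"):
    mad = dr.biome_mean_absolute_difference(c, biome)
    print(f"mean |D| over all traits, {biome}: {mad:.3f} s.d.")
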