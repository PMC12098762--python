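"""Generate a synthetic global forest inventory and inspect its realism.

The generator produces three linked tables — plots (with climate), a
plot×species stem-count table, and per-occurrence trait values — with the
statistical structure a global plot compilation shows: ~0.07 ha plots,
speciose tropics vs. species-poor boreal forests, log-series abundance
curves, gymnosperms concentrated in cold/humid climates, and weakly
negatively correlated temperature and water-availability fields.
"""

from scipy.stats import spearmanr

import domrare as dr

config = dr.GeneratorConfig().scaled(200)   # 200 plots per biome
plots, trees, traits, truth = dr.generate(config, seed=42)

print(f"{len(plots)} plots, {len(trees)} plot-species records\n")
print(dr.summarize_realism(plots, trees).to_string(index=False,
                                                   float_format="%.3f"))

rho = spearmanr(plots["mat_c"], plots["wai"]).statistic
print(f"\nSpearman correlation of temperature and water availability: "
      f"{rho:+.3f}")
print("A value near -0.09 means the two climate gradients are nearly "
      "independent,\nso their effects on trait contrasts can be separated "
      "downstream.")
print("Mean plot size near 0.07 ha and the gymnosperm share rising from "
      "tropical\nto boreal rows mirror the inventory structure the "
      "analysis assumes.")
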