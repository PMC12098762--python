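# domrare

Functional-trait contrasts between locally **dom**inant and **rare** tree
species along climate gradients.

## The scientific problem

In almost every forest plot a handful of species holds most of the stems
while many species are represented by one or two individuals.  Whether
those locally dominant species are *functionally* different from the
locally rare ones — taller, denser-wooded, deeper-rooted, more
conservative in their leaves — and whether that difference grows or
shrinks along temperature and water-availability gradients, is a central
question of trait-based community ecology.  `domrare` implements the full
analysis pipeline for this question as a tested, reusable Python library,
exercised end-to-end on a synthetic forest-inventory generator whose
trait–dominance coupling is known exactly, so every stage can be verified
against ground truth.

It is aimed at community ecologists and macroecologists who work with
plot-based inventory data (plot id, species, stem counts, climate
covariates, per-species trait values).

## The method

Per forest plot with `S ≥ 6` species, species are ranked by stem count;
the top and bottom 10% (the top-2 and bottom-2 for `6 ≤ S ≤ 19`,
`k = max(2, ⌊S·pct/100⌋)` for `S ≥ 20`) are the plot's **dominant** and
**rare** sets.  Plots whose rarest species exceeds 10% of stems are
excluded.  Trait values (10 traits: height, rooting depth, SLA, conduit
diameter, crown diameter, wood density, bark thickness, leaf N, leaf N:P,
seed mass) are `ln`-transformed and z-scored over all tree-level
occurrences, and the per-plot contrast for trait *j* is

    D_j = median(z_j, dominant set) − median(z_j, rare set)   [s.d. units]

`D` is tested per biome with Wilcoxon signed-rank tests (exact null for
small tie-free samples, Edgeworth-corrected normal approximation
otherwise), ordinated with a correlation-basis PCA, and modelled along
climate with

    D ~ t + t² + w + w² + t·w + plot size + forest age + elevation + biome

on z-scored predictors, with the model R² decomposed into grouped
LMG/Shapley importance shares (t with t² as the temperature group, w with
w² as the water group) and the fitted quadratic's roots and vertex
reported in original climate units.  Robustness is checked with a
fixed-margin (Patefield / `r2dtable`-style) community null model that
preserves every plot's tree total and every species' individual total.

## Worked example

`examples/04_climate_model.py` builds a synthetic inventory in which the
height contrast is coupled to temperature through a parabola crossing zero
at 5 °C and 25 °C (vertex 15 °C), fits the climate model, and prints:

```
n = 3910 plots, R² = 0.267

standardized coefficients:
  t      -0.0077
  t2     -0.6414
  ...

grouped LMG importance shares (sum to R²):
  temperature  0.2540
  water        0.0003
  interaction  0.0118
  ...

fitted temperature curve: zero crossings at 4.89 and 25.06 °C, vertex at 14.98 °C
```

The negative `t²` coefficient is the hump shape; the LMG shares say
essentially all explained variance sits in the temperature group (as
constructed); and the recovered crossings/vertex agree with the built-in
5/25/15 °C geometry to ~0.1 °C.  The other example scripts walk through
simulation realism (`01`), the dominance classifier (`02`), trait
contrasts and per-biome tests (`03`), and the null model (`05`).

A thin CLI wraps the same stages:

```bash
domrare simulate --seed 1 --out sim/
domrare run --seed 1 --reps 100 --out run/
```

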