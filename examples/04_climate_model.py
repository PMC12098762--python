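"""Model a trait contrast along temperature and water availability.

The contrast D is regressed on z-scored temperature (t, t²), water
availability (w, w²), their interaction and covariates; the model R² is
decomposed into grouped LMG importance shares (each group's average
incremental R² over all orders of model entry), and the fitted quadratic's
roots and vertex are reported in °C.
"""

import domrare as dr
from domrare.stats import fit_climate_model

# construct a hump-shaped temperature response: contrast crosses zero at
# 5 and 25 degC and peaks at 15 degC
coupling = dr.quadratic_temperature_coupling(
    amplitude=0.5, root_low=5.0, root_high=25.0, trait="height")
config = dr.homogeneous_config(4000).with_coupling(coupling)
result = dr.run_pipeline(config, seed=3, null_reps=0)

fit = fit_climate_model(result.contrasts, "d_height",
                        covariates=("plot_size", "forest_age", "elevation"))
print(f"n = {fit.n} plots, R² = {fit.r_squared:.3f}\n")
print("standardized coefficients:")
for k in ("t", "t2", "w", "w2", "t_x_w"):
    print(f"  {k:6s} {fit.params[k]:+.4f}")
print("\ngrouped LMG importance shares (sum to R²):")
for g, s in fit.lmg_shares.items():
    print(f"  {g:12s} {s:.4f}")

geo = fit.geometry["mat_c"]
print(f"\nfitted temperature curve: zero crossings at "
      f"{geo['roots'][0]:.2f} and {geo['roots'][1]:.2f} °C, "
      f"vertex at {geo['vertex']:.2f} °C")
print("The construction placed them at 5, 25 and 15 °C — the fit recovers "
      "the geometry\nfrom the noisy per-plot contrasts.  The temperature "
      "group dominates the LMG\nshares because only temperature was "
      "coupled to dominance.")
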