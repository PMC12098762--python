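"""End-to-end orchestration: simulate → filter → classify → contrast →
PCA → climate models → null models, with a reproducible run manifest.

Every stage writes a re-readable TSV (or JSON) artifact; the manifest
records the seed, a configuration hash and per-stage row counts, and is
byte-identical across runs with the same seed and configuration.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as dio
from .contrast import attach_pca_scores, build_contrasts, standardize_traits
from .dominance import classify_all
from .filters import FilterThresholds, apply_filters
from .nullmodels import main_biome_ensembles
from .pca import fit_pca
from .stats import (
    RESPONSES,
    biome_test_battery,
    compare_importance,
    fit_all_responses,
    importance_table,
)
from .synthetic import GeneratorConfig, generate
from .types import TRAITS


@dataclass
class PipelineResult:
    plots: pd.DataFrame
    trees: pd.DataFrame
    filtered_plots: pd.DataFrame
    filter_report: pd.DataFrame
    assignments: dict
    contrasts: pd.DataFrame
    pca: object
    wilcoxon: pd.DataFrame
    climate_fits: dict
    importance_comparison: dict
    null_overlap: dict
    manifest: dict
    truth: dict = field(default_factory=dict)


def _config_hash(*parts: object) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(repr(p).encode())
    return h.hexdigest()[:16]


def run_pipeline(
    gen_config: GeneratorConfig,
    seed: int,
    out_dir: str | None = None,
    thresholds: FilterThresholds | None = None,
    pct: float = 10.0,
    temperate_subsample: tuple[int, int] | None = None,
    wilcoxon_min_plots: int = 200,
    null_reps: int = 0,
    null_seed: int | None = None,
) -> PipelineResult:
    """Run the full analysis on a synthetic inventory.

    ``null_reps = 0`` skips the (expensive) null-model stage.  When
    ``out_dir`` is given, every stage artifact plus ``manifest.json`` is
    written there.
    """
    thresholds = thresholds or FilterThresholds()

    plots, trees, traits, truth = generate(gen_config, seed)
    filtered, report = apply_filters(plots, trees, thresholds)
    assignments, cls_info = classify_all(
        trees, filtered, pct=pct, temperate_subsample=temperate_subsample
    )

    # standardization population: tree-level occurrences in retained,
    # classified plots
    retained = set(assignments)
    pop = traits.index[traits["plot_id"].isin(retained)] \
        if "plot_id" in traits.columns else None
    ztraits = standardize_traits(traits, population=pop)

    contrasts = build_contrasts(filtered, trees, ztraits, assignments)
    pca_rows = np.vstack([
        contrasts[[f"dom_{t}" for t in TRAITS]].to_numpy(dtype=float),
        contrasts[[f"rare_{t}" for t in TRAITS]].to_numpy(dtype=float),
    ])
    pca_rows = pca_rows[~np.isnan(pca_rows).any(axis=1)]
    pca = fit_pca(pca_rows)
    contrasts = attach_pca_scores(contrasts, pca)

    wilcoxon = biome_test_battery(contrasts, min_plots=wilcoxon_min_plots)

    climate_fits = {}
    fit_notes = {}
    for resp in RESPONSES:
        try:
            climate_fits.update(fit_all_responses(contrasts, (resp,)))
        except ValueError as exc:
            fit_notes[resp] = str(exc)
    shares = importance_table(climate_fits)
    if not shares.empty:
        tshare = shares.query("group == 'temperature'")["share"].to_numpy()
        wshare = shares.query("group == 'water'")["share"].to_numpy()
        comparison = compare_importance(tshare, wshare)
    else:
        comparison = {}

    null_overlap: dict = {}
    if null_reps > 0:
        ens = main_biome_ensembles(
            filtered, trees, ztraits, n_reps=null_reps,
            seed=seed if null_seed is None else null_seed,
        )
        null_overlap = {
            b: e.overlap.to_dict(orient="records") for b, e in ens.items()
        }

    manifest = {
        "seed": int(seed),
        "config_hash": _config_hash(gen_config, thresholds, pct,
                                    temperate_subsample, null_reps),
        "stage_counts": {
            "plots_generated": int(len(plots)),
            "plots_filtered": int(len(filtered)),
            "plots_classified": int(len(assignments)),
            "plots_excluded_rarest": int(sum(
                1 for r in cls_info["excluded"].values()
                if r == "rarest_gt_10pct")),
            "contrast_rows": int(len(contrasts)),
            "climate_fits": len(climate_fits),
        },
        "filter_report": report.to_frame().to_dict(orient="records"),
        "climate_fit_skipped": fit_notes,
        "temperate_subsample_n": (len(cls_info["temperate_subsample"])
                                  if cls_info["temperate_subsample"] else 0),
    }

    result = PipelineResult(
        plots=plots, trees=trees, filtered_plots=filtered,
        filter_report=report.to_frame(), assignments=assignments,
        contrasts=contrasts, pca=pca, wilcoxon=wilcoxon,
        climate_fits=climate_fits, importance_comparison=comparison,
        null_overlap=null_overlap, manifest=manifest, truth=truth,
    )
    if out_dir is not None:
        _write_outputs(result, traits, out_dir)
    return result


def _write_outputs(res: PipelineResult, traits: pd.DataFrame, out_dir: str):
    os.makedirs(out_dir, exist_ok=True)
    dio.write_frame(res.plots, os.path.join(out_dir, "plots.tsv"))
    dio.write_frame(res.trees, os.path.join(out_dir, "trees.tsv"))
    dio.write_frame(traits, os.path.join(out_dir, "traits.tsv"))
    dio.write_frame(res.filtered_plots,
                    os.path.join(out_dir, "plots_filtered.tsv"))
    dio.write_frame(res.filter_report,
                    os.path.join(out_dir, "filter_report.tsv"))
    assign = pd.DataFrame(
        [(a.plot_id, sp, group)
         for a in res.assignments.values()
         for group, ss in (("dominant", a.dominant_set),
                           ("rare", a.rare_set))
         for sp in ss],
        columns=["plot_id", "species", "class"],
    )
    dio.write_frame(assign, os.path.join(out_dir, "assignments.tsv"))
    dio.write_frame(res.contrasts, os.path.join(out_dir, "contrasts.tsv"))
    dio.write_frame(res.wilcoxon, os.path.join(out_dir, "wilcoxon.tsv"))
    if res.pca is not None:
        dio.write_frame(res.pca.loadings.reset_index(names="trait"),
                        os.path.join(out_dir, "pca_loadings.tsv"))
        dio.write_frame(
            pd.DataFrame({
                "component": [f"pc{i+1}" for i in
                              range(len(res.pca.explained_fraction))],
                "explained_fraction": res.pca.explained_fraction,
            }),
            os.path.join(out_dir, "explained.tsv"))
    fit_rows = []
    for resp, f in res.climate_fits.items():
        row = {"response": resp, "n": f.n, "r_squared": f.r_squared,
               "aic_full": f.aic_full, "aic_linear_water": f.aic_linear_water}
        row.update({f"coef_{k}": v for k, v in f.params.items()})
        row.update({f"lmg_{k}": v for k, v in f.lmg_shares.items()})
        for var in ("mat_c", "wai"):
            g = f.geometry[var]
            roots = list(g["roots"]) + [float("nan")] * (2 - len(g["roots"]))
            row[f"{var}_root_lo"], row[f"{var}_root_hi"] = roots[:2]
            row[f"{var}_vertex"] = g["vertex"]
        fit_rows.append(row)
    dio.write_frame(pd.DataFrame(fit_rows),
                    os.path.join(out_dir, "climate_fits.tsv"))
    with open(os.path.join(out_dir, "importance_test.json"), "w") as fh:
        json.dump(res.importance_comparison, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if res.null_overlap:
        with open(os.path.join(out_dir, "overlap_report.json"), "w") as fh:
            json.dump(res.null_overlap, fh, indent=2, sort_keys=True)
            fh.write("\n")
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(res.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    dio.write_manifest(res.manifest, os.path.join(out_dir, "manifest.json"))


def sensitivity_suite(
    gen_config: GeneratorConfig,
    seed: int,
    pcts: tuple[float, ...] = (5.0, 10.0, 15.0),
    age_mins: tuple[float, ...] = (25.0, 30.0, 35.0),
) -> pd.DataFrame:
    """Re-run classification and contrasts under alternative settings.

    One synthetic dataset is generated; each variant (selection percentage,
    minimum forest age) is applied to the same data so differences between
    variants are not confounded with sampling noise.  Returns one row per
    variant with the retained-plot count and the per-trait mean contrast.
    """
    plots, trees, traits, _ = generate(gen_config, seed)
    rows = []

    def run_variant(kind: str, value: float, thresholds: FilterThresholds,
                    pct: float):
        filtered, _rep = apply_filters(plots, trees, thresholds)
        assignments, _info = classify_all(trees, filtered, pct=pct)
        retained = set(assignments)
        pop = traits.index[traits["plot_id"].isin(retained)]
        ztraits = standardize_traits(traits, population=pop)
        contrasts = build_contrasts(filtered, trees, ztraits, assignments)
        row = {"variant": kind, "value": value,
               "n_plots": int(len(contrasts))}
        for t in TRAITS:
            row[f"mean_d_{t}"] = (float(contrasts[f"d_{t}"].mean())
                                  if len(contrasts) else float("nan"))
        rows.append(row)

    for pct in pcts:
        run_variant("pct", pct, FilterThresholds(), pct)
    for age in age_mins:
        run_variant("age_min", age, FilterThresholds(age_min=age), 10.0)
    return pd.DataFrame(rows)
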