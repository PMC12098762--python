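import itertools
import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from domrare.stats import (
    compare_importance,
    fit_climate_model,
    lmg_importance,
    biome_test_battery,
    trait_climate_correlation,
    wilcoxon_signed_rank,
)


# --- independent oracles ----------------------------------------------------

def enumerate_signed_rank_p(d: np.ndarray) -> tuple[float, float]:
    """Brute-force two-sided exact test: every sign pattern of 2^n."""
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    m = n * (n + 1) / 2
    lo, hi = min(w_obs, m - w_obs), max(w_obs, m - w_obs)
    hits = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if w <= lo or w >= hi:
            hits += 1
    return w_obs, hits / 2**n


def lmg_factorial_oracle(groups: dict, y: np.ndarray) -> dict:
    """Average sequential R² gains over every ordering of the groups,
    with R² taken from statsmodels rather than the package's solver."""
    names = list(groups)

    def r2(subset):
        if not subset:
            return 0.0
        x = np.column_stack([groups[g] for g in subset])
        return sm.OLS(y, sm.add_constant(x)).fit().rsquared

    shares = {g: 0.0 for g in names}
    perms = list(itertools.permutations(names))
    for perm in perms:
        seen = []
        for g in perm:
            before = r2(seen)
            seen.append(g)
            shares[g] += r2(seen) - before
    return {g: s / len(perms) for g, s in shares.items()}


# --- signed-rank ------------------------------------------------------------

class TestWilcoxon:
    def test_three_positive_differences(self):
        r = wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0]))
        assert r.w == 6 and r.p == pytest.approx(0.25)
        assert r.method == "exact"

    def test_antisymmetry(self):
        d = np.array([1.5, -2.0, 3.0, 0.5, -4.0])
        a = wilcoxon_signed_rank(d)
        b = wilcoxon_signed_rank(-d)
        assert b.w == pytest.approx(len(d) * (len(d) + 1) / 2 - a.w)
        assert b.p == pytest.approx(a.p)

    def test_all_zero_is_undefined(self):
        r = wilcoxon_signed_rank(np.zeros(3))
        assert r.method == "undefined" and math.isnan(r.p)
        assert r.n_zero_dropped == 3

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            n = int(rng.integers(4, 13))
            d = rng.standard_normal(n)
            d = np.where(d == 0, 0.1, d)
            r = wilcoxon_signed_rank(d)
            w_ref, p_ref = enumerate_signed_rank_p(d)
            assert r.method == "exact"
            assert r.w == pytest.approx(w_ref)
            assert r.p == pytest.approx(p_ref)

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            d = rng.standard_normal(int(rng.integers(6, 20)))
            r = wilcoxon_signed_rank(d)
            ref = sps.wilcoxon(d, method="exact")
            assert r.p == pytest.approx(ref.pvalue)

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(2)
        for n in range(15, 26):
            d = rng.standard_normal(n)
            exact = wilcoxon_signed_rank(d)
            approx = wilcoxon_signed_rank(d, exact_max_n=0)
            assert exact.method == "exact"
            assert approx.method == "normal_approx"
            assert abs(approx.p - exact.p) < 0.01

    def test_paired_input_equals_difference_input(self):
        rng = np.random.default_rng(3)
        dom, rare = rng.standard_normal(10), rng.standard_normal(10)
        assert wilcoxon_signed_rank(dom, rare).p == pytest.approx(
            wilcoxon_signed_rank(dom - rare).p)


def test_battery_skips_small_biomes(small_run):
    grid = biome_test_battery(small_run.contrasts, min_plots=10**6)
    assert grid["skipped"].all()
    grid = biome_test_battery(small_run.contrasts, min_plots=10)
    assert not grid["skipped"].any()
    assert len(grid) == 13 * 5


# --- correlations -----------------------------------------------------------

class TestCorrelation:
    def test_exact_linear(self):
        x = np.arange(10.0)
        out = trait_climate_correlation(x, 2 * x + 1)
        assert out["r"] == pytest.approx(1.0)

    def test_t_formula(self):
        # engineered r = 0.6 at n = 27 -> t = 0.6*5/0.8 = 3.75
        rng = np.random.default_rng(4)
        x = rng.standard_normal(27)
        y = rng.standard_normal(27)
        out = trait_climate_correlation(x, y)
        r, n = out["r"], out["n"]
        assert out["t"] == pytest.approx(r * math.sqrt(n - 2)
                                         / math.sqrt(1 - r**2))
        synthetic = {"r": 0.6, "n": 27}
        t = synthetic["r"] * math.sqrt(25) / math.sqrt(1 - 0.36)
        assert t == pytest.approx(3.75)

    def test_permutation_destroys_correlation(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(4000)
        y = 0.8 * x + 0.2 * rng.standard_normal(4000)
        assert trait_climate_correlation(x, y)["r"] > 0.9
        out = trait_climate_correlation(x, rng.permutation(y),
                                        method="spearman")
        assert abs(out["r"]) < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            trait_climate_correlation(np.ones(10), np.arange(10.0))


# --- LMG --------------------------------------------------------------------

class TestLMG:
    def test_single_group_gets_full_r2(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((100, 2))
        y = x @ [1.0, -0.5] + rng.standard_normal(100)
        shares = lmg_importance({"all": x}, y)
        full = sm.OLS(y, sm.add_constant(x)).fit().rsquared
        assert shares["all"] == pytest.approx(full, abs=1e-12)

    def test_orthogonal_groups_get_marginal_r2(self):
        n = 400
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)  # orthogonal to x1
        y = 2 * x1 + x2
        shares = lmg_importance({"a": x1[:, None], "b": x2[:, None]}, y)
        m1 = sm.OLS(y, sm.add_constant(x1)).fit().rsquared
        m2 = sm.OLS(y, sm.add_constant(x2)).fit().rsquared
        assert shares["a"] == pytest.approx(m1, abs=1e-9)
        assert shares["b"] == pytest.approx(m2, abs=1e-9)

    @pytest.mark.parametrize("n_groups", [2, 3, 4])
    def test_matches_factorial_oracle(self, n_groups):
        rng = np.random.default_rng(7 + n_groups)
        groups = {f"g{i}": rng.standard_normal((80, rng.integers(1, 3)))
                  for i in range(n_groups)}
        y = sum(g.sum(axis=1) for g in groups.values()) \
            + rng.standard_normal(80)
        mine = lmg_importance(groups, y)
        ref = lmg_factorial_oracle(groups, y)
        for g in groups:
            assert mine[g] == pytest.approx(ref[g], abs=1e-9)

    def test_shares_sum_to_r2(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            groups = {f"g{i}": rng.standard_normal((60, 2))
                      for i in range(4)}
            y = rng.standard_normal(60)
            shares = lmg_importance(groups, y)
            x = np.column_stack(list(groups.values()))
            full = sm.OLS(y, sm.add_constant(x)).fit().rsquared
            assert sum(shares.values()) == pytest.approx(full, abs=1e-9)

    def test_group_limit_guard(self):
        groups = {f"g{i}": np.ones((5, 1)) for i in range(25)}
        with pytest.raises(ValueError, match="guard"):
            lmg_importance(groups, np.ones(5))


# --- climate model ----------------------------------------------------------

def _contrast_frame(n=600, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "biome": rng.choice(["temperate", "boreal"], size=n),
        "mat_c": rng.uniform(-5, 30, size=n),
        "wai": rng.uniform(0.3, 3.0, size=n),
        "area_ha": rng.uniform(0.02, 2.0, size=n),
        "age": rng.uniform(25, 150, size=n),
        "elevation_m": rng.uniform(0, 2000, size=n),
    })


class TestClimateModel:
    def test_identity_response_recovers_unit_coefficient(self):
        df = _contrast_frame()
        z = (df["mat_c"] - df["mat_c"].mean()) / df["mat_c"].std(ddof=0)
        df["d_x"] = z
        fit = fit_climate_model(df, "d_x")
        assert fit.params["t"] == pytest.approx(1.0, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_constructed_quadratic_geometry(self):
        df = _contrast_frame(seed=1)
        # D = -(t - 5)(t - 25)/100: roots 5 and 25, vertex 15
        df["d_x"] = -(df["mat_c"] - 5) * (df["mat_c"] - 25) / 100.0
        fit = fit_climate_model(df, "d_x")
        g = fit.geometry["mat_c"]
        assert g["roots"][0] == pytest.approx(5.0, abs=1e-6)
        assert g["roots"][1] == pytest.approx(25.0, abs=1e-6)
        assert g["vertex"] == pytest.approx(15.0, abs=1e-6)

    def test_pure_noise_has_tiny_r2_and_shares(self):
        df = _contrast_frame(n=4000, seed=2)
        df["d_x"] = np.random.default_rng(3).standard_normal(len(df))
        fit = fit_climate_model(df, "d_x")
        assert fit.r_squared < 0.01
        assert all(s < 0.01 for s in fit.lmg_shares.values())
        assert sum(fit.lmg_shares.values()) == pytest.approx(fit.r_squared,
                                                             abs=1e-9)

    def test_constant_shift_moves_only_intercept(self):
        df = _contrast_frame(seed=4)
        rng = np.random.default_rng(5)
        df["d_x"] = rng.standard_normal(len(df))
        f1 = fit_climate_model(df, "d_x")
        df["d_x"] = df["d_x"] + 10.0
        f2 = fit_climate_model(df, "d_x")
        assert f2.params["intercept"] - f1.params["intercept"] \
            == pytest.approx(10.0, abs=1e-8)
        for k in f1.params.index:
            if k != "intercept":
                assert f2.params[k] == pytest.approx(f1.params[k], abs=1e-8)

    def test_too_few_rows_rejected(self):
        df = _contrast_frame(n=30, seed=6)
        df["d_x"] = 0.0
        with pytest.raises(ValueError, match="plots"):
            fit_climate_model(df, "d_x")


class TestCompareImportance:
    def test_identical_samples(self):
        x = np.arange(13.0)
        out = compare_importance(x, x.copy())
        assert out["t"] == pytest.approx(0.0)
        assert out["f"] == pytest.approx(1.0)

    def test_shifted_sample_matches_hand_formula(self):
        a = np.arange(1.0, 14.0)
        b = a + 10.0
        out = compare_importance(a, b)
        sp2 = a.var(ddof=1)  # equal variances
        t_hand = (a.mean() - b.mean()) / math.sqrt(sp2 * (2 / 13))
        assert out["t"] == pytest.approx(t_hand)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert out["t"] == pytest.approx(ref.statistic)
        assert out["p_t"] == pytest.approx(ref.pvalue)

    def test_constant_sample_degenerate(self):
        out = compare_importance(np.ones(13), np.arange(13.0))
        assert out["degenerate"]
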