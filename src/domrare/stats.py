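"""Statistical tests and climate-response models for the contrast table.

Implements the paired signed-rank test used per biome, Pearson/Spearman
trait–climate correlations, the second-order polynomial climate model of
the per-plot contrast D (with plot size, forest age, elevation and biome
as covariates), the grouped LMG (Shapley) decomposition of the model R²,
and the comparison of temperature vs. water-availability importances
across responses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import MAIN_BIOMES, TRAITS

#: The thirteen response variables evaluated per biome: the ten traits,
#: the gymnosperm percentage and the first two PCA axes.
RESPONSES: tuple[str, ...] = tuple(
    f"d_{t}" for t in TRAITS
) + ("d_gym_pct", "d_pc1", "d_pc2")


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WilcoxonResult:
    n: int                      # nonzero paired differences
    w: float                    # sum of ranks of positive differences
    p: float                    # two-sided
    method: str                 # exact | normal_approx | undefined
    n_zero_dropped: int = 0
    response: str | None = None
    biome: str | None = None


def _signed_rank_counts(n: int) -> np.ndarray:
    """Exact null distribution of W for n tie-free differences: counts of
    sign patterns per value of W (polynomial product of (1 + x^r))."""
    m = n * (n + 1) // 2
    c = np.zeros(m + 1, dtype=float)
    c[0] = 1.0
    for r in range(1, n + 1):
        c[r:] += c[:-r].copy()
    return c


def wilcoxon_signed_rank(
    dom: np.ndarray, rare: np.ndarray | None = None, exact_max_n: int = 25
) -> WilcoxonResult:
    """Two-sided signed-rank test on paired values (or on differences).

    Exact-null enumeration when there are no tied |d| and n <= 25;
    otherwise an Edgeworth-corrected normal approximation built from the
    exact second and fourth cumulants of the midrank sum (the variance
    term embodies the usual tie correction) with a 0.5 continuity
    correction.  Exact zeros are dropped and counted; an all-zero input is
    flagged undefined rather than assigned a p-value.
    """
    dom = np.asarray(dom, dtype=float)
    d = dom if rare is None else dom - np.asarray(rare, dtype=float)
    d = d[~np.isnan(d)]
    nonzero = d[d != 0]
    n_zero = len(d) - len(nonzero)
    n = len(nonzero)
    if n == 0:
        return WilcoxonResult(0, math.nan, math.nan, "undefined", n_zero)

    ranks = sps.rankdata(np.abs(nonzero))
    w = float(ranks[nonzero > 0].sum())
    m_total = n * (n + 1) / 2.0
    has_ties = len(np.unique(np.abs(nonzero))) < n

    if not has_ties and n <= exact_max_n:
        counts = _signed_rank_counts(n)
        total = counts.sum()
        wi = int(round(w))
        lo, hi = min(wi, int(m_total) - wi), max(wi, int(m_total) - wi)
        p = (counts[: lo + 1].sum() + counts[hi:].sum()) / total
        return WilcoxonResult(n, w, min(1.0, float(p)), "exact", n_zero)

    mu = m_total / 2.0
    # exact cumulants of the midrank sum under random signs (tie-robust):
    # var from the second, kurtosis correction from the fourth
    var = float((ranks**2).sum()) / 4.0
    if var == 0:
        return WilcoxonResult(n, w, math.nan, "undefined", n_zero)
    k4 = -float((ranks**4).sum()) / 8.0
    g2 = k4 / var**2
    x = max(w, m_total - w)
    z = (x - mu - 0.5) / math.sqrt(var)
    # Edgeworth tail with the kurtosis term; the plain normal-with-
    # continuity approximation misses the exact tail by up to ~0.011 at
    # n = 15, this stays within ~0.001
    sf = sps.norm.sf(z) + sps.norm.pdf(z) * (z**3 - 3 * z) * g2 / 24.0
    p = 2.0 * min(max(float(sf), 0.0), 1.0)
    return WilcoxonResult(n, w, min(1.0, p), "normal_approx", n_zero)


def biome_test_battery(
    contrasts: pd.DataFrame,
    responses: tuple[str, ...] = RESPONSES,
    biomes: tuple[str, ...] = MAIN_BIOMES,
    min_plots: int = 200,
) -> pd.DataFrame:
    """Signed-rank tests for every response × biome cell.

    A biome with fewer plots than ``min_plots`` is skipped with a flag
    (the analysis drops its smallest biome the same way) but still listed.
    """
    rows = []
    for b in biomes:
        sub = contrasts[contrasts["biome"] == b]
        skipped = len(sub) < min_plots
        for resp in responses:
            if skipped or resp not in sub.columns:
                rows.append({"biome": b, "response": resp, "n": len(sub),
                             "w": math.nan, "p": math.nan,
                             "method": "skipped", "skipped": True})
                continue
            r = wilcoxon_signed_rank(sub[resp].to_numpy())
            rows.append({"biome": b, "response": resp, "n": r.n, "w": r.w,
                         "p": r.p, "method": r.method, "skipped": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def trait_climate_correlation(
    values: np.ndarray, climate: np.ndarray, method: str = "pearson"
) -> dict:
    """Correlation of tree-level trait values with a climate variable,
    reported as (r, t, n, p) with t = r sqrt(n-2)/sqrt(1-r^2)."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(climate, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    if method == "spearman":
        r = float(sps.spearmanr(x, y).statistic)
    elif method == "pearson":
        r = float(sps.pearsonr(x, y).statistic)
    else:
        raise ValueError(f"unknown method {method!r}")
    if abs(r) >= 1.0:
        t = math.inf * np.sign(r)
        p = 0.0
    else:
        t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
        p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return {"r": r, "t": float(t), "n": n, "p": float(p), "method": method}


# ---------------------------------------------------------------------------
# LMG / Shapley relative importance
# ---------------------------------------------------------------------------

def _r2(x: np.ndarray, y: np.ndarray) -> float:
    yc = y - y.mean()
    sst = float(yc @ yc)
    if sst == 0:
        return 0.0
    if x.shape[1] == 0:
        return 0.0
    xi = np.column_stack([np.ones(len(y)), x])
    beta, *_ = np.linalg.lstsq(xi, y, rcond=None)
    resid = y - xi @ beta
    return 1.0 - float(resid @ resid) / sst


def lmg_importance(
    groups: dict[str, np.ndarray], y: np.ndarray, max_groups: int = 20
) -> dict[str, float]:
    """Grouped LMG decomposition of R².

    Each group's share is its incremental R² averaged over all orders in
    which the groups can enter the model (the Shapley value of R² with
    groups as players); shares are non-negative-in-expectation and sum to
    the full-model R² exactly.  Evaluated over all 2^G subsets with
    factorial ordering weights — refuse beyond ``max_groups`` groups.
    """
    names = list(groups)
    G = len(names)
    if G > max_groups:
        raise ValueError(f"{G} groups exceeds the combinatorial guard "
                         f"({max_groups})")
    y = np.asarray(y, dtype=float)
    mats = [np.atleast_2d(np.asarray(groups[g], dtype=float).T).T
            for g in names]
    cache: dict[int, float] = {}

    def r2_of(mask: int) -> float:
        if mask not in cache:
            cols = [mats[i] for i in range(G) if mask >> i & 1]
            x = np.column_stack(cols) if cols else np.empty((len(y), 0))
            cache[mask] = _r2(x, y)
        return cache[mask]

    fact = [math.factorial(k) for k in range(G + 1)]
    shares = {g: 0.0 for g in names}
    for mask in range(1 << G):
        k = bin(mask).count("1")
        base = r2_of(mask)
        wgt = fact[k] * fact[G - k - 1] / fact[G]
        for i in range(G):
            if not mask >> i & 1:
                shares[names[i]] += wgt * (r2_of(mask | 1 << i) - base)
    return shares


# ---------------------------------------------------------------------------
# Climate-response model
# ---------------------------------------------------------------------------

@dataclass
class ClimateFitResult:
    response: str
    n: int
    params: pd.Series               # standardized coefficients
    r_squared: float
    lmg_shares: dict[str, float]    # per regressor group, sums to R²
    geometry: dict[str, dict]       # per climate variable: roots, vertex
    scaling: dict[str, tuple[float, float]]  # (mean, sd) per scaled column
    aic_full: float
    aic_linear_water: float
    notes: list[str] = field(default_factory=list)

    @property
    def grouped_importance(self) -> dict[str, float]:
        return dict(self.lmg_shares)


def _quadratic_geometry(
    c: float, b1: float, b2: float, mean: float, sd: float
) -> dict:
    """Roots and vertex of c + b1 z + b2 z² mapped to original units."""
    out: dict = {"roots": (), "vertex": math.nan}
    if abs(b2) < 1e-12:
        if abs(b1) > 1e-12:
            out["roots"] = (mean + sd * (-c / b1),)
        return out
    disc = b1 * b1 - 4 * b2 * c
    if disc >= 0:
        r = math.sqrt(disc)
        z = sorted([(-b1 - r) / (2 * b2), (-b1 + r) / (2 * b2)])
        out["roots"] = tuple(mean + sd * zz for zz in z)
    out["vertex"] = mean + sd * (-b1 / (2 * b2))
    return out


def fit_climate_model(
    contrasts: pd.DataFrame,
    response: str,
    covariates: tuple[str, ...] = ("plot_size", "forest_age", "elevation",
                                   "biome"),
    condition_limit: float = 1e8,
) -> ClimateFitResult:
    """Second-order polynomial climate model of one contrast response.

    ``D ~ t + t² + w + w² + t·w + plot size + forest age + elevation +
    biome`` with every continuous predictor z-scored *before* squaring, so
    the displayed coefficients are on comparable scales and t² means
    (z_t)².  Requires at least ten plots per regressor.  Returns
    standardized coefficients, R², grouped LMG shares (temperature pools t
    with t², water pools w with w²), and the fitted quadratic's roots and
    vertex in original climate units (the other climate variable and all
    covariates held at their means).  ``aic_linear_water`` is the AIC of
    the same model without w², flagging when a linear water response is
    preferred.
    """
    data = contrasts.dropna(subset=[response]).reset_index(drop=True)
    y = data[response].to_numpy(dtype=float)
    n = len(y)

    scaling: dict[str, tuple[float, float]] = {}

    def zscore(col: str) -> np.ndarray:
        v = data[col].to_numpy(dtype=float)
        mu, sd = float(v.mean()), float(v.std())
        if sd == 0:
            raise ValueError(f"zero variance predictor {col!r}")
        scaling[col] = (mu, sd)
        return (v - mu) / sd

    t = zscore("mat_c")
    w = zscore("wai")
    cols: dict[str, np.ndarray] = {
        "t": t, "t2": t**2, "w": w, "w2": w**2, "t_x_w": t * w,
    }
    cov_source = {"plot_size": "area_ha", "forest_age": "age",
                  "elevation": "elevation_m"}
    for cov, src in cov_source.items():
        if cov in covariates:
            cols[cov] = zscore(src)
    biomes_present = sorted(data["biome"].unique())
    dummy_names: list[str] = []
    if "biome" in covariates and len(biomes_present) > 1:
        ref = data["biome"].value_counts().idxmax()
        for b in biomes_present:
            if b == ref:
                continue
            name = f"biome_{b}"
            cols[name] = (data["biome"] == b).to_numpy(dtype=float)
            dummy_names.append(name)

    n_regressors = len(cols)
    if n < 10 * n_regressors:
        raise ValueError(
            f"need >= {10 * n_regressors} plots for {n_regressors} "
            f"regressors, got {n}"
        )

    x = np.column_stack([np.ones(n)] + list(cols.values()))
    names = ["intercept"] + list(cols)
    cond = np.linalg.cond(x)
    notes = []
    if cond > condition_limit:
        warnings.warn(f"ill-conditioned design (cond={cond:.3g})")
        notes.append(f"ill-conditioned design (cond={cond:.3g})")

    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    ssr = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ssr / sst if sst > 0 else 0.0
    params = pd.Series(beta, index=names)

    def aic(rss: float, k: int) -> float:
        return n * math.log(max(rss, 1e-300) / n) + 2 * (k + 1)

    aic_full = aic(ssr, x.shape[1])
    x_lin = np.column_stack([np.ones(n)] + [v for k_, v in cols.items()
                                            if k_ != "w2"])
    beta_l, *_ = np.linalg.lstsq(x_lin, y, rcond=None)
    aic_lin = aic(float(((y - x_lin @ beta_l) ** 2).sum()), x_lin.shape[1])

    groups: dict[str, np.ndarray] = {
        "temperature": np.column_stack([cols["t"], cols["t2"]]),
        "water": np.column_stack([cols["w"], cols["w2"]]),
        "interaction": cols["t_x_w"][:, None],
    }
    for cov in cov_source:
        if cov in cols:
            groups[cov] = cols[cov][:, None]
    if dummy_names:
        groups["biome"] = np.column_stack([cols[d] for d in dummy_names])
    shares = lmg_importance(groups, y)

    # curve geometry: other climate variable at its mean (z = 0), dummies
    # at their sample means
    base = params["intercept"] + sum(
        params[d] * cols[d].mean() for d in dummy_names
    )
    geometry = {
        "mat_c": _quadratic_geometry(base, params["t"], params["t2"],
                                     *scaling["mat_c"]),
        "wai": _quadratic_geometry(base, params["w"], params["w2"],
                                   *scaling["wai"]),
    }
    return ClimateFitResult(
        response=response, n=n, params=params, r_squared=r2,
        lmg_shares=shares, geometry=geometry, scaling=scaling,
        aic_full=aic_full, aic_linear_water=aic_lin, notes=notes,
    )


def fit_all_responses(
    contrasts: pd.DataFrame, responses: tuple[str, ...] = RESPONSES
) -> dict[str, ClimateFitResult]:
    """Fit the climate model for every response column present."""
    out = {}
    for resp in responses:
        if resp in contrasts.columns:
            out[resp] = fit_climate_model(contrasts, resp)
    return out


def importance_table(fits: dict[str, ClimateFitResult]) -> pd.DataFrame:
    """Long table of grouped LMG shares (one row per response x group)."""
    rows = []
    for resp, f in fits.items():
        for g, s in f.lmg_shares.items():
            rows.append({"response": resp, "group": g, "share": s,
                         "r_squared": f.r_squared})
    return pd.DataFrame(rows)


def compare_importance(
    temperature_shares: np.ndarray, water_shares: np.ndarray
) -> dict:
    """Compare climate importances across responses.

    Reports both the pooled-variance two-sample t statistic and the
    variance-ratio F statistic with their p-values plus the sample means.
    (The source analysis labels a pooled-variance t-test as an F-test with
    a single statistic; both are surfaced here, neither privileged.)
    """
    a = np.asarray(temperature_shares, dtype=float)
    b = np.asarray(water_shares, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 != 13 or n2 != 13:
        warnings.warn(f"expected 13 responses per sample, got {n1} and {n2}")
    out: dict = {"n_temperature": n1, "n_water": n2,
                 "mean_temperature": float(a.mean()),
                 "mean_water": float(b.mean())}
    v1, v2 = float(a.var(ddof=1)), float(b.var(ddof=1))
    if v1 == 0 or v2 == 0:
        out.update(t=math.nan, p_t=math.nan, f=math.nan, p_f=math.nan,
                   degenerate=True)
        return out
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    tstat = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p_t = 2.0 * sps.t.sf(abs(tstat), df=n1 + n2 - 2)
    fstat = v1 / v2
    p_f = 2.0 * min(sps.f.sf(fstat, n1 - 1, n2 - 1),
                    sps.f.cdf(fstat, n1 - 1, n2 - 1))
    out.update(t=float(tstat), p_t=float(p_t), f=float(fstat),
               p_f=float(p_f), degenerate=False)
    return out
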