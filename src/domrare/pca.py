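"""Correlation-based PCA over the ten-trait space.

Inputs are (already z-scored) trait vectors — one row per plot×group median
vector in the main mode, or one row per species in the species-level mode.
The decomposition is the eigendecomposition of the correlation matrix of
the fit rows, so trait units can never leak into the axes.  Components are
deterministically oriented: each axis is flipped, if needed, so that its
largest-magnitude loading is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import TRAITS


@dataclass(frozen=True)
class PCAResult:
    loadings: pd.DataFrame          # trait x component, orthonormal columns
    explained_fraction: np.ndarray  # non-increasing, sums to 1
    scores: np.ndarray              # fit rows x components
    center: np.ndarray              # per-trait mean of the fit rows
    scale: np.ndarray               # per-trait sd of the fit rows
    orientation_anchor: tuple[str, ...]  # trait whose loading anchors each sign

    def transform(self, rows: np.ndarray) -> np.ndarray:
        """Project new rows using the fit's centring/scaling constants."""
        rows = np.asarray(rows, dtype=float)
        if rows.shape[1] != len(self.center):
            raise ValueError("row width does not match the fitted trait count")
        if np.isnan(rows).any():
            raise ValueError("missing trait value in projection input")
        z = (rows - self.center) / self.scale
        return z @ self.loadings.to_numpy()


def fit_pca(rows: pd.DataFrame | np.ndarray, traits: tuple[str, ...] = TRAITS) -> PCAResult:
    """Fit the trait PCA; rows with any missing cell are dropped first.

    Raises on fewer than two complete rows.  Rank-deficient inputs are
    fine — trailing eigenvalues are simply zero.
    """
    if isinstance(rows, pd.DataFrame):
        x = rows[list(traits)].to_numpy(dtype=float)
    else:
        x = np.asarray(rows, dtype=float)
    x = x[~np.isnan(x).any(axis=1)]
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least two complete rows")
    center = x.mean(0)
    scale = x.std(0, ddof=0)
    if (scale == 0).any():
        raise ValueError("constant trait column in PCA input")
    z = (x - center) / scale
    corr = (z.T @ z) / len(z)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    anchors = []
    for j in range(evecs.shape[1]):
        k = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
        anchors.append(traits[k])
    loadings = pd.DataFrame(
        evecs, index=list(traits),
        columns=[f"pc{j + 1}" for j in range(evecs.shape[1])],
    )
    return PCAResult(
        loadings=loadings,
        explained_fraction=evals / evals.sum(),
        scores=z @ evecs,
        center=center,
        scale=scale,
        orientation_anchor=tuple(anchors),
    )


def species_level_rows(ztraits_frame: pd.DataFrame) -> pd.DataFrame:
    """Mean z-trait vector per species (the species-level PCA mode),
    with the division flag retained for orientation checks."""
    agg = {t: "mean" for t in TRAITS}
    agg["division"] = "first"
    return ztraits_frame.groupby("species").agg(agg).reset_index()
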