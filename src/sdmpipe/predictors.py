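"""Predictor harmonisation and collinearity screening.

Raster harmonisation follows the usual preparation chain for mixed-source
predictor stacks: multi-year layers are averaged per cell, paired soil-depth
layers are averaged (optionally thickness-weighted), and layers on foreign
grids are resampled to the modelling grid by bilinear interpolation of the
four surrounding source cell centers.

Collinearity screening removes predictors iteratively by variance inflation
factor, VIF_j = 1 / (1 - R²_j), where R²_j comes from OLS of column j on all
other retained columns; while any VIF meets the threshold the worst column
is dropped (ties resolve to the later column in input order). The screen is
also available as the sklearn-style transformer :class:`VIFScreen`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .grids import EnvironmentalStack, GridSpec

__all__ = [
    "FeatureTable",
    "VifReport",
    "temporal_mean",
    "depth_average",
    "resample_bilinear",
    "extract_at_points",
    "vif",
    "vif_filter",
    "VIFScreen",
]


@dataclass
class FeatureTable:
    """Per-point predictor values plus point coordinates (degrees)."""

    features: pd.DataFrame
    lon: np.ndarray
    lat: np.ndarray
    n_nodata_dropped: int = 0

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        if not (len(self.features) == self.lon.size == self.lat.size):
            raise ValueError("features and coordinates disagree in length")

    def __len__(self) -> int:
        return len(self.features)


@dataclass
class VifReport:
    """Per-iteration VIF table and the order in which columns were removed."""

    iterations: list[pd.DataFrame] = field(default_factory=list)
    removed: list[str] = field(default_factory=list)
    threshold: float = 5.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, table in enumerate(self.iterations):
            for _, r in table.iterrows():
                rows.append(
                    {
                        "iteration": i,
                        "variable": r["variable"],
                        "vif": r["vif"],
                        "removed": bool(r["removed"]),
                    }
                )
        return pd.DataFrame(rows)


# -- harmonisation ------------------------------------------------------------

def temporal_mean(layers: list[np.ndarray]) -> np.ndarray:
    """Per-cell mean over time-indexed grids, ignoring nodata.

    A cell is nodata in the output only when it is nodata in every input.
    """
    if not layers:
        raise ValueError("temporal_mean needs at least one layer")
    arrs = [np.asarray(a, dtype=float) for a in layers]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("temporal_mean requires conformal grids")
    stacked = np.stack(arrs)
    with np.errstate(invalid="ignore"):
        out = np.nanmean(stacked, axis=0)
    return out


def depth_average(
    shallow: np.ndarray,
    deep: np.ndarray,
    thickness_weighted: bool = False,
    thicknesses: tuple[float, float] = (5.0, 10.0),
) -> np.ndarray:
    """Average two soil-depth layers per cell.

    Unweighted by default; ``thickness_weighted`` weights each layer by its
    depth-interval thickness in cm (defaults 0-5 and 5-15 cm).
    """
    shallow = np.asarray(shallow, dtype=float)
    deep = np.asarray(deep, dtype=float)
    if shallow.shape != deep.shape:
        raise ValueError("depth_average requires conformal grids")
    if thickness_weighted:
        w1, w2 = thicknesses
        return (w1 * shallow + w2 * deep) / (w1 + w2)
    return (shallow + deep) / 2.0


def resample_bilinear(layer: np.ndarray, src: GridSpec, dst: GridSpec) -> np.ndarray:
    """Resample a layer between grids by bilinear interpolation.

    Each target cell center is interpolated from the four surrounding source
    cell centers; target centers outside the source center lattice, or with
    any nodata corner, become nodata.
    """
    layer = np.asarray(layer, dtype=float)
    if layer.shape != src.shape:
        raise ValueError("layer does not conform to the source GridSpec")
    s_minlon, s_minlat, s_maxlon, s_maxlat = src.bounds
    d_minlon, d_minlat, d_maxlon, d_maxlat = dst.bounds
    if d_minlon >= s_maxlon or d_maxlon <= s_minlon or d_minlat >= s_maxlat or d_maxlat <= s_minlat:
        raise ValueError("source and target extents are disjoint")

    lon = dst.lon_centers()
    lat = dst.lat_centers()
    # fractional index of target centers in the source center lattice
    fx = (lon - (src.origin_lon + 0.5 * src.cell_size)) / src.cell_size
    fy = ((src.origin_lat - 0.5 * src.cell_size) - lat) / src.cell_size
    fx2, fy2 = np.meshgrid(fx, fy)

    x0 = np.floor(fx2).astype(int)
    y0 = np.floor(fy2).astype(int)
    eps = 1e-9  # tolerate float error at the center-lattice boundary
    inside = (
        (fx2 >= -eps) & (fx2 <= src.n_cols - 1 + eps)
        & (fy2 >= -eps) & (fy2 <= src.n_rows - 1 + eps)
    )
    x0c = np.clip(x0, 0, src.n_cols - 2)
    y0c = np.clip(y0, 0, src.n_rows - 2)
    tx = np.clip(fx2 - x0c, 0.0, 1.0)
    ty = np.clip(fy2 - y0c, 0.0, 1.0)
    v00 = layer[y0c, x0c]
    v01 = layer[y0c, x0c + 1]
    v10 = layer[y0c + 1, x0c]
    v11 = layer[y0c + 1, x0c + 1]
    out = (
        v00 * (1 - tx) * (1 - ty)
        + v01 * tx * (1 - ty)
        + v10 * (1 - tx) * ty
        + v11 * tx * ty
    )
    return np.where(inside, out, np.nan)


def extract_at_points(stack: EnvironmentalStack, lon, lat) -> FeatureTable:
    """Per-point value of the containing cell for every layer.

    Containment, not interpolation: each point takes the value of the cell
    it falls in. Points outside the grid extent raise; points in nodata
    cells are dropped and counted in ``n_nodata_dropped``.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    outside = ~stack.spec.contains(lon, lat)
    if outside.any():
        i = int(np.flatnonzero(outside)[0])
        raise ValueError(
            f"point ({lon[i]}, {lat[i]}) at index {i} lies outside the grid extent"
        )
    row, col = stack.spec.cell_of(lon, lat)
    ok = ~stack.nodata_mask[row, col]
    data = {
        name: grid[row[ok], col[ok]] for name, grid in stack.layers.items()
    }
    return FeatureTable(
        features=pd.DataFrame(data),
        lon=lon[ok],
        lat=lat[ok],
        n_nodata_dropped=int((~ok).sum()),
    )


# -- VIF screening ------------------------------------------------------------

def _vif_one(X: np.ndarray, j: int) -> float:
    """VIF of column j from OLS of j on the remaining columns (+ intercept)."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    yc = y - y.mean()
    ss_tot = float(yc @ yc)
    if ss_tot <= 0:
        return np.inf  # constant column: flagged for removal
    A = np.column_stack([np.ones(X.shape[0]), others])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    r2 = 1.0 - float(resid @ resid) / ss_tot
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return max(1.0 / (1.0 - r2), 1.0)


def vif(table: pd.DataFrame) -> pd.Series:
    """VIF of every column of a feature table (requires >= 2 columns)."""
    if table.shape[1] < 2:
        raise ValueError("VIF needs at least two columns")
    if len(table) <= table.shape[1]:
        raise ValueError(
            f"VIF needs more rows ({len(table)}) than columns ({table.shape[1]})"
        )
    X = table.to_numpy(dtype=float)
    return pd.Series(
        [_vif_one(X, j) for j in range(X.shape[1])], index=table.columns, name="vif"
    )


def vif_filter(
    table: pd.DataFrame, threshold: float = 5.0
) -> tuple[pd.DataFrame, VifReport]:
    """Iteratively drop the worst-VIF column while any VIF >= threshold.

    Exact collinearity (and constant columns) count as infinite VIF. When
    two columns tie at the maximum, the later one in input order is dropped.
    Returns the retained table and a full per-iteration report.
    """
    work = table.copy()
    report = VifReport(threshold=threshold)
    while True:
        values = vif(work)
        worst = float(values.max())
        # ties at the max (including inf) resolve to the later column
        drop = values[values == worst].index[-1]
        remove = worst >= threshold
        report.iterations.append(
            pd.DataFrame(
                {
                    "variable": values.index,
                    "vif": values.values,
                    "removed": [remove and (v == drop) for v in values.index],
                }
            )
        )
        if not remove:
            return work, report
        report.removed.append(drop)
        work = work.drop(columns=[drop])
        if work.shape[1] < 2:
            return work, report


class VIFScreen(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer wrapping the iterative VIF screen.

    Fitting records which columns survive (``retained_``) and the
    per-iteration report (``report_``); ``transform`` subsets any conforming
    DataFrame or array to the retained columns.
    """

    def __init__(self, threshold: float = 5.0):
        self.threshold = threshold

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        _, report = vif_filter(X, threshold=self.threshold)
        self.report_ = report
        self.removed_ = list(report.removed)
        self.retained_ = [c for c in X.columns if c not in self.removed_]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "retained_")
        X = pd.DataFrame(X)
        missing = [c for c in self.retained_ if c not in X.columns]
        if missing:
            raise ValueError(f"input lacks retained column(s) {missing}")
        return X[self.retained_]

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "retained_")
        return np.asarray(self.retained_, dtype=object)
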