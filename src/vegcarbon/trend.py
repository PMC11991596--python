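"""Per-pixel linear trend of annual NEP with F-test significance classes.

The trend statistic is the ordinary least-squares slope in its closed
summation form over the time index i = 1..n,

    Slope = (n·Σ i·y_i − Σi · Σy_i) / (n·Σ i² − (Σ i)²),

and significance comes from the regression F statistic
F = r²(n−2)/(1−r²) on (1, n−2) degrees of freedom.  Each pixel is assigned
one of five classes: extremely significant increase (p < 0.01, slope > 0),
significant increase (0.01 ≤ p < 0.05, slope > 0), stable (p ≥ 0.05), and
the two mirrored decrease classes.  Boundary p-values fall into the
less-significant class; a constant series gets slope 0, p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grid_io import GridStack, RasterGrid

__all__ = [
    "TREND_CLASSES",
    "TrendMap",
    "fit_trend",
    "fit_trend_stack",
    "classify_trend",
    "trend_map",
]

TREND_CLASSES = {
    2: "extremely_significant_increase",
    1: "significant_increase",
    0: "stable",
    -1: "significant_decrease",
    -2: "extremely_significant_decrease",
}


@dataclass
class TrendMap:
    slope: RasterGrid
    p_value: RasterGrid
    trend_class: RasterGrid
    class_proportions: dict[str, float]
    n: int


def _slope_p_from_arrays(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised closed-form slope and F-test p over the leading axis."""
    n = y.shape[0]
    i = np.arange(1, n + 1, dtype=float).reshape((n,) + (1,) * (y.ndim - 1))
    si = n * (n + 1) / 2.0
    sii = n * (n + 1) * (2 * n + 1) / 6.0
    sy = y.sum(axis=0)
    siy = (i * y).sum(axis=0)
    denom = n * sii - si * si
    slope = (n * siy - si * sy) / denom
    # r² via regression sums of squares
    ybar = sy / n
    sst = ((y - ybar) ** 2).sum(axis=0)
    ssr = slope ** 2 * (sii - si * si / n)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(sst > 0, ssr / sst, 0.0)
    r2 = np.clip(r2, 0.0, 1.0)
    df2 = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        f = r2 * df2 / (1.0 - r2)
    p = np.where(r2 >= 1.0, 0.0, stats.f.sf(f, 1, df2))
    p = np.where(sst > 0, p, 1.0)
    slope = np.where(sst > 0, slope, 0.0)
    return slope, p


def fit_trend(series) -> tuple[float, float]:
    """Slope and p-value of one annual series (n ≥ 3)."""
    y = np.asarray(series, dtype=float)
    if y.ndim != 1:
        raise ValueError("series must be 1-D")
    if y.size < 3 or not np.isfinite(y).all():
        raise ValueError("need at least 3 finite values")
    slope, p = _slope_p_from_arrays(y[:, None])
    return float(slope[0]), float(p[0])


def fit_trend_stack(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel slope and p for a (n_years, rows, cols) array; pixels with
    any non-finite year come back NaN."""
    finite = np.isfinite(arr).all(axis=0)
    slope, p = _slope_p_from_arrays(np.where(finite[None], arr, 0.0))
    slope = np.where(finite, slope, np.nan)
    p = np.where(finite, p, np.nan)
    return slope, p


def classify_trend(slope: float, p: float) -> int:
    """Five-way class code from (slope, p); see :data:`TREND_CLASSES`."""
    codes = _classify_arrays(np.asarray([slope], float), np.asarray([p], float))
    return int(codes[0])


def _classify_arrays(slope: np.ndarray, p: np.ndarray) -> np.ndarray:
    codes = np.zeros(slope.shape, dtype=np.int8)
    inc = slope > 0
    dec = slope < 0
    codes[inc & (p < 0.01)] = 2
    codes[inc & (p >= 0.01) & (p < 0.05)] = 1
    codes[dec & (p < 0.01)] = -2
    codes[dec & (p >= 0.01) & (p < 0.05)] = -1
    return codes


def trend_map(nep_annual_stack: GridStack) -> TrendMap:
    """Per-pixel trend fit and classification with area proportions."""
    arr = nep_annual_stack.as_array()
    n = arr.shape[0]
    if n < 3:
        raise ValueError("need at least 3 annual layers")
    slope, p = fit_trend_stack(arr)
    valid = np.isfinite(slope)
    codes = _classify_arrays(np.where(valid, slope, 0.0), np.where(valid, p, 1.0))
    codes_grid = np.where(valid, codes, 0).astype(np.int8)
    ref = nep_annual_stack.layers[0]
    mask = ~valid
    n_valid = int(valid.sum())
    proportions = {}
    for code, name in TREND_CLASSES.items():
        count = int(((codes == code) & valid).sum())
        proportions[name] = count / n_valid if n_valid else 0.0
    return TrendMap(
        slope=RasterGrid(np.where(valid, slope, np.nan), ref.transform, ref.crs,
                         mask, semantic="nep_trend_slope"),
        p_value=RasterGrid(np.where(valid, p, np.nan), ref.transform, ref.crs,
                           mask, semantic="trend_p"),
        trend_class=RasterGrid(codes_grid, ref.transform, ref.crs, mask.copy(),
                               semantic="trend_class"),
        class_proportions=proportions,
        n=n,
    )
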