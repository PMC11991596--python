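"""Climate attribution of NEP variability by partial and multiple correlation.

For each pixel's annual series, the association between NEP and each of
temperature, precipitation and solar radiation is measured by the
second-order partial correlation (controlling the other two), computed
from the inverse Ω of the 4-variable correlation matrix:

    r_yx·c = −Ω_yx / √(Ω_yy · Ω_xx),     t = r·√((n−4)/(1−r²)),  df = n−4.

The joint climate effect is the multiple correlation R of NEP on (T, P, S),
with F = (R²/3) / ((1−R²)/(n−4)) on (3, n−4) degrees of freedom.  Each
pixel is then assigned one of nine driving types.  The nine-type decision
table is a reconstruction (the published criteria are cited, not printed):
pixels whose multiple correlation is not significant (p ≥ 0.05) are
non-climatic; otherwise the set of individually significant partials
(p < 0.05) selects single-factor, two-factor, strong (all three) or weak
(none) climate driving.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grid_io import GridStack, RasterGrid

__all__ = [
    "DRIVER_TYPES",
    "AttributionMap",
    "partial_correlation",
    "multiple_correlation",
    "classify_driver_type",
    "attribution_map",
]

DRIVER_TYPES = {
    1: "temperature_driven",
    2: "precipitation_driven",
    3: "solar_radiation_driven",
    4: "temperature_precipitation_driven",
    5: "temperature_solar_radiation_driven",
    6: "precipitation_solar_radiation_driven",
    7: "strongly_driven_by_T_P_S",
    8: "weakly_driven_by_T_P_S",
    9: "non_climatic_factor_driven",
}

_FACTORS = ("temperature", "precipitation", "solar_radiation")


@dataclass
class AttributionMap:
    r_partial: dict[str, RasterGrid]
    p_partial: dict[str, RasterGrid]
    r_multiple: RasterGrid
    p_multiple: RasterGrid
    driver_type: RasterGrid
    type_proportions: dict[str, float]
    significance_proportions: dict[str, dict[str, float]]
    n: int


def _corr_inverse(data: np.ndarray) -> np.ndarray:
    """Inverse correlation matrix of columns of an (n, k) matrix."""
    c = np.corrcoef(data, rowvar=False)
    if not np.all(np.isfinite(c)):
        raise ValueError("constant series: correlation undefined")
    try:
        return np.linalg.inv(c)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular correlation matrix (collinear inputs)") from exc


def partial_correlation(y, x, controls) -> tuple[float, float]:
    """Second-order partial correlation of y with x given two controls."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    c1, c2 = (np.asarray(c, float) for c in controls)
    n = y.size
    if not (x.size == c1.size == c2.size == n):
        raise ValueError("all series must share length")
    if n < 5:
        raise ValueError("need n >= 5 for a second-order partial correlation")
    r_yx = np.corrcoef(y, x)[0, 1]
    if np.isfinite(r_yx) and abs(r_yx) >= 1.0 - 1e-12:
        # y and x coincide up to affine transform: partial r = ±1 by continuity
        return float(np.sign(r_yx)), 0.0
    omega = _corr_inverse(np.column_stack([y, x, c1, c2]))
    r = float(-omega[0, 1] / np.sqrt(omega[0, 0] * omega[1, 1]))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 4
    if 1.0 - r * r <= 0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


def multiple_correlation(y, X) -> tuple[float, float]:
    """Multiple correlation R of y on the columns of X (with intercept)."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n, k) matching y")
    n, k = X.shape
    if n < k + 3:
        raise ValueError(f"need n >= {k + 3} observations")
    A = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(A) < k + 1:
        raise ValueError("collinear predictors")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("constant response")
    r2 = max(0.0, 1.0 - float((resid ** 2).sum()) / sst)
    df2 = n - k - 1
    if r2 >= 1.0:
        return 1.0, 0.0
    f = (r2 / k) / ((1.0 - r2) / df2)
    return float(np.sqrt(r2)), float(stats.f.sf(f, k, df2))


def classify_driver_type(p_partial, p_multiple: float, alpha: float = 0.05) -> int:
    """Nine-type code from the three partial p-values and the multiple p."""
    p_t, p_p, p_s = (float(v) for v in p_partial)
    if not (p_multiple < alpha):
        return 9
    sig = (p_t < alpha, p_p < alpha, p_s < alpha)
    count = sum(sig)
    if count == 3:
        return 7
    if count == 0:
        return 8
    if count == 1:
        return {0: 1, 1: 2, 2: 3}[sig.index(True)]
    # exactly two significant
    if sig[0] and sig[1]:
        return 4
    if sig[0] and sig[2]:
        return 5
    return 6


def _batch_attribution(data: np.ndarray):
    """Vectorised per-pixel statistics.

    ``data`` is (n_years, 4, n_pix) ordered [NEP, T, P, S].  Returns partial
    r/p per factor, multiple R/p and a validity mask.
    """
    n = data.shape[0]
    mean = data.mean(axis=0, keepdims=True)
    sd = data.std(axis=0, keepdims=True)
    ok = (sd[0] > 0).all(axis=0) & np.isfinite(data).all(axis=(0, 1))
    z = np.where(sd > 0, (data - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    corr = np.einsum("tip,tjp->pij", z, z) / n
    corr[~ok] = np.eye(4)
    det = np.linalg.det(corr)
    ok &= np.abs(det) > 1e-12
    corr[~ok] = np.eye(4)
    omega = np.linalg.inv(corr)
    diag = np.sqrt(np.einsum("pii->pi", omega))
    r_part = np.empty((3, corr.shape[0]))
    for k in range(3):
        r_part[k] = np.clip(-omega[:, 0, k + 1] / (diag[:, 0] * diag[:, k + 1]), -1, 1)
    df = n - 4
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r_part * np.sqrt(df / np.clip(1.0 - r_part ** 2, 1e-300, None))
    p_part = 2.0 * stats.t.sf(np.abs(t), df)
    p_part = np.where(np.abs(r_part) >= 1.0, 0.0, p_part)
    r2 = np.clip(1.0 - 1.0 / omega[:, 0, 0], 0.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (r2 / 3.0) / np.clip((1.0 - r2) / df, 1e-300, None)
    p_mult = np.where(r2 >= 1.0, 0.0, stats.f.sf(f, 3, df))
    return r_part, p_part, np.sqrt(r2), p_mult, ok


def attribution_map(
    nep_annual: GridStack,
    temperature_annual: GridStack,
    precipitation_annual: GridStack,
    solar_annual: GridStack,
    alpha: float = 0.05,
) -> AttributionMap:
    """Pixel-by-pixel partial/multiple correlation and nine-type typology.

    All four stacks must be annual layers over the same years.  Pixels with
    any masked year (complete-case) or a constant series are dropped and
    excluded from all proportions.
    """
    stacks = [nep_annual, temperature_annual, precipitation_annual, solar_annual]
    n = len(nep_annual)
    for s in stacks[1:]:
        if len(s) != n:
            raise ValueError("stacks cover different numbers of years")
    if n < 6:
        raise ValueError("need at least 6 annual layers")
    ref = nep_annual.layers[0]
    shape = ref.shape
    data = np.stack([s.as_array().reshape(n, -1) for s in stacks], axis=1)
    r_part, p_part, r_mult, p_mult, ok = _batch_attribution(data)

    sig = p_part < alpha
    types = np.full(ok.size, 9, dtype=np.int8)
    gate = ok & (p_mult < alpha)
    count = sig.sum(axis=0)
    types[gate & (count == 3)] = 7
    types[gate & (count == 0)] = 8
    single = {0: 1, 1: 2, 2: 3}
    for k in range(3):
        only = gate & (count == 1) & sig[k]
        types[only] = single[k]
    types[gate & (count == 2) & sig[0] & sig[1]] = 4
    types[gate & (count == 2) & sig[0] & sig[2]] = 5
    types[gate & (count == 2) & sig[1] & sig[2]] = 6

    mask = ~ok.reshape(shape)

    def _grid(vals, semantic):
        v = vals.reshape(shape).astype(float)
        return RasterGrid(np.where(mask, np.nan, v), ref.transform, ref.crs,
                          mask.copy(), semantic=semantic)

    n_valid = int(ok.sum())
    type_props = {}
    for code, name in DRIVER_TYPES.items():
        type_props[name] = float((types[ok] == code).sum()) / n_valid if n_valid else 0.0

    sig_props = {}
    for k, factor in enumerate(_FACTORS):
        pv = p_part[k][ok]
        rv = r_part[k][ok]
        tot = max(pv.size, 1)
        sig_props[factor] = {
            "highly_significant": float((pv < 0.01).sum()) / tot,
            "significant": float(((pv >= 0.01) & (pv < 0.05)).sum()) / tot,
            "not_significant": float((pv >= 0.05).sum()) / tot,
            "positive_fraction": float((rv > 0).sum()) / tot,
        }

    type_grid = np.where(mask, 0, types.reshape(shape)).astype(np.int8)
    return AttributionMap(
        r_partial={f: _grid(r_part[k], f"r_partial_{f}") for k, f in enumerate(_FACTORS)},
        p_partial={f: _grid(p_part[k], f"p_partial_{f}") for k, f in enumerate(_FACTORS)},
        r_multiple=_grid(r_mult, "r_multiple"),
        p_multiple=_grid(p_mult, "p_multiple"),
        driver_type=RasterGrid(type_grid, ref.transform, ref.crs, mask.copy(),
                               semantic="driver_type"),
        type_proportions=type_props,
        significance_proportions=sig_props,
        n=n,
    )
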