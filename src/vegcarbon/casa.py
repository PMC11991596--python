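"""Light-use-efficiency (CASA-style) NPP estimation and validation.

The productivity model is the classic light-use-efficiency decomposition

    NPP(x, t) = APAR(x, t) × ε(x, t)            [g C m⁻² month⁻¹]
    APAR      = SOL × FPAR × 0.5                [MJ m⁻²]
    ε         = Tε1 × Tε2 × Wε × εmax           [g C MJ⁻¹]

with FPAR linear in NDVI between vegetation-type-specific bounds and capped
at 0.95; Tε1 a quadratic in the pixel's optimum-month temperature, Tε2 a
logistic penalty for months far from that optimum, and Wε a moisture scalar
``0.5 + 0.5·(E/Ep)`` with the evapotranspiration ratio approximated by a
monthly precipitation / atmospheric-demand ratio.  Every constant lives in
:class:`VegTypeParams` / :class:`CasaConfig`, not in code, so per-type
calibrations are configuration changes.

Monthly NPP sums to annual NPP; months with NDVI at or below the type's
bare-soil minimum contribute zero (never negative) productivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .grid_io import GridStack, RasterGrid
from .synthetic import MonthlyClimate

__all__ = [
    "VegTypeParams",
    "CasaConfig",
    "NPPCube",
    "ValidationStats",
    "compute_fpar",
    "compute_apar",
    "compute_lue",
    "compute_npp",
    "validate_npp",
]

#: fraction of incident solar radiation that is photosynthetically active
PAR_FRACTION = 0.5
#: FPAR saturation cap
FPAR_MAX = 0.95


@dataclass(frozen=True)
class VegTypeParams:
    """Per-vegetation-type CASA constants."""

    name: str
    ndvi_min: float      # bare-soil NDVI: FPAR = 0 at or below
    ndvi_max: float      # saturating NDVI: FPAR = FPAR_MAX at or above
    eps_max: float       # maximal light-use efficiency, g C MJ⁻¹


def _default_veg_table() -> dict[int, VegTypeParams]:
    # Subtropical defaults: evergreen forest, shrub/grassland, cropland.
    return {
        1: VegTypeParams("forest", ndvi_min=0.023, ndvi_max=0.90, eps_max=0.65),
        2: VegTypeParams("shrub_grass", ndvi_min=0.023, ndvi_max=0.88, eps_max=0.45),
        3: VegTypeParams("cropland", ndvi_min=0.023, ndvi_max=0.85, eps_max=0.55),
    }


@dataclass
class CasaConfig:
    """All tunables of the productivity model."""

    veg_table: dict[int, VegTypeParams] = field(default_factory=_default_veg_table)
    par_fraction: float = PAR_FRACTION
    fpar_max: float = FPAR_MAX
    moisture_demand: float = 120.0  # mm month⁻¹ atmospheric demand for E/Ep

    @classmethod
    def from_dict(cls, d: dict) -> "CasaConfig":
        table = {
            int(code): VegTypeParams(**params)
            for code, params in d.get("veg_table", {}).items()
        } or _default_veg_table()
        return cls(
            veg_table=table,
            par_fraction=float(d.get("par_fraction", PAR_FRACTION)),
            fpar_max=float(d.get("fpar_max", FPAR_MAX)),
            moisture_demand=float(d.get("moisture_demand", 120.0)),
        )

    def to_dict(self) -> dict:
        return {
            "veg_table": {code: asdict(p) for code, p in self.veg_table.items()},
            "par_fraction": self.par_fraction,
            "fpar_max": self.fpar_max,
            "moisture_demand": self.moisture_demand,
        }


@dataclass
class NPPCube:
    """Monthly and annual NPP with the APAR/ε factors that produced them."""

    npp_monthly: GridStack
    npp_annual: GridStack
    apar: GridStack
    lue: GridStack


@dataclass
class ValidationStats:
    r: float
    r2: float
    p: float
    n: int


def _lookup(vegtype: RasterGrid, config: CasaConfig, attr: str) -> np.ndarray:
    codes = vegtype.values.astype(int)
    known = sorted(config.veg_table)
    out = np.full(codes.shape, np.nan)
    seen = np.zeros(codes.shape, dtype=bool)
    for code, params in config.veg_table.items():
        sel = codes == code
        out[sel] = getattr(params, attr)
        seen |= sel
    unknown = ~seen & ~vegtype.nodata_mask
    if unknown.any():
        bad = sorted(set(codes[unknown].tolist()))
        raise ValueError(f"unknown vegetation codes {bad}; known codes: {known}")
    return out


def compute_fpar(ndvi: RasterGrid, vegtype: RasterGrid,
                 config: CasaConfig | None = None) -> RasterGrid:
    """Fraction of absorbed PAR, linear in NDVI between per-type bounds.

    FPAR = fpar_max · (NDVI − NDVI_min) / (NDVI_max − NDVI_min), clipped to
    [0, fpar_max]; exactly 0 at or below the bare-soil minimum.
    """
    config = config or CasaConfig()
    vals = ndvi.values.astype(float)
    valid = ~(ndvi.nodata_mask | vegtype.nodata_mask)
    if np.any((vals[valid] < -1) | (vals[valid] > 1)):
        raise ValueError("NDVI outside [-1, 1]")
    lo = _lookup(vegtype, config, "ndvi_min")
    hi = _lookup(vegtype, config, "ndvi_max")
    frac = (vals - lo) / (hi - lo)
    fpar = np.clip(frac, 0.0, 1.0) * config.fpar_max
    mask = ~valid
    return RasterGrid(np.where(mask, np.nan, fpar), ndvi.transform, ndvi.crs,
                      mask, semantic="fpar")


def compute_apar(sol: RasterGrid, fpar: RasterGrid,
                 config: CasaConfig | None = None) -> RasterGrid:
    """APAR = SOL × FPAR × par_fraction (MJ m⁻²)."""
    config = config or CasaConfig()
    valid = ~(sol.nodata_mask | fpar.nodata_mask)
    if np.any(sol.values[valid] < 0):
        raise ValueError("negative solar radiation")
    apar = sol.values * fpar.values * config.par_fraction
    mask = ~valid
    return RasterGrid(np.where(mask, np.nan, apar), sol.transform, sol.crs,
                      mask, semantic="apar_MJ_m2")


def temperature_stress(t_monthly: np.ndarray, t_opt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """CASA temperature scalars.

    Tε1 = 0.8 + 0.02·Topt − 0.0005·Topt² (clipped to [0, 1]) depends only on
    the pixel's optimum-month temperature; Tε2 penalises months whose
    temperature departs from that optimum via the standard double-logistic,
    normalised so Tε2 ≤ 1.
    """
    te1 = np.clip(0.8 + 0.02 * t_opt - 0.0005 * t_opt ** 2, 0.0, 1.0)
    te2 = 1.1814 / (
        (1.0 + np.exp(0.2 * (t_opt - 10.0 - t_monthly)))
        * (1.0 + np.exp(0.3 * (-t_opt - 10.0 + t_monthly)))
    )
    return te1, np.clip(te2, 0.0, 1.0)


def water_stress(precip: np.ndarray, demand: float) -> np.ndarray:
    """Wε = 0.5 + 0.5·(E/Ep), E/Ep ≈ clip(R / demand, 0, 1); floor 0.5."""
    ratio = np.clip(precip / demand, 0.0, 1.0)
    return 0.5 + 0.5 * ratio


def _optimum_temperature(t_arr: np.ndarray, ndvi_arr: np.ndarray) -> np.ndarray:
    """Per-pixel temperature of the month with maximal NDVI (classic CASA),
    computed per year then averaged over years."""
    n_months, rows, cols = t_arr.shape
    n_years = n_months // 12
    t_y = t_arr[: n_years * 12].reshape(n_years, 12, rows, cols)
    v_y = ndvi_arr[: n_years * 12].reshape(n_years, 12, rows, cols)
    idx = np.nanargmax(np.where(np.isnan(v_y), -np.inf, v_y), axis=1)
    topt = np.take_along_axis(t_y, idx[:, None], axis=1)[:, 0]
    return np.nanmean(topt, axis=0)


def compute_lue(
    temperature: GridStack,
    precipitation: GridStack,
    ndvi: GridStack,
    vegtype: RasterGrid,
    config: CasaConfig | None = None,
) -> GridStack:
    """Monthly light-use efficiency ε = Tε1 × Tε2 × Wε × εmax (g C MJ⁻¹)."""
    config = config or CasaConfig()
    eps_max = _lookup(vegtype, config, "eps_max")
    t_arr = temperature.as_array()
    r_arr = precipitation.as_array()
    v_arr = ndvi.as_array()
    t_opt = _optimum_temperature(t_arr, v_arr)
    te1, te2 = temperature_stress(t_arr, t_opt[None])
    we = water_stress(r_arr, config.moisture_demand)
    eps = te1 * te2 * we * eps_max[None]
    ref = temperature.layers[0]
    layers = []
    for i in range(eps.shape[0]):
        mask = ~np.isfinite(eps[i]) | vegtype.nodata_mask
        layers.append(RasterGrid(np.where(mask, np.nan, eps[i]), ref.transform,
                                 ref.crs, mask, semantic="lue_gC_MJ"))
    return GridStack(layers, time_index=temperature.time_index)


def compute_npp(
    climate: MonthlyClimate,
    ndvi: GridStack,
    vegtype: RasterGrid,
    config: CasaConfig | None = None,
) -> NPPCube:
    """Monthly NPP = APAR × ε, summed to annual, masks propagated."""
    config = config or CasaConfig()
    if ndvi.time_index != climate.temperature.time_index:
        raise ValueError("climate and NDVI stacks have different time indices")
    lue = compute_lue(climate.temperature, climate.precipitation, ndvi, vegtype, config)
    apar_layers = []
    npp_layers = []
    for i, (y, m) in enumerate(climate.temperature.time_index):
        fpar = compute_fpar(ndvi.layers[i], vegtype, config)
        apar = compute_apar(climate.solar_radiation.layers[i], fpar, config)
        eps = lue.layers[i]
        mask = apar.nodata_mask | eps.nodata_mask
        npp_vals = apar.values * eps.values
        npp = RasterGrid(np.where(mask, np.nan, npp_vals), apar.transform,
                         apar.crs, mask, semantic="npp_gC_m2_month")
        apar_layers.append(apar)
        npp_layers.append(npp)
    ti = climate.temperature.time_index
    npp_monthly = GridStack(npp_layers, time_index=ti)
    years = sorted({y for y, _ in ti})
    annual = []
    ref = npp_layers[0]
    for year in years:
        idx = [i for i, (y, _) in enumerate(ti) if y == year]
        arr = np.stack([npp_layers[i].masked() for i in idx]).sum(axis=0)
        mask = ~np.isfinite(arr)
        annual.append(RasterGrid(np.where(mask, np.nan, arr), ref.transform,
                                 ref.crs, mask, semantic="npp_gC_m2_a"))
    npp_annual = GridStack(annual, time_index=[(y, 12) for y in years])
    return NPPCube(npp_monthly, npp_annual, GridStack(apar_layers, time_index=ti), lue)


def validate_npp(estimated: RasterGrid, reference: RasterGrid,
                 n_points: int = 100, seed: int = 0) -> ValidationStats:
    """Pearson correlation between estimated and reference annual NPP at
    randomly sampled valid pixels (without replacement, seeded)."""
    if not estimated.same_grid(reference):
        raise ValueError("estimated and reference NPP are not on the same grid")
    valid = ~(estimated.nodata_mask | reference.nodata_mask)
    idx = np.flatnonzero(valid)
    if idx.size < n_points:
        raise ValueError(f"only {idx.size} valid common pixels, need {n_points}")
    rng = np.random.default_rng(seed)
    pick = rng.choice(idx, size=n_points, replace=False)
    a = estimated.values.ravel()[pick]
    b = reference.values.ravel()[pick]
    res = stats.pearsonr(a, b)
    r = float(res.statistic)
    return ValidationStats(r=r, r2=r * r, p=float(res.pvalue), n=n_points)
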