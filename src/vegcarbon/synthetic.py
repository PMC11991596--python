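"""Synthetic raster scenarios with recorded ground truth.

Every analysis stage of the pipeline is testable against data whose
generating process is known: monthly climate with seasonal cycles, spatial
gradients and linear trends; NDVI coupled to temperature and precipitation;
a 12-factor driver set in which one factor carries known additive stratum
effects on NEP while the rest are null; and directly injected linear NEP
trends for trend-recovery checks.

Default magnitudes emulate a subtropical monsoon province on a 1 km
equal-area grid: mean annual temperature ~16.5 °C with an ~11 °C seasonal
half-amplitude, ~1500 mm annual precipitation, ~4600 MJ m⁻² annual solar
radiation, and NDVI around 0.6 rising with warmth and moisture.

Randomness is organised as one master seed spawning named substreams
(:data:`STREAMS`), so adding a new layer never perturbs existing ones and
identical scenario+seed yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid_io import Affine, GridStack, RasterGrid

__all__ = [
    "ClimateVarParams",
    "NDVIParams",
    "DriverParams",
    "SyntheticScenario",
    "TruthRecord",
    "MonthlyClimate",
    "generate_climate",
    "generate_vegetation",
    "generate_drivers",
    "generate_nep_trend_stack",
    "annual_series",
]

# fixed substream codes: layer identity, never positional
STREAMS = {
    "temperature": 11,
    "precipitation": 12,
    "solar_radiation": 13,
    "ndvi": 21,
    "vegtype": 22,
    "elevation": 31,
    "slope": 32,
    "nighttime_light": 33,
    "population_density": 34,
    "impervious_change": 41,
    "human_footprint_change": 42,
    "land_use_change": 43,
    "arable_expansion_change": 44,
    "nep_effect_noise": 51,
    "nep_trend_noise": 52,
}

#: per-driver layer kind and (for categorical drivers) stratum count
DRIVER_KINDS = {
    "elevation": ("continuous", None),
    "slope": ("continuous", None),
    "nighttime_light": ("continuous", None),
    "population_density": ("continuous", None),
    "impervious_change": ("categorical", 3),
    "human_footprint_change": ("categorical", 6),
    "land_use_change": ("categorical", 12),
    "arable_expansion_change": ("categorical", 4),
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(STREAMS[stream],)))


@dataclass
class ClimateVarParams:
    """Generating parameters for one monthly climate variable."""

    mean: float                  # spatial/annual mean level
    seasonal_amplitude: float    # half-amplitude of the sinusoidal annual cycle
    gradient: float              # north→south linear difference across the grid
    noise_sd: float              # i.i.d. Gaussian monthly noise
    trend_per_year: float = 0.0  # linear interannual trend
    peak_month: int = 7          # month of the seasonal maximum
    floor: float | None = None   # hard lower clip (precipitation ≥ 0)


@dataclass
class NDVIParams:
    baseline: float = 0.62       # mean NDVI before climate coupling
    spatial_sd: float = 0.08     # smooth spatial variation of the baseline
    coef_temperature: float = 0.06   # NDVI response per z-score of monthly T
    coef_precipitation: float = 0.05
    trend_per_year: float = 0.002    # greening trend
    noise_sd: float = 0.02
    lo: float = -0.2
    hi: float = 1.0


@dataclass
class DriverParams:
    """Additive NEP effects (g C m⁻² a⁻¹) by stratum for one driver.

    ``effects[k]`` is the shift applied to pixels in stratum ``k+1``.  A
    driver with all-zero effects is a null driver.
    """

    effects: tuple[float, ...] = ()


def _default_climate() -> dict[str, ClimateVarParams]:
    return {
        "temperature": ClimateVarParams(
            mean=16.5, seasonal_amplitude=11.0, gradient=3.0, noise_sd=1.0,
            trend_per_year=0.02),
        "precipitation": ClimateVarParams(
            mean=128.0, seasonal_amplitude=60.0, gradient=-25.0, noise_sd=18.0,
            trend_per_year=0.1, peak_month=6, floor=0.0),
        "solar_radiation": ClimateVarParams(
            mean=385.0, seasonal_amplitude=150.0, gradient=-30.0, noise_sd=20.0),
    }


def _default_drivers() -> dict[str, DriverParams]:
    out = {name: DriverParams(effects=(0.0,) * (n or 0)) for name, (_, n) in DRIVER_KINDS.items()}
    # one causal driver with strong stratified structure; the rest are null
    out["impervious_change"] = DriverParams(effects=(100.0, 300.0, 500.0))
    return out


@dataclass
class SyntheticScenario:
    """Full description of a synthetic study: grid, years, process parameters."""

    shape: tuple[int, int] = (100, 100)
    start_year: int = 2000
    n_years: int = 24
    seed: int = 0
    pixel_size: float = 1000.0           # metres; 1 km → 10⁶ m² per pixel
    crs: str = "EPSG:6933"
    climate_params: dict[str, ClimateVarParams] = field(default_factory=_default_climate)
    ndvi_params: NDVIParams = field(default_factory=NDVIParams)
    driver_params: dict[str, DriverParams] = field(default_factory=_default_drivers)
    nep_effect_base: float = 0.0
    nep_effect_noise_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ValueError("scenario needs at least one year")

    @property
    def transform(self) -> Affine:
        return Affine.from_origin(0.0, self.shape[0] * self.pixel_size,
                                  self.pixel_size, self.pixel_size)

    @property
    def years(self) -> list[int]:
        return list(range(self.start_year, self.start_year + self.n_years))

    @property
    def time_index(self) -> list[tuple[int, int]]:
        return [(y, m) for y in self.years for m in range(1, 13)]

    def grid(self, values: np.ndarray, semantic: str = "") -> RasterGrid:
        return RasterGrid(values, self.transform, self.crs, semantic=semantic)


@dataclass
class TruthRecord:
    """Ground truth of everything a generator injected."""

    injected_nep_slope: float | None = None
    stratum_means: dict[str, np.ndarray] = field(default_factory=dict)
    stratum_effects: dict[str, np.ndarray] = field(default_factory=dict)
    causal_drivers: list[str] = field(default_factory=list)
    partial_structure: dict[str, float] = field(default_factory=dict)


@dataclass
class MonthlyClimate:
    temperature: GridStack
    precipitation: GridStack
    solar_radiation: GridStack

    def as_dict(self) -> dict[str, GridStack]:
        return {
            "temperature": self.temperature,
            "precipitation": self.precipitation,
            "solar_radiation": self.solar_radiation,
        }


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float = 8.0) -> np.ndarray:
    """Zero-mean, unit-sd spatially smooth Gaussian random field."""
    raw = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(raw, sigma=sigma, mode="reflect")
    sd = sm.std()
    return (sm - sm.mean()) / (sd if sd > 0 else 1.0)


def _ns_gradient(shape: tuple[int, int]) -> np.ndarray:
    """0 at the north edge to 1 at the south edge, constant along columns."""
    rows = np.arange(shape[0], dtype=float)
    g = rows / max(shape[0] - 1, 1)
    return np.repeat(g[:, None], shape[1], axis=1)


def generate_climate(scenario: SyntheticScenario) -> MonthlyClimate:
    """Monthly T/R/SOL stacks with seasonal cycle, gradient, trend and noise."""
    grad = _ns_gradient(scenario.shape)
    stacks = {}
    for name, p in scenario.climate_params.items():
        rng = _rng(scenario.seed, name)
        base = p.mean + p.gradient * (grad - 0.5) + 0.3 * p.noise_sd * _smooth_field(rng, scenario.shape)
        layers = []
        for yi in range(scenario.n_years):
            for m in range(1, 13):
                season = p.seasonal_amplitude * np.cos(2 * np.pi * (m - p.peak_month) / 12.0)
                vals = base + season + p.trend_per_year * yi
                if p.noise_sd > 0:
                    vals = vals + rng.normal(0.0, p.noise_sd, scenario.shape)
                else:
                    vals = vals.copy()
                if p.floor is not None:
                    np.clip(vals, p.floor, None, out=vals)
                layers.append(scenario.grid(vals, semantic=name))
        stacks[name] = GridStack(layers, time_index=scenario.time_index)
    return MonthlyClimate(stacks["temperature"], stacks["precipitation"],
                          stacks["solar_radiation"])


def _climate_anomaly(arr: np.ndarray, p: ClimateVarParams) -> np.ndarray:
    """Standardised deviation of a monthly stack from its deterministic
    global expectation (mean + seasonal cycle + trend; gradients and noise
    remain in the anomaly, so it carries both spatial and temporal signal)."""
    n_months = arr.shape[0]
    months = np.arange(n_months) % 12 + 1
    years = np.arange(n_months) // 12
    det = p.mean + p.seasonal_amplitude * np.cos(2 * np.pi * (months - p.peak_month) / 12.0) \
        + p.trend_per_year * years
    anom = arr - det[:, None, None]
    sd = anom.std()
    return anom / (sd if sd > 0 else 1.0)


def generate_vegetation(
    scenario: SyntheticScenario, climate: MonthlyClimate
) -> tuple[GridStack, RasterGrid]:
    """Monthly NDVI coupled to climate, plus a ≥2-class vegetation-type map.

    NDVI(x, t) = clip(baseline(x) + a·zT(x,t) + b·zR(x,t) + greening + noise)
    where zT, zR are standardised climate anomalies about the deterministic
    seasonal expectation, so NDVI tracks both the spatial climate gradient
    and interannual fluctuations.  Raises if the configured coupling and
    noise make NDVI constant everywhere (degenerate for every
    correlation-based stage downstream).
    """
    p = scenario.ndvi_params
    rng = _rng(scenario.seed, "ndvi")
    baseline = p.baseline + p.spatial_sd * _smooth_field(rng, scenario.shape)
    zt = _climate_anomaly(climate.temperature.as_array(),
                          scenario.climate_params["temperature"])
    zr = _climate_anomaly(climate.precipitation.as_array(),
                          scenario.climate_params["precipitation"])
    layers = []
    for i in range(zt.shape[0]):
        vals = baseline + p.coef_temperature * zt[i] \
            + p.coef_precipitation * zr[i] \
            + p.trend_per_year * (i // 12)
        if p.noise_sd > 0:
            vals = vals + rng.normal(0.0, p.noise_sd, scenario.shape)
        np.clip(vals, p.lo, p.hi, out=vals)
        layers.append(scenario.grid(vals, semantic="ndvi"))
    ndvi = GridStack(layers, time_index=scenario.time_index)
    arr = ndvi.as_array()
    if np.ptp(arr) == 0:
        raise ValueError("degenerate scenario: NDVI constant everywhere "
                         "(zero coupling, zero noise, flat baseline)")
    vt_rng = _rng(scenario.seed, "vegtype")
    zone = _smooth_field(vt_rng, scenario.shape, sigma=12.0) + 0.8 * _ns_gradient(scenario.shape)
    codes = np.digitize(zone, np.quantile(zone, [0.45, 0.8])) + 1  # 1 forest, 2 shrub/grass, 3 crop
    vegtype = scenario.grid(codes.astype(np.int32), semantic="vegetation_type")
    return ndvi, vegtype


def _categorical_layer(rng: np.random.Generator, shape: tuple[int, int], n_strata: int) -> np.ndarray:
    """Blocky categorical field: quantile slices of a smooth random field."""
    f = _smooth_field(rng, shape, sigma=6.0)
    qs = np.quantile(f, np.linspace(0, 1, n_strata + 1)[1:-1])
    return (np.digitize(f, qs) + 1).astype(np.int32)


def generate_drivers(
    scenario: SyntheticScenario,
) -> tuple[dict[str, RasterGrid], RasterGrid, TruthRecord]:
    """The driver layer set, a stratified NEP-effect surface, and its truth.

    Continuous drivers are smooth spatial fields (elevation in metres, slope
    in degrees derived from the elevation field, nighttime light and
    population density as non-negative skewed fields).  Categorical drivers
    carry 3/6/12/4 strata respectively.  The effect surface is
    ``base + Σ_driver effects[stratum] + noise`` with every injected mean
    recorded in the :class:`TruthRecord`.
    """
    shape = scenario.shape
    drivers: dict[str, RasterGrid] = {}

    elev_rng = _rng(scenario.seed, "elevation")
    elev = 400.0 + 450.0 * _smooth_field(elev_rng, shape, sigma=10.0) \
        + 350.0 * (1.0 - _ns_gradient(shape))
    elev = np.clip(elev, 0.0, None)
    drivers["elevation"] = scenario.grid(elev, semantic="elevation_m")

    gy, gx = np.gradient(elev, scenario.pixel_size)
    slope_deg = np.degrees(np.arctan(np.hypot(gx, gy)))
    slope_deg = slope_deg + 0.5 * np.abs(_smooth_field(_rng(scenario.seed, "slope"), shape, sigma=5.0))
    drivers["slope"] = scenario.grid(slope_deg, semantic="slope_deg")

    ntl = np.exp(1.2 * _smooth_field(_rng(scenario.seed, "nighttime_light"), shape, sigma=7.0)
                 + 1.5 * _ns_gradient(shape) - 1.5)
    drivers["nighttime_light"] = scenario.grid(ntl, semantic="nighttime_light")

    pop = 200.0 * np.exp(1.0 * _smooth_field(_rng(scenario.seed, "population_density"), shape, sigma=7.0)
                         + 1.2 * _ns_gradient(shape) - 0.6)
    drivers["population_density"] = scenario.grid(pop, semantic="pop_per_km2")

    for name, (kind, n_strata) in DRIVER_KINDS.items():
        if kind != "categorical":
            continue
        codes = _categorical_layer(_rng(scenario.seed, name), shape, n_strata)
        counts = np.bincount(codes.ravel(), minlength=n_strata + 1)[1:]
        if (counts == 0).any():
            raise RuntimeError(f"driver {name}: empty stratum in generated layer")
        drivers[name] = scenario.grid(codes, semantic=name)

    truth = TruthRecord()
    effect = np.full(shape, float(scenario.nep_effect_base))
    for name, params in scenario.driver_params.items():
        kind, n_strata = DRIVER_KINDS[name]
        eff = np.asarray(params.effects, dtype=float)
        if kind == "categorical":
            if eff.size != n_strata:
                raise ValueError(
                    f"driver {name}: {eff.size} effects for {n_strata} strata")
            codes = drivers[name].values
            effect = effect + eff[codes - 1]
            truth.stratum_effects[name] = eff
            truth.stratum_means[name] = scenario.nep_effect_base + eff
            if np.ptp(eff) > 0:
                truth.causal_drivers.append(name)
        elif eff.size and np.ptp(eff) > 0:
            raise ValueError(f"continuous driver {name} cannot take stratum effects")
    noise_rng = _rng(scenario.seed, "nep_effect_noise")
    surface = effect + noise_rng.normal(0.0, scenario.nep_effect_noise_sd, shape)
    nep_effect = scenario.grid(surface, semantic="nep_effect")
    return drivers, nep_effect, truth


def generate_nep_trend_stack(
    scenario: SyntheticScenario,
    slope: float,
    noise_sd: float,
    base: float = 380.0,
) -> tuple[GridStack, TruthRecord]:
    """Annual NEP stack with a directly injected per-pixel linear trend.

    ``NEP(x, i) = base + slope·i + ε``, ε ~ N(0, noise_sd²) i.i.d. per pixel
    and year — the controlled input for trend-recovery checks.
    """
    rng = _rng(scenario.seed, "nep_trend_noise")
    layers = []
    for yi, year in enumerate(scenario.years):
        vals = base + slope * yi + rng.normal(0.0, noise_sd, scenario.shape)
        layers.append(scenario.grid(vals, semantic="nep_annual"))
    stack = GridStack(layers, time_index=[(y, 12) for y in scenario.years])
    return stack, TruthRecord(injected_nep_slope=slope)


def annual_series(stack: GridStack, how: str = "mean") -> GridStack:
    """Collapse a monthly stack to annual layers (mean for states such as
    temperature, sum for fluxes such as precipitation or NPP)."""
    if stack.time_index is None:
        raise ValueError("stack has no time index")
    years = sorted({y for y, _ in stack.time_index})
    ref = stack.layers[0]
    out = []
    for year in years:
        idx = [i for i, (y, _) in enumerate(stack.time_index) if y == year]
        arr = np.stack([stack.layers[i].masked() for i in idx])
        if how == "mean":
            vals = np.nanmean(arr, axis=0)
        elif how == "sum":
            vals = arr.sum(axis=0)  # nan propagates: a masked month masks the year
        else:
            raise ValueError(f"how must be 'mean' or 'sum', got {how!r}")
        mask = ~np.isfinite(vals)
        out.append(RasterGrid(np.where(mask, np.nan, vals), ref.transform, ref.crs,
                              mask, stack.layers[idx[0]].semantic))
    return GridStack(out, time_index=[(y, 12) for y in years])
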