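"""Net ecosystem productivity: heterotrophic respiration, NEP, sink/source
classification and regional carbon budgets.

Soil heterotrophic respiration follows the empirical monthly form

    Rh = 0.22 × (exp(0.0913·T) + ln(0.3145·R) + 1) × 30 × 0.465

with T air temperature (°C) and R precipitation (mm month⁻¹); the day
factor 30 and carbon fraction 46.5 % are applied literally as printed
constants.  NEP = NPP − Rh per month, summed to annual; pixels with
positive annual NEP act as carbon sinks, negative as sources.

Cells with R ≤ 0 in a month leave the logarithm undefined; they are masked
for that month and counted in a diagnostics record, never silently zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid_io import GridStack, RasterGrid
from .casa import NPPCube

__all__ = [
    "RH_COEF",
    "NEPCube",
    "RegionalBudget",
    "compute_rh",
    "compute_rh_stack",
    "compute_nep",
    "classify_sink_source",
    "aggregate_regional",
    "SINK",
    "SOURCE",
    "NEUTRAL",
]

RH_COEF = {"a": 0.22, "b": 0.0913, "c": 0.3145, "days": 30.0, "carbon_fraction": 0.465}

SINK, NEUTRAL, SOURCE = 1, 0, -1


@dataclass
class RhDiagnostics:
    """Per-month counts of cells masked because precipitation ≤ 0."""

    masked_nonpositive_precip: list[int] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.masked_nonpositive_precip)


@dataclass
class NEPCube:
    rh_monthly: GridStack
    nep_monthly: GridStack
    nep_annual: GridStack
    diagnostics: RhDiagnostics


@dataclass
class RegionalBudget:
    """Carbon totals in Tg C a⁻¹ (10¹² g) split by NEP sign."""

    sink_total: float
    source_total: float
    net_total: float
    sink_area_fraction: float
    source_area_fraction: float
    neutral_area_fraction: float
    pixel_area_m2: float
    n_valid: int

    def to_dict(self) -> dict:
        return {
            "sink_total_TgC": self.sink_total,
            "source_total_TgC": self.source_total,
            "net_total_TgC": self.net_total,
            "sink_area_fraction": self.sink_area_fraction,
            "source_area_fraction": self.source_area_fraction,
            "neutral_area_fraction": self.neutral_area_fraction,
            "pixel_area_m2": self.pixel_area_m2,
            "n_valid": self.n_valid,
        }


def compute_rh(temperature: RasterGrid, precipitation: RasterGrid) -> tuple[RasterGrid, int]:
    """Monthly Rh grid (g C m⁻² month⁻¹) and the count of cells masked for
    non-positive precipitation."""
    t = temperature.values.astype(float)
    r = precipitation.values.astype(float)
    base_mask = temperature.nodata_mask | precipitation.nodata_mask
    nonpos = (~base_mask) & (r <= 0)
    mask = base_mask | nonpos
    with np.errstate(invalid="ignore", divide="ignore"):
        rh = (
            RH_COEF["a"]
            * (np.exp(RH_COEF["b"] * t) + np.log(RH_COEF["c"] * r) + 1.0)
            * RH_COEF["days"]
            * RH_COEF["carbon_fraction"]
        )
    return (
        RasterGrid(np.where(mask, np.nan, rh), temperature.transform,
                   temperature.crs, mask, semantic="rh_gC_m2_month"),
        int(nonpos.sum()),
    )


def compute_rh_stack(temperature: GridStack, precipitation: GridStack) -> tuple[GridStack, RhDiagnostics]:
    if temperature.time_index != precipitation.time_index:
        raise ValueError("temperature and precipitation stacks have different time indices")
    diag = RhDiagnostics()
    layers = []
    for t_lyr, r_lyr in zip(temperature.layers, precipitation.layers):
        rh, n_bad = compute_rh(t_lyr, r_lyr)
        diag.masked_nonpositive_precip.append(n_bad)
        layers.append(rh)
    return GridStack(layers, time_index=temperature.time_index), diag


def compute_nep(npp: NPPCube, rh_monthly: GridStack,
                diagnostics: RhDiagnostics | None = None) -> NEPCube:
    """NEP(x, t) = NPP(x, t) − Rh(x, t), monthly and summed to annual."""
    ti = npp.npp_monthly.time_index
    if ti != rh_monthly.time_index:
        raise ValueError("NPP and Rh stacks have different time indices")
    nep_layers = []
    ref = npp.npp_monthly.layers[0]
    for npp_lyr, rh_lyr in zip(npp.npp_monthly.layers, rh_monthly.layers):
        mask = npp_lyr.nodata_mask | rh_lyr.nodata_mask
        vals = npp_lyr.values - rh_lyr.values
        nep_layers.append(RasterGrid(np.where(mask, np.nan, vals), ref.transform,
                                     ref.crs, mask, semantic="nep_gC_m2_month"))
    nep_monthly = GridStack(nep_layers, time_index=ti)
    years = sorted({y for y, _ in ti})
    annual = []
    for year in years:
        idx = [i for i, (y, _) in enumerate(ti) if y == year]
        arr = np.stack([nep_layers[i].masked() for i in idx]).sum(axis=0)
        mask = ~np.isfinite(arr)
        annual.append(RasterGrid(np.where(mask, np.nan, arr), ref.transform,
                                 ref.crs, mask, semantic="nep_gC_m2_a"))
    nep_annual = GridStack(annual, time_index=[(y, 12) for y in years])
    return NEPCube(rh_monthly, nep_monthly, nep_annual,
                   diagnostics or RhDiagnostics())


def classify_sink_source(nep_annual: RasterGrid) -> RasterGrid:
    """Sink (+1) where NEP > 0, source (−1) where NEP < 0, neutral (0) at
    exactly zero."""
    vals = nep_annual.values
    codes = np.zeros(vals.shape, dtype=np.int8)
    codes[vals > 0] = SINK
    codes[vals < 0] = SOURCE
    return RasterGrid(codes, nep_annual.transform, nep_annual.crs,
                      nep_annual.nodata_mask.copy(), semantic="sink_source")


def aggregate_regional(nep_annual: RasterGrid) -> RegionalBudget:
    """Regional totals: Σ NEP × pixel area split by sign, in Tg C a⁻¹.

    Assumes an equal-area georeference so one pixel area applies everywhere
    (the transform's pixel area, 10⁶ m² for a 1 km grid).
    """
    area = nep_annual.transform.pixel_area
    valid = ~nep_annual.nodata_mask
    vals = nep_annual.values[valid].astype(float)
    n = vals.size
    if n == 0:
        return RegionalBudget(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, area, 0)
    g_to_tg = 1e-12
    sink = float(vals[vals > 0].sum() * area * g_to_tg)
    source = float(vals[vals < 0].sum() * area * g_to_tg)
    return RegionalBudget(
        sink_total=sink,
        source_total=source,
        net_total=sink + source,
        sink_area_fraction=float((vals > 0).mean()),
        source_area_fraction=float((vals < 0).mean()),
        neutral_area_fraction=float((vals == 0).mean()),
        pixel_area_m2=area,
        n_valid=n,
    )
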