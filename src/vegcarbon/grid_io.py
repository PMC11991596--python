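"""Georeferenced raster containers, GeoTIFF I/O and grid alignment.

All layers in a pipeline run live on one common grid (the usual
"resample everything to 1 km" preprocessing contract).  The conventions
used throughout:

* pixel registration by cell centre; index (row 0, col 0) is the
  north-west pixel, rows increase southwards;
* a rectilinear affine transform (no rotation/shear) maps pixel edges to
  world coordinates; pixel sizes are strictly positive (dy stored negative
  internally, north-up);
* ``nodata_mask`` is boolean with True = invalid; masked cells are excluded
  from every downstream statistic.

GeoTIFF files are written with ModelPixelScale / ModelTiepoint /
GeoKeyDirectory / GDAL_NODATA tags so they are readable by standard GIS
software; temporal stacks are multi-band files whose band labels
("YYYY-MM") travel in the image description.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import tifffile

__all__ = [
    "Affine",
    "RasterGrid",
    "GridStack",
    "read_raster",
    "read_stack",
    "write_raster",
    "write_stack",
    "align_to_grid",
]

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class Affine:
    """Rectilinear map from pixel space to world coordinates.

    ``x = x0 + dx * col``, ``y = y0 + dy * row`` for the pixel's upper-left
    corner; cell centres sit at ``col + 0.5, row + 0.5``.  ``dx > 0`` and
    ``dy < 0`` for a north-up grid.
    """

    x0: float
    y0: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if self.dx == 0 or self.dy == 0:
            raise ValueError("pixel size must be non-zero (transform must be invertible)")

    @classmethod
    def from_origin(cls, west: float, north: float, xsize: float, ysize: float) -> "Affine":
        """North-up transform from the grid's NW corner and positive pixel sizes."""
        if xsize <= 0 or ysize <= 0:
            raise ValueError("pixel sizes must be strictly positive")
        return cls(west, north, xsize, -ysize)

    @property
    def pixel_area(self) -> float:
        return abs(self.dx * self.dy)

    def xy(self, row, col, center: bool = True):
        """World coordinates of a pixel (cell centre by default)."""
        off = 0.5 if center else 0.0
        x = self.x0 + self.dx * (np.asarray(col, dtype=float) + off)
        y = self.y0 + self.dy * (np.asarray(row, dtype=float) + off)
        return x, y

    def rowcol(self, x, y, center: bool = True):
        """Fractional pixel indices of world coordinates (inverse of :meth:`xy`)."""
        off = 0.5 if center else 0.0
        col = (np.asarray(x, dtype=float) - self.x0) / self.dx - off
        row = (np.asarray(y, dtype=float) - self.y0) / self.dy - off
        return row, col

    def bounds(self, shape: tuple[int, int]) -> tuple[float, float, float, float]:
        """(west, south, east, north) extent for a grid of ``shape``."""
        rows, cols = shape
        xs = (self.x0, self.x0 + self.dx * cols)
        ys = (self.y0, self.y0 + self.dy * rows)
        return min(xs), min(ys), max(xs), max(ys)


@dataclass
class RasterGrid:
    """A single georeferenced 2-D layer with an explicit nodata mask."""

    values: np.ndarray
    transform: Affine
    crs: str = "EPSG:6933"
    nodata_mask: np.ndarray | None = None
    semantic: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"RasterGrid values must be 2-D, got shape {self.values.shape}")
        if self.nodata_mask is None:
            mask = np.zeros(self.values.shape, dtype=bool)
            if np.issubdtype(self.values.dtype, np.floating):
                mask |= ~np.isfinite(self.values)
            self.nodata_mask = mask
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("values and nodata_mask must share shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_count(self) -> int:
        return int((~self.nodata_mask).sum())

    def valid_values(self) -> np.ndarray:
        return self.values[~self.nodata_mask]

    def masked(self, fill=np.nan) -> np.ndarray:
        """Values as float with masked cells replaced by ``fill``."""
        out = self.values.astype(float, copy=True)
        out[self.nodata_mask] = fill
        return out

    def same_grid(self, other: "RasterGrid", rtol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and self.crs == other.crs
            and np.allclose(
                [self.transform.x0, self.transform.y0, self.transform.dx, self.transform.dy],
                [other.transform.x0, other.transform.y0, other.transform.dx, other.transform.dy],
                rtol=rtol,
                atol=0,
            )
        )

    def with_values(self, values: np.ndarray, mask: np.ndarray | None = None,
                    semantic: str | None = None) -> "RasterGrid":
        return RasterGrid(
            values=np.asarray(values),
            transform=self.transform,
            crs=self.crs,
            nodata_mask=self.nodata_mask.copy() if mask is None else np.asarray(mask, bool),
            semantic=self.semantic if semantic is None else semantic,
        )


@dataclass
class GridStack:
    """Ordered layers on one shared grid, optionally labelled by (year, month)."""

    layers: list[RasterGrid]
    time_index: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("GridStack needs at least one layer")
        ref = self.layers[0]
        for lyr in self.layers[1:]:
            if not lyr.same_grid(ref):
                raise ValueError("all layers of a GridStack must share shape/transform/crs")
        if self.time_index is not None and len(self.time_index) != len(self.layers):
            raise ValueError(
                f"time_index length {len(self.time_index)} != layer count {len(self.layers)}"
            )

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, i) -> RasterGrid:
        return self.layers[i]

    @property
    def transform(self) -> Affine:
        return self.layers[0].transform

    @property
    def crs(self) -> str:
        return self.layers[0].crs

    @property
    def shape(self) -> tuple[int, int]:
        return self.layers[0].shape

    def as_array(self, fill=np.nan) -> np.ndarray:
        """(n_layers, rows, cols) float array with masked cells = ``fill``."""
        return np.stack([lyr.masked(fill) for lyr in self.layers])

    def common_mask(self) -> np.ndarray:
        """True where ANY layer is masked (complete-case mask)."""
        m = np.zeros(self.shape, dtype=bool)
        for lyr in self.layers:
            m |= lyr.nodata_mask
        return m


# ---------------------------------------------------------------------------
# GeoTIFF plumbing


def _geokeys_for_crs(crs: str) -> tuple[int, ...]:
    code = 0
    if crs and crs.upper().startswith("EPSG:"):
        code = int(crs.split(":")[1])
    geographic = code == 4326
    model = 2 if geographic else 1
    crs_key = 2048 if geographic else 3072
    # GeoKeyDirectory header: version 1, revision 1.0, 3 keys
    return (
        1, 1, 0, 3,
        1024, 0, 1, model,        # GTModelType: 1 projected / 2 geographic
        1025, 0, 1, 1,            # GTRasterType: PixelIsArea
        crs_key, 0, 1, code or 32767,
    )


def _crs_from_geokeys(keys: Sequence[int]) -> str:
    vals = {}
    for i in range(4, len(keys) - 3, 4):
        vals[keys[i]] = keys[i + 3]
    for k in (3072, 2048):
        if k in vals and vals[k] not in (0, 32767):
            return f"EPSG:{vals[k]}"
    return ""


def _geo_extratags(grid: RasterGrid, nodata) -> list:
    t = grid.transform
    if t.dx <= 0 or t.dy >= 0:
        raise ValueError("GeoTIFF writing expects a north-up transform (dx > 0, dy < 0)")
    keys = _geokeys_for_crs(grid.crs)
    return [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (float(t.dx), float(-t.dy), 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(t.x0), float(t.y0), 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(keys), keys),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]


def _prepare_band(grid: RasterGrid, nodata: float) -> np.ndarray:
    vals = grid.values
    if np.issubdtype(vals.dtype, np.floating):
        out = vals.astype(np.float64, copy=True)
    else:
        out = vals.astype(np.float64)
    out[grid.nodata_mask] = nodata
    return out


def write_raster(grid: RasterGrid, path: str | os.PathLike, nodata: float = -9999.0) -> None:
    """Write a single-band GeoTIFF; masked cells get the nodata value."""
    write_stack(GridStack([grid]), path, nodata=nodata)


def write_stack(stack: GridStack, path: str | os.PathLike, nodata: float = -9999.0) -> None:
    """Write a (multi-band) GeoTIFF with georeference and band labels."""
    ref = stack.layers[0]
    data = np.stack([_prepare_band(lyr, nodata) for lyr in stack.layers])
    if stack.time_index is not None:
        labels = [f"{y:04d}-{m:02d}" for y, m in stack.time_index]
    else:
        labels = [lyr.semantic or f"band{i+1}" for i, lyr in enumerate(stack.layers)]
    desc = json.dumps(
        {
            "vegcarbon": 1,
            "crs": ref.crs,
            "nodata": nodata,
            "band_labels": labels,
            "semantics": [lyr.semantic for lyr in stack.layers],
        }
    )
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        extratags=_geo_extratags(ref, nodata),
        description=desc,
        metadata=None,
    )


def _read_pages(path: str | os.PathLike):
    if not os.path.exists(path):
        raise FileNotFoundError(f"raster not found: {path}")
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        tags = {tag.code: tag.value for tag in page.tags.values()}
        data = tif.asarray()
    if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
        raise ValueError(f"{path}: no georeference (ModelPixelScale/ModelTiepoint missing)")
    sx, sy = float(tags[_TAG_MODEL_PIXEL_SCALE][0]), float(tags[_TAG_MODEL_PIXEL_SCALE][1])
    tie = tags[_TAG_MODEL_TIEPOINT]
    # tiepoint maps raster (i, j) -> world (x, y); standard files anchor at (0, 0)
    x0 = float(tie[3]) - float(tie[0]) * sx
    y0 = float(tie[4]) + float(tie[1]) * sy
    transform = Affine(x0, y0, sx, -sy)
    crs = ""
    if _TAG_GEO_KEY_DIRECTORY in tags:
        crs = _crs_from_geokeys(tags[_TAG_GEO_KEY_DIRECTORY])
    nodata = None
    if _TAG_GDAL_NODATA in tags:
        try:
            nodata = float(str(tags[_TAG_GDAL_NODATA]).strip())
        except ValueError:
            nodata = None
    meta = {}
    desc = tags.get(270, "")
    if isinstance(desc, bytes):
        desc = desc.decode("utf-8", "replace")
    if desc:
        try:
            parsed = json.loads(desc)
            if isinstance(parsed, dict) and parsed.get("vegcarbon"):
                meta = parsed
        except (json.JSONDecodeError, TypeError):
            pass
    if meta.get("crs"):
        crs = meta["crs"]
    if data.ndim == 2:
        data = data[None]
    return data.astype(np.float64), transform, crs, nodata, meta


def _band_to_grid(band: np.ndarray, transform: Affine, crs: str, nodata, semantic: str) -> RasterGrid:
    mask = ~np.isfinite(band)
    if nodata is not None and np.isfinite(nodata):
        mask |= band == nodata
    return RasterGrid(band, transform, crs or "EPSG:6933", mask, semantic)


def read_raster(path: str | os.PathLike, semantic: str = ""):
    """Read a GeoTIFF.

    Returns a :class:`RasterGrid` for single-band files and a
    :class:`GridStack` (one layer per band, with "YYYY-MM" time labels when
    present) for multi-band files.
    """
    data, transform, crs, nodata, meta = _read_pages(path)
    labels = meta.get("band_labels") or [""] * len(data)
    semantics = meta.get("semantics") or [semantic] * len(data)
    if len(data) == 1:
        return _band_to_grid(data[0], transform, crs, nodata, semantic or semantics[0])
    layers = [
        _band_to_grid(band, transform, crs, nodata, semantics[i] or semantic)
        for i, band in enumerate(data)
    ]
    time_index = None
    if all(len(lbl) == 7 and lbl[4] == "-" for lbl in labels):
        time_index = [(int(lbl[:4]), int(lbl[5:7])) for lbl in labels]
    return GridStack(layers, time_index=time_index)


def read_stack(path: str | os.PathLike, semantic: str = "") -> GridStack:
    """Read a GeoTIFF as a stack even when it has a single band."""
    out = read_raster(path, semantic=semantic)
    if isinstance(out, RasterGrid):
        return GridStack([out])
    return out


# ---------------------------------------------------------------------------
# Alignment


def _bilinear_sample(src: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """NaN-aware bilinear sampling; a neighbour contaminates only if its
    weight is non-zero, so nodata never bleeds into valid cells."""
    nr, nc = src.shape
    out = np.full(rows.shape, np.nan)
    inside = (rows >= -0.5) & (rows <= nr - 0.5) & (cols >= -0.5) & (cols <= nc - 0.5)
    r = np.clip(rows[inside], 0, nr - 1)
    c = np.clip(cols[inside], 0, nc - 1)
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    r0 = np.minimum(r0, nr - 1)
    c0 = np.minimum(c0, nc - 1)
    fr = r - r0
    fc = c - c0
    r1 = np.minimum(r0 + 1, nr - 1)
    c1 = np.minimum(c0 + 1, nc - 1)
    vals = np.zeros(r.shape)
    bad = np.zeros(r.shape, dtype=bool)
    for (ri, ci, w) in (
        (r0, c0, (1 - fr) * (1 - fc)),
        (r0, c1, (1 - fr) * fc),
        (r1, c0, fr * (1 - fc)),
        (r1, c1, fr * fc),
    ):
        active = w > 0
        v = src[ri, ci]
        contrib = np.where(active, w * np.where(np.isnan(v), 0.0, v), 0.0)
        bad |= active & np.isnan(v)
        vals += contrib
    vals[bad] = np.nan
    out[inside] = vals
    return out


def _nearest_sample(src: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    nr, nc = src.shape
    out = np.full(rows.shape, np.nan)
    ri = np.rint(rows).astype(int)
    ci = np.rint(cols).astype(int)
    inside = (ri >= 0) & (ri < nr) & (ci >= 0) & (ci < nc)
    out[inside] = src[ri[inside], ci[inside]]
    return out


def align_to_grid(src: RasterGrid, target: RasterGrid, kind: str = "continuous") -> RasterGrid:
    """Resample ``src`` onto ``target``'s grid.

    Continuous layers use bilinear interpolation, categorical layers nearest
    neighbour so class codes are never blended.  A source grid already on the
    target grid is returned value-identical.
    """
    if kind not in ("continuous", "categorical"):
        raise ValueError(f"kind must be 'continuous' or 'categorical', got {kind!r}")
    if src.crs and target.crs and src.crs != target.crs:
        raise ValueError(f"CRS mismatch: {src.crs} vs {target.crs} (reproject first)")
    if src.same_grid(target):
        return RasterGrid(src.values.copy(), target.transform, target.crs,
                          src.nodata_mask.copy(), src.semantic)
    sb = src.transform.bounds(src.shape)
    tb = target.transform.bounds(target.shape)
    if sb[2] <= tb[0] or tb[2] <= sb[0] or sb[3] <= tb[1] or tb[3] <= sb[1]:
        raise ValueError(
            f"extents do not overlap: src (w,s,e,n)={sb} vs target (w,s,e,n)={tb}"
        )
    rr, cc = np.meshgrid(
        np.arange(target.shape[0]), np.arange(target.shape[1]), indexing="ij"
    )
    x, y = target.transform.xy(rr, cc)
    srows, scols = src.transform.rowcol(x, y)
    filled = src.masked(np.nan)
    if kind == "continuous":
        vals = _bilinear_sample(filled, srows, scols)
    else:
        vals = _nearest_sample(filled, srows, scols)
    mask = ~np.isfinite(vals)
    vals = np.where(mask, np.nan, vals)
    if kind == "categorical":
        out_vals = np.where(mask, -1, np.rint(vals)).astype(src.values.dtype, copy=False) \
            if np.issubdtype(src.values.dtype, np.integer) else vals
    else:
        out_vals = vals
    return RasterGrid(out_vals, target.transform, target.crs, mask, src.semantic)
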