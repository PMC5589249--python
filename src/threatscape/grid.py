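"""Common-grid raster data model and transforms.

All analysis layers live on a single geographic (lat/lon) grid whose rows run
north to south and whose cell registration is by the north-west corner.  The
default resolution is 2.5 arc-minutes, roughly 4.5 km at the equator.  Every
layer is forced onto one :class:`GridSpec` before any raster arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

logger = logging.getLogger(__name__)

#: 2.5 arc-minutes in decimal degrees.
DEFAULT_CELL_SIZE = 2.5 / 60.0

#: Kilometres per degree of latitude (spherical approximation).
KM_PER_DEGREE = 111.32

#: Nominal cell side in km for a 2.5-arc-minute cell, as conventionally quoted.
NOMINAL_SIDE_KM = 4.5

CLASS_NO_THREAT = 0
CLASS_LOW = 1
CLASS_MEDIUM = 2
CLASS_HIGH = 3
CLASS_VERY_HIGH = 4

CLASS_NAMES = ("No threat", "Low", "Medium", "High", "Very high")


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the common analysis grid.

    ``origin_lon``/``origin_lat`` locate the north-west corner of the grid;
    cell centers sit at ``origin + (index + 0.5) * cell_size`` (latitude
    decreasing with row index).
    """

    n_rows: int
    n_cols: int
    cell_size: float = DEFAULT_CELL_SIZE
    origin_lon: float = 0.0
    origin_lat: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_center_lons(self) -> np.ndarray:
        return self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def cell_center_lats(self) -> np.ndarray:
        return self.origin_lat - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of (lon, lat) cell centers, each shaped like the grid."""
        lon, lat = np.meshgrid(self.cell_center_lons(), self.cell_center_lats())
        return lon, lat

    def extent(self) -> tuple[float, float, float, float]:
        """(west, east, south, north) outer bounds."""
        return (
            self.origin_lon,
            self.origin_lon + self.n_cols * self.cell_size,
            self.origin_lat - self.n_rows * self.cell_size,
            self.origin_lat,
        )


@dataclass
class GridLayer:
    """A single real-valued raster variable with a validity mask."""

    spec: GridSpec
    values: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.spec.shape}"
            )
        if self.mask is None:
            self.mask = np.ones(self.spec.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.spec.shape:
                raise ValueError("mask shape does not match grid shape")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite values inside the validity mask")

    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]

    def copy_with(self, values: np.ndarray, mask: np.ndarray | None = None) -> "GridLayer":
        return GridLayer(self.spec, values, self.mask.copy() if mask is None else mask)


@dataclass
class ClassLayer:
    """Per-pixel ordinal threat class (0=No threat .. 4=Very high)."""

    spec: GridSpec
    classes: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.int16)
        if self.classes.shape != self.spec.shape:
            raise ValueError("classes shape does not match grid shape")
        if self.mask is None:
            self.mask = np.ones(self.spec.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.spec.shape:
                raise ValueError("mask shape does not match grid shape")
        inside = self.classes[self.mask]
        if inside.size and (inside.min() < 0 or inside.max() > 4):
            raise ValueError("class codes must lie in 0..4 inside the mask")


def resample_bilinear(source: GridLayer, target: GridSpec) -> GridLayer:
    """Resample *source* onto *target* by bilinear interpolation of cell centers.

    Target cells falling outside the source's cell-center envelope, or whose
    interpolation touches a masked-out source cell, are masked out.
    """
    sw, se, ss, sn = source.spec.extent()
    tw, te, ts, tn = target.extent()
    if se <= tw or te <= sw or sn <= ts or tn <= ss:
        raise ValueError("source and target grids are spatially disjoint")

    src_lats = source.spec.cell_center_lats()  # descending
    src_lons = source.spec.cell_center_lons()
    vals = np.where(source.mask, source.values, np.nan)
    # RegularGridInterpolator needs ascending axes; flip latitude.
    interp = RegularGridInterpolator(
        (src_lats[::-1], src_lons),
        vals[::-1, :],
        method="linear",
        bounds_error=False,
        fill_value=np.nan,
    )
    tlon, tlat = target.cell_centers()
    out = interp(np.column_stack([tlat.ravel(), tlon.ravel()])).reshape(target.shape)
    mask = np.isfinite(out)
    out = np.where(mask, out, 0.0)
    return GridLayer(target, out, mask)


def normalize_minmax(layer: GridLayer) -> GridLayer:
    """Min-max normalize over masked cells, mapping onto [0, 1].

    A constant layer normalizes to all zeros (logged), so degenerate inputs
    flow through the pipeline rather than aborting it.
    """
    inside = layer.masked_values()
    if inside.size == 0:
        raise ValueError("cannot normalize a layer with an empty mask")
    lo, hi = float(inside.min()), float(inside.max())
    out = np.zeros_like(layer.values)
    if hi == lo:
        logger.warning("normalize_minmax: constant layer (value %g) -> all zeros", lo)
    else:
        out[layer.mask] = (inside - lo) / (hi - lo)
    return layer.copy_with(out)


def sqrt_transform(layer: GridLayer) -> GridLayer:
    """Element-wise square root; used to tame heavily right-skewed layers."""
    inside = layer.masked_values()
    if inside.size and inside.min() < 0:
        raise ValueError("sqrt_transform requires non-negative values")
    out = np.zeros_like(layer.values)
    out[layer.mask] = np.sqrt(inside)
    return layer.copy_with(out)


def rasterize_points(
    lons: np.ndarray,
    lats: np.ndarray,
    target: GridSpec,
    weights: np.ndarray | None = None,
) -> GridLayer:
    """Sum point weights into grid cells (default weight 1 per point).

    Cell membership is half-open: [west, east) in longitude and
    (south, north] in latitude, so a point on a shared edge lands in exactly
    one cell.  Points outside the grid are dropped with a logged count.
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if weights is None:
        weights = np.ones_like(lons)
    else:
        weights = np.asarray(weights, dtype=float)

    cols = np.floor((lons - target.origin_lon) / target.cell_size).astype(int)
    # floor implements (south, north]: a point on a cell's north edge maps to
    # that cell's own row index; the cell above excludes its south edge.
    rows = np.floor((target.origin_lat - lats) / target.cell_size).astype(int)

    ok = (cols >= 0) & (cols < target.n_cols) & (rows >= 0) & (rows < target.n_rows)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("rasterize_points: dropped %d point(s) outside the grid", n_dropped)
    out = np.zeros(target.shape)
    np.add.at(out, (rows[ok], cols[ok]), weights[ok])
    return GridLayer(target, out)


def pixel_area_km2(spec: GridSpec, latitude: float, mode: str = "geodesic") -> float:
    """Area of one grid cell in km² at the given latitude.

    ``geodesic`` scales the east-west side by cos(latitude); ``nominal`` uses
    the conventional 4.5 km side for a 2.5-arc-minute cell (20.25 km²)
    independent of latitude, for parity with area figures quoted at that
    rounding.
    """
    if abs(latitude) >= 90:
        raise ValueError("latitude must satisfy |lat| < 90")
    if mode == "nominal":
        side = NOMINAL_SIDE_KM * (spec.cell_size / DEFAULT_CELL_SIZE)
        return side * side
    if mode != "geodesic":
        raise ValueError(f"unknown mode {mode!r}")
    ns = spec.cell_size * KM_PER_DEGREE
    ew = spec.cell_size * KM_PER_DEGREE * np.cos(np.deg2rad(latitude))
    return float(ew * ns)
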