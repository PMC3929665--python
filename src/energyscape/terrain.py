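"""Geomorphometric and focal land-cover covariates.

Derives the terrain surfaces commonly used as predictors of energy
infrastructure siting: slope and aspect (Horn's 3x3 finite differences,
the convention of standard GIS toolboxes), aspect transforms, windowed
texture statistics (variance of elevation, surface relief ratio, slope
position), the McCune-Keon heat load index, a D8 topographic wetness
index, and focal class percentages (e.g. percent forest within 1 km).

All outputs align cell-for-cell with the input grid. Focal windows
shrink at raster edges rather than emitting nodata, so covariate stacks
stay gap-free for the classifier.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .grids import GridRaster

__all__ = [
    "WindowSpec",
    "slope_aspect",
    "aspect_transform",
    "scosa",
    "focal_statistic",
    "slope_position",
    "heat_load_index",
    "wetness_index",
    "focal_percent",
    "covariate_stack",
]

FOCAL_STATISTICS = ("variance", "relief_ratio", "mean")


@dataclasses.dataclass(frozen=True)
class WindowSpec:
    """Square focal window: odd ``size`` in cells and a statistic name."""

    size: int
    statistic: str

    def __post_init__(self) -> None:
        if self.size < 3 or self.size % 2 == 0:
            raise ValueError("window size must be odd and >= 3")
        if self.statistic not in FOCAL_STATISTICS:
            raise ValueError(f"statistic must be one of {FOCAL_STATISTICS}")


def _horn_gradients(dem: GridRaster) -> tuple[np.ndarray, np.ndarray]:
    """Horn (1981) 3x3 weighted finite differences, edge-replicated."""
    z = np.pad(dem.data, 1, mode="edge")
    h = dem.cell_size
    a, b, c = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    d, f = z[1:-1, :-2], z[1:-1, 2:]
    g, hh, i = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * h)
    dzdy = ((g + 2 * hh + i) - (a + 2 * b + c)) / (8 * h)
    return dzdx, dzdy


def slope_aspect(dem: GridRaster) -> tuple[GridRaster, GridRaster]:
    """Slope (degrees, [0, 90]) and compass aspect (degrees, [0, 360)).

    Aspect is the downslope azimuth measured clockwise from north; flat
    cells (slope 0) carry NaN aspect as an explicit "undefined" flag.
    """
    if min(dem.shape) < 3:
        raise ValueError("dem must be at least 3x3")
    dzdx, dzdy = _horn_gradients(dem)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    aspect_math = np.degrees(np.arctan2(dzdy, -dzdx))
    aspect = np.where(aspect_math < 90.0, 90.0 - aspect_math, 450.0 - aspect_math)
    aspect = np.mod(aspect, 360.0)
    aspect = np.where(slope == 0.0, np.nan, aspect)
    return dem.like(slope), dem.like(aspect)


def aspect_transform(aspect_deg: GridRaster) -> GridRaster:
    """Northness, cos(aspect) in [-1, 1]; flat (flagged) cells map to 0."""
    a = aspect_deg.data
    out = np.where(np.isnan(a), 0.0, np.cos(np.radians(a)))
    return aspect_deg.like(out)


def scosa(slope_deg: GridRaster, aspect_deg: GridRaster) -> GridRaster:
    """Slope x cos(aspect): signed north-facing steepness; flat cells 0."""
    slope_deg.require_aligned(aspect_deg, "aspect")
    a = aspect_deg.data
    out = np.where(np.isnan(a), 0.0, slope_deg.data * np.cos(np.radians(a)))
    return slope_deg.like(out)


def _window_sums(data: np.ndarray, size: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Windowed sum, sum of squares, and cell count with edge shrink."""
    kernel = np.ones((size, size))
    s = ndimage.convolve(data, kernel, mode="constant", cval=0.0)
    s2 = ndimage.convolve(data**2, kernel, mode="constant", cval=0.0)
    n = ndimage.convolve(np.ones_like(data), kernel, mode="constant", cval=0.0)
    return s, s2, np.round(n)


def focal_statistic(dem: GridRaster, window: WindowSpec) -> GridRaster:
    """Windowed statistic of elevation.

    ``variance`` is the sample variance (texture), ``relief_ratio`` is
    (mean - min) / (max - min) with 0 on constant windows, and ``mean``
    is the plain focal average. Edge cells use the shrunken window.
    """
    if window.size > min(dem.shape):
        raise ValueError("window does not fit in raster")
    s, s2, n = _window_sums(dem.data, window.size)
    mean = s / n
    if window.statistic == "mean":
        return dem.like(mean)
    if window.statistic == "variance":
        ss = np.maximum(s2 - s**2 / n, 0.0)
        var = np.where(n > 1, ss / np.maximum(n - 1, 1), 0.0)
        return dem.like(var)
    wmin = ndimage.minimum_filter(dem.data, size=window.size, mode="constant", cval=np.inf)
    wmax = ndimage.maximum_filter(dem.data, size=window.size, mode="constant", cval=-np.inf)
    span = wmax - wmin
    rr = np.where(span > 0, (mean - wmin) / np.where(span > 0, span, 1.0), 0.0)
    return dem.like(rr)


def slope_position(dem: GridRaster, size: int) -> GridRaster:
    """Hierarchical slope position: elevation minus the focal mean."""
    mean = focal_statistic(dem, WindowSpec(size, "mean"))
    return dem.like(dem.data - mean.data)


def heat_load_index(
    slope_deg: GridRaster, aspect_deg: GridRaster, latitude_deg: float
) -> GridRaster:
    """McCune-Keon (2002) heat load.

    Aspect is folded about the SW-NE axis, ``A = |180 - |aspect - 225||``,
    so southwest slopes score hottest, and the index is

        HL = 0.339 + 0.808 cos(lat) cos(s) - 0.196 sin(lat) sin(s)
             - 0.482 cos(A) sin(s)

    (valid for slopes below ~60 deg at mid latitudes). Flat cells take
    the folded-aspect-neutral value with sin(s) = 0.
    """
    if not 0.0 <= latitude_deg <= 60.0:
        raise ValueError("latitude must be in [0, 60] degrees")
    slope_deg.require_aligned(aspect_deg, "aspect")
    s = np.radians(slope_deg.data)
    a = aspect_deg.data
    folded = np.radians(np.abs(180.0 - np.abs(np.where(np.isnan(a), 225.0, a) - 225.0)))
    lat = np.radians(latitude_deg)
    hl = (
        0.339
        + 0.808 * np.cos(lat) * np.cos(s)
        - 0.196 * np.sin(lat) * np.sin(s)
        - 0.482 * np.cos(folded) * np.sin(s)
    )
    return slope_deg.like(hl)


def fold_aspect(aspect_deg: np.ndarray | float) -> np.ndarray | float:
    """Fold compass aspect about the 225 deg (SW) axis into [0, 180]."""
    return np.abs(180.0 - np.abs(np.asarray(aspect_deg, float) - 225.0))


_D8_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def flow_accumulation(dem: GridRaster) -> GridRaster:
    """D8 flow accumulation in cells (each cell contributes itself).

    Every cell drains to its steepest-descent neighbor; cells with no
    lower neighbor (pits, flats, edge outlets) retain what they have
    accumulated. Cells are processed in descending elevation order so
    each donor is settled before its receiver.
    """
    z = dem.data
    rows, cols = z.shape
    dists = np.array([np.hypot(dr, dc) for dr, dc in _D8_OFFSETS]) * dem.cell_size
    zp = np.pad(z, 1, mode="constant", constant_values=np.inf)
    best_drop = np.full(z.shape, 0.0)
    receiver = np.full(z.shape, -1, dtype=np.int64)
    flat = np.arange(rows * cols).reshape(rows, cols)
    flat_p = np.pad(flat, 1, mode="constant", constant_values=-1)
    for k, (dr, dc) in enumerate(_D8_OFFSETS):
        zn = zp[1 + dr : 1 + dr + rows, 1 + dc : 1 + dc + cols]
        drop = (z - zn) / dists[k]
        better = drop > best_drop
        best_drop = np.where(better, drop, best_drop)
        rec = flat_p[1 + dr : 1 + dr + rows, 1 + dc : 1 + dc + cols]
        receiver = np.where(better, rec, receiver)
    acc = np.ones(rows * cols)
    order = np.argsort(z.ravel(), kind="stable")[::-1]
    rec_flat = receiver.ravel()
    for idx in order:
        r = rec_flat[idx]
        if r >= 0:
            acc[r] += acc[idx]
    return dem.like(acc.reshape(rows, cols))


def wetness_index(dem: GridRaster, slope_floor_rad: float = 0.001) -> GridRaster:
    """Topographic wetness index ln(a / tan(slope)).

    ``a`` is the D8 flow-accumulation area (cells x cell area, m^2);
    slope is floored at ``slope_floor_rad`` radians so flats stay finite.
    """
    acc = flow_accumulation(dem)
    slope, _ = slope_aspect(dem)
    beta = np.maximum(np.radians(slope.data), slope_floor_rad)
    cti = np.log(acc.data * dem.cell_area / np.tan(beta))
    return dem.like(cti)


def _circular_kernel(radius_cells: float) -> np.ndarray:
    r = int(np.floor(radius_cells))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (np.hypot(yy, xx) <= radius_cells).astype(float)


def focal_percent(landcover: GridRaster, class_id: int, radius_m: float) -> GridRaster:
    """Fraction of cells of ``class_id`` within a circular window.

    The window shrinks at edges (the denominator counts only in-grid
    cells), so values stay in [0, 1] everywhere.
    """
    if radius_m < landcover.cell_size:
        raise ValueError("radius must be at least one cell size")
    present = np.unique(landcover.data[~np.isnan(landcover.data)])
    if class_id not in present:
        raise ValueError(f"class_id {class_id} not present in landcover raster")
    kernel = _circular_kernel(radius_m / landcover.cell_size)
    member = (landcover.data == class_id).astype(float)
    hits = ndimage.convolve(member, kernel, mode="constant", cval=0.0)
    n = ndimage.convolve(np.ones_like(member), kernel, mode="constant", cval=0.0)
    return landcover.like(np.clip(hits / n, 0.0, 1.0))


def covariate_stack(
    dem: GridRaster,
    landcover: GridRaster | None = None,
    forest_class: int = 1,
    latitude_deg: float = 41.0,
    radius_m: float = 1000.0,
) -> dict[str, GridRaster]:
    """Standard terrain covariate set keyed by conventional short names."""
    slope, aspect = slope_aspect(dem)
    stack: dict[str, GridRaster] = {
        "elev": dem,
        "slp": slope,
        "asp": aspect_transform(aspect),
        "scosa": scosa(slope, aspect),
        "hli": heat_load_index(slope, aspect, latitude_deg),
        "cti": wetness_index(dem),
        "tex3": focal_statistic(dem, WindowSpec(3, "variance")),
        "tex27": focal_statistic(dem, WindowSpec(27, "variance")),
        "srr27": focal_statistic(dem, WindowSpec(27, "relief_ratio")),
        "hsp": slope_position(dem, 15),
    }
    if landcover is not None:
        stack["pfor"] = focal_percent(landcover, forest_class, radius_m)
    return stack
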