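"""Build-out scenario simulation.

Turns a resource projection into development counts (wells, pads,
turbines), allocates new sites on the probability surface in ranked
order with exclusions and minimum spacing, and converts each site into
surface disturbance: an impervious pad footprint, a cleared-forest
ring, and per-watershed pipeline hectares.

The well/pad arithmetic uses floor division throughout: the projection
is exhausted by whole wells, existing pads absorb wells first at the
scenario density, and only the remainder spawns new pads.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import shapely

from .grids import GridRaster, PresenceSet, WatershedSet

__all__ = [
    "GasScenario",
    "WindScenario",
    "FootprintSpec",
    "gas_counts",
    "pipeline_area",
    "apply_exclusions",
    "allocate_sites",
    "apply_footprints",
]

KM_PER_MILE = 1.60934
#: hectares of pipeline right-of-way disturbance per mile at a 30.48 m ROW
HA_PER_MILE_ROW = 4.86


@dataclasses.dataclass(frozen=True)
class GasScenario:
    """Gas resource projection and pad-density assumptions.

    Defaults are a 141 trillion cu ft technically recoverable resource,
    1.15 billion cu ft estimated ultimate recovery per well, and 4151
    existing pads that absorb new wells first.
    """

    resource_cuft: float = 141e12
    eur_per_well_cuft: float = 1.15e9
    wells_per_pad: int = 4
    current_pads: int = 4151

    def __post_init__(self) -> None:
        if self.eur_per_well_cuft <= 0:
            raise ValueError("EUR must be positive")
        if self.resource_cuft <= 0 or self.current_pads < 0 or self.wells_per_pad < 1:
            raise ValueError("invalid scenario parameters")


@dataclasses.dataclass(frozen=True)
class WindScenario:
    """Wind build-out: turbine count and generation assumptions."""

    n_new_turbines: int = 10798
    nameplate_mw: float = 2.5
    capacity_factor: float = 0.52

    def __post_init__(self) -> None:
        if self.n_new_turbines < 0:
            raise ValueError("turbine count must be >= 0")
        if not 0.0 < self.capacity_factor <= 1.0:
            raise ValueError("capacity factor must be in (0, 1]")

    @property
    def expected_mw(self) -> float:
        return self.n_new_turbines * self.nameplate_mw * self.capacity_factor


@dataclasses.dataclass(frozen=True)
class FootprintSpec:
    """Per-unit surface disturbance, in hectares.

    ``impervious_ha`` becomes fully impervious (and deforested);
    ``cleared_forest_ha`` is the total cleared area, so any excess over
    the impervious core forms a cleared-but-pervious ring. Pipelines
    are charged per pad at the watershed level, not placed spatially.
    """

    impervious_ha: float = 1.2
    cleared_forest_ha: float = 3.0
    pipeline_km: float = 2.66
    pipeline_row_m: float = 30.48

    def __post_init__(self) -> None:
        fields = (self.impervious_ha, self.cleared_forest_ha, self.pipeline_km, self.pipeline_row_m)
        if any(v < 0 for v in fields):
            raise ValueError("footprint values must be >= 0")


def gas_counts(s: GasScenario) -> dict[str, int]:
    """Wells and pads needed to exhaust the resource.

    total wells = floor(resource / EUR); existing pads absorb
    ``current_pads x wells_per_pad`` wells first; the remainder fills
    new pads at the scenario density. All quantities floored at zero.
    """
    total_wells = int(s.resource_cuft // s.eur_per_well_cuft)
    absorbed = s.current_pads * s.wells_per_pad
    new_wells = max(total_wells - absorbed, 0)
    new_pads = new_wells // s.wells_per_pad
    return {
        "total_wells": total_wells,
        "new_wells": new_wells,
        "new_pads": int(new_pads),
    }


def pipeline_area(spec: FootprintSpec) -> dict[str, float]:
    """Pipeline right-of-way disturbance per pad, in hectares.

    Reports both the geometric area (length x width) and the
    conventional per-mile factor (4.86 ha per mile of 30.48 m ROW);
    the two differ slightly by rounding of the per-mile constant.
    """
    geometric = spec.pipeline_km * 1000.0 * spec.pipeline_row_m / 1e4
    per_mile = spec.pipeline_km / KM_PER_MILE * HA_PER_MILE_ROW
    return {"geometric_ha": geometric, "per_mile_factor_ha": per_mile}


def apply_exclusions(
    prob: GridRaster,
    features: dict[str, shapely.Geometry | list[shapely.Geometry]],
    buffers_m: dict[str, float] | None = None,
) -> GridRaster:
    """Zero probability inside (buffered) exclusion features.

    ``features`` maps layer names (protected areas, airports, streams,
    roads, ...) to shapely geometries; cells whose centers fall inside
    any buffered feature are recoded to exactly 0.
    """
    buffers_m = buffers_m or {}
    unknown = set(buffers_m) - set(features)
    if unknown:
        raise ValueError(f"buffers reference unknown layers: {sorted(unknown)}")
    gx, gy = prob.cell_centers()
    pts = shapely.points(gx.ravel(), gy.ravel())
    excluded = np.zeros(prob.n_cells, dtype=bool)
    for name, geoms in features.items():
        if not isinstance(geoms, (list, tuple)):
            geoms = [geoms]
        merged = shapely.union_all(
            [shapely.from_wkt(g) if isinstance(g, str) else g for g in geoms]
        )
        buf = buffers_m.get(name, 0.0)
        if buf > 0:
            merged = merged.buffer(buf)
        excluded |= shapely.intersects(merged, pts)
    out = prob.data.copy().ravel()
    out[excluded] = 0.0
    return prob.like(out.reshape(prob.shape))


def allocate_sites(
    prob: GridRaster, n: int, min_spacing_m: float = 0.0, seed: int = 0
) -> PresenceSet:
    """Place ``n`` sites by descending probability with spacing.

    Cells are visited from the highest probability down (ties shuffled
    by the seeded generator); a cell is accepted unless it lies within
    ``min_spacing_m`` of an already accepted site. Zero-probability
    (excluded) cells are never selected. Raises if the surface cannot
    host ``n`` sites.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    p = prob.data.ravel()
    eligible = np.flatnonzero(np.nan_to_num(p, nan=0.0) > 0)
    if len(eligible) == 0:
        raise ValueError("no cells with positive probability")
    rng = np.random.default_rng(seed)
    tiebreak = rng.random(len(eligible))
    order = eligible[np.lexsort((tiebreak, -p[eligible]))]

    rows, cols = prob.shape
    accepted_xy: list[tuple[float, float]] = []
    accepted_idx: list[int] = []
    for idx in order:
        r, c = divmod(int(idx), cols)
        x, y = prob.rowcol_to_xy(np.array(r), np.array(c))
        x, y = float(x), float(y)
        if min_spacing_m > 0 and accepted_xy:
            axy = np.asarray(accepted_xy)
            if np.min(np.hypot(axy[:, 0] - x, axy[:, 1] - y)) < min_spacing_m:
                continue
        accepted_xy.append((x, y))
        accepted_idx.append(int(idx))
        if len(accepted_xy) == n:
            break
    if len(accepted_xy) < n:
        raise ValueError(
            f"could only place {len(accepted_xy)} of {n} sites under the spacing constraint"
        )
    axy = np.asarray(accepted_xy)
    return PresenceSet.from_xy(axy[:, 0], axy[:, 1], probability=p[accepted_idx])


def _disk_mask(raster: GridRaster, x: float, y: float, radius_m: float) -> np.ndarray:
    gx, gy = raster.cell_centers()
    return np.hypot(gx - x, gy - y) <= radius_m


def apply_footprints(
    sites: PresenceSet,
    spec: FootprintSpec,
    impervious: GridRaster,
    forest_mask: GridRaster,
    watersheds: WatershedSet | None = None,
) -> tuple[GridRaster, GridRaster, np.ndarray]:
    """Burn site footprints into the impervious and forest rasters.

    Each site gets a circular impervious core of area ``impervious_ha``
    (cells set to fraction 1, forest cleared) and, if
    ``cleared_forest_ha`` exceeds the core, a concentric cleared ring
    where only forest is removed. Overlaps are not double counted (the
    burn is a cell-level max / clear). Pipeline disturbance is returned
    as hectares per watershed (pads in watershed x per-pad pipeline
    area, geometric variant) without spatial placement.
    """
    impervious.require_aligned(forest_mask, "forest_mask")
    imp = impervious.data.copy()
    forest = forest_mask.data.copy()
    core_r = np.sqrt(spec.impervious_ha * 1e4 / np.pi)
    total_r = np.sqrt(max(spec.cleared_forest_ha, spec.impervious_ha) * 1e4 / np.pi)
    if 0 < core_r < impervious.cell_size / 2:
        warnings.warn("footprint radius smaller than half a cell; burning single cells")
    for x, y in sites.xy:
        core = _disk_mask(impervious, x, y, max(core_r, 1e-9))
        if not core.any():  # tiny footprint: at least the host cell
            r, c = impervious.xy_to_rowcol(np.array(x), np.array(y))
            core = np.zeros_like(imp, dtype=bool)
            core[int(r), int(c)] = True
        imp[core] = 1.0
        forest[core] = 0.0
        if total_r > core_r:
            forest[_disk_mask(impervious, x, y, total_r)] = 0.0

    n_watersheds = watersheds.n_subwatersheds if watersheds is not None else 0
    pipeline_ha = np.zeros(n_watersheds)
    if watersheds is not None and len(sites):
        per_pad = pipeline_area(spec)["geometric_ha"]
        wid = watersheds.watershed_of_points(sites.xy)
        counts = np.bincount(wid, minlength=n_watersheds)
        pipeline_ha = counts * per_pad
    return impervious.like(imp), forest_mask.like(forest), pipeline_ha
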