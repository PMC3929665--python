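"""Synthetic study-area generator with known ground truth.

Builds a self-contained gridded landscape — terrain, smooth geologic
gradients sampled at sparse points, land cover with a calibrated forest
share, baseline impervious cover, a nested basin/subwatershed
tessellation with a water-importance index, and development presence
points drawn from a KNOWN logistic probability surface — so that every
downstream stage (kriging, background sampling, the iterative
classifier, scenario allocation, watershed impact classification) can
be tested against recoverable truth without any external data.

Everything is deterministic under ``(config, seed)``: each generator
stage draws from an independent stream spawned from the master seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.special import expit

from .grids import GridRaster, PresenceSet, WatershedSet

__all__ = [
    "LandscapeConfig",
    "SyntheticLandscape",
    "make_dem",
    "make_geology",
    "make_landcover_impervious",
    "make_watersheds",
    "make_presences",
    "generate",
]

FOREST, AGRICULTURE, DEVELOPED = 1, 2, 3

#: Default true coefficients of the development-probability surface:
#: development favors low, gentle, less-forested terrain and is rare
#: overall (negative intercept), as real build-out is — only a small
#: share of any landscape ever hosts a pad or turbine.
DEFAULT_COEFFICIENTS: dict[str, float] = {
    "intercept": -5.5,
    "elev": -3.2,
    "slp": -2.0,
    "pfor": -2.6,
}


@dataclasses.dataclass
class LandscapeConfig:
    """Knobs of the synthetic study area.

    Defaults mirror the desk-scale analysis frame: a 128x128 grid of
    30 m cells, 500 presence points per energy mode, 200 sparse geology
    samples, and a 70% forested landscape partitioned into 64
    subwatersheds nested in 4 basins.
    """

    extent_cells: tuple[int, int] = (128, 128)
    cell_size: float = 30.0
    seed: int = 20140219
    n_presence_gas: int = 500
    n_presence_wind: int = 500
    true_coefficients: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    n_geology_samples: int = 200
    n_subwatersheds: int = 64
    n_basins: int = 4
    forest_fraction_target: float = 0.70

    def __post_init__(self) -> None:
        if min(self.extent_cells) < 64:
            raise ValueError("extent must be at least 64x64 cells")
        counts = (
            self.n_presence_gas,
            self.n_presence_wind,
            self.n_geology_samples,
            self.n_subwatersheds,
            self.n_basins,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        if self.n_subwatersheds < self.n_basins:
            raise ValueError("need at least as many subwatersheds as basins")
        if not 0.0 <= self.forest_fraction_target <= 1.0:
            raise ValueError("forest_fraction_target must be in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one named stage."""
        return np.random.default_rng([self.seed, stream])

    def blank_grid(self) -> GridRaster:
        return GridRaster(np.zeros(self.extent_cells), self.cell_size)


def _smooth_field(
    rng: np.random.Generator, shape: tuple[int, int], scales: tuple[float, ...]
) -> np.ndarray:
    """Sum of Gaussian-smoothed white-noise fields, standardized.

    Each smoothing scale (in cells) contributes one spatial frequency
    band; summing 2-3 bands gives plausibly rough-but-correlated
    terrain and geology without spectral synthesis machinery.
    """
    field = np.zeros(shape)
    for s in scales:
        layer = ndimage.gaussian_filter(rng.standard_normal(shape), s)
        field += layer / max(layer.std(), 1e-12)
    return (field - field.mean()) / field.std()


def make_dem(config: LandscapeConfig) -> GridRaster:
    """Smooth synthetic elevation surface with ~400 m of relief."""
    rng = config.rng(1)
    z = _smooth_field(rng, config.extent_cells, scales=(4.0, 12.0, 32.0))
    dem = 500.0 + 80.0 * z
    return GridRaster(dem, config.cell_size)


def make_geology(
    config: LandscapeConfig, dem: GridRaster
) -> tuple[dict[str, GridRaster], pd.DataFrame]:
    """Smooth geologic surfaces plus sparse point samples of them.

    Returns shale depth (m), shale thickness (m) and thermal maturity
    (dimensionless vitrinite-reflectance-like index), each a broad
    regional gradient plus a long-wavelength random field, and a sample
    table (x, y, depth, thickness, tmaturity) drawn at distinct random
    cells — the input for kriging-recovery experiments.
    """
    rng = config.rng(2)
    shape = config.extent_cells
    if config.n_geology_samples > dem.n_cells:
        raise ValueError("more geology samples requested than grid cells")
    rows_i, cols_i = np.mgrid[0 : shape[0], 0 : shape[1]]
    east = cols_i / max(shape[1] - 1, 1)
    south = rows_i / max(shape[0] - 1, 1)

    depth = 1800.0 + 600.0 * east + 150.0 * _smooth_field(rng, shape, (16.0, 40.0))
    thickness = 45.0 + 25.0 * south + 8.0 * _smooth_field(rng, shape, (16.0, 40.0))
    maturity = 1.8 + 1.0 * (east + south) / 2 + 0.25 * _smooth_field(rng, shape, (16.0, 40.0))
    fields = {
        "depth": dem.like(depth),
        "thickness": dem.like(thickness),
        "tmaturity": dem.like(maturity),
    }

    idx = rng.choice(dem.n_cells, size=config.n_geology_samples, replace=False)
    row, col = np.unravel_index(idx, shape)
    x, y = dem.rowcol_to_xy(row, col)
    samples = pd.DataFrame(
        {
            "x": x,
            "y": y,
            "depth": depth[row, col],
            "thickness": thickness[row, col],
            "tmaturity": maturity[row, col],
        }
    )
    return fields, samples


def make_landcover_impervious(
    config: LandscapeConfig, dem: GridRaster
) -> tuple[GridRaster, GridRaster, GridRaster]:
    """Land-cover classes, baseline impervious fraction, forest mask.

    Forest occupies the cells with the highest values of a smooth
    suitability field, thresholded at the quantile that realizes
    ``forest_fraction_target``; the remainder splits into agriculture
    and a small developed class. Impervious fraction is positive only
    on developed cells.
    """
    rng = config.rng(3)
    shape = config.extent_cells
    suit = _smooth_field(rng, shape, (6.0, 20.0)) + 0.3 * (
        (dem.data - dem.data.mean()) / dem.data.std()
    )
    cut = np.quantile(suit, 1.0 - config.forest_fraction_target)
    forest = suit >= cut

    dev_field = _smooth_field(rng, shape, (4.0, 12.0))
    dev_field[forest] = -np.inf
    n_open = int((~forest).sum())
    n_dev = max(int(0.12 * n_open), 1)
    dev_cut = np.sort(dev_field[~forest])[-n_dev]
    developed = (dev_field >= dev_cut) & ~forest

    landcover = np.full(shape, AGRICULTURE, dtype=float)
    landcover[forest] = FOREST
    landcover[developed] = DEVELOPED

    impervious = np.zeros(shape)
    impervious[developed] = rng.uniform(0.3, 0.9, size=int(developed.sum()))
    return dem.like(landcover), dem.like(impervious), dem.like(forest.astype(float))


def make_watersheds(config: LandscapeConfig, dem: GridRaster) -> WatershedSet:
    """Nested watershed tessellation by seeded Voronoi growth.

    Subwatersheds are the Voronoi cells of random seed points on the
    grid (a clean space-filling partition — what the zonal statistics
    downstream require); each subwatershed belongs to the basin whose
    seed its own seed is nearest. The water-importance index is drawn
    from Beta(2, 2) and the first basin is forced high (>= 0.75) so
    high-value-watershed logic always has positive cases.
    """
    rng = config.rng(4)
    shape = config.extent_cells
    idx = rng.choice(dem.n_cells, size=config.n_subwatersheds, replace=False)
    srow, scol = np.unravel_index(idx, shape)
    sx, sy = dem.rowcol_to_xy(srow, scol)
    seeds = np.column_stack([sx, sy])

    gx, gy = dem.cell_centers()
    _, labels = cKDTree(seeds).query(np.column_stack([gx.ravel(), gy.ravel()]))
    label_grid = dem.like(labels.reshape(shape).astype(float))

    basin_seed_ids = rng.choice(config.n_subwatersheds, size=config.n_basins, replace=False)
    _, basin_of = cKDTree(seeds[basin_seed_ids]).query(seeds)

    importance = rng.beta(2.0, 2.0, size=config.n_subwatersheds)
    first_basin = basin_of == 0
    importance[first_basin] = np.maximum(
        importance[first_basin], rng.uniform(0.75, 1.0, size=int(first_basin.sum()))
    )
    table = pd.DataFrame(
        {
            "watershed_id": np.arange(config.n_subwatersheds),
            "basin_id": basin_of,
            "importance": importance,
            "seed_x": sx,
            "seed_y": sy,
        }
    )
    return WatershedSet(label_grid, table)


def make_presences(
    config: LandscapeConfig,
    covariates: dict[str, GridRaster],
    n: int | None = None,
    stream: int = 5,
) -> tuple[PresenceSet, GridRaster]:
    """Presence points from a known logistic probability surface.

    The true cellwise development probability is
    ``logistic(beta_0 + sum_j beta_j z_j)`` over the standardized
    covariates named in ``true_coefficients`` (the reserved name
    ``intercept`` supplies beta_0); ``n`` presence cells are drawn
    without replacement with weights proportional to that probability
    and placed at cell centers (pads do not stack).
    """
    coefs = dict(config.true_coefficients)
    intercept = coefs.pop("intercept", 0.0)
    missing = set(coefs) - set(covariates)
    if missing:
        raise ValueError(f"true_coefficients name unknown covariates: {sorted(missing)}")
    if n is None:
        n = config.n_presence_gas
    template = next(iter(covariates.values()))
    eta = np.full(template.shape, float(intercept))
    for name, beta in coefs.items():
        v = covariates[name].data
        sd = v.std()
        eta += beta * ((v - v.mean()) / sd if sd > 0 else 0.0)
    prob = expit(eta)
    true_prob = template.like(prob)

    w = prob.ravel()
    n_positive = int((w > 0).sum())
    if n > n_positive:
        raise ValueError(f"requested {n} presences but only {n_positive} cells have p > 0")
    rng = config.rng(stream)
    idx = rng.choice(template.n_cells, size=n, replace=False, p=w / w.sum())
    row, col = np.unravel_index(idx, template.shape)
    x, y = template.rowcol_to_xy(row, col)
    return PresenceSet.from_xy(x, y, true_probability=prob[row, col]), true_prob


@dataclasses.dataclass
class SyntheticLandscape:
    """Bundle of generated layers plus the ground truth."""

    config: LandscapeConfig
    dem: GridRaster
    covariates: dict[str, GridRaster]
    geology_fields: dict[str, GridRaster]
    geology_samples: pd.DataFrame
    landcover: GridRaster
    impervious: GridRaster
    forest_mask: GridRaster
    watersheds: WatershedSet
    presences_gas: PresenceSet
    presences_wind: PresenceSet
    true_probability: GridRaster


def generate(config: LandscapeConfig, noise_covariates: int = 0) -> SyntheticLandscape:
    """Run every generator stage and assemble the full landscape.

    ``noise_covariates`` appends that many spatially smooth but
    probability-irrelevant covariates (named noise1..noiseK) to the
    stack, for variable-selection recovery experiments.
    """
    from . import terrain  # local import to avoid cycle at module load

    dem = make_dem(config)
    landcover, impervious, forest_mask = make_landcover_impervious(config, dem)
    slope, aspect = terrain.slope_aspect(dem)
    covariates: dict[str, GridRaster] = {
        "elev": dem,
        "slp": slope,
        "asp": terrain.aspect_transform(aspect),
        "pfor": terrain.focal_percent(landcover, FOREST, 1000.0),
    }
    geology_fields, geology_samples = make_geology(config, dem)
    covariates.update(geology_fields)
    if noise_covariates:
        rng = config.rng(6)
        for k in range(noise_covariates):
            covariates[f"noise{k + 1}"] = dem.like(
                _smooth_field(rng, config.extent_cells, (8.0, 24.0))
            )
    watersheds = make_watersheds(config, dem)
    presences_gas, true_prob = make_presences(
        config, covariates, n=config.n_presence_gas, stream=5
    )
    presences_wind, _ = make_presences(
        config, covariates, n=config.n_presence_wind, stream=7
    )
    return SyntheticLandscape(
        config=config,
        dem=dem,
        covariates=covariates,
        geology_fields=geology_fields,
        geology_samples=geology_samples,
        landcover=landcover,
        impervious=impervious,
        forest_mask=forest_mask,
        watersheds=watersheds,
        presences_gas=presences_gas,
        presences_wind=presences_wind,
        true_probability=true_prob,
    )
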