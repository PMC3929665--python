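"""Ordinary kriging, Gaussian kernel density surfaces, and
inverse-density conditional background sampling.

Three geostatistical primitives back the pipeline:

* sparse geology samples (shale depth, thickness, thermal maturity) are
  interpolated to the analysis grid by ordinary kriging on a fitted
  semivariogram;
* known development locations yield an isotropic Gaussian kernel
  intensity surface, with the bandwidth chosen by leave-one-out
  cross-validation;
* pseudo-absence ("background") points for the presence-only classifier
  are drawn with sampling weights proportional to the *complement* of
  that intensity, so the null class is placed preferentially away from
  existing development.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist, pdist, squareform

from .grids import GridRaster, PresenceSet

__all__ = [
    "VariogramModel",
    "KDEConfig",
    "empirical_semivariogram",
    "fit_variogram",
    "ordinary_krige",
    "kriging_diagnostic",
    "kde_intensity",
    "select_sigma_cv",
    "background_sample",
]

VARIOGRAM_MODELS = ("spherical", "exponential", "gaussian")


@dataclasses.dataclass(frozen=True)
class VariogramModel:
    """Isotropic semivariogram: nugget + partial sill reached at range."""

    model: str
    nugget: float
    partial_sill: float
    range_: float

    def __post_init__(self) -> None:
        if self.model not in VARIOGRAM_MODELS:
            raise ValueError(f"model must be one of {VARIOGRAM_MODELS}")
        if self.nugget < 0 or self.partial_sill < 0 or self.range_ <= 0:
            raise ValueError("require nugget >= 0, partial_sill >= 0, range > 0")

    def __call__(self, h: np.ndarray) -> np.ndarray:
        """Semivariance gamma(h); gamma(0) = 0, jumping to the nugget."""
        h = np.asarray(h, dtype=float)
        r, c0, c1 = self.range_, self.nugget, self.partial_sill
        if self.model == "spherical":
            hr = np.minimum(h / r, 1.0)
            struct = 1.5 * hr - 0.5 * hr**3
        elif self.model == "exponential":
            struct = 1.0 - np.exp(-3.0 * h / r)
        else:  # gaussian
            struct = 1.0 - np.exp(-3.0 * (h / r) ** 2)
        return np.where(h > 0, c0 + c1 * struct, 0.0)


@dataclasses.dataclass(frozen=True)
class KDEConfig:
    """Gaussian kernel bandwidth (meters) and the evaluation grid."""

    sigma: float
    grid: GridRaster

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


# ---------------------------------------------------------------------
# Variography
# ---------------------------------------------------------------------

def empirical_semivariogram(
    points: np.ndarray, values: np.ndarray, n_lags: int = 15, max_dist: float | None = None
) -> pd.DataFrame:
    """Binned empirical semivariogram.

    For pairs (i, j) falling in lag bin k,
    ``gamma_k = sum (z_i - z_j)^2 / (2 N_k)``. Empty bins are dropped.

    Returns a DataFrame with columns distance (bin midpoint of pair
    distances), semivariance, and n_pairs.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(points) < 10:
        raise ValueError("need at least 10 points for a semivariogram")
    d = pdist(points)
    if np.all(d == 0):
        raise ValueError("all point coordinates are identical")
    if max_dist is None:
        max_dist = d.max()
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    sq = 0.5 * pdist(values[:, None], metric="sqeuclidean")
    edges = np.linspace(0.0, max_dist, n_lags + 1)
    which = np.digitize(d, edges[1:-1])
    keep = d <= max_dist
    rows = []
    for k in range(n_lags):
        m = keep & (which == k)
        n_pairs = int(m.sum())
        if n_pairs == 0:
            continue
        rows.append(
            {
                "distance": float(d[m].mean()),
                "semivariance": float(sq[m].mean()),
                "n_pairs": n_pairs,
            }
        )
    return pd.DataFrame(rows)


def fit_variogram(lag_table: pd.DataFrame, model: str = "spherical") -> VariogramModel:
    """Weighted least-squares fit of a variogram model to a lag table.

    Weights are ``n_pairs / distance^2``, emphasizing well-populated
    short lags where kriging weights are decided.
    """
    if len(lag_table) < 3:
        raise ValueError("need at least 3 nonempty lags to fit a variogram")
    h = lag_table["distance"].to_numpy(float)
    g = lag_table["semivariance"].to_numpy(float)
    w = np.sqrt(lag_table["n_pairs"].to_numpy(float)) / h
    sill0 = max(g.max(), 1e-12)
    x0 = np.array([0.1 * sill0, 0.9 * sill0, h.max() / 2])

    def residuals(p):
        vm = VariogramModel(model, max(p[0], 0.0), max(p[1], 0.0), max(p[2], 1e-9))
        return w * (vm(h) - g)

    sol = least_squares(
        residuals,
        x0,
        bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, 10 * h.max()]),
        method="trf",
    )
    if not sol.success:
        raise RuntimeError(f"variogram fit did not converge: {sol.message}")
    nugget, psill, rng = sol.x
    return VariogramModel(model, float(nugget), float(psill), float(rng))


# ---------------------------------------------------------------------
# Ordinary kriging
# ---------------------------------------------------------------------

def _ok_system(points: np.ndarray, vmodel: VariogramModel) -> np.ndarray:
    n = len(points)
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = vmodel(squareform(pdist(points)))
    a[n, :] = 1.0
    a[:, n] = 1.0
    a[n, n] = 0.0
    return a


def ordinary_krige(
    points: np.ndarray,
    values: np.ndarray,
    vmodel: VariogramModel,
    grid: GridRaster,
    on_duplicates: str = "mean",
) -> tuple[GridRaster, GridRaster]:
    """Ordinary kriging of point samples to every cell of ``grid``.

    Solves the standard unbiased system (weights summing to one through
    a Lagrange multiplier) in the semivariance formulation:

        [Gamma 1; 1' 0] [w; mu] = [gamma_0; 1]

    prediction = w'z, variance = w'gamma_0 + mu. With a zero nugget the
    predictor interpolates exactly: at a sample cell the prediction is
    the sample value and the variance is zero.

    Duplicate coordinates make the system singular; by default they are
    averaged with a warning (``on_duplicates="error"`` to reject).
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(points) < 2:
        raise ValueError("need at least 2 points to krige")
    uniq, inverse = np.unique(points, axis=0, return_inverse=True)
    if len(uniq) < len(points):
        if on_duplicates == "error":
            raise ValueError("duplicate sample coordinates")
        warnings.warn("duplicate sample coordinates averaged before kriging")
        agg = np.zeros(len(uniq))
        np.add.at(agg, inverse, values)
        counts = np.bincount(inverse, minlength=len(uniq))
        points, values = uniq, agg / counts
    n = len(points)
    a = _ok_system(points, vmodel)
    gx, gy = grid.cell_centers()
    targets = np.column_stack([gx.ravel(), gy.ravel()])
    gamma0 = vmodel(cdist(points, targets))  # (n, m)
    rhs = np.vstack([gamma0, np.ones(targets.shape[0])])
    sol = np.linalg.solve(a, rhs)
    weights, mu = sol[:n, :], sol[n, :]
    pred = weights.T @ values
    var = np.einsum("im,im->m", weights, gamma0) + mu
    var = np.maximum(var, 0.0)
    return grid.like(pred.reshape(grid.shape)), grid.like(var.reshape(grid.shape))


def kriging_diagnostic(
    prediction: GridRaster, kriging_variance: GridRaster
) -> tuple[bool, dict]:
    """Precision check used to vet interpolated geology surfaces.

    Passes when the root-mean kriging variance (typical prediction
    error) is smaller than the standard deviation of the predicted
    surface itself, i.e. the interpolation error is small relative to
    the spatial signal being mapped.
    """
    prediction.require_aligned(kriging_variance, "kriging_variance")
    rm_kv = float(np.sqrt(np.nanmean(kriging_variance.data)))
    sd_pred = float(np.nanstd(prediction.data))
    passed = rm_kv < sd_pred
    return passed, {
        "root_mean_kriging_variance": rm_kv,
        "prediction_sd": sd_pred,
        "passed": passed,
    }


# ---------------------------------------------------------------------
# Kernel intensity and background sampling
# ---------------------------------------------------------------------

def kde_intensity(points: np.ndarray | PresenceSet, config: KDEConfig) -> GridRaster:
    """Isotropic Gaussian kernel intensity surface.

    lambda(u) = sum_i (2 pi sigma^2)^-1 exp(-|u - s_i|^2 / 2 sigma^2),
    evaluated at cell centers; integrates to the point count (up to
    edge truncation).
    """
    if isinstance(points, PresenceSet):
        points = points.xy
    points = np.asarray(points, dtype=float)
    if len(points) < 1:
        raise ValueError("need at least one point")
    grid = config.grid
    gx, gy = grid.cell_centers()
    targets = np.column_stack([gx.ravel(), gy.ravel()])
    s2 = config.sigma**2
    norm = 1.0 / (2.0 * np.pi * s2)
    lam = np.zeros(targets.shape[0])
    # chunk over points to bound the distance-matrix memory
    for start in range(0, len(points), 256):
        chunk = points[start : start + 256]
        d2 = cdist(chunk, targets, metric="sqeuclidean")
        lam += norm * np.exp(-d2 / (2.0 * s2)).sum(axis=0)
    return grid.like(lam.reshape(grid.shape))


def select_sigma_cv(
    points: np.ndarray | PresenceSet, candidate_sigmas: np.ndarray
) -> float:
    """Bandwidth selection by leave-one-out log-likelihood.

    For each candidate sigma, scores sum_i log lambda_{-i}(s_i) where
    lambda_{-i} omits point i's own kernel; returns the maximizer
    (ties go to the smallest sigma). If every candidate leaves some
    point with zero leave-one-out density the grid is too narrow.
    """
    if isinstance(points, PresenceSet):
        points = points.xy
    points = np.asarray(points, dtype=float)
    candidate_sigmas = np.sort(np.asarray(candidate_sigmas, dtype=float))
    if len(points) < 10:
        raise ValueError("need at least 10 points for cross-validation")
    if len(candidate_sigmas) == 1:
        return float(candidate_sigmas[0])
    d2 = squareform(pdist(points, metric="sqeuclidean"))
    np.fill_diagonal(d2, np.inf)  # exclude self-kernel
    best_sigma, best_ll = None, -np.inf
    for sigma in candidate_sigmas:
        s2 = sigma**2
        lam = (1.0 / (2.0 * np.pi * s2)) * np.exp(-d2 / (2.0 * s2)).sum(axis=1)
        if np.any(lam <= 0):
            continue
        ll = float(np.log(lam).sum())
        if ll > best_ll:  # strict: ties keep the smaller sigma
            best_sigma, best_ll = float(sigma), ll
    if best_sigma is None:
        raise ValueError(
            "all candidate bandwidths give zero leave-one-out density; widen the grid"
        )
    return best_sigma


def background_weights(
    kde: GridRaster, mode: str = "complement", exclusion_mask: np.ndarray | None = None
) -> np.ndarray:
    """Normalized pseudo-absence sampling weights from a KDE surface.

    ``complement`` (default) uses max(lambda) - lambda, bounded and zero
    at intensity peaks; ``reciprocal`` uses 1 / lambda. Cells under the
    exclusion mask get weight zero.
    """
    lam = kde.data.ravel()
    if np.any(lam < 0):
        raise ValueError("kde must be nonnegative")
    if mode == "complement":
        w = lam.max() - lam
    elif mode == "reciprocal":
        with np.errstate(divide="ignore"):
            w = np.where(lam > 0, 1.0 / lam, 0.0)
    else:
        raise ValueError("mode must be 'complement' or 'reciprocal'")
    if exclusion_mask is not None:
        w = np.where(np.asarray(exclusion_mask).ravel(), 0.0, w)
    total = w.sum()
    if total <= 0:
        raise ValueError("no cells with positive background weight")
    return w / total


def background_sample(
    kde: GridRaster,
    n: int,
    seed: int,
    exclusion_mask: np.ndarray | None = None,
    mode: str = "complement",
) -> PresenceSet:
    """Draw ``n`` pseudo-absence cells without replacement.

    Cells are drawn with probability proportional to the inverse-KDE
    weight (see :func:`background_weights`) and returned as points at
    cell centers; deterministic under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    w = background_weights(kde, mode=mode, exclusion_mask=exclusion_mask)
    n_eligible = int((w > 0).sum())
    if n > n_eligible:
        raise ValueError(f"requested {n} draws but only {n_eligible} cells have positive weight")
    rng = np.random.default_rng(seed)
    idx = rng.choice(kde.n_cells, size=n, replace=False, p=w)
    row, col = np.unravel_index(idx, kde.shape)
    x, y = kde.rowcol_to_xy(row, col)
    return PresenceSet.from_xy(x, y)
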