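"""Watershed-level impact assessment.

Zonal summaries of impervious and forest fractions over the
subwatershed partition, Impervious Cover Model (ICM) classification
(Sensitive / Impacted / Nonsupporting / Urban drainage), scenario
change tables, drinking-water vulnerability flags, and basin rollups.

The ICM relates watershed percent impervious cover to expected stream
condition; it is used here as a screening classification, not a
site-level water-quality prediction.
"""

from __future__ import annotations

import enum

import numpy as np
import pandas as pd

from .grids import GridRaster, PresenceSet, WatershedSet

__all__ = [
    "ICMClass",
    "zonal_percent",
    "icm_classify",
    "watershed_impacts",
    "change_summary",
    "high_value_flags",
    "footprint_by_value_class",
    "basin_rollup",
]


class ICMClass(enum.IntEnum):
    """Ordered stream-condition classes of the Impervious Cover Model."""

    Sensitive = 0
    Impacted = 1
    Nonsupporting = 2
    UrbanDrainage = 3


#: Lower-bound-inclusive percent-impervious thresholds of the ICM.
ICM_THRESHOLDS = (10.0, 25.0, 60.0)


def zonal_percent(
    fraction_raster: GridRaster,
    watersheds: WatershedSet,
    pipeline_ha: np.ndarray | None = None,
) -> np.ndarray:
    """Area-weighted percent cover per subwatershed.

    pct = 100 x (sum of cell fractions x cell area + pipeline area) /
    watershed area. Pipeline hectares, when given, are counted as fully
    impervious area within their watershed. Watersheds with no cells
    are reported as NaN (never silently dropped).
    """
    data = fraction_raster.data
    if np.nanmin(data) < 0 or np.nanmax(data) > 1:
        raise ValueError("fraction raster must lie in [0, 1]")
    labels = watersheds.labels.data.astype(int).ravel()
    n = watersheds.n_subwatersheds
    frac_area = np.bincount(
        labels, weights=np.nan_to_num(data).ravel(), minlength=n
    ) * fraction_raster.cell_area
    counts = np.bincount(labels, minlength=n)
    if pipeline_ha is not None:
        frac_area = frac_area + np.asarray(pipeline_ha, float) * 1e4
    area = counts * fraction_raster.cell_area
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * frac_area / area
    return np.where(counts > 0, pct, np.nan)


def icm_classify(pct_impervious: float | np.ndarray) -> np.ndarray | ICMClass:
    """ICM class from percent impervious (lower bounds inclusive):
    [0,10) Sensitive, [10,25) Impacted, [25,60) Nonsupporting,
    [60,100] Urban drainage."""
    pct = np.asarray(pct_impervious, dtype=float)
    if np.any((pct < 0) | (pct > 100)):
        raise ValueError("percent impervious must be in [0, 100]")
    cls = np.digitize(pct, ICM_THRESHOLDS, right=False)
    if cls.ndim == 0:
        return ICMClass(int(cls))
    return cls


def watershed_impacts(
    impervious: GridRaster,
    forest_mask: GridRaster,
    watersheds: WatershedSet,
    pipeline_ha: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-subwatershed impact table: percent impervious (with optional
    pipeline surcharge), percent forest, ICM class, importance."""
    pct_imp = np.minimum(zonal_percent(impervious, watersheds, pipeline_ha), 100.0)
    pct_for = zonal_percent(forest_mask, watersheds)
    out = watersheds.table[["watershed_id", "basin_id", "importance", "area_ha"]].copy()
    out["pct_impervious"] = pct_imp
    out["pct_forest"] = pct_for
    out["icm"] = [ICMClass(int(c)).name for c in np.asarray(icm_classify(pct_imp))]
    return out


def change_summary(before: pd.DataFrame, after: pd.DataFrame) -> pd.DataFrame:
    """Per-ICM-class counts before/after a scenario and their change.

    Percent change is (after - before) / before x 100, reported as NA
    when the class was empty before.
    """
    b = before.sort_values("watershed_id").reset_index(drop=True)
    a = after.sort_values("watershed_id").reset_index(drop=True)
    if not (b["watershed_id"].to_numpy() == a["watershed_id"].to_numpy()).all():
        raise ValueError("before/after watershed ids do not match")
    rows = []
    n_total = len(b)
    for cls in ICMClass:
        nb = int((b["icm"] == cls.name).sum())
        na = int((a["icm"] == cls.name).sum())
        rows.append(
            {
                "icm": cls.name,
                "n_before": nb,
                "n_after": na,
                "pct_of_total_before": 100.0 * nb / n_total,
                "pct_of_total_after": 100.0 * na / n_total,
                "count_change": na - nb,
                "pct_change": (100.0 * (na - nb) / nb) if nb > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def high_value_flags(
    impacts: pd.DataFrame,
    rimp_threshold: float = 0.75,
    forest_threshold: float = 0.75,
) -> np.ndarray:
    """Watershed ids with both high water importance and high forest.

    Flags watersheds whose importance index and forest *fraction* both
    meet their thresholds (inclusive) — forested drinking-water source
    areas most vulnerable to build-out.
    """
    imp_ok = impacts["importance"].to_numpy() >= rimp_threshold
    forest_ok = impacts["pct_forest"].to_numpy() / 100.0 >= forest_threshold
    return impacts.loc[imp_ok & forest_ok, "watershed_id"].to_numpy()


def footprint_by_value_class(
    sites: PresenceSet,
    watersheds: WatershedSet,
    impacts: pd.DataFrame,
    site_footprint_ha: float = 1.0,
) -> pd.Series:
    """Share of new footprint area falling in each value quartile.

    Watersheds are ranked by the average of their importance rank and
    forest-fraction rank and cut into quartiles (q4 = most intact /
    most important). Each site contributes its footprint area to the
    quartile of its host watershed; shares sum to 1.
    """
    t = impacts.sort_values("watershed_id").reset_index(drop=True)
    score = (
        t["importance"].rank(pct=True) + t["pct_forest"].rank(pct=True)
    ) / 2.0
    quartile = np.minimum((score.rank(pct=True) * 4).apply(np.ceil).astype(int), 4)
    q_of_wid = dict(zip(t["watershed_id"], quartile))
    wid = watersheds.watershed_of_points(sites.xy)
    shares = pd.Series(0.0, index=[1, 2, 3, 4], name="footprint_share")
    for w in wid:
        shares[q_of_wid[int(w)]] += site_footprint_ha
    total = shares.sum()
    if total > 0:
        shares /= total
    return shares


def basin_rollup(impacts: pd.DataFrame, value_cols: list[str] | None = None) -> pd.DataFrame:
    """Aggregate subwatershed impact layers to basins.

    Hectare columns are summed per basin; each impact layer stays
    separate (increments are not accumulated across layers). The grand
    total over basins equals the study-area total by construction.
    """
    if impacts["basin_id"].isna().any():
        raise ValueError("every subwatershed must map to a basin")
    if value_cols is None:
        value_cols = [c for c in impacts.columns if c.endswith("_ha")]
    rolled = impacts.groupby("basin_id", as_index=False)[value_cols].sum()
    rolled["n_subwatersheds"] = impacts.groupby("basin_id").size().to_numpy()
    return rolled
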