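# Methods

This note documents the models and procedures energyscape implements,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data tests do and do not demonstrate.

## Spatial frame

All layers live on a single projected equal-area grid of square cells
(default 30 m, the resolution of the national elevation and land-cover
products this kind of analysis consumes). `GridRaster` carries the
array, cell size and lower-left origin; row 0 is the northern edge.
There is no CRS machinery: one consistent planar frame is assumed, and
alignment (same shape, cell size, origin) is enforced wherever two
rasters are combined. Rasters serialize as ESRI ASCII grids, points as
CSV/GeoJSON, and watershed zones as a label grid plus attribute table —
the partition (which cell belongs to which subwatershed) is the only
geometric fact the zonal statistics need, so polygon geometry is never
reconstructed.

## Synthetic landscape generator

The generator builds a study area in which every downstream claim is
checkable against known truth. What it emulates, and how:

- **Terrain** — sums of Gaussian-smoothed white noise at three scales
  (4, 12, 32 cells), standardized and scaled to ~80 m standard
  deviation around a 500 m base. This gives spatially correlated,
  differentiable relief without spectral-synthesis machinery; it makes
  no claim to fluvial realism.
- **Geology** (shale depth, thickness, thermal maturity) — broad
  regional gradients plus long-wavelength random fields (smoothing at
  16 and 40 cells), sampled at `n_geology_samples` random cells. The
  smoothness is deliberate: the real surfaces are interpolated from
  sparse boreholes, which is only defensible when the field varies
  slowly, and the kriging-recovery test (correlation ≥ 0.9 from 200
  samples on a 128×128 grid) quantifies exactly that regime.
- **Land cover** — forest occupies the top quantile of a smooth
  suitability field, thresholded to hit `forest_fraction_target`
  (default 0.70, the reference landscape's share); the open remainder
  splits into agriculture and ~12% developed cells, and baseline
  impervious fraction is positive only on developed cells.
- **Watersheds** — seeded Voronoi growth: subwatersheds are the
  nearest-seed partitions of random seed cells, each assigned to the
  basin of its nearest basin seed. This is a tessellation, not a
  hydrologic delineation; the downstream stages need the partition
  property (every cell in exactly one subwatershed), not drainage
  topology. The water-importance index is Beta(2, 2) per subwatershed,
  with one basin forced ≥ 0.75 so high-value-watershed logic always has
  positive cases.
- **Presences** — the true development probability is
  logistic(β₀ + Σ βⱼ zⱼ) over standardized covariates; presence cells
  are drawn without replacement with weights proportional to it, one
  per cell (pads do not stack).

Default coefficients are intercept −5.5, elevation −3.2, slope −2.0,
percent forest −2.6. Development in this truth is rare (mean cell
probability ~0.15) and strongly terrain-driven: low, gentle, open
ground is favored. Both properties are essential to realism — in any
real energy landscape only a small fraction of cells ever hosts
infrastructure, and siting is highly predictable from covariates. A
truth surface without the rare-event intercept would make half the
landscape "probable" and cap every classifier's attainable
discrimination near AUC 0.75 regardless of skill, which is a statement
about the toy, not the method.

Determinism: every stage draws from `default_rng([seed, stage_index])`,
so identical config + seed is bit-identical, and changing the seed
changes all layers.

What passing tests on this generator do **not** show: robustness to
covariate measurement error, spatial sampling bias in the presence
record (the generator samples from the true probability itself),
non-stationary siting preferences, or hydrologically meaningful
watershed boundaries. Results on real data depend on all four.

## Terrain covariates

Slope and aspect use Horn's 3×3 weighted finite differences — the
default of the standard GIS toolboxes — with edges replicated, so edge
cells are defined but their gradients are attenuated; analytic tests
therefore assert on interior cells. Flat cells carry NaN aspect as an
explicit flag, and every aspect transform maps the flag to 0.

- ASP (northness) = cos(aspect); SCOSA = slope × cos(aspect).
- TEX (variance), SRR (relief ratio, (mean−min)/(max−min), 0 on
  constant windows) and focal mean use square windows of 3/15/27 cells;
  HSP (slope position) is elevation minus the focal mean. Windows
  shrink at edges rather than emitting nodata, so covariate stacks stay
  gap-free for the classifier.
- HLI follows McCune–Keon (2002): aspect folded about the SW–NE axis,
  A = |180 − |aspect − 225||, then
  HL = 0.339 + 0.808 cos(lat)cos(s) − 0.196 sin(lat)sin(s)
  − 0.482 cos(A) sin(s). Southwest slopes (A = 180, cos A = −1) score
  hottest; valid for slopes ≲ 60° at latitudes 0–60°.
- CTI = ln(a / tan β) with D8 flow accumulation (a = contributing cells
  × cell area, slope floored at 0.001 rad). Cells are settled in
  descending elevation order; pits and flats simply retain their
  accumulation — no breaching or filling beyond the slope floor, which
  is adequate on the smooth synthetic terrain but would need pit
  removal on real DEMs.
- Focal class percentages (percent forest / agriculture / developed
  within 1 km) use a circular kernel with edge-shrunk denominators.

## Geostatistics

**Variography and kriging.** The empirical semivariogram bins
γ̂ₖ = Σ(zᵢ−zⱼ)²/2Nₖ over distance lags; spherical, exponential and
Gaussian models are fitted by least squares with weights
√(pairs)/distance (the fitting criterion is not prescribed by any
standard, so the conventional count/short-lag weighting was chosen and
is visible in one function). Ordinary kriging solves the unit-sum
system in semivariance form per cell, factorizing the data matrix once
and solving all cells as one right-hand-side block; with a zero nugget
it interpolates exactly (prediction = value, variance = 0 at samples).
Duplicate coordinates are averaged with a warning by default because
they make the system singular. The surface-quality diagnostic passes
when √(mean kriging variance) < sd(predictions) — the typical
interpolation error must be smaller than the spatial signal being
mapped; the inequality is deliberately stated in comparable units
(both standard deviations) since "variance smaller than one standard
deviation" is dimensionally ambiguous.

**Kernel intensity and background weights.** λ(u) =
Σᵢ (2πσ²)⁻¹ exp(−d²ᵢ/2σ²), unnormalized and without edge correction (at
30 m cells the interior dominates). Bandwidth is selected by maximizing
the leave-one-out log-likelihood Σᵢ log λ₋ᵢ(sᵢ) over a candidate grid,
ties to the smallest σ. Note a consequence of the LOO criterion:
coincident duplicate points drag the selection toward the smallest
candidate (each point's twin contributes the kernel peak), so the
presence record should be deduplicated — which the one-per-cell
convention upstream guarantees.

"Inverse" of the intensity for background sampling is the bounded
complement w = max λ − λ: zero (not infinite) weight at presence
hotspots, positive elsewhere, which matches the intent of placing the
null class away from development. The unbounded alternative 1/λ is
available behind `mode="reciprocal"`. Draws are without replacement at
cell centers — duplicate training rows cannot occur — and an exclusion
mask zeroes cells before normalization.

## Ensemble model

Each iteration is balanced by construction (|background| = |presences|)
and fits a 500-tree Random Forest (scikit-learn, default mtry);
zero-variance covariates are dropped with a warning. Pooling is the
arithmetic mean of per-presence probabilities across iterations, which
for equal tree counts equals pooling all trees into one forest and is
order-invariant. Convergence compares the pooled distribution after
iteration t with the pooled distribution after t−1 by two-sample KS at
α = 0.001 — "converged" means *not significantly different*. The
pooled-vs-pooled comparison (rather than new-iteration-vs-pool) is the
only variant that can converge at all: a single fresh iteration always
differs from the pool by sampling noise of constant size, whereas the
pooled sequence is Cauchy in t. Minimum 2 iterations (KS needs two
distributions), maximum 100, per-iteration seeds are master seed +
iteration index. Non-convergence at the cap returns the state with an
explicit flag rather than raising.

MIR selection: permutation importance (5 repeats) from a pilot fit,
scaled by the maximum; thresholds 0.05–0.95 in steps of 0.1; each
retained subset is refitted with out-of-bag scoring on the same
training rows and the subset with minimum OOB error wins, ties to the
smaller subset.

Validation metrics: AUC is the rank-based Mann–Whitney form (ties
half-counted), implemented directly and cross-checked against
scikit-learn in the tests. "Sensitivity-weighted kappa" has no
citation-free standard definition; here it is Cohen's κ evaluated at
the threshold maximizing κ × sensitivity over the observed
probabilities — an interpretation, isolated in one function so an
alternative can be swapped in. Holdout evaluation treats 20% of
presences as positives against 1000 random cells as negatives, the
standard presence-only compromise (some "negatives" are truly
developable, which biases AUC downward slightly).

## Scenarios and footprints

Well/pad arithmetic is floor division throughout; this exactly
reproduces the reference projection's printed counts (122,608 total
wells; 106,004 new; 26,501 pads at 4 wells/pad; 11,175 at 8). The
published per-pad pipeline disturbance can be recomputed two ways —
geometric length × width (2.66 km × 30.48 m = 8.108 ha) or via the
rounded per-mile factor (4.86 ha/mile → 8.033 ha) — and the two differ
below the percent level; `pipeline_area` reports both rather than
adopting either silently.

Allocation visits cells in strictly descending probability with
seeded-random tie-breaks, skipping cells within `min_spacing_m` of an
accepted site (default intent: one footprint diameter, so pads cannot
overlap physically) and never selecting zero-probability (excluded)
cells; a shortfall raises rather than returning a partial set.
Footprints are circular: an impervious core of `impervious_ha` (cells
set to fraction 1, forest cleared) and, when `cleared_forest_ha`
exceeds the core, a concentric ring clearing forest only. Burns are
cell-level max/clear, so overlapping footprints are not double-counted
and reapplication is idempotent. Pipelines are charged per pad to the
host watershed without spatial placement — their routes are not
modeled, only their area. The default pad footprints (1.2 ha
impervious, 3.0 ha cleared) are config values of pad-scale magnitude,
clearly replaceable by survey-based measurements when available.

## Watershed impacts

Percent impervious is area-weighted from the fractional raster (not
binarized), plus the pipeline hectares counted as fully impervious —
the conservative reading of "summed disturbance" — and capped at 100.
ICM classes use lower-bound-inclusive breaks at 10/25/60 percent;
10.0 is Impacted, 25.0 Nonsupporting, 60.0 Urban drainage.
Change summaries report per-class counts, shares and percent change,
with NA (not infinity) when a class was empty before. Vulnerability
flags require water-importance index ≥ 0.75 AND forest fraction ≥ 0.75,
both inclusive. Footprint-by-value-quartile ranks watersheds by the
mean of their importance and forest-fraction percentile ranks; each
site contributes its footprint area to its host watershed's quartile.
Basin rollups sum member-subwatershed hectares per impact layer,
keeping layers separate (baseline, current and scenario increments are
not accumulated).

## Numerical and degenerate-input conventions

- Flat terrain: aspect NaN-flagged; transforms return 0; CTI slope
  floor 0.001 rad.
- Relief ratio on constant windows: 0 (not NaN).
- Variogram γ(0) = 0 exactly, jumping to the nugget for h > 0.
- Kriging variances clipped at 0 against roundoff.
- KS with identical samples: D = 0 forced to p = 1.
- Allocation ties: seeded uniform secondary sort key.
- Sub-cell footprints: warned, burned as the single host cell.
- Watersheds with zero cells: reported NaN, never dropped silently.

## Problem sizes

The reference configuration — 128×128 cells, 500 presences, 200
geology samples, 64 subwatersheds in 4 basins, 500 trees per iteration
— is the package's standard desk-scale experiment: large enough that
kriging recovery, background-frequency and surface-recovery statistics
are stable, small enough that the full pipeline (generation through
impact tables) completes in seconds and the complete test suite in
about two minutes on one CPU. The MIR recovery experiment uses 250
trees per refit across its 5 replicate seeds, where the OOB ranking is
already stable.

## Known limitations

- One planar frame; no CRS transforms, no real-data readers beyond
  ASCII grid / CSV / GeoJSON points.
- D8/CTI without pit filling; unsuitable for raw real-world DEMs.
- Isotropic variograms and KDE only; no co-kriging, no edge-corrected
  intensity.
- The ensemble's pseudo-absence scheme assumes the presence record is
  a reasonably complete census of development within the frame;
  strongly biased records would bias the complement weights.
- Pipeline impacts are areal surcharges, not routed corridors; turbine
  scenarios take the turbine count as an input rather than deriving it
  from electricity-market modeling.
- Percent-change on empty baseline classes is NA; downstream consumers
  must handle it.
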