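# energyscape

Cumulative-impact analysis of energy build-out on gridded landscapes:
presence-only development-probability surfaces for shale-gas pads and
wind turbines, resource-driven build-out scenarios, and watershed-level
impervious-cover and forest-loss assessment.

The package is aimed at landscape ecologists and conservation planners
who need to ask: *given where energy infrastructure already is, where
is it likely to go next, and what will that do to the watersheds people
drink from?* Every stage runs on a self-contained synthetic landscape
with known ground truth, so the full pipeline is testable end to end
without any proprietary GIS layers.

## The model

**Development probability.** Known infrastructure locations are a fixed
positive class. At each iteration *t*, an equal-size pseudo-absence set
is drawn from grid cells with sampling weights from the *complement* of
a Gaussian kernel intensity surface λ(u) over the presences
(w ∝ max λ − λ, so the null class is placed away from existing
development; the bandwidth σ is chosen by leave-one-out
cross-validation). A Random Forest is fitted to presence (y = 1)
vs. background (y = 0) and its class-1 probabilities p̂ᵗ are predicted
back to the presence points. Iterations are pooled by averaging,
p̄ᵀ = T⁻¹ Σₜ p̂ᵗ, and iteration stops when a two-sample
Kolmogorov–Smirnov test can no longer distinguish successive pooled
distributions (p ≥ α, default α = 0.001). The pooled forest is then
predicted to the covariate rasters, giving a probability surface.
Covariate selection uses the model improvement ratio
MIRⱼ = importanceⱼ / maxₖ importanceₖ: subsets formed by thresholding
MIR are refitted and the one minimizing out-of-bag error is retained.

**Build-out scenarios.** A resource projection is converted to counts
with floor arithmetic — total wells = ⌊resource / EUR⌋, existing pads
absorb wells first at the scenario density, the remainder spawns new
pads. New sites are placed on the probability surface in ranked order
(exclusion features recoded to zero, seeded tie-breaks, minimum
spacing), and each site burns a circular impervious footprint plus a
cleared-forest ring into the land-cover rasters; pipeline disturbance
is charged per pad at the watershed level.

**Watershed impacts.** Subwatersheds get area-weighted percent
impervious and percent forest, and an Impervious Cover Model class —
Sensitive [0, 10), Impacted [10, 25), Nonsupporting [25, 60),
Urban drainage [60, 100] percent impervious — before and after the
scenario, plus drinking-water vulnerability flags (water-importance
index and forest fraction both ≥ 0.75) and basin rollups.

Sparse geology samples (shale depth, thickness, thermal maturity) are
interpolated to the grid by ordinary kriging on a weighted-least-squares
variogram fit, with a diagnostic requiring the root-mean kriging
variance to be smaller than the spread of the predicted surface.

## Worked example

```python
import energyscape as es
from energyscape import ensemble, geostats, scenario

# the published gas projection: 141 Tcf, 1.15 Bcf/well, 4151 pads
print(scenario.gas_counts(scenario.GasScenario(141e12, 1.15e9,
                                               wells_per_pad=4,
                                               current_pads=4151)))

# synthetic 128x128 study area with a known probability surface
config = es.LandscapeConfig(seed=42)
land = es.generate(config)
sigma = geostats.select_sigma_cv(land.presences_gas, [250, 500, 1000, 2000])
kde = geostats.kde_intensity(land.presences_gas,
                             geostats.KDEConfig(sigma, land.dem))
state = ensemble.run_until_convergence(land.presences_gas,
                                       land.covariates, kde, seed=42)
prob = ensemble.predict_raster(state, land.covariates)

from scipy.stats import spearmanr
rho = spearmanr(prob.data.ravel(), land.true_probability.data.ravel()).statistic
print(f"sigma={sigma:.0f} m, iterations={state.n_iterations}, "
      f"converged={state.converged}")
print(f"Spearman rho vs known probability surface: {rho:.3f}")
```

prints

```
{'total_wells': 122608, 'new_wells': 106004, 'new_pads': 26501}
sigma=250 m, iterations=2, converged=True
Spearman rho vs known probability surface: 0.911
```

i.e. the projection needs 122,608 wells in total, of which 106,004 are
new and fill 26,501 new pads at 4 wells per pad; the ensemble converged
under the KS rule after two iterations and its surface rank-correlates
at ρ = 0.91 with the generator's true probability. Allocating 40 pads
on that surface and reassessing the watersheds:

```
          icm  n_before  n_after  count_change  pct_change
    Sensitive        58       40           -18  -31.034483
     Impacted         3        1            -2  -66.666667
Nonsupporting         3        7             4  133.333333
UrbanDrainage        0        16            16         NaN
```

— pads plus their per-watershed pipeline surcharge push 20 of 64
subwatersheds into the two degraded condition classes (NA marks a
class that was empty before development).

The same chain runs from the shell:

```sh
energyscape run --seed 42 --outdir run/
```

which writes every layer, table and a provenance manifest
(`manifest.csv` with per-file checksums); a rerun with the same seed is
bit-identical. Individual stages are available as subcommands
(`simulate-landscape`, `covariates`, `krige`, `fit`, `predict`,
`scenario`, `impact`, `report`), all configurable via `--config
config.yaml`.

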