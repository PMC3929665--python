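import numpy as np
import pytest
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_auc_score

from energyscape import ensemble, geostats
from energyscape.ensemble import ConvergenceConfig, EnsembleState
from energyscape.grids import GridRaster, PresenceSet


def toy_problem(n=30, cell=10.0, seed=0):
    """Separable toy: presences on the east half where x-covariate = 1."""
    g = GridRaster(np.zeros((20, 20)), cell_size=cell)
    gx, gy = g.cell_centers()
    xcov = g.like((gx > gx.mean()).astype(float))
    rng = np.random.default_rng(seed)
    east = np.argwhere(xcov.data == 1)
    pick = east[rng.choice(len(east), n, replace=False)]
    x, y = g.rowcol_to_xy(pick[:, 0], pick[:, 1])
    pres = PresenceSet.from_xy(x, y)
    kde = geostats.kde_intensity(pres, geostats.KDEConfig(30.0, g))
    return pres, {"x": xcov, "noise": g.like(rng.normal(size=g.shape))}, kde


class TestFitIteration:
    def test_training_set_balanced(self):
        pres, covs, kde = toy_problem()
        it = ensemble.fit_iteration(pres, covs, kde, seed=1, n_trees=100)
        assert it.y_train.sum() == len(pres)
        assert (it.y_train == 0).sum() == len(pres)

    def test_separable_toy_high_training_probabilities(self):
        # presences fill the entire east half and the east half is
        # excluded from background sampling, so background sits at x=0
        # and the x covariate separates the classes perfectly
        g = GridRaster(np.zeros((20, 20)), cell_size=10.0)
        gx, gy = g.cell_centers()
        xcov = g.like((gx > gx.mean()).astype(float))
        east = np.argwhere(xcov.data == 1)
        x, y = g.rowcol_to_xy(east[:, 0], east[:, 1])
        pres = PresenceSet.from_xy(x, y)
        kde = geostats.kde_intensity(pres, geostats.KDEConfig(30.0, g))
        it = ensemble.fit_iteration(
            pres, {"x": xcov}, kde, seed=1, n_trees=100,
            exclusion_mask=xcov.data == 1,
        )
        assert np.all(it.X_train[it.y_train == 0] == 0.0)  # background at x=0
        assert np.all(it.training_probabilities > 0.9)

    def test_different_seeds_different_backgrounds(self):
        pres, covs, kde = toy_problem()
        a = ensemble.fit_iteration(pres, covs, kde, seed=1, n_trees=20)
        b = ensemble.fit_iteration(pres, covs, kde, seed=2, n_trees=20)
        assert np.any(a.X_train[len(pres):] != b.X_train[len(pres):])

    def test_zero_variance_covariate_dropped(self):
        pres, covs, kde = toy_problem()
        covs = dict(covs, flat=covs["x"].like(np.full((20, 20), 3.0)))
        with pytest.warns(UserWarning, match="zero-variance"):
            it = ensemble.fit_iteration(pres, covs, kde, seed=1, n_trees=20)
        assert "flat" not in it.covariate_names

    def test_too_few_presences_rejected(self):
        pres, covs, kde = toy_problem(n=5)
        with pytest.raises(ValueError):
            ensemble.fit_iteration(pres, covs, kde, seed=1)


class TestCombine:
    def _state_with(self, prob_vectors):
        state = EnsembleState()
        pres, covs, kde = toy_problem()
        for i, p in enumerate(prob_vectors):
            it = ensemble.fit_iteration(pres, covs, kde, seed=i, n_trees=10)
            it.training_probabilities = np.asarray(p, float)
            state = ensemble.combine(state, it)
        return state

    def test_single_iteration_identity(self):
        p = np.linspace(0.1, 0.9, 30)
        state = self._state_with([p])
        np.testing.assert_array_equal(state.pooled_probabilities, p)

    def test_mean_of_two(self):
        state = self._state_with([np.full(30, 0.4), np.full(30, 0.6)])
        np.testing.assert_allclose(state.pooled_probabilities, 0.5)

    def test_order_invariant(self, rng):
        vecs = [rng.uniform(size=30) for _ in range(4)]
        a = self._state_with(vecs).pooled_probabilities
        b = self._state_with(vecs[::-1]).pooled_probabilities
        np.testing.assert_allclose(a, b)

    def test_pooled_stays_within_iteration_bounds(self, rng):
        vecs = [rng.uniform(size=30) for _ in range(5)]
        pooled = self._state_with(vecs).pooled_probabilities
        stacked = np.stack(vecs)
        assert np.all(pooled >= stacked.min(axis=0) - 1e-12)
        assert np.all(pooled <= stacked.max(axis=0) + 1e-12)

    def test_covariate_mismatch_rejected(self):
        pres, covs, kde = toy_problem()
        state = ensemble.combine(
            EnsembleState(), ensemble.fit_iteration(pres, covs, kde, seed=0, n_trees=10)
        )
        other = ensemble.fit_iteration(
            pres, {"x": covs["x"]}, kde, seed=1, n_trees=10
        )
        with pytest.raises(ValueError):
            ensemble.combine(state, other)


class TestKSConvergence:
    cfg = ConvergenceConfig()

    def test_identical_vectors_converged(self):
        v = np.linspace(0, 1, 50)
        ok, d, p = ensemble.ks_converged(v, v.copy(), self.cfg)
        assert ok and d == 0.0

    def test_disjoint_distributions_not_converged(self):
        ok, d, p = ensemble.ks_converged(np.zeros(50), np.ones(50), self.cfg)
        assert not ok and d == 1.0

    def test_statistic_matches_ecdf_oracle(self, rng):
        a, b = rng.uniform(size=40), rng.beta(2, 5, size=40)
        _, d, _ = ensemble.ks_converged(a, b, self.cfg)
        xs = np.sort(np.concatenate([a, b]))
        sup = max(
            abs(np.searchsorted(np.sort(a), x, side="right") / 40
                - np.searchsorted(np.sort(b), x, side="right") / 40)
            for x in xs
        )
        assert d == pytest.approx(sup, abs=1e-12)

    def test_alpha_bounds_enforced(self):
        with pytest.raises(ValueError):
            ConvergenceConfig(alpha=0.0)


class TestRunUntilConvergence:
    def test_separable_data_converges_quickly(self):
        pres, covs, kde = toy_problem()
        state = ensemble.run_until_convergence(
            pres, covs, kde, ConvergenceConfig(max_iterations=10), seed=3, n_trees=50
        )
        assert state.converged
        assert state.n_iterations <= 10
        assert len(state.convergence_history) == state.n_iterations

    def test_deterministic_under_master_seed(self):
        pres, covs, kde = toy_problem()
        a = ensemble.run_until_convergence(pres, covs, kde, seed=5, n_trees=30)
        b = ensemble.run_until_convergence(pres, covs, kde, seed=5, n_trees=30)
        np.testing.assert_array_equal(a.pooled_probabilities, b.pooled_probabilities)
        assert a.convergence_history == b.convergence_history

    def test_ks_distance_trends_to_zero(self, small_landscape, small_kde):
        state = ensemble.run_until_convergence(
            small_landscape.presences_gas,
            small_landscape.covariates,
            small_kde,
            ConvergenceConfig(alpha=0.999, max_iterations=8),  # force many iterations
            seed=2,
            n_trees=60,
        )
        ds = [d for _, d, _ in state.convergence_history[1:]]
        assert np.median(ds[-3:]) <= np.median(ds[:3])


class TestPredictRaster:
    def test_constant_covariates_constant_surface(self):
        pres, covs, kde = toy_problem()
        state = ensemble.run_until_convergence(pres, covs, kde, seed=1, n_trees=30)
        const = {n: c.like(np.full(c.shape, 0.5)) for n, c in covs.items()}
        out = ensemble.predict_raster(state, const, force=True)
        assert np.unique(out.data).size == 1

    def test_unconverged_requires_force(self):
        pres, covs, kde = toy_problem()
        state = ensemble.combine(
            EnsembleState(), ensemble.fit_iteration(pres, covs, kde, seed=0, n_trees=10)
        )
        with pytest.raises(RuntimeError):
            ensemble.predict_raster(state, covs)

    def test_missing_covariate_rejected(self):
        pres, covs, kde = toy_problem()
        state = ensemble.run_until_convergence(pres, covs, kde, seed=1, n_trees=10)
        with pytest.raises(ValueError):
            ensemble.predict_raster(state, {"x": covs["x"]}, force=True)

    def test_presences_outrank_background_cells(self, small_landscape, small_kde):
        land = small_landscape
        state = ensemble.run_until_convergence(
            land.presences_gas, land.covariates, small_kde, seed=4, n_trees=100
        )
        prob = ensemble.predict_raster(state, land.covariates, force=True)
        pres_p = land.presences_gas.sample(prob)
        rng = np.random.default_rng(0)
        bg_p = prob.data.ravel()[rng.choice(prob.n_cells, 200, replace=False)]
        assert mannwhitneyu(pres_p, bg_p, alternative="greater").pvalue < 0.01


class TestModelSelection:
    def test_max_importance_always_survives(self):
        pres, covs, kde = toy_problem()
        sel = ensemble.model_selection_mir(
            pres, covs, kde, thresholds=[0.1, 0.5, 1.0], seed=0, n_trees=50
        )
        assert "x" in sel  # the only informative covariate has MIR = 1

    def test_informative_covariates_recovered(self, full_landscape, small_kde):
        """With 3 informative and 5 noise covariates the MIR scan keeps
        every informative one in most seeds."""
        land = full_landscape
        sigma = geostats.select_sigma_cv(land.presences_gas, [250.0, 500.0, 1000.0])
        kde = geostats.kde_intensity(
            land.presences_gas, geostats.KDEConfig(sigma, land.dem)
        )
        informative = {k for k in land.config.true_coefficients if k != "intercept"}
        hits = 0
        for seed in range(5):
            sel = ensemble.model_selection_mir(
                land.presences_gas, land.covariates, kde, seed=seed, n_trees=250
            )
            hits += informative <= set(sel)
        assert hits >= 4

    def test_needs_two_covariates(self):
        pres, covs, kde = toy_problem()
        with pytest.raises(ValueError):
            ensemble.model_selection_mir(pres, {"x": covs["x"]}, kde)


class TestValidationMetrics:
    def test_auc_perfect_separation(self):
        p = np.array([0.9, 0.8, 0.2, 0.1])
        y = np.array([1, 1, 0, 0])
        assert ensemble.auc_roc(p, y) == 1.0

    def test_auc_random_labels_near_half(self, rng):
        p = rng.uniform(size=4000)
        y = rng.integers(0, 2, 4000)
        assert ensemble.auc_roc(p, y) == pytest.approx(0.5, abs=0.05)

    def test_auc_matches_pairwise_concordance_and_sklearn(self, rng):
        p = rng.uniform(size=20).round(1)  # force ties
        y = rng.integers(0, 2, 20)
        y[:2] = [0, 1]  # both classes present
        pos, neg = p[y == 1], p[y == 0]
        brute = np.mean(
            [(a > b) + 0.5 * (a == b) for a in pos for b in neg]
        )
        ours = ensemble.auc_roc(p, y)
        assert ours == pytest.approx(brute, abs=1e-12)
        assert ours == pytest.approx(roc_auc_score(y, p), abs=1e-12)

    def test_auc_single_class_rejected(self):
        with pytest.raises(ValueError):
            ensemble.auc_roc(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_kappa_perfect_classifier(self):
        p = np.array([0.95, 0.9, 0.85, 0.15, 0.1, 0.05])
        y = np.array([1, 1, 1, 0, 0, 0])
        kappa, cut = ensemble.sensitivity_weighted_kappa(p, y)
        assert kappa == pytest.approx(1.0)
        assert 0.15 < cut <= 0.85

    def test_kappa_random_labels_near_zero(self, rng):
        p = rng.uniform(size=3000)
        y = rng.integers(0, 2, 3000)
        kappa, _ = ensemble.sensitivity_weighted_kappa(p, y)
        assert abs(kappa) < 0.1

    def test_kappa_closed_form_confusion(self):
        # TP=40 TN=40 FP=10 FN=10: po=0.8, pe=0.5, kappa=0.6
        p = np.concatenate([np.full(40, 0.9), np.full(10, 0.1),
                            np.full(10, 0.9), np.full(40, 0.1)])
        y = np.concatenate([np.ones(50), np.zeros(50)])
        kappa, cut = ensemble.sensitivity_weighted_kappa(p, y)
        assert kappa == pytest.approx(0.6)

    @pytest.mark.parametrize(
        "values,cutoff,expected",
        [
            (np.ones(5), 0.65, 1.0),
            (np.array([0.5, 0.7]), 0.65, 0.5),
        ],
    )
    def test_exceedance_examples(self, values, cutoff, expected):
        assert ensemble.probability_exceedance(values, cutoff) == expected

    def test_exceedance_matches_direct_count(self, rng):
        v = rng.uniform(size=500)
        assert ensemble.probability_exceedance(v, 0.3) == (v > 0.3).sum() / 500
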