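import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit

import enmpipe as ep
from enmpipe.ensemble import (
    SuitabilityMap,
    TrainingTable,
    build_training_table,
    calibrate_replicate,
    ensemble_mean,
    fit_learner,
    predict_surface,
    registered_families,
)
from enmpipe.grids import GridSpec
from enmpipe.pseudo_absence import FAMILY_PA_CLASS, build_pa_sets, presence_distance_bounds

ALL_FAMILIES = ["GBM", "CTA", "RF", "GLM", "GAM", "ANN", "FDA", "MARS", "MAXENT"]


def toy_table(n_pres=12, n_abs=30, seed=0, family="GLM"):
    """Linearly separable-ish 2-predictor table."""
    rng = np.random.default_rng(seed)
    Xp = rng.normal(loc=[1.5, 0.5], scale=0.5, size=(n_pres, 2))
    Xa = rng.normal(loc=[-1.0, -0.5], scale=0.8, size=(n_abs, 2))
    X = np.vstack([Xp, Xa])
    y = np.array([1] * n_pres + [0] * n_abs)
    cells = [(i, 0) for i in range(n_pres + n_abs)]
    return TrainingTable(cell_ids=cells, X=X, y=y,
                         predictor_names=["PC1", "PC2"], family=family)


class TestFitLearner:
    def test_registry_contains_the_nine_families(self):
        assert set(ALL_FAMILIES) <= set(registered_families())

    def test_glm_probability_monotone_in_predictor(self):
        # 6 hand-made 1-D points, separable: logistic fit must be increasing
        table = TrainingTable(
            cell_ids=[(i, 0) for i in range(6)],
            X=np.array([[-2.0], [-1.0], [-0.5], [0.5], [1.0], [2.0]]),
            y=np.array([0, 0, 0, 1, 1, 1]),
            predictor_names=["PC1"],
            family="GLM",
        )
        model = fit_learner(table, "GLM", seed=0)
        grid_x = np.linspace(-3, 3, 13)[:, None]
        p = model.estimator.predict_proba(grid_x)[:, 1]
        assert np.all(np.diff(p) > 0)

    def test_single_class_rejected(self):
        table = toy_table()
        table.y[:] = 1
        with pytest.raises(ValueError, match="single class"):
            fit_learner(table, "GLM", seed=0)

    def test_unregistered_family_rejected(self):
        with pytest.raises(ValueError, match="unregistered"):
            fit_learner(toy_table(), "KRIGING", seed=0)

    @pytest.mark.parametrize("family", ALL_FAMILIES)
    def test_same_seed_gives_identical_predictions(self, family):
        table = toy_table(seed=3, family=family)
        Xq = np.random.default_rng(9).normal(size=(50, 2))
        p1 = fit_learner(table, family, seed=42).estimator.predict_proba(Xq)
        p2 = fit_learner(table, family, seed=42).estimator.predict_proba(Xq)
        assert np.array_equal(p1, p2)


class TestPredictSurface:
    def _score_stack(self, seed=0):
        rng = np.random.default_rng(seed)
        grid = GridSpec(west=0.0, north=1.0, cell_deg=0.1, n_rows=10, n_cols=10)
        vals = rng.normal(size=(2, 10, 10))
        vals[:, 0, 0] = np.nan
        return ep.EnvStack(grid=grid, layer_names=["PC1", "PC2"], values=vals)

    def test_known_logistic_coefficients_give_closed_form(self):
        class KnownLogistic:
            classes_ = np.array([0, 1])
            w = np.array([1.2, -0.7])
            b = 0.3

            def predict_proba(self, X):
                p = expit(X @ self.w + self.b)
                return np.column_stack([1 - p, p])

        stack = self._score_stack()
        model = ep.FittedModel(family="GLM", predictor_names=["PC1", "PC2"],
                               estimator=KnownLogistic())
        surface = predict_surface(model, stack)
        m = stack.mask
        expected = expit(stack.values[0][m] * 1.2 + stack.values[1][m] * (-0.7) + 0.3)
        assert np.allclose(surface.values[m], expected, atol=1e-8)
        assert np.isnan(surface.values[0, 0])  # NoData propagates

    def test_values_clamped_into_unit_interval(self):
        class Overshooting:
            classes_ = np.array([0, 1])

            def predict_proba(self, X):
                p = np.full(len(X), 1.0 + 1e-12)
                return np.column_stack([1 - p, p])

        stack = self._score_stack()
        model = ep.FittedModel(family="GLM", predictor_names=["PC1", "PC2"],
                               estimator=Overshooting())
        surface = predict_surface(model, stack)
        assert np.nanmax(surface.values) <= 1.0

    def test_predictor_mismatch_rejected(self):
        stack = self._score_stack()
        model = ep.FittedModel(family="GLM", predictor_names=["PC1", "PC9"],
                               estimator=None)
        with pytest.raises(ValueError, match="PC9"):
            predict_surface(model, stack)


class TestEnsembleMean:
    def _map(self, value, grid):
        return SuitabilityMap(grid=grid, values=np.full(grid.shape, value))

    def test_two_member_arithmetic(self):
        grid = GridSpec(west=0.0, north=1.0, cell_deg=0.5, n_rows=2, n_cols=2)
        mean = ensemble_mean([self._map(0.2, grid), self._map(0.4, grid)])
        assert np.allclose(mean.values, 0.3)

    def test_single_map_is_identity(self):
        grid = GridSpec(west=0.0, north=1.0, cell_deg=0.5, n_rows=2, n_cols=2)
        m = self._map(0.7, grid)
        assert np.allclose(ensemble_mean([m]).values, m.values)

    @given(st.integers(2, 6), st.integers(0, 1000))
    def test_mean_bounded_by_member_envelope(self, n_maps, seed):
        rng = np.random.default_rng(seed)
        grid = GridSpec(west=0.0, north=1.0, cell_deg=0.25, n_rows=4, n_cols=4)
        maps = [SuitabilityMap(grid=grid, values=rng.uniform(size=(4, 4)))
                for _ in range(n_maps)]
        mean = ensemble_mean(maps)
        lo = np.min([m.values for m in maps], axis=0)
        hi = np.max([m.values for m in maps], axis=0)
        assert np.all(mean.values >= lo - 1e-12)
        assert np.all(mean.values <= hi + 1e-12)


class TestCalibrateReplicate:
    def _setup(self, small_scene, small_score_stacks, strong_spec, n=8):
        occ = ep.thin_to_cells(
            ep.sample_presences(strong_spec, small_scene, n, seed=5), small_scene.grid
        )
        bounds = presence_distance_bounds(occ.cell_ids, small_scene.grid)
        pa_sets = build_pa_sets(
            small_scene.grid, small_scene.stack.mask, occ.cell_ids,
            ["GLM", "CTA"], 2, bounds, seed_base=3,
        )
        return occ, pa_sets

    def test_model_count_is_families_times_sets_times_runs(
        self, small_scene, small_score_stacks, strong_spec
    ):
        occ, pa_sets = self._setup(small_scene, small_score_stacks, strong_spec)
        rep = calibrate_replicate(occ.cell_ids, pa_sets, small_score_stacks,
                                  ["GLM", "CTA"], n_runs=2, seed_base=1)
        assert rep.n_models == 2 * 2 * 2
        assert len(rep.provenance) == 8

    def test_full_replicate_is_deterministic(
        self, small_scene, small_score_stacks, strong_spec
    ):
        occ, pa_sets = self._setup(small_scene, small_score_stacks, strong_spec)
        a = calibrate_replicate(occ.cell_ids, pa_sets, small_score_stacks,
                                ["GLM", "CTA"], n_runs=1, seed_base=7)
        b = calibrate_replicate(occ.cell_ids, pa_sets, small_score_stacks,
                                ["GLM", "CTA"], n_runs=1, seed_base=7)
        assert np.array_equal(a.maps["current"].values, b.maps["current"].values,
                              equal_nan=True)

    @pytest.mark.parametrize("family", ALL_FAMILIES)
    def test_each_family_ranks_suitable_above_unsuitable(
        self, small_scene, small_score_stacks, strong_spec, family
    ):
        # sanity of every learner adapter on a strong virtual species
        occ = ep.thin_to_cells(
            ep.sample_presences(strong_spec, small_scene, 15, seed=21),
            small_scene.grid,
        )
        bounds = presence_distance_bounds(occ.cell_ids, small_scene.grid)
        pa_sets = build_pa_sets(
            small_scene.grid, small_scene.stack.mask, occ.cell_ids,
            [family], 1, bounds, seed_base=13,
        )
        table = build_training_table(
            occ.cell_ids, pa_sets[0][FAMILY_PA_CLASS[family]],
            small_score_stacks["current"], family,
        )
        model = fit_learner(table, family, seed=17)
        surface = predict_surface(model, small_score_stacks["current"])
        suit = ep.true_suitability(strong_spec, small_scene)
        m = small_scene.stack.mask
        hi = surface.values[m & (suit >= 0.8)]
        lo = surface.values[m & (suit <= 0.2)]
        assert np.nanmean(hi) > np.nanmean(lo)
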