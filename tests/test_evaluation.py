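import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import enmpipe as ep
from enmpipe.consensus import BinaryMap
from enmpipe.ensemble import SuitabilityMap
from enmpipe.evaluation import (
    area_weighted_presence_proportion,
    homogeneous_binomial_pvalue,
    jackknife_run,
    maxsensspec_threshold,
    poisson_binomial_pmf,
    poisson_binomial_pvalue,
)
from enmpipe.grids import EARTH_RADIUS_KM, GridSpec


class TestMaxSensSpec:
    def test_separable_example(self):
        t, sens, spec = maxsensspec_threshold([0.9, 0.8, 0.7], [0.2, 0.3, 0.6])
        assert t == pytest.approx(0.65)
        assert sens == 1.0 and spec == 1.0

    def test_perfect_separation_sums_to_two(self):
        t, sens, spec = maxsensspec_threshold([0.8, 0.9], [0.1, 0.2])
        assert sens + spec == pytest.approx(2.0)

    def test_coincident_scores_cap_at_one(self):
        t, sens, spec = maxsensspec_threshold([0.5], [0.5])
        assert sens + spec == pytest.approx(1.0)

    def test_tie_breaks_toward_smallest_threshold(self):
        # plateau of equal sens+spec: the smallest candidate must win
        t1, *_ = maxsensspec_threshold([0.5], [0.5])
        assert t1 == 0.0

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            maxsensspec_threshold([], [0.5])

    @given(st.integers(0, 500))
    def test_no_finer_threshold_beats_the_returned_one(self, seed):
        rng = np.random.default_rng(seed)
        pres = rng.uniform(size=rng.integers(1, 12))
        absent = rng.uniform(size=rng.integers(1, 12))
        t, sens, spec = maxsensspec_threshold(pres, absent)
        grid = np.linspace(0, 1, 101)
        gs = (pres[None, :] >= grid[:, None]).mean(axis=1)
        gp = (absent[None, :] < grid[:, None]).mean(axis=1)
        assert sens + spec >= (gs + gp).max() - 1e-12


class TestPoissonBinomial:
    def test_zero_successes_is_certain(self):
        assert poisson_binomial_pvalue([0.2, 0.9], 0) == 1.0

    def test_two_trials_both_succeed(self):
        assert poisson_binomial_pvalue([0.3, 0.3], 2) == pytest.approx(0.09)

    def test_fair_coin_tail(self):
        assert poisson_binomial_pvalue([0.5] * 4, 2) == pytest.approx(11 / 16)

    def test_all_successes_equals_product(self):
        p = [0.2, 0.5, 0.9, 0.4]
        assert poisson_binomial_pvalue(p, 4) == pytest.approx(np.prod(p))

    def test_monotone_nonincreasing_in_D(self):
        p = [0.1, 0.4, 0.6, 0.8, 0.3]
        tails = [poisson_binomial_pvalue(p, d) for d in range(6)]
        assert np.all(np.diff(tails) <= 1e-12)

    def test_matches_exhaustive_enumeration_small_n(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(1, 9))
            p = rng.uniform(size=n)
            d = int(rng.integers(0, n + 1))
            exact = 0.0
            for bits in itertools.product([0, 1], repeat=n):
                if sum(bits) >= d:
                    exact += np.prod([pi if b else 1 - pi for pi, b in zip(p, bits)])
            assert poisson_binomial_pvalue(p, d) == pytest.approx(exact, abs=1e-12)

    def test_homogeneous_variant_matches_binomial_tail(self):
        p = [0.3] * 6
        assert homogeneous_binomial_pvalue(p, 4) == pytest.approx(
            float(stats.binom.sf(3, 6, 0.3))
        )

    def test_pmf_sums_to_one(self):
        pmf = poisson_binomial_pmf([0.1, 0.5, 0.7, 0.2])
        assert pmf.sum() == pytest.approx(1.0)

    def test_invalid_D_rejected(self):
        with pytest.raises(ValueError):
            poisson_binomial_pvalue([0.5], 2)


class TestAreaWeightedProportion:
    def test_all_present_is_one(self):
        grid = GridSpec(west=0.0, north=1.0, cell_deg=0.5, n_rows=2, n_cols=2)
        bmap = BinaryMap(grid=grid, values=np.ones((2, 2)), threshold=0.5)
        assert area_weighted_presence_proportion(bmap) == 1.0

    def test_equal_latitude_band_is_count_fraction(self):
        grid = GridSpec(west=-180.0, north=0.5, cell_deg=1.0, n_rows=1, n_cols=360)
        vals = np.zeros((1, 360))
        vals[0, :180] = 1.0
        bmap = BinaryMap(grid=grid, values=vals, threshold=0.5)
        assert area_weighted_presence_proportion(bmap) == pytest.approx(0.5)

    def test_high_latitude_cells_weigh_less(self):
        # two valid one-cell rows, one at 60N (present) and one touching the
        # equator (absent); everything between is NoData
        cell = 1.0 / 12.0
        n_rows = 721  # spans exactly 0 .. 60 + cell degrees
        grid = GridSpec(west=0.0, north=60.0 + cell, cell_deg=cell,
                        n_rows=n_rows, n_cols=1)
        vals = np.full((n_rows, 1), np.nan)
        vals[0, 0] = 1.0  # (60, 60+cell]
        vals[n_rows - 1, 0] = 0.0  # (0, cell]
        bmap = BinaryMap(grid=grid, values=vals, threshold=0.5)

        def band(phi_bot_deg):
            top = np.radians(phi_bot_deg + cell)
            bot = np.radians(phi_bot_deg)
            return EARTH_RADIUS_KM**2 * np.radians(cell) * (np.sin(top) - np.sin(bot))

        a0, a60 = band(0.0), band(60.0)
        expected = a60 / (a0 + a60)
        assert expected == pytest.approx(0.334, abs=0.002)
        assert area_weighted_presence_proportion(bmap) == pytest.approx(expected)

    def test_no_valid_cells_rejected(self):
        grid = GridSpec(west=0.0, north=1.0, cell_deg=1.0, n_rows=1, n_cols=1)
        bmap = BinaryMap(grid=grid, values=np.array([[np.nan]]), threshold=0.5)
        with pytest.raises(ValueError):
            area_weighted_presence_proportion(bmap)


class TestJackknife:
    def _occ(self, scene, spec, n, seed):
        return ep.thin_to_cells(
            ep.sample_presences(spec, scene, n, seed=seed), scene.grid
        )

    def test_one_replicate_per_presence_cell(
        self, small_scene, small_score_stacks, strong_spec
    ):
        occ = self._occ(small_scene, strong_spec, 6, seed=2)
        jk = jackknife_run(occ, small_score_stacks, families=["GLM"],
                           n_pa_sets=2, n_runs=1, seed=4)
        assert jk.report.n == occ.n_cells
        assert len(jk.report.rows) == occ.n_cells
        assert jk.report.D == int(jk.report.rows["success"].sum())

    def test_oracle_model_succeeds_everywhere(
        self, small_scene, small_score_stacks, strong_spec
    ):
        # inject the true suitable region (binarised truth) as the fitted
        # ensemble: every left-out presence inside the region must be
        # predicted, and the exact tail reduces to the product of the
        # replicate area proportions
        suit = ep.true_suitability(strong_spec, small_scene)
        occ = self._occ(small_scene, strong_spec, 20, seed=6)
        interior = [rc for rc in occ.cell_ids if suit[rc] >= 0.9][:8]
        assert len(interior) == 8
        occ = ep.OccurrenceSet(
            table=occ.table.iloc[:8], thinned=True, cell_ids=interior
        )
        oracle = SuitabilityMap(
            grid=small_scene.grid,
            values=np.where(
                small_scene.stack.mask, (suit >= 0.5).astype(float), np.nan
            ),
        )

        def calibrator(training, pa_sets, stacks, seed):
            return {"current": oracle}

        jk = jackknife_run(occ, small_score_stacks, families=["GLM"],
                           n_pa_sets=2, n_runs=1, seed=8, calibrator=calibrator)
        assert jk.report.D == jk.report.n
        p_list = jk.report.rows["predicted_presence_proportion"].to_numpy()
        assert jk.report.p_value == pytest.approx(float(np.prod(p_list)))

    def test_trivial_all_present_model_gets_no_credit(
        self, small_scene, small_score_stacks, strong_spec
    ):
        occ = self._occ(small_scene, strong_spec, 5, seed=9)
        ones = SuitabilityMap(
            grid=small_scene.grid,
            values=np.where(small_scene.stack.mask, 1.0, np.nan),
        )

        def calibrator(training, pa_sets, stacks, seed):
            return {"current": ones}

        jk = jackknife_run(occ, small_score_stacks, families=["GLM"],
                           n_pa_sets=2, n_runs=1, seed=10, calibrator=calibrator)
        assert all(jk.report.rows["success"] == 1)
        assert jk.report.p_value == pytest.approx(1.0)

    def test_too_few_cells_rejected(self, small_scene, small_score_stacks, strong_spec):
        occ = self._occ(small_scene, strong_spec, 2, seed=3)
        with pytest.raises(ValueError, match=">= 3"):
            jackknife_run(occ, small_score_stacks, families=["GLM"],
                          n_pa_sets=1, n_runs=1, seed=1)
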