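"""Poisson LN-GLM: design, penalized fitting, CV and forward selection."""

import numpy as np
import pytest

from hippogeom import glm, maps, synth
from hippogeom.glm import (
    build_design_matrix,
    cross_validate,
    fit_poisson_glm,
    grid_laplacian,
    model_prediction_quality,
    select_model,
)
from hippogeom.maps import bin_position

DT = 1.0 / 60.0


@pytest.fixture(scope="module")
def rw_bins(rw_session, grid):
    return {
        v: bin_position(rw_session.trajectories[v], grid, rw_session)
        for v in ("self", "chosen_prey")
    }


class TestDesignMatrix:
    def test_two_variable_block_structure(self, rw_bins):
        d = build_design_matrix([rw_bins["self"], rw_bins["chosen_prey"]])
        assert d.n_params == 1 + 72
        x = d.onehot(d.combo_bins)
        # intercept + exactly one 1 per variable block
        np.testing.assert_array_equal(x.sum(axis=1), 3.0)
        np.testing.assert_array_equal(x[:, 1:37].sum(axis=1), 1.0)

    def test_single_variable_one_hot_position(self, grid):
        from hippogeom.maps import BinSeries

        bs = BinSeries("self", np.array([7, 7, 12]), grid)
        d = build_design_matrix([bs])
        row = d.onehot(d.combo_bins[d.combo_id[:1]])
        assert row[0, 1 + 7] == 1.0 and row[0, 1:].sum() == 1.0

    def test_missing_frames_masked_complete_case(self, grid):
        from hippogeom.maps import BinSeries

        a = BinSeries("self", np.array([1, 2, 3, 4]), grid)
        g = BinSeries("gaze", np.array([5, -1, 6, 7]), grid)
        d = build_design_matrix([a, g])
        np.testing.assert_array_equal(d.frame_index, [0, 2, 3])
        d_solo = build_design_matrix([a])
        assert d_solo.n_frames == 4

    def test_all_frames_missing_raises(self, grid):
        from hippogeom.maps import BinSeries

        bs = BinSeries("gaze", np.array([-1, -1]), grid)
        with pytest.raises(ValueError):
            build_design_matrix([bs])


class TestLaplacianPenalty:
    def test_quadratic_form_equals_sum_of_squared_differences(self):
        lap = grid_laplacian(6, 6)
        rng = np.random.default_rng(0)
        w = rng.standard_normal(36)
        m = w.reshape(6, 6)
        direct = ((np.diff(m, axis=0) ** 2).sum()
                  + (np.diff(m, axis=1) ** 2).sum())
        assert np.isclose(w @ lap @ w, direct)

    def test_constant_in_null_space(self):
        lap = grid_laplacian()
        assert np.allclose(lap @ np.ones(36), 0.0)


class TestFitting:
    def test_saturated_mle_matches_per_bin_means(self, rw_session, rw_bins):
        """With beta=0 and a single variable, the fitted per-bin rates equal
        the closed-form per-bin Poisson MLE (empirical mean rates)."""
        pop = synth.untuned_population(1, seed=1)
        pop.weight_maps["self"][0] = np.random.default_rng(2).normal(0, 0.6, 36)
        spikes = synth.simulate_spikes(rw_session, pop, seed=3)
        y = spikes.counts[:, 0]
        d = build_design_matrix([rw_bins["self"]])
        fit = fit_poisson_glm(d, y, beta=0.0, dt=DT)
        y_inc = y[d.frame_index]
        bins_inc = d.bin_idx[:, 0]
        eta_hat = fit.intercept + fit.weights["self"]
        for b in range(36):
            sel = bins_inc == b
            if sel.sum() == 0 or y_inc[sel].sum() == 0:
                continue
            np.testing.assert_allclose(
                np.exp(eta_hat[b]), y_inc[sel].mean(), rtol=1e-6
            )

    def test_large_beta_forces_flat_weights(self, rw_session, rw_bins):
        pop = synth.untuned_population(1, seed=4, baseline_rate_range=(6.0, 6.0))
        spikes = synth.simulate_spikes(rw_session, pop, seed=5)
        y = spikes.counts[:, 0]
        d = build_design_matrix([rw_bins["self"]])
        fit = fit_poisson_glm(d, y, beta=1e7, dt=DT)
        w = fit.weights["self"]
        assert np.ptp(w) < 1e-3
        y_inc = y[d.frame_index]
        rate_hat = np.exp(fit.intercept + w.mean()) / DT
        assert np.isclose(rate_hat, y_inc.mean() / DT, rtol=1e-3)

    def test_roughness_monotone_in_beta(self, rw_session, rw_bins):
        pop = synth.untuned_population(1, seed=6)
        pop.weight_maps["self"][0] = np.random.default_rng(7).normal(0, 0.8, 36)
        spikes = synth.simulate_spikes(rw_session, pop, seed=8)
        y = spikes.counts[:, 0]
        d = build_design_matrix([rw_bins["self"]])
        lap = grid_laplacian()
        rough = []
        for beta in (0.0, 1.0, 10.0, 100.0, 1000.0):
            fit = fit_poisson_glm(d, y, beta=beta, dt=DT)
            w = fit.weights["self"]
            rough.append(w @ lap @ w)
        assert all(a >= b - 1e-9 for a, b in zip(rough[:-1], rough[1:]))

    def test_all_zero_counts_no_crash(self, rw_bins):
        d = build_design_matrix([rw_bins["self"]])
        y = np.zeros(len(rw_bins["self"].bins), dtype=int)
        fit = fit_poisson_glm(d, y, beta=10.0, dt=DT)
        assert np.isfinite(fit.intercept)
        assert np.exp(fit.intercept) < 1e-3  # near-zero predicted counts

    def test_negative_inputs_rejected(self, rw_bins):
        d = build_design_matrix([rw_bins["self"]])
        y = np.zeros(d.n_frames + (len(rw_bins["self"].bins) - d.n_frames),
                     dtype=int)
        with pytest.raises(ValueError):
            fit_poisson_glm(d, y, beta=-1.0, dt=DT)
        y2 = np.zeros(len(rw_bins["self"].bins), dtype=int)
        y2[0] = -1
        with pytest.raises(ValueError):
            fit_poisson_glm(d, y2, beta=1.0, dt=DT)


class TestCrossValidation:
    def test_untuned_neuron_llh_increase_near_zero(self, rw_session, rw_bins):
        pop = synth.untuned_population(1, seed=9, baseline_rate_range=(5.0, 5.0))
        spikes = synth.simulate_spikes(rw_session, pop, seed=10)
        d = build_design_matrix([rw_bins["self"]])
        _, fold_vals = cross_validate(d, spikes.counts[:, 0], dt=DT)
        assert abs(np.nanmean(fold_vals)) < 0.01  # bits/spike

    def test_tuned_neuron_positive_in_most_folds(self, rw_session, rw_bins):
        pop = synth.untuned_population(1, seed=11, baseline_rate_range=(5.0, 5.0))
        w = np.random.default_rng(12).normal(0, 0.8, 36)
        pop.weight_maps["self"][0] = w - w.mean()
        spikes = synth.simulate_spikes(rw_session, pop, seed=13)
        d = build_design_matrix([rw_bins["self"]])
        _, fold_vals = cross_validate(d, spikes.counts[:, 0], dt=DT)
        assert np.sum(fold_vals > 0) >= 9

    def test_single_point_beta_grid_returned(self, rw_session, rw_bins):
        pop = synth.untuned_population(1, seed=14)
        spikes = synth.simulate_spikes(rw_session, pop, seed=15)
        d = build_design_matrix([rw_bins["self"]])
        beta, _ = cross_validate(d, spikes.counts[:, 0], beta_grid=(42.0,), dt=DT)
        assert beta == 42.0


class TestForwardSelection:
    def _one_variable_pop(self, n, seed, gain=0.8):
        """Neurons tuned to self only (chosen_prey weights zeroed)."""
        pop = synth.untuned_population(n, seed=seed,
                                       baseline_rate_range=(4.0, 8.0))
        rng = np.random.default_rng(seed + 1)
        for i in range(n):
            w = rng.normal(0, gain, 36)
            pop.weight_maps["self"][i] = w - w.mean()
            pop.tuned_variables[i] = {"self"}
        return pop

    def test_recovers_self_only_tuning(self, rw_session, rw_bins):
        n = 6
        pop = self._one_variable_pop(n, seed=16)
        spikes = synth.simulate_spikes(rw_session, pop, seed=17)
        hits = 0
        for i in range(n):
            m = select_model(rw_bins, spikes.counts[:, i],
                             candidates=("self", "chosen_prey"), dt=DT)
            hits += m.tuned and m.selected_variables == ("self",)
        assert hits >= round(0.9 * n)

    def test_recovers_two_variable_tuning(self, rw_session, rw_bins):
        n = 5
        pop = synth.untuned_population(n, seed=18,
                                       baseline_rate_range=(4.0, 8.0))
        rng = np.random.default_rng(19)
        for i in range(n):
            for v in ("self", "chosen_prey"):
                w = rng.normal(0, 0.8, 36)
                pop.weight_maps[v][i] = w - w.mean()
            pop.tuned_variables[i] = {"self", "chosen_prey"}
        spikes = synth.simulate_spikes(rw_session, pop, seed=20)
        hits = 0
        for i in range(n):
            m = select_model(rw_bins, spikes.counts[:, i],
                             candidates=("self", "chosen_prey"), dt=DT)
            hits += set(m.selected_variables) == {"self", "chosen_prey"}
        assert hits >= round(0.8 * n)

    def test_untuned_neurons_mostly_not_tuned(self, rw_session, rw_bins):
        n = 12
        pop = synth.untuned_population(n, seed=21)
        spikes = synth.simulate_spikes(rw_session, pop, seed=22)
        declared = sum(
            select_model(rw_bins, spikes.counts[:, i],
                         candidates=("self", "chosen_prey"), dt=DT).tuned
            for i in range(n)
        )
        assert declared <= 2  # ~alpha of 12, generous binomial slack

    def test_selection_path_records_all_steps(self, rw_session, rw_bins):
        pop = self._one_variable_pop(1, seed=23)
        spikes = synth.simulate_spikes(rw_session, pop, seed=24)
        m = select_model(rw_bins, spikes.counts[:, 0],
                         candidates=("self", "chosen_prey"), dt=DT)
        singles = [s for s in m.selection_path if len(s.variables) == 1]
        assert len(singles) == 2
        assert m.p_vs_null is not None


class TestPredictionQuality:
    def test_perfect_prediction(self, rw_session, rw_bins):
        pop = self_pop = synth.untuned_population(1, seed=25)
        pop.weight_maps["self"][0] = np.random.default_rng(26).normal(0, 0.5, 36)
        spikes = synth.simulate_spikes(rw_session, pop, seed=27)
        y = spikes.counts[:, 0]
        d = build_design_matrix([rw_bins["self"]])
        fit = fit_poisson_glm(d, y, beta=1.0, dt=DT)
        # correlate prediction with itself: r = 1 by construction
        pred = fit.rate_hz(d)
        from scipy.ndimage import gaussian_filter1d

        r = np.corrcoef(gaussian_filter1d(pred, 15.0),
                        gaussian_filter1d(pred, 15.0))[0, 1]
        assert np.isclose(r, 1.0)

    def test_tuned_neuron_positive_corr_untuned_near_zero(
        self, rw_session, rw_bins
    ):
        pop = synth.untuned_population(2, seed=28, baseline_rate_range=(5.0, 5.0))
        pop.weight_maps["self"][0] = np.random.default_rng(29).normal(0, 0.8, 36)
        spikes = synth.simulate_spikes(rw_session, pop, seed=30)
        d = build_design_matrix([rw_bins["self"]])
        fit0 = fit_poisson_glm(d, spikes.counts[:, 0], beta=1.0, dt=DT)
        r_tuned = model_prediction_quality(fit0, d, spikes.counts[:, 0])
        assert r_tuned > 0.05
        # untuned neuron scored against the tuned neuron's model: no relation
        r_null = model_prediction_quality(fit0, d, spikes.counts[:, 1])
        assert abs(r_null) < 0.05

    def test_constant_series_reported_missing(self, rw_bins):
        d = build_design_matrix([rw_bins["self"]])
        y = np.zeros(len(rw_bins["self"].bins), dtype=int)
        fit = fit_poisson_glm(d, y, beta=1.0, dt=DT)
        r = model_prediction_quality(fit, d, y)
        assert np.isnan(r)
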