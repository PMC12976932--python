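"""Alignment index, orthogonal subspace optimization, linear maps."""

import numpy as np
import pytest

from hippogeom import subspaces, synth
from hippogeom.subspaces import (
    alignment_index,
    alignment_index_value,
    covariance_split_correlation,
    cross_projection_variance,
    fit_linear_map,
    neuron_covariance,
    optimize_orthogonal_subspaces,
    pca_cross_variance,
    project_onto_basis,
    top_eigvectors,
)
from hippogeom.maps import PopulationMatrix, zscore_rows

from conftest import planted_session


def _pm(raw, variable="v"):
    z, _ = zscore_rows(raw)
    return PopulationMatrix(variable, z, np.arange(len(raw)), raw)


def planted_pair(angle, n=60, d=4, noise_sd=0.0, seed=0):
    """Raw map-matrix pair with exact planted principal angles."""
    spec = synth.GeometrySpec(
        variables=("self", "chosen_prey"),
        latent_dim=d,
        angles_deg={"chosen_prey": angle},
        noise_sd=noise_sd,
        map_gain=1.0,
    )
    pop = synth.plant_population(spec, n_neurons=n, seed=seed)
    return pop.weight_maps["self"], pop.weight_maps["chosen_prey"], pop


class TestPcaCrossVariance:
    def test_reference_equals_itself(self):
        raw = np.random.default_rng(0).random((40, 36))
        pm = _pm(raw, "self")
        res = pca_cross_variance(pm, [pm], k=10)
        assert res.var_explained["self"] == pytest.approx(
            res.var_explained_ref
        )

    def test_orthogonal_complement_captures_nothing(self):
        ma, mb, _ = planted_pair(90.0, seed=1)
        pm_a, pm_b = _pm(ma, "self"), _pm(mb, "chosen_prey")
        res = pca_cross_variance(_as_noz(ma, "self"), [_as_noz(mb, "chosen_prey")],
                                 k=4)
        assert res.var_explained["chosen_prey"] < 1e-6

    def test_planted_partial_share(self):
        """A 50/50 mix of reference-subspace and orthogonal components puts
        half the variance in the reference PCs (analytic construction)."""
        rng = np.random.default_rng(2)
        n = 80
        q, _ = np.linalg.qr(rng.standard_normal((n, 8)))
        a_lat = rng.standard_normal((4, 36))
        m_ref = q[:, :4] @ a_lat
        mix = np.concatenate([a_lat, rng.standard_normal((4, 36))])
        m_other = q @ mix / np.sqrt(2)
        # equalize component scales so the split is exactly 50/50
        lat_scale = np.linalg.norm(m_ref)
        res = pca_cross_variance(_as_noz(m_ref, "a"), [_as_noz(m_other, "b")],
                                 k=4)
        share = res.var_explained["b"]
        expect = np.linalg.norm(a_lat) ** 2 / np.linalg.norm(mix) ** 2
        assert share == pytest.approx(expect, abs=0.05)

    def test_too_few_neurons_rejected(self):
        pm = _pm(np.random.default_rng(3).random((8, 36)))
        with pytest.raises(ValueError):
            pca_cross_variance(pm, [pm], k=10)


def _as_noz(raw, variable):
    """PopulationMatrix wrapper that keeps the raw matrix as M (no
    z-scoring), for exact linear-algebra oracles on planted constructions."""
    return PopulationMatrix(variable, np.asarray(raw, float),
                            np.arange(len(raw)), np.asarray(raw, float))


class TestAlignmentIndex:
    def test_self_alignment_is_one(self):
        raw = np.random.default_rng(4).random((50, 36))
        pm = _pm(raw)
        assert alignment_index_value(pm, pm, k=10) == pytest.approx(1.0)

    def test_orthogonal_construction_is_zero(self):
        ma, mb, _ = planted_pair(90.0, seed=5)
        assert alignment_index_value(ma, mb, k=4) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("angle", [0.0, 30.0, 60.0, 90.0])
    def test_cos_squared_recovery_noiseless(self, angle):
        ma, mb, _ = planted_pair(angle, seed=6)
        ai = alignment_index_value(ma, mb, k=4)
        assert ai == pytest.approx(np.cos(np.deg2rad(angle)) ** 2, abs=1e-6)

    @pytest.mark.parametrize("angle", [0.0, 30.0, 60.0, 90.0])
    def test_cos_squared_recovery_snr10(self, angle):
        """Map noise at a tenth of the signal scale shifts AI < 0.05."""
        ma, mb, _ = planted_pair(angle, n=200, seed=7)
        scale = np.sqrt(np.mean(ma**2))
        rng = np.random.default_rng(8)
        ma = ma + rng.normal(0, scale / np.sqrt(10), ma.shape)
        mb = mb + rng.normal(0, scale / np.sqrt(10), mb.shape)
        ai = alignment_index_value(ma, mb, k=4)
        assert ai == pytest.approx(np.cos(np.deg2rad(angle)) ** 2, abs=0.05)

    def test_joint_neuron_permutation_invariance(self):
        ma, mb, _ = planted_pair(45.0, seed=9)
        perm = np.random.default_rng(10).permutation(len(ma))
        a1 = alignment_index_value(ma, mb, k=4)
        a2 = alignment_index_value(ma[perm], mb[perm], k=4)
        assert a1 == pytest.approx(a2, abs=1e-10)

    def test_null_p_direction(self):
        """For strongly orthogonal subspaces most covariance-matched random
        bases align better than the observed one: small p."""
        ma, mb, _ = planted_pair(90.0, n=80, seed=11)
        res = alignment_index(ma, mb, k=4, n_null=200, seed=12)
        assert res.p < 0.05
        assert res.null is not None and len(res.null) == 200

    def test_rank_deficiency_rejected(self):
        rng = np.random.default_rng(13)
        thin = rng.standard_normal((30, 2)) @ rng.standard_normal((2, 36))
        with pytest.raises(ValueError):
            alignment_index(thin, thin, k=10, n_null=10, seed=0)


@pytest.fixture(scope="module")
def shared_session():
    """Identical planted maps for both variables (angle 0, identity latent
    map), so only Poisson noise separates cross from within."""
    base = synth.random_walk_session(12_000, ("self", "chosen_prey"), seed=61)
    n, d = 25, 4
    spec = synth.GeometrySpec(
        variables=("self", "chosen_prey"),
        latent_dim=d,
        angles_deg={"chosen_prey": 0.0},
        linear_map=("self", "chosen_prey", np.eye(d)),
        map_gain=0.5 * np.sqrt(n / d),
    )
    pop = synth.plant_population(spec, n_neurons=n, seed=62)
    return synth.Session(
        trajectories=base.trajectories,
        trials=base.trials,
        spikes=synth.simulate_spikes(base, pop, seed=63),
        frame_dt=base.frame_dt,
        field_size=base.field_size,
    )


@pytest.fixture(scope="module")
def independent_session():
    base = synth.random_walk_session(12_000, ("self", "chosen_prey"), seed=63)
    session, _ = planted_session(base, n_neurons=25, angle=90.0, seed=64)
    return session


class TestCovarianceSplitCorrelation:
    def test_self_pair_coin_flip(self, shared_session):
        _, _, p = covariance_split_correlation(
            shared_session, ("self", "self"), n_iter=60, seed=1
        )
        assert 0.25 < p < 0.75

    def test_shared_structure_cross_near_within(self, shared_session):
        cross, within, p = covariance_split_correlation(
            shared_session, ("self", "chosen_prey"), n_iter=60, seed=2
        )
        assert cross > 0.5 * within
        assert p < 0.999  # not overwhelmingly below the ceiling

    def test_independent_structure_cross_below_within(self, independent_session):
        cross, within, p = covariance_split_correlation(
            independent_session, ("self", "chosen_prey"), n_iter=60, seed=3
        )
        assert cross < within
        assert p > 0.95


class TestOrthogonalSubspaces:
    def test_single_variable_reduces_to_pca(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal((40, 36))
        c = neuron_covariance(x)
        basis = optimize_orthogonal_subspaces([c], [4], ("self",), seed=0)
        assert basis.var_captured["self"] == pytest.approx(1.0, abs=1e-6)
        assert basis.objective == pytest.approx(1.0, abs=1e-6)

    def test_orthogonality_constraints_hold(self):
        ma, mb, _ = planted_pair(50.0, n=50, noise_sd=0.05, seed=15)
        cs = [neuron_covariance(ma), neuron_covariance(mb)]
        basis = optimize_orthogonal_subspaces(cs, [4, 4],
                                              ("self", "chosen_prey"), seed=1)
        qa, qb = basis.bases["self"], basis.bases["chosen_prey"]
        assert np.abs(qa.T @ qa - np.eye(4)).max() < 1e-8
        assert np.abs(qb.T @ qb - np.eye(4)).max() < 1e-8
        assert np.abs(qa.T @ qb).max() < 1e-8

    def test_objective_trace_monotone(self):
        ma, mb, _ = planted_pair(40.0, n=40, seed=16)
        cs = [neuron_covariance(ma), neuron_covariance(mb)]
        basis = optimize_orthogonal_subspaces(cs, [4, 4],
                                              ("a", "b"), seed=2)
        diffs = np.diff(basis.objective_trace)
        assert np.all(diffs >= -1e-12)

    def test_orthogonal_planted_structure_fully_captured(self):
        ma, mb, _ = planted_pair(90.0, n=60, seed=17)
        cs = [neuron_covariance(ma), neuron_covariance(mb)]
        basis = optimize_orthogonal_subspaces(cs, [4, 4],
                                              ("a", "b"), seed=3)
        assert basis.var_captured["a"] > 0.99
        assert basis.var_captured["b"] > 0.99

    def test_collinear_variables_pay_a_cost(self):
        rng = np.random.default_rng(18)
        x = rng.standard_normal((40, 36))
        c = neuron_covariance(x)
        basis = optimize_orthogonal_subspaces([c, c.copy()], [4, 4],
                                              ("a", "b"), seed=4)
        total = basis.var_captured["a"] + basis.var_captured["b"]
        assert total < 2.0 - 1e-3  # identical covariances cannot both win

    def test_infeasible_dimensions_rejected(self):
        c = np.eye(6)
        with pytest.raises(ValueError):
            optimize_orthogonal_subspaces([c, c], [4, 4], ("a", "b"))


class TestCrossProjection:
    def test_own_projection_matches_basis_capture(self):
        ma, mb, _ = planted_pair(90.0, n=50, seed=19)
        cs = [neuron_covariance(ma), neuron_covariance(mb)]
        basis = optimize_orthogonal_subspaces(cs, [4, 4], ("a", "b"), seed=5)
        fracs, _ = cross_projection_variance({"a": ma, "b": mb}, basis,
                                             n_boot=10, seed=6)
        # own-subspace fraction of total variance; bases capture all of the
        # rank-4 structure, so fraction of total == fraction of top-4
        assert fracs[("a", "a")] == pytest.approx(
            basis.var_captured["a"]
            * top_eigvectors(cs[0], 4)[1].sum() / np.trace(cs[0]),
            abs=1e-6,
        )

    def test_planted_orthogonal_cross_fraction_small(self):
        ma, mb, _ = planted_pair(90.0, n=50, seed=20)
        cs = [neuron_covariance(ma), neuron_covariance(mb)]
        basis = optimize_orthogonal_subspaces(cs, [4, 4], ("a", "b"), seed=7)
        fracs, ps = cross_projection_variance({"a": ma, "b": mb}, basis,
                                              n_boot=50, seed=8)
        assert fracs[("a", "b")] < 0.05
        assert ps[("a", "b")] < 0.05  # cross capture below own capture

    def test_basis_column_rotation_invariance(self):
        ma, mb, _ = planted_pair(90.0, n=50, seed=21)
        cs = [neuron_covariance(ma), neuron_covariance(mb)]
        basis = optimize_orthogonal_subspaces(cs, [4, 4], ("a", "b"), seed=9)
        fr1, _ = cross_projection_variance({"a": ma}, basis, n_boot=0, seed=0)
        rot, _ = np.linalg.qr(np.random.default_rng(22).standard_normal((4, 4)))
        basis.bases["b"] = basis.bases["b"] @ rot
        fr2, _ = cross_projection_variance({"a": ma}, basis, n_boot=0, seed=0)
        assert fr1[("a", "b")] == pytest.approx(fr2[("a", "b")], abs=1e-10)


class TestLinearMap:
    def brute_force_loocv(self, x_a, x_b):
        c = x_a.shape[1]
        pred = np.empty_like(x_b)
        for j in range(c):
            keep = [i for i in range(c) if i != j]
            w = np.linalg.lstsq(x_a[:, keep].T, x_b[:, keep].T, rcond=None)[0].T
            pred[:, j] = w @ x_a[:, j]
        return 1 - np.linalg.norm(x_b - pred) ** 2 / np.linalg.norm(x_b) ** 2

    def test_exact_linear_relation(self):
        rng = np.random.default_rng(23)
        x_a = rng.standard_normal((4, 36))
        w_true = rng.standard_normal((4, 4))
        res = fit_linear_map(x_a, w_true @ x_a, n_shuffle=0)
        assert res.r2_train == pytest.approx(1.0)
        assert res.r2_loocv == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(res.w, w_true, atol=1e-9)

    def test_noisy_recovery_within_20_percent(self):
        rng = np.random.default_rng(24)
        x_a = rng.standard_normal((4, 36))
        w_true = rng.standard_normal((4, 4))
        x_b = w_true @ x_a
        x_b = x_b + rng.normal(0, 0.1 * x_b.std(), x_b.shape)
        res = fit_linear_map(x_a, x_b, n_shuffle=0)
        rel = np.linalg.norm(res.w - w_true) / np.linalg.norm(w_true)
        assert rel < 0.2

    def test_loocv_matches_brute_force(self):
        rng = np.random.default_rng(25)
        for _ in range(5):
            x_a = rng.standard_normal((4, 36))
            x_b = rng.standard_normal((3, 36))
            res = fit_linear_map(x_a, x_b, n_shuffle=0)
            assert res.r2_loocv == pytest.approx(
                self.brute_force_loocv(x_a, x_b), abs=1e-12
            )

    def test_independent_coordinates_not_significant(self):
        rng = np.random.default_rng(26)
        x_a = rng.standard_normal((4, 36))
        x_b = rng.standard_normal((4, 36))
        res = fit_linear_map(x_a, x_b, n_shuffle=200, seed=1)
        assert res.r2_loocv <= 0.2
        assert res.p > 0.05

    def test_planted_relation_significant(self):
        rng = np.random.default_rng(27)
        x_a = rng.standard_normal((4, 36))
        w_true = rng.standard_normal((4, 4))
        x_b = w_true @ x_a + rng.normal(0, 0.2, (4, 36))
        res = fit_linear_map(x_a, x_b, n_shuffle=200, seed=2)
        assert res.p < 0.05

    def test_projection_pipeline_recovers_planted_map(self):
        """End to end: planted latent linear relation between orthogonal
        subspaces is recovered from the fitted bases' coordinates."""
        rng = np.random.default_rng(28)
        w_true = rng.standard_normal((4, 4))
        spec = synth.GeometrySpec(
            variables=("self", "chosen_prey"),
            latent_dim=4,
            angles_deg={"chosen_prey": 90.0},
            linear_map=("self", "chosen_prey", w_true),
        )
        pop = synth.plant_population(spec, n_neurons=60, seed=29)
        ma = pop.weight_maps["self"]
        mb = pop.weight_maps["chosen_prey"]
        cs = [neuron_covariance(ma), neuron_covariance(mb)]
        basis = optimize_orthogonal_subspaces(cs, [4, 4],
                                              ("self", "chosen_prey"), seed=10)
        x_a = project_onto_basis(ma, basis.bases["self"])
        x_b = project_onto_basis(mb, basis.bases["chosen_prey"])
        res = fit_linear_map(x_a, x_b, n_shuffle=100, seed=3)
        assert res.r2_train > 0.99
        assert res.r2_loocv > 0.95
        assert res.p < 0.05
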