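import numpy as np
import pytest

import fuzzycomplex as fc
from fuzzycomplex.msm import (
    DisconnectedWarning, count_matrix, crisp_assignment,
)
from fuzzycomplex import synthetic as syn


class TestFeaturize:
    def test_zero_angle_maps_to_sin0_cos1(self):
        traj = fc.DihedralTrajectory([[0.0], [0.0]], [[90.0], [90.0]])
        f = fc.featurize(traj)
        assert f[0, 0] == pytest.approx(0.0)   # sin(phi)
        assert f[0, 1] == pytest.approx(1.0)   # cos(phi)

    def test_wrap_continuity_at_180(self):
        t1 = fc.DihedralTrajectory([[180.0], [180.0]], [[0.0], [0.0]])
        t2 = fc.DihedralTrajectory([[-179.999], [-179.999]], [[0.0], [0.0]])
        assert np.allclose(fc.featurize(t1), fc.featurize(t2), atol=1e-4)

    def test_feature_count(self):
        traj = fc.DihedralTrajectory(np.zeros((5, 3)), np.zeros((5, 3)))
        assert fc.featurize(traj).shape == (5, 12)


class TestTICA:
    def _ar1_pair(self, n=100000, seed=0):
        rng = np.random.default_rng(seed)
        slow = np.empty(n)
        fast = np.empty(n)
        slow[0] = fast[0] = 0.0
        es, ef = rng.normal(size=n), rng.normal(size=n)
        for t in range(1, n):
            slow[t] = 0.99 * slow[t - 1] + es[t]
            fast[t] = 0.1 * fast[t - 1] + ef[t]
        return np.stack([slow / slow.std(), fast / fast.std()], axis=1)

    def test_first_component_finds_slow_axis(self):
        X = self._ar1_pair()
        res = fc.tica(X, lag=10)
        v = res.components[:, 0] / np.linalg.norm(res.components[:, 0])
        assert abs(v[0]) > 0.99
        assert res.eigenvalues[0] > res.eigenvalues[1]

    def test_white_noise_eigenvalues_near_zero(self, rng):
        X = rng.normal(size=(20000, 4))
        res = fc.tica(X, lag=5)
        assert np.all(np.abs(res.eigenvalues) < 5 / np.sqrt(20000))

    def test_projection_mean_free_and_eigenvalues_bounded(self):
        X = self._ar1_pair(20000, seed=3)
        res = fc.tica(X, lag=10)
        assert np.allclose(res.projection.mean(axis=0), 0.0, atol=1e-10)
        assert np.all(res.eigenvalues <= 1.0)
        assert np.all(res.eigenvalues >= -1.0)

    def test_excessive_lag_rejected(self):
        with pytest.raises(ValueError):
            fc.tica(np.zeros((10, 2)), lag=10)


class TestKMeans:
    def test_two_blobs_recovered(self, rng):
        X = np.concatenate([rng.normal(0, 0.1, size=(100, 2)),
                            rng.normal(5, 0.1, size=(100, 2))])
        labels = fc.kmeans_discretize(X, 2, seed=0)
        assert len(set(labels[:100])) == 1
        assert len(set(labels[100:])) == 1
        assert labels[0] != labels[150]

    def test_k_equals_frames_gives_singletons(self, rng):
        X = rng.normal(size=(8, 2))
        labels = fc.kmeans_discretize(X, 8, seed=0)
        assert len(set(labels)) == 8

    def test_seed_determinism(self, rng):
        X = rng.normal(size=(200, 3))
        a = fc.kmeans_discretize(X, 5, seed=7)
        b = fc.kmeans_discretize(X, 5, seed=7)
        assert np.array_equal(a, b)

    def test_k_exceeding_frames_rejected(self):
        with pytest.raises(ValueError):
            fc.kmeans_discretize(np.zeros((3, 1)), 4)


class TestMSMEstimation:
    def test_alternating_chain(self):
        model = fc.estimate_msm(np.array([0, 1] * 50), lag=1)
        assert np.allclose(model.transition_matrix, [[0, 1], [1, 0]])
        assert np.allclose(model.stationary, [0.5, 0.5])

    def test_single_state(self):
        model = fc.estimate_msm(np.zeros(10, dtype=int), lag=1)
        assert model.transition_matrix.shape == (1, 1)
        assert model.transition_matrix[0, 0] == 1.0

    def test_two_state_stationary_within_3se(self):
        rng = np.random.default_rng(0)
        T = np.array([[0.9, 0.1], [0.8, 0.2]])
        n = 100000
        d = np.empty(n, dtype=int)
        d[0] = 0
        u = rng.random(n)
        for t in range(1, n):
            d[t] = int(u[t] < T[d[t - 1], 1])
        model = fc.estimate_msm(d, lag=1)
        # p01=0.1, p10=0.8 -> pi = (8/9, 1/9)
        pi_true = np.array([8 / 9, 1 / 9])
        se = np.sqrt(pi_true * (1 - pi_true) / n) * 3  # generous envelope
        assert np.all(np.abs(model.stationary - pi_true) < 3 * se + 0.01)

    def test_invariants_on_random_chain(self, rng):
        d = rng.integers(0, 5, size=5000)
        model = fc.estimate_msm(d, lag=2)
        T, pi = model.transition_matrix, model.stationary
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-10)
        assert np.allclose(pi @ T, pi, atol=1e-8)
        assert np.allclose(pi[:, None] * T, (pi[:, None] * T).T, atol=1e-8)

    def test_nonreversible_mode_row_normalises_counts(self):
        d = np.array([0, 0, 1, 0, 1, 1, 0])
        model = fc.estimate_msm(d, lag=1, mode="nonreversible")
        C = count_matrix(d, 1)
        assert np.allclose(model.transition_matrix,
                           C / C.sum(axis=1, keepdims=True))

    def test_disconnected_states_dropped_with_warning(self):
        d = np.array([0, 1, 0, 1, 0, 1, 2])  # state 2 is absorbing-ish
        with pytest.warns(DisconnectedWarning, match="2"):
            model = fc.estimate_msm(d, lag=1)
        assert model.n_states == 2

    def test_implied_timescale_matches_analytic_two_state(self):
        rng = np.random.default_rng(4)
        p01, p10 = 0.1, 0.2
        n = 200000
        d = np.empty(n, dtype=int)
        d[0] = 0
        u = rng.random(n)
        for t in range(1, n):
            d[t] = 1 - d[t - 1] if u[t] < (p01 if d[t - 1] == 0 else p10) \
                else d[t - 1]
        model = fc.estimate_msm(d, lag=1)
        analytic = -1.0 / np.log(1 - p01 - p10)
        assert model.implied_timescales(1)[0] == pytest.approx(analytic,
                                                               rel=0.05)

    def test_model_fit_wrapper(self):
        model = fc.MarkovStateModel(lag=1).fit(np.array([0, 1] * 20))
        assert model.n_states == 2


class TestPCCA:
    def test_block_structure_recovered(self):
        eps = 1e-3
        T = np.array([
            [0.5 - eps / 2, 0.5 - eps / 2, eps / 2, eps / 2],
            [0.5 - eps / 2, 0.5 - eps / 2, eps / 2, eps / 2],
            [eps / 2, eps / 2, 0.5 - eps / 2, 0.5 - eps / 2],
            [eps / 2, eps / 2, 0.5 - eps / 2, 0.5 - eps / 2],
        ])
        pi = np.full(4, 0.25)
        model = fc.MSMModel(T, 1, pi, np.arange(4), reversible=True)
        chi = fc.pcca(model, 2)
        crisp = crisp_assignment(chi)
        assert crisp[0] == crisp[1]
        assert crisp[2] == crisp[3]
        assert crisp[0] != crisp[2]

    def test_memberships_rows_sum_to_one(self):
        traj = syn.gen_torsion_traj(n_frames=3000, seed=1)
        feats = fc.featurize(traj)
        proj = fc.tica(feats, lag=5).projection[:, :3]
        dtraj = fc.kmeans_discretize(proj, 10, seed=0)
        model = fc.estimate_msm(dtraj, lag=5)
        chi = fc.pcca(model, 3)
        assert np.allclose(chi.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(chi >= 0.0) and np.all(chi <= 1.0)

    def test_full_resolution_is_identity(self):
        model = fc.estimate_msm(np.array([0, 1] * 50), lag=1)
        chi = fc.pcca(model, 2)
        assert np.allclose(np.sort(chi, axis=1), np.eye(2)[::-1], atol=1e-8) \
            or np.allclose(chi @ chi.T, np.eye(2), atol=1e-8)

    def test_nonreversible_model_rejected(self):
        d = np.array([0, 1, 2] * 30)
        model = fc.estimate_msm(d, lag=1, mode="nonreversible")
        if not model.reversible:
            with pytest.raises(ValueError):
                fc.pcca(model, 2)


class TestCKTest:
    def _pipeline(self, seed, n_frames=4000, k=10):
        traj = syn.gen_torsion_traj(n_frames=n_frames, seed=seed)
        proj = fc.tica(fc.featurize(traj), lag=5).projection[:, :3]
        dtraj = fc.kmeans_discretize(proj, k, seed=seed)
        return fc.estimate_msm(dtraj, lag=5), dtraj

    def test_markovian_data_passes(self):
        model, dtraj = self._pipeline(0)
        res = fc.ck_test(model, dtraj, n_metastable=3, seed=0)
        assert res.passed

    def test_hidden_state_lumping_fails_at_short_lag(self):
        """Lumping two slow states into one observable breaks the CK test."""
        # 3-state chain where states 1 and 2 interconvert slowly, observed
        # only as two symbols (0 vs {1,2} lumped)
        rng = np.random.default_rng(2)
        T = np.array([[0.95, 0.05, 0.0],
                      [0.05, 0.93, 0.02],
                      [0.0, 0.02, 0.98]])
        n = 30000
        d = np.empty(n, dtype=int)
        d[0] = 0
        for t in range(1, n):
            d[t] = rng.choice(3, p=T[d[t - 1]])
        lumped = np.where(d == 2, 1, d)
        model = fc.estimate_msm(lumped, lag=1)
        res = fc.ck_test(model, lumped, factors=(5, 10, 20),
                         n_metastable=2, seed=0)
        assert not res.passed

    def test_factor_one_is_exact(self):
        model, dtraj = self._pipeline(1)
        res = fc.ck_test(model, dtraj, factors=(1,), n_metastable=3, seed=0)
        for k in res.factors:
            assert np.allclose(res.predicted[k], res.estimated[k], atol=1e-8)

    def test_too_short_trajectory_rejected(self):
        model = fc.estimate_msm(np.array([0, 1] * 10), lag=1)
        with pytest.raises(ValueError):
            fc.ck_test(model, np.array([0, 1] * 10), factors=(50,))


class TestFreeEnergySurface:
    def test_uniform_samples_flat_surface(self, rng):
        x, y = rng.uniform(0, 1, 50000), rng.uniform(0, 1, 50000)
        fes = fc.free_energy_surface(x, y, bins=5)
        assert np.nanmax(fes.free_energy) < 0.2

    def test_two_gaussian_mixture_depth_ratio(self, rng):
        n = 200000
        pick = rng.random(n) < 0.9
        x = np.where(pick, rng.normal(-2, 0.3, n), rng.normal(2, 0.3, n))
        y = rng.normal(0, 0.3, n)
        fes = fc.free_energy_surface(x, y, bins=60, kT=1.0)
        half = fes.free_energy[:30], fes.free_energy[30:]
        depth = np.nanmin(half[1]) - np.nanmin(half[0])
        assert depth == pytest.approx(np.log(9), rel=0.10)

    def test_single_bin_zero_rest_unobserved(self):
        fes = fc.free_energy_surface([0.5], [0.5], bins=4)
        assert np.nansum(fes.free_energy == 0.0) == 1
        assert fes.observed.sum() == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fc.free_energy_surface([], [], bins=4)


class TestEndToEndRecovery:
    def test_pcca_recovers_planted_states(self):
        from itertools import permutations

        traj, states = syn.gen_torsion_traj(n_frames=5000, seed=2,
                                            return_states=True)
        proj = fc.tica(fc.featurize(traj), lag=5).projection[:, :3]
        dtraj = fc.kmeans_discretize(proj, 12, seed=0)
        model = fc.estimate_msm(dtraj, lag=5)
        chi = fc.pcca(model, 3)
        assign = crisp_assignment(chi)[dtraj]
        best = max(np.mean(np.array([p[a] for a in assign]) == states)
                   for p in permutations(range(3)))
        assert best >= 0.95
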