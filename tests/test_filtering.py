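"""Particle filter against exact oracles, and resampling schemes."""

import numpy as np
import pytest
from scipy import stats

from ordssm import (
    DegeneracyError,
    GRMItem,
    LinearItem,
    MeasurementModel,
    identify_innovations,
    kalman_filter,
    particle_filter,
    resample,
    simulate_measurements,
    simulate_states,
)
from ordssm.dynamics import IdentifiedCovariances


class TestResample:
    def test_systematic_equal_weights_is_permutation(self):
        idx = resample(np.zeros(64), 64, scheme="systematic", seed=1)
        np.testing.assert_array_equal(np.sort(idx), np.arange(64))

    def test_degenerate_one_hot(self):
        lw = np.full(10, -np.inf)
        lw[3] = 0.0
        for scheme in ("systematic", "multinomial"):
            idx = resample(lw, 10, scheme=scheme, seed=2)
            assert np.all(idx == 3)

    def test_multinomial_counts_match_weights(self):
        w = np.array([0.5, 0.3, 0.15, 0.05])
        n = 100_000
        idx = resample(np.log(w), n, scheme="multinomial", seed=3)
        counts = np.bincount(idx, minlength=4) / n
        se = np.sqrt(w * (1 - w) / n)
        assert np.all(np.abs(counts - w) < 3 * se)

    def test_all_impossible_raises(self):
        with pytest.raises(DegeneracyError):
            resample(np.full(5, -np.inf), 5)


class TestParticleFilterDeterministicLimit:
    def test_zero_innovation_tracks_deterministic_path(self, a_tri, grm_pair_model):
        """With Sigma forced to 0 and a common start, every particle follows
        x_{t+1} = A x_t exactly, so the filtered mean is that trajectory."""
        T = 12
        y = np.ones((T, 2), dtype=np.int64)
        x0 = np.array([1.0, -0.5])
        out = particle_filter(
            y, a_tri, grm_pair_model, K=50, seed=0, sigma=np.zeros(2), x0=x0
        )
        path = np.empty((T, 2))
        x = x0.copy()
        for t in range(T):
            x = a_tri @ x
            path[t] = x
        np.testing.assert_allclose(out.filtered_means, path, atol=1e-12)

    def test_reproducible(self, a_tri, grm_pair_model):
        traj = simulate_states(a_tri, 30, 1)
        y = simulate_measurements(traj, grm_pair_model, 2)
        o1 = particle_filter(y, a_tri, grm_pair_model, K=200, seed=5)
        o2 = particle_filter(y, a_tri, grm_pair_model, K=200, seed=5)
        assert o1.loglik == o2.loglik
        np.testing.assert_array_equal(o1.filtered_means, o2.filtered_means)


@pytest.fixture(scope="module")
def linear_dataset(a_tri, linear_six_model):
    traj = simulate_states(a_tri, 50, 21)
    y = simulate_measurements(traj, linear_six_model, 22)
    covs = identify_innovations(a_tri)
    return traj, y, covs


class TestKalmanOracle:
    def test_pf_matches_kalman_loglik(self, a_tri, linear_six_model, linear_dataset):
        _, y, covs = linear_dataset
        kf = kalman_filter(y, a_tri, covs, linear_six_model)
        lls = np.array([
            particle_filter(y, a_tri, linear_six_model, K=5000, seed=s).loglik
            for s in range(20)
        ])
        assert abs(lls.mean() - kf.loglik) < 3 * lls.std()

    def test_pf_likelihood_nearly_unbiased(self, a_tri, linear_six_model):
        """exp of PF loglik is an unbiased likelihood estimate: over seeds,
        the normalized likelihood ratios vs the exact value center on 1."""
        traj = simulate_states(a_tri, 15, 31)
        y = simulate_measurements(traj, linear_six_model, 32)
        covs = identify_innovations(a_tri)
        kf = kalman_filter(y, a_tri, covs, linear_six_model)
        lls = np.array([
            particle_filter(y, a_tri, linear_six_model, K=2000, seed=s).loglik
            for s in range(40)
        ])
        ratios = np.exp(lls - kf.loglik)
        assert 0.8 < ratios.mean() < 1.2

    def test_pf_means_converge_to_kalman(self, a_tri, linear_six_model, linear_dataset):
        _, y, covs = linear_dataset
        kf = kalman_filter(y, a_tri, covs, linear_six_model)
        mads = []
        for K in (100, 1000, 10000):
            pf = particle_filter(y, a_tri, linear_six_model, K=K, seed=7)
            mads.append(np.mean(np.abs(pf.filtered_means - kf.filtered_means)))
        assert mads[2] < mads[0]
        assert mads[2] < 0.05

    def test_kalman_vs_joint_gaussian_brute_force(self, a_tri, linear_six_model):
        """T=3: the likelihood equals the density of the joint 18-dim normal
        of the stacked observations, built directly from the model."""
        T, p, q = 3, 2, 6
        covs = identify_innovations(a_tri)
        traj = simulate_states(a_tri, T, 41)
        y = simulate_measurements(traj, linear_six_model, 42)
        # state covariances: x_1 has P1 = A P0 A' + Sigma with P0 = I (filter prior)
        Ps = {}
        P = a_tri @ a_tri.T + covs.Sigma
        cov_x = np.zeros((T * p, T * p))
        cov_x[:p, :p] = P
        for t in range(1, T):
            cov_x[t * p:(t + 1) * p, t * p:(t + 1) * p] = (
                a_tri @ cov_x[(t - 1) * p:t * p, (t - 1) * p:t * p] @ a_tri.T + covs.Sigma
            )
        for s in range(T):
            for t in range(s + 1, T):
                blk = cov_x[s * p:(s + 1) * p, s * p:(s + 1) * p]
                for _ in range(t - s):
                    blk = blk @ a_tri.T
                cov_x[s * p:(s + 1) * p, t * p:(t + 1) * p] = blk
                cov_x[t * p:(t + 1) * p, s * p:(s + 1) * p] = blk.T
        C = np.zeros((q, p))
        for i, it in enumerate(linear_six_model.items):
            C[i, it.state_index - 1] = it.loading
        Cbig = np.kron(np.eye(T), C)
        R = np.diag([it.error_var for it in linear_six_model.items])
        cov_y = Cbig @ cov_x @ Cbig.T + np.kron(np.eye(T), R)
        expected = stats.multivariate_normal.logpdf(y.flatten(), mean=np.zeros(T * q), cov=cov_y)
        kf = kalman_filter(y, a_tri, covs, linear_six_model)
        assert kf.loglik == pytest.approx(expected, rel=1e-9)

    def test_zero_loadings_no_information(self, a_tri):
        model = MeasurementModel(
            kind="linear",
            items=tuple(LinearItem(f"m{i}", 1 + i % 2, 0.0, 2.0) for i in range(4)),
        )
        covs = identify_innovations(a_tri)
        rng = np.random.default_rng(0)
        y = rng.standard_normal((20, 4))
        kf = kalman_filter(y, a_tri, covs, model)
        np.testing.assert_allclose(kf.filtered_means, 0.0, atol=1e-12)
        iid = stats.norm.logpdf(y, scale=np.sqrt(2.0)).sum()
        assert kf.loglik == pytest.approx(iid, rel=1e-12)

    def test_scalar_riccati_steady_state(self):
        """1-state model: the filtered variance settles at the Riccati fixed
        point."""
        a, lam, r = 0.8, 1.0, 0.5
        A = np.array([[a]])
        covs = identify_innovations(A)
        sig = covs.sigma_diag[0]
        model = MeasurementModel(kind="linear", items=(LinearItem("m", 1, lam, r),))
        rng = np.random.default_rng(11)
        y = rng.standard_normal((400, 1))
        kf = kalman_filter(y, A, covs, model)
        Pf = 1.0
        for _ in range(1000):
            Pp = a * a * Pf + sig
            Pf = Pp - (Pp * lam) ** 2 / (lam * lam * Pp + r)
        assert kf.filtered_covs[-1, 0, 0] == pytest.approx(Pf, rel=1e-8)

    def test_missing_rows_dropped(self, a_tri, linear_six_model, linear_dataset):
        _, y, covs = linear_dataset
        y2 = y.copy().astype(float)
        y2[5, :3] = np.nan
        y2[9, :] = np.nan
        kf = kalman_filter(y2, a_tri, covs, linear_six_model)
        assert np.isfinite(kf.loglik)
        pf = particle_filter(y2, a_tri, linear_six_model, K=4000, seed=3)
        assert abs(pf.loglik - kf.loglik) < 3.0


class TestMeasurementInformativeness:
    def test_sharper_items_recover_states_better(self, a_tri):
        """Raising discrimination never hurts median recovery (matched seeds),
        and a near-noiseless GR battery pins the states."""
        traj = simulate_states(a_tri, 200, 51)
        medians = []
        for alpha in (0.5, 2.0, 8.0):
            items = tuple(
                GRMItem(f"g{s}{k}", s, alpha, np.linspace(-2, 2, 9))
                for s in (1, 2) for k in range(3)
            )
            model = MeasurementModel(kind="grm", items=items)
            corrs = []
            for seed in range(5):
                y = simulate_measurements(traj, model, 100 + seed)
                out = particle_filter(y, a_tri, model, K=800, seed=seed)
                corrs.append(np.mean([
                    np.corrcoef(out.filtered_means[:, j], traj.states[:, j])[0, 1]
                    for j in range(2)
                ]))
            medians.append(np.median(corrs))
        assert medians[1] >= medians[0] - 0.02
        assert medians[2] >= medians[1] - 0.02

    def test_near_noiseless_limit(self, a_tri):
        traj = simulate_states(a_tri, 200, 61)
        items = tuple(
            GRMItem(f"g{s}{k}", s, 50.0, np.linspace(-2.5, 2.5, 21))
            for s in (1, 2) for k in range(2)
        )
        model = MeasurementModel(kind="grm", items=items)
        y = simulate_measurements(traj, model, 62)
        out = particle_filter(y, a_tri, model, K=2000, seed=63)
        for j in range(2):
            r = stats.pearsonr(out.filtered_means[:, j], traj.states[:, j]).statistic
            assert r > 0.95
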