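"""Parameter encoding, cooling, and the iterated-filtering estimator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ordssm import (
    MIF2Config,
    ParameterError,
    cooling_sd,
    decode_params,
    decode_thresholds,
    default_init,
    encode_linear_params,
    encode_params,
    encode_thresholds,
    fit,
    grm_condition_model,
    make_condition_dataset,
    mif2_run,
    model_at,
    particle_filter,
    pf_loglik,
    preset_desk,
    SimCondition,
)
from ordssm.mif2 import _canonicalize_linear_signs
from ordssm.study import linear_structure_model


class TestParameterEncoding:
    def test_initial_value_convention(self):
        """First threshold -2, interval .36 on the log scale."""
        block = encode_thresholds([-2.0, -1.64])
        assert block[0] == -2.0
        assert block[1] == pytest.approx(np.log(0.36))
        np.testing.assert_allclose(decode_thresholds(block), [-2.0, -1.64])

    @given(
        first=st.floats(-5, 5),
        logd=st.lists(st.floats(-3, 2), min_size=1, max_size=6),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_round_trip_and_order_preservation(self, first, logd):
        block = np.array([first] + logd)
        beta = decode_thresholds(block)
        assert np.all(np.diff(beta) > 0)
        np.testing.assert_allclose(encode_thresholds(beta), block, atol=1e-9)

    def test_encode_rejects_unordered(self):
        with pytest.raises(ParameterError):
            encode_thresholds([0.0, 0.0])

    def test_grm_round_trip(self):
        A = np.array([[0.4, 0.1], [0.0, 0.5]])
        thresholds = [np.array([-1.0, 0.5]), np.array([-0.2, 0.1, 2.0])]
        pv = encode_params(A, thresholds)
        A2, thr2 = decode_params(pv)
        np.testing.assert_allclose(A2, A)
        for a, b in zip(thr2, thresholds):
            np.testing.assert_allclose(a, b)

    def test_linear_round_trip(self):
        pv = encode_linear_params(np.diag([0.1, 0.1]), [1.0, -0.5], [0.5, 2.0])
        A2, (lam, v) = decode_params(pv)
        np.testing.assert_allclose(lam, [1.0, -0.5])
        np.testing.assert_allclose(v, [0.5, 2.0])

    def test_default_init_matches_protocol(self):
        model = grm_condition_model(3, 7, "equal")
        pv = default_init(model, estimate_measurement=True)
        A, thr = decode_params(pv)
        np.testing.assert_allclose(A, np.diag([0.1, 0.1]))
        for beta in thr:
            assert beta[0] == -2.0
            np.testing.assert_allclose(np.diff(beta), 0.36)


class TestCooling:
    def test_first_iteration_is_base(self):
        assert cooling_sd(1, 0.3, 0.05) == 0.3
        assert cooling_sd(1, 0.3, 0.05, on_sd=True) == 0.3

    def test_variance_convention_after_50(self):
        sd = cooling_sd(51, 0.3, 0.05)
        assert sd**2 == pytest.approx(0.05 * 0.3**2)

    def test_sd_convention_after_50(self):
        assert cooling_sd(51, 0.3, 0.05, on_sd=True) == pytest.approx(0.05 * 0.3)

    def test_strictly_decreasing_to_zero(self):
        seq = [cooling_sd(m, 0.3, 0.05) for m in range(1, 400)]
        assert np.all(np.diff(seq) < 0)
        assert seq[-1] < 1e-3


class TestSignCanonicalization:
    def test_flipped_state_is_restored(self):
        pv = encode_linear_params(
            np.array([[0.3, 0.2], [-0.1, 0.4]]), [-1.0, -0.8, 0.9, 1.1], [1.0] * 4
        )
        out = _canonicalize_linear_signs(pv, np.array([0, 0, 1, 1]))
        A, (lam, _) = decode_params(out)
        np.testing.assert_allclose(lam, [1.0, 0.8, 0.9, 1.1])
        # one state flipped: off-diagonals change sign, diagonals do not
        np.testing.assert_allclose(A, [[0.3, -0.2], [0.1, 0.4]])

    def test_noop_when_already_canonical(self):
        pv = encode_linear_params(np.diag([0.3, 0.4]), [1.0, 1.0], [1.0, 1.0])
        out = _canonicalize_linear_signs(pv, np.array([0, 1]))
        np.testing.assert_array_equal(out.values, pv.values)


@pytest.fixture(scope="module")
def small_grm_dataset():
    cond = SimCondition(T=60, items_per_state=3, J=3, AR=0.5, CR=0.2,
                        thresholds="equal", replicate_seed=314)
    return make_condition_dataset(cond)


class TestMIF2Run:
    def test_zero_perturbation_returns_init(self, small_grm_dataset):
        _, y, model = small_grm_dataset
        init = default_init(model, estimate_measurement=True)
        cfg = MIF2Config(K=100, M=3, perturb_sd=0.0, n_runs=1, seed=0)
        est, trace = mif2_run(y, model, init, cfg, run_seed=5)
        # identical up to summation round-off in the swarm mean
        np.testing.assert_allclose(est.values, init.values, rtol=0, atol=1e-13)
        assert trace.shape == (3,)

    def test_zero_perturbation_reduces_to_particle_filter(self, small_grm_dataset):
        """With a frozen swarm each iteration is an ordinary particle filter
        at the initial parameters."""
        _, y, model = small_grm_dataset
        init = default_init(model, estimate_measurement=False)
        cfg = MIF2Config(K=400, M=4, perturb_sd=0.0, n_runs=1,
                         seed=0, estimate_measurement=False)
        _, trace = mif2_run(y, model, init, cfg, run_seed=5)
        lls = [particle_filter(y, init.A, model, K=400, seed=s).loglik for s in range(12)]
        assert np.all(np.abs(trace - np.mean(lls)) < 5 * np.std(lls) + 1e-9)

    def test_loglik_climbs(self, small_grm_dataset):
        _, y, model = small_grm_dataset
        init = default_init(model, estimate_measurement=True)
        up = 0
        for s in range(5):
            cfg = MIF2Config(K=200, M=25, n_runs=1, seed=s)
            _, trace = mif2_run(y, model, init, cfg, run_seed=s)
            up += trace[-1] > trace[0]
        assert up >= 4


class TestFit:
    def test_single_run_average_is_identity(self, small_grm_dataset):
        _, y, model = small_grm_dataset
        cfg = MIF2Config(K=150, M=8, n_runs=1, seed=3)
        res = fit(y, model, cfg)
        np.testing.assert_array_equal(
            res.averaged_estimate.values, res.per_run_estimates[0].values
        )
        assert res.final_filter.filtered_means.shape == (60, 2)

    def test_deterministic(self, small_grm_dataset):
        _, y, model = small_grm_dataset
        cfg = MIF2Config(K=100, M=5, n_runs=2, seed=9)
        r1 = fit(y, model, cfg)
        r2 = fit(y, model, cfg)
        np.testing.assert_array_equal(
            r1.averaged_estimate.values, r2.averaged_estimate.values
        )
        assert r1.final_filter.loglik == r2.final_filter.loglik

    def test_linear_fit_estimates_loadings(self, small_grm_dataset):
        _, y, model = small_grm_dataset
        lin = linear_structure_model(model)
        cfg = MIF2Config(K=150, M=10, n_runs=1, seed=4)
        res = fit(y.astype(float), lin, cfg)
        A, (lam, v) = decode_params(res.averaged_estimate)
        assert lam.shape == (6,) and np.all(v > 0)
        # canonical representative: nonnegative loading sums per state
        assert lam[:3].sum() >= 0 and lam[3:].sum() >= 0

    def test_model_at_materializes_estimate(self, small_grm_dataset):
        _, y, model = small_grm_dataset
        cfg = MIF2Config(K=100, M=5, n_runs=1, seed=2)
        res = fit(y, model, cfg)
        m2 = model_at(res.averaged_estimate, model)
        _, thr = decode_params(res.averaged_estimate)
        for it, beta in zip(m2.items, thr):
            np.testing.assert_allclose(it.beta, beta)
        # pf_loglik at the estimate is reproducible and finite
        ll = pf_loglik(y, model, res.averaged_estimate, K=200, seed=1)
        assert np.isfinite(ll)

    def test_config_validation(self):
        with pytest.raises(ParameterError):
            MIF2Config(K=1)
        with pytest.raises(ParameterError):
            MIF2Config(cooling_fraction_50=1.5)
        with pytest.raises(ParameterError):
            MIF2Config(perturb_sd=-0.1)
        assert preset_desk().K == 500
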