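"""The data-generating model: threshold builders, state and measurement
simulation, and the study grid."""

import numpy as np
import pytest

from ordssm import (
    GRMItem,
    LinearItem,
    MeasurementModel,
    ParameterError,
    SimCondition,
    condition_grid,
    equal_thresholds,
    grm_condition_model,
    identify_innovations,
    make_condition_dataset,
    offset_thresholds,
    replicate_seed,
    simulate_measurements,
    simulate_states,
)
from ordssm.synthetic import marginal_category_probs


class TestThresholdBuilders:
    @pytest.mark.parametrize(
        "J, expected",
        [
            (7, [-2.5, -1.5, -0.5, 0.5, 1.5, 2.5]),
            (2, [0.0]),
            (3, [-0.5, 0.5]),
        ],
    )
    def test_equal(self, J, expected):
        np.testing.assert_array_equal(equal_thresholds(J), expected)

    def test_equal_rejects_degenerate(self):
        with pytest.raises(ParameterError):
            equal_thresholds(1)

    def test_offset_three_items_seven_categories(self):
        got = offset_thresholds(3, 7)
        np.testing.assert_array_equal(got[0], [-3, -2, -1, 0, 1, 2])
        np.testing.assert_array_equal(got[1], [-2.5, -1.5, -0.5, 0.5, 1.5, 2.5])
        np.testing.assert_array_equal(got[2], [-2, -1, 0, 1, 2, 3])

    def test_offset_single_item(self):
        np.testing.assert_array_equal(offset_thresholds(1, 5)[0], equal_thresholds(5))

    def test_offset_cap_rule(self):
        # 6 items, J=3: raw offset 6/2 = 3 is capped at 1.25
        got = offset_thresholds(6, 3)
        centers = [v.mean() for v in got]
        np.testing.assert_allclose(np.diff(centers), 1.25)
        np.testing.assert_allclose(centers[0], -3.125)
        np.testing.assert_allclose(centers[-1], 3.125)
        # the whole set is symmetric about 0
        flat = np.sort(np.concatenate(got))
        np.testing.assert_allclose(flat + flat[::-1], 0, atol=1e-12)


class TestSimulateStates:
    def test_no_dynamics_iid(self):
        traj = simulate_states(np.zeros((2, 2)), 20000, 5)
        assert traj.states.shape == (20000, 2)
        np.testing.assert_allclose(traj.states.mean(axis=0), 0, atol=0.05)
        np.testing.assert_allclose(np.cov(traj.states.T), np.eye(2), atol=0.05)

    def test_deterministic_under_seed(self, a_tri):
        s1 = simulate_states(a_tri, 200, 42).states
        s2 = simulate_states(a_tri, 200, 42).states
        np.testing.assert_array_equal(s1, s2)
        assert not np.array_equal(s1, simulate_states(a_tri, 200, 43).states)

    def test_yule_walker_moments(self, a_tri):
        """Long-run sample variance 1 and lag-1 autocovariance (A Gamma)."""
        traj = simulate_states(a_tri, 100_000, 9)
        covs = identify_innovations(a_tri)
        np.testing.assert_allclose(traj.states.var(axis=0), 1.0, atol=0.02)
        lag1 = np.mean(traj.states[1:, 1] * traj.states[:-1, 1])
        expected = (a_tri @ covs.Gamma)[1, 1]
        assert lag1 == pytest.approx(expected, abs=0.02)


class TestSimulateMeasurements:
    def test_saturated_binary_item(self, a_tri):
        traj = simulate_states(a_tri, 500, 3)
        model = MeasurementModel(
            kind="grm", items=(GRMItem("sat", 1, 1.0, np.array([-100.0])),)
        )
        y = simulate_measurements(traj, model, 4)
        assert np.all(y == 2)

    def test_linear_noise_free(self, a_tri):
        traj = simulate_states(a_tri, 300, 6)
        model = MeasurementModel(
            kind="linear", items=(LinearItem("m", 2, 1.7, 1e-18),)
        )
        y = simulate_measurements(traj, model, 7)
        np.testing.assert_allclose(y[:, 0], 1.7 * traj.states[:, 1], atol=1e-6)

    def test_marginal_category_frequencies(self, a_tri):
        """Generated category frequencies match quadrature over the
        stationary N(0,1) state law within 3 binomial SEs."""
        T = 100_000
        traj = simulate_states(a_tri, T, 12)
        item = GRMItem("i", 1, 1.0, equal_thresholds(5))
        model = MeasurementModel(kind="grm", items=(item,))
        y = simulate_measurements(traj, model, 13)
        expected = marginal_category_probs(item)
        for j in range(5):
            freq = np.mean(y[:, 0] == j + 1)
            se = np.sqrt(expected[j] * (1 - expected[j]) / T)
            # wider than iid binomial: states are autocorrelated
            assert abs(freq - expected[j]) < 3 * se * np.sqrt(1 + 2 * 0.7 / 0.3)


class TestConditionDatasets:
    def test_equal_condition_composition(self):
        cond = SimCondition(T=100, items_per_state=3, J=3, AR=0.3, CR=0.0,
                            thresholds="equal", replicate_seed=1)
        traj, y, model = make_condition_dataset(cond)
        assert model.q == 6
        for it in model.items:
            np.testing.assert_array_equal(it.beta, [-0.5, 0.5])
            assert it.alpha == 1.0
        assert y.shape == (100, 6)
        assert set(np.unique(y)) <= {1, 2, 3}
        np.testing.assert_allclose(np.linalg.eigvals(traj.A_true), [0.3, 0.3])

    def test_offset_condition_items_differ_within_state(self):
        model = grm_condition_model(3, 7, "offset")
        betas = [it.beta for it in model.items[:3]]
        assert not np.array_equal(betas[0], betas[1])
        # both states carry identical item sets
        for a, b in zip(model.items[:3], model.items[3:]):
            np.testing.assert_array_equal(a.beta, b.beta)
            assert a.state_index == 1 and b.state_index == 2

    def test_grid_is_fully_crossed(self):
        grid = condition_grid()
        assert len(grid) == 64
        assert len({c.label for c in grid}) == 64

    def test_replicate_seed_pure_and_distinct(self):
        s = replicate_seed(1, 2, 3)
        assert s == replicate_seed(1, 2, 3)
        assert 0 <= s < 2**31
        assert len({replicate_seed(1, c, r) for c in range(8) for r in range(50)}) == 400

    def test_condition_reproducible(self):
        cond = SimCondition(replicate_seed=77)
        _, y1, _ = make_condition_dataset(cond)
        _, y2, _ = make_condition_dataset(cond)
        np.testing.assert_array_equal(y1, y2)
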