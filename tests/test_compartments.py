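import json

import numpy as np
import pytest

from socpools.compartments import (PoolModelSpec, build_system_matrix,
                                   predict_cumulative_co2, solve_pools,
                                   two_pool_spec)
from socpools.curves import SAMPLING_DAYS

from conftest import euler_trajectory, random_stable_spec


class TestSystemMatrix:
    def test_fixed_transfer_two_pool_structure(self):
        # forward 0.85, feedback 0.15: A = [[-k1, 0.15 k2], [0.85 k1, -k2]]
        spec = two_pool_spec(gamma1=0.1, k1=0.1, k2=0.01, c_init=1e4)
        A = build_system_matrix(spec)
        np.testing.assert_allclose(
            A, [[-0.1, 0.15 * 0.01], [0.85 * 0.1, -0.01]])

    def test_no_transfers_gives_diagonal(self):
        spec = PoolModelSpec(k=[0.3, 0.02], alpha=np.zeros((2, 2)),
                             gamma=[0.4, 0.6], c_init=100.0)
        np.testing.assert_allclose(build_system_matrix(spec),
                                   np.diag([-0.3, -0.02]))

    def test_three_pool_matches_index_oracle(self, rng):
        for _ in range(10):
            spec = random_stable_spec(rng, 3)
            A = build_system_matrix(spec)
            # hand-coded elementwise construction of the series/feedback system
            k, a = spec.k, spec.alpha
            expected = np.array([
                [-k[0], a[0, 1] * k[1], 0.0],
                [a[1, 0] * k[0], -k[1], a[1, 2] * k[2]],
                [0.0, a[2, 1] * k[1], -k[2]],
            ])
            np.testing.assert_allclose(A, expected)

    @pytest.mark.parametrize("bad", [
        dict(k=[-0.1, 0.01]),                       # non-positive rate
        dict(gamma=[0.6, 0.6]),                     # gamma does not sum to 1
        dict(c_init=0.0),                           # no initial carbon
        dict(alpha=np.array([[0, 0.2], [1.2, 0]])),  # alpha > 1
    ])
    def test_invalid_specs_rejected(self, bad):
        base = dict(k=[0.1, 0.01], alpha=np.array([[0, 0.15], [0.85, 0]]),
                    gamma=[0.1, 0.9], c_init=1e4)
        base.update(bad)
        with pytest.raises(ValueError):
            PoolModelSpec(**base)

    def test_non_adjacent_transfer_rejected(self):
        alpha = np.zeros((3, 3))
        alpha[2, 0] = 0.3  # pool 1 -> pool 3 skips the chain
        with pytest.raises(ValueError, match="topology"):
            PoolModelSpec(k=[0.1, 0.01, 0.001], alpha=alpha,
                          gamma=[0.2, 0.5, 0.3], c_init=1e4)


class TestSolvePools:
    def test_single_pool_closed_form(self):
        spec = PoolModelSpec(k=[0.2, 0.01], alpha=np.zeros((2, 2)),
                             gamma=[1.0, 0.0], c_init=500.0)
        t = np.array([0.0, 1.0, 5.0, 30.0, 90.0])
        traj = solve_pools(spec, t)
        np.testing.assert_allclose(traj.pools[:, 0], 500 * np.exp(-0.2 * t),
                                   rtol=1e-12)
        np.testing.assert_allclose(traj.cumulative_respired,
                                   500 * (1 - np.exp(-0.2 * t)), rtol=1e-10,
                                   atol=1e-10)

    def test_initial_condition(self, rng):
        spec = random_stable_spec(rng, 2)
        traj = solve_pools(spec, np.array([0.0, 1.0]))
        np.testing.assert_allclose(traj.pools[0], spec.c_init * spec.gamma)
        assert traj.cumulative_respired[0] == 0.0

    @pytest.mark.parametrize("n_pools", [2, 3])
    def test_matches_fine_step_euler(self, rng, n_pools):
        days = np.array([0.0, 10.0, 45.0, 90.0])
        for _ in range(3):
            spec = random_stable_spec(rng, n_pools)
            traj = solve_pools(spec, days)
            oracle = euler_trajectory(spec, days, dt=1e-3)
            rel = np.abs(traj.pools - oracle) / spec.c_init
            assert rel.max() < 1e-4

    def test_mass_conservation(self, rng):
        days = SAMPLING_DAYS
        for n_pools in (2, 3):
            for _ in range(5):
                spec = random_stable_spec(rng, n_pools)
                traj = solve_pools(spec, days)
                balance = traj.total + traj.cumulative_respired
                np.testing.assert_allclose(balance, spec.c_init,
                                           rtol=1e-8)

    def test_cumulative_respiration_strictly_increasing(self, rng):
        for _ in range(5):
            spec = random_stable_spec(rng, 2)
            traj = solve_pools(spec, SAMPLING_DAYS)
            assert np.all(np.diff(traj.cumulative_respired) > 0)

    def test_two_pool_embeds_in_three_pool(self, rng):
        spec2 = random_stable_spec(rng, 2)
        alpha3 = np.zeros((3, 3))
        alpha3[:2, :2] = spec2.alpha
        spec3 = PoolModelSpec(
            k=np.r_[spec2.k, 1e-3], alpha=alpha3,
            gamma=np.r_[spec2.gamma, 0.0], c_init=spec2.c_init)
        days = SAMPLING_DAYS
        t2 = solve_pools(spec2, days)
        t3 = solve_pools(spec3, days)
        assert np.max(np.abs(t2.pools - t3.pools[:, :2])) < 1e-10 * spec2.c_init

    def test_constant_inputs_reach_steady_state(self):
        spec = PoolModelSpec(k=[0.2, 0.02], alpha=np.zeros((2, 2)),
                             gamma=[0.5, 0.5], c_init=100.0,
                             inputs=[2.0, 0.4])
        traj = solve_pools(spec, np.array([0.0, 2000.0]))
        np.testing.assert_allclose(traj.pools[-1], [2.0 / 0.2, 0.4 / 0.02],
                                   rtol=1e-6)

    def test_times_must_start_at_zero(self, rng):
        spec = random_stable_spec(rng, 2)
        with pytest.raises(ValueError):
            solve_pools(spec, np.array([1.0, 2.0]))


class TestPredictCumulativeCo2:
    def test_default_schedule_has_25_points(self, rng):
        curve = predict_cumulative_co2(random_stable_spec(rng, 2))
        assert len(curve) == 25
        assert curve.days[0] == 0 and curve.days[-1] == 90

    def test_equal_rates_single_pool_collapse(self):
        # gamma1 = 1 with no transfers is a single exponential accumulation
        spec = PoolModelSpec(k=[0.05, 0.05], alpha=np.zeros((2, 2)),
                             gamma=[1.0, 0.0], c_init=2e3)
        curve = predict_cumulative_co2(spec)
        np.testing.assert_allclose(
            curve.values, 2e3 * (1 - np.exp(-0.05 * curve.days)),
            rtol=1e-10, atol=1e-8)

    def test_cannot_respire_more_than_initial_carbon(self, rng):
        for _ in range(10):
            spec = random_stable_spec(rng, 2)
            curve = predict_cumulative_co2(spec)
            assert curve.values[-1] < spec.c_init

    def test_empty_schedule_rejected(self, rng):
        with pytest.raises(ValueError):
            predict_cumulative_co2(random_stable_spec(rng, 2), [])


def test_spec_json_roundtrip(rng):
    spec = random_stable_spec(rng, 3)
    restored = PoolModelSpec.from_json(spec.to_json())
    np.testing.assert_allclose(restored.k, spec.k)
    np.testing.assert_allclose(restored.alpha, spec.alpha)
    np.testing.assert_allclose(restored.gamma, spec.gamma)
    assert json.loads(spec.to_json())["n_pools"] == 3


def test_trajectory_frame_layout(rng):
    spec = random_stable_spec(rng, 2)
    frame = solve_pools(spec, SAMPLING_DAYS).to_frame()
    assert list(frame.columns) == ["time", "pool_1", "pool_2", "total",
                                   "cum_co2"]
    assert len(frame) == 25
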