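"""Deterministic model construction, integration and oscillation calls."""

import numpy as np
import pytest

import oscreen as oc
from oscreen.dynamics import IntegrationError, stability_rate_bound
from tests.conftest import unregulated_gene_params


def random_parameter_set(t, seed=0):
    from oscreen.screen import SamplerConfig, sample_parameter_set

    return sample_parameter_set(SamplerConfig(), t, np.random.default_rng(seed))


class TestParameterSet:
    def test_delta_rule_enforced(self, activator_inhibitor):
        n = 2
        v = np.array([[1.0, 1.0], [0.0, 0.0]])
        K = np.array([[1.0, 1.0], [1.0, 0.0]])
        r = np.array([0.1, 0.1])
        # gene A has an activator (itself): delta_A must be zero
        with pytest.raises(ValueError, match="delta"):
            oc.ParameterSet(
                activator_inhibitor, v, K, np.array([1.0, 0.0]), r, k_basal=0.01
            )
        # gene B has an activator: fine with delta_B = 0
        oc.ParameterSet(
            activator_inhibitor, v, K, np.array([0.0, 0.0]), r, k_basal=0.01
        )

    def test_missing_link_parameter_rejected(self, activator_inhibitor):
        v = np.array([[1.0, 0.0], [0.0, 0.0]])  # missing v for A->B
        K = np.array([[1.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="production rate"):
            oc.ParameterSet(
                activator_inhibitor, v, K, np.zeros(2), np.array([0.1, 0.1]),
                k_basal=0.01,
            )

    def test_flat_dict_round_trip(self, activator_inhibitor):
        p = random_parameter_set(activator_inhibitor, seed=3)
        q = oc.ParameterSet.from_flat_dict(activator_inhibitor, p.to_flat_dict())
        assert np.allclose(p.v, q.v) and np.allclose(p.K, q.K)
        assert np.allclose(p.delta, q.delta) and np.allclose(p.r, q.r)

    def test_hill_exponent_fixed(self, activator_inhibitor):
        p = random_parameter_set(activator_inhibitor)
        with pytest.raises(ValueError, match="Hill"):
            oc.ParameterSet(
                p.topology, p.v, p.K, p.delta, p.r, p.k_basal, hill_n=2
            )


class TestRhs:
    def test_unregulated_gene_closed_form(self):
        t, p = unregulated_gene_params(delta=2.0, r=0.2, k_basal=0.01)
        rhs = oc.build_rhs(t, p)
        x = np.array([3.0, 0.0])
        # dA/dt = k_basal + delta - r A
        assert rhs(x)[0] == pytest.approx(0.01 + 2.0 - 0.2 * 3.0)
        x_star = (0.01 + 2.0) / 0.2
        assert rhs(np.array([x_star, 0.0]))[0] == pytest.approx(0.0, abs=1e-12)

    def test_half_occupancy_production(self):
        # gene A self-activated and inhibited by B, both at their K:
        # production = k_basal + v_AA / 3
        t = oc.SignedTopology.from_links(2, [("A", "A", 1), ("B", "A", -1), ("A", "B", 1)])
        v = np.array([[2.0, 1.0], [0.0, 0.0]])
        K = np.array([[0.7, 1.0], [1.3, 0.0]])
        p = oc.ParameterSet(t, v, K, np.zeros(2), np.array([0.1, 0.1]), k_basal=0.01)
        rhs = oc.build_rhs(t, p)
        x = np.array([0.7, 1.3])  # A = K_AA, B = K_BA
        production_A = rhs(x)[0] + p.r[0] * x[0]
        assert production_A == pytest.approx(0.01 + 2.0 / 3.0, rel=1e-12)

    def test_rhs_matches_independent_recomputation(self, repressilator):
        p = random_parameter_set(repressilator, seed=7)
        rhs = oc.build_rhs(repressilator, p)
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.uniform(0.0, 20.0, 3)
            expected = np.empty(3)
            for j in range(3):
                num, den = p.delta[j], 1.0
                for i in range(3):
                    s = repressilator.sign(i, j)
                    if s != 0:
                        h = (x[i] / p.K[i, j]) ** 3
                        den += h
                        if s > 0:
                            num += p.v[i, j] * h
                expected[j] = p.k_basal + num / den - p.r[j] * x[j]
            assert np.allclose(rhs(x), expected, rtol=1e-12)

    def test_jacobian_matches_finite_differences(self, repressilator):
        p = random_parameter_set(repressilator, seed=11)
        rhs = oc.build_rhs(repressilator, p)
        jac = oc.build_jacobian(repressilator, p)
        x = np.array([1.3, 0.4, 2.2])
        J = jac(x)
        eps = 1e-6
        for m in range(3):
            dx = np.zeros(3)
            dx[m] = eps
            col = (rhs(x + dx) - rhs(x - dx)) / (2 * eps)
            assert np.allclose(J[:, m], col, rtol=1e-5, atol=1e-8)

    def test_production_bounded_by_saturation(self, repressilator):
        # k_basal <= production <= k_basal + max(v, delta)
        p = random_parameter_set(repressilator, seed=5)
        rhs = oc.build_rhs(repressilator, p)
        rng = np.random.default_rng(1)
        hi = max(p.v.max(), p.delta.max())
        for _ in range(20):
            x = rng.uniform(0, 50, 3)
            production = rhs(x) + p.r * x
            assert np.all(production >= p.k_basal - 1e-12)
            assert np.all(production <= p.k_basal + hi + 1e-9)

    def test_mismatched_topology_rejected(self, repressilator, activator_inhibitor):
        p = random_parameter_set(repressilator)
        with pytest.raises(ValueError, match="different topology"):
            oc.build_rhs(activator_inhibitor, p)


class TestIntegration:
    def test_unregulated_monotone_approach(self):
        t, p = unregulated_gene_params(delta=2.0, r=0.2, k_basal=0.01)
        traj = oc.simulate_deterministic(t, p, t_end=100.0)
        a = traj.values[:, 0]
        assert np.all(np.diff(a) >= -1e-9)
        assert a[-1] == pytest.approx((0.01 + 2.0) / 0.2, rel=1e-4)

    def test_rk4_matches_lsoda(self, ai_oscillator):
        t, p = ai_oscillator
        rk4 = oc.simulate_deterministic(t, p, t_end=200.0)
        lsoda = oc.simulate_deterministic(t, p, t_end=200.0, method="lsoda")
        # phase-sensitive comparison on a chaotic-free smooth system
        assert np.allclose(rk4.values[:500], lsoda.values[:500], rtol=2e-3, atol=1e-4)

    def test_nonnegativity(self, repressilator):
        p = random_parameter_set(repressilator, seed=13)
        traj = oc.simulate_deterministic(repressilator, p, t_end=300.0)
        assert np.all(traj.values >= 0.0)

    def test_stability_bound_positive(self, repressilator):
        p = random_parameter_set(repressilator, seed=2)
        assert stability_rate_bound(repressilator, p) > 0


class TestDetectOscillation:
    def make_traj(self, f, t_end=1000.0, dt=0.1, n_nodes=3):
        times = np.arange(0.0, t_end + dt / 2, dt)
        vals = np.column_stack([f(times)] * n_nodes)
        return oc.Trajectory(times, vals)

    def test_constant_is_not_oscillatory(self):
        traj = self.make_traj(lambda t: np.full_like(t, 4.2))
        assert not oc.detect_oscillation(traj).oscillatory

    def test_damped_cosine_excluded(self):
        # ~10% amplitude decay per 20-unit cycle
        traj = self.make_traj(
            lambda t: 5 + 50 * np.exp(-0.005 * t) * np.cos(2 * np.pi * t / 20)
        )
        assert not oc.detect_oscillation(traj).oscillatory

    def test_clean_sinusoid(self):
        traj = self.make_traj(lambda t: 5 + np.sin(2 * np.pi * t / 20))
        feats = oc.detect_oscillation(traj)
        assert feats.oscillatory
        assert feats.period_T == pytest.approx(20.0, rel=1e-4)
        assert feats.amplitude == pytest.approx(6.0, rel=1e-6)

    def test_time_shift_invariance(self):
        base = self.make_traj(lambda t: 5 + np.sin(2 * np.pi * t / 17))
        shifted = self.make_traj(lambda t: 5 + np.sin(2 * np.pi * (t + 4.31) / 17))
        f0 = oc.detect_oscillation(base)
        f1 = oc.detect_oscillation(shifted)
        assert f0.oscillatory and f1.oscillatory
        assert f0.period_T == pytest.approx(f1.period_T, rel=1e-4)
        assert f0.amplitude == pytest.approx(f1.amplitude, rel=1e-6)

    def test_short_trajectory_rejected(self):
        traj = self.make_traj(lambda t: np.sin(t), t_end=500.0)
        with pytest.raises(ValueError, match="window"):
            oc.detect_oscillation(traj)

    def test_fixture_oscillator_detected(self, ai_features):
        _traj, feats, _x0 = ai_features
        assert feats.oscillatory and feats.period_T > 0 and feats.amplitude > 0

    def test_b_peak_state(self, ai_features):
        traj, _feats, x0 = ai_features
        win = traj.window(700.0, 1000.0)
        assert x0[1] == pytest.approx(win.values[:, 1].max())


class TestTrajectoryIO:
    def test_csv_round_trip(self, tmp_path, ai_features):
        traj, _, _ = ai_features
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = oc.Trajectory.from_csv(path)
        assert np.allclose(back.times, traj.times)
        assert np.allclose(back.values, traj.values)

    def test_hdf5_round_trip(self, tmp_path, ai_features):
        traj, _, _ = ai_features
        path = tmp_path / "batch.h5"
        traj.to_hdf5(path, "run0")
        back = oc.Trajectory.from_hdf5(path, "run0")
        assert np.array_equal(back.times, traj.times)
        assert np.array_equal(back.values, traj.values)
        assert back.meta["kind"] == traj.meta["kind"]
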