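"""Mechanics: matrix assembly, impulse, and the two transient solvers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from toothtap.mechanics import (
    ImpulseSpec,
    SimConfig,
    SystemMatrices,
    ToothLayerParams,
    assemble_matrices,
    exact_lti_response,
    impulse_force,
    simulate_percussion,
)


def random_params(rng: np.random.Generator) -> ToothLayerParams:
    """A random positive parameter set within an order of magnitude of baseline."""
    base = ToothLayerParams().as_array()
    return ToothLayerParams.from_array(base * rng.uniform(0.3, 3.0, size=9))


class TestAssembly:
    def test_baseline_matrices(self, baseline_params):
        mat = assemble_matrices(baseline_params)
        assert np.array_equal(mat.M, np.diag([1.0, 1.5, 2.0]))
        assert np.array_equal(mat.K[1], [-1.0e7, 1.5e7, -5.0e6])
        assert np.array_equal(mat.K[2], [0.0, -5.0e6, 2.5e7])
        assert np.array_equal(mat.C[0], [50.0, -50.0, 0.0])

    def test_undamped_chain_has_zero_damping_matrix(self):
        mat = assemble_matrices(ToothLayerParams(c1=0.0, c2=0.0, c3=0.0))
        assert np.all(mat.C == 0.0)

    def test_symmetry_and_positive_definiteness(self, rng):
        for _ in range(20):
            mat = assemble_matrices(random_params(rng))
            assert np.array_equal(mat.K, mat.K.T)
            assert np.array_equal(mat.C, mat.C.T)
            assert np.all(np.linalg.eigvalsh(mat.K) > 0.0)

    @pytest.mark.parametrize("bad", [{"m1": 0.0}, {"k2": -1.0}, {"c3": -0.1}])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            ToothLayerParams(**bad)


class TestImpulse:
    @pytest.mark.parametrize(
        "t, expected_f1",
        [(5.0e-5, 1.0), (1.0e-4, 1.0), (2.0e-4, 0.0), (0.0, 1.0)],
    )
    def test_rectangular_profile(self, t, expected_f1):
        f = impulse_force(t, ImpulseSpec())
        assert f[0] == expected_f1
        assert f[1] == f[2] == 0.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            impulse_force(-1.0e-6)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ImpulseSpec(F0=-1.0)
        with pytest.raises(ValueError):
            ImpulseSpec(tau=0.0)


class TestSimulation:
    def test_grid_geometry(self, baseline_params, sim_cfg):
        traj = simulate_percussion(baseline_params, cfg=sim_cfg)
        assert len(traj.x1) == 2205
        assert sim_cfg.n_samples == 2205
        assert np.allclose(traj.times, np.arange(2205) / 44100.0)
        assert traj.x[0] == pytest.approx(0.0) and traj.v[0] == pytest.approx(0.0)
        assert np.all(np.isfinite(traj.x))

    def test_zero_forcing_gives_zero_trajectory(self, baseline_params):
        traj = simulate_percussion(baseline_params, ImpulseSpec(F0=0.0))
        assert np.all(traj.x == 0.0)
        exact = exact_lti_response(assemble_matrices(baseline_params), ImpulseSpec(F0=0.0))
        assert np.all(exact.x == 0.0)

    def test_linearity_in_force_amplitude(self, baseline_params):
        one = simulate_percussion(baseline_params, ImpulseSpec(F0=1.0), method="exact")
        two = simulate_percussion(baseline_params, ImpulseSpec(F0=2.0), method="exact")
        np.testing.assert_allclose(two.x1, 2.0 * one.x1, rtol=1e-12, atol=1e-18)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rk45_matches_exact_discretization(self, seed):
        params = random_params(np.random.default_rng(seed))
        rk = simulate_percussion(params, method="rk45")
        ex = exact_lti_response(assemble_matrices(params))
        scale = np.max(np.abs(ex.x1))
        assert np.max(np.abs(rk.x1 - ex.x1)) / scale < 1e-6

    def test_damped_envelope_non_increasing(self, baseline_params, sim_cfg):
        traj = simulate_percussion(baseline_params, method="exact")
        x1, t = np.abs(traj.x1), traj.times
        peaks = [
            x1[(t >= lo) & (t < lo + 0.005)].max()
            for lo in np.arange(0.005, 0.05, 0.005)
        ]
        assert np.all(np.diff(peaks) <= 0.0)

    def test_unknown_method_rejected(self, baseline_params):
        with pytest.raises(ValueError):
            simulate_percussion(baseline_params, method="euler")


class TestExactOracle:
    def test_undamped_energy_conserved_after_impulse(self, impulse, sim_cfg):
        mat = assemble_matrices(ToothLayerParams(c1=0.0, c2=0.0, c3=0.0))
        traj = exact_lti_response(mat, impulse, sim_cfg)
        energy = 0.5 * np.einsum("ij,jk,ik->i", traj.v, mat.M, traj.v) + 0.5 * np.einsum(
            "ij,jk,ik->i", traj.x, mat.K, traj.x
        )
        post = energy[sim_cfg.times > impulse.tau]
        assert (post.max() - post.min()) / post.mean() < 1e-3

    def test_single_oscillator_closed_form(self, impulse, sim_cfg):
        # decouple layer 1: k2 = 0 and immobile (huge) masses 2 and 3
        m1, k1, c1 = 1.0, 1.0e7, 50.0
        big = 1.0e12
        mat = SystemMatrices(
            M=np.diag([m1, big, big]),
            K=np.array([[k1, -k1, 0.0], [-k1, k1, 0.0], [0.0, 0.0, 1.0e7]]),
            C=np.array([[c1, -c1, 0.0], [-c1, c1, 0.0], [0.0, 0.0, 0.0]]),
        )
        traj = exact_lti_response(mat, impulse, sim_cfg)

        # closed-form underdamped response: step force on [0, tau], then free decay
        t, tau, F0 = sim_cfg.times, impulse.tau, impulse.F0
        w0 = np.sqrt(k1 / m1)
        zeta = c1 / (2.0 * np.sqrt(k1 * m1))
        wd = w0 * np.sqrt(1.0 - zeta**2)
        sig = zeta * w0
        step = lambda u: (F0 / k1) * (
            1.0 - np.exp(-sig * u) * (np.cos(wd * u) + (sig / wd) * np.sin(wd * u))
        )
        step_v = lambda u: (F0 / (m1 * wd)) * np.exp(-sig * u) * np.sin(wd * u)
        x_tau, v_tau = step(tau), step_v(tau)
        d = t - tau
        free = np.exp(-sig * d) * (
            x_tau * np.cos(wd * d) + ((v_tau + sig * x_tau) / wd) * np.sin(wd * d)
        )
        expected = np.where(t <= tau, step(t), free)
        assert np.max(np.abs(traj.x1 - expected)) / np.max(np.abs(expected)) < 1e-6

    def test_singular_mass_matrix_rejected(self, impulse, sim_cfg):
        mat = SystemMatrices(M=np.diag([1.0, 0.0, 1.0]), K=np.eye(3), C=np.zeros((3, 3)))
        with pytest.raises((ValueError, np.linalg.LinAlgError)):
            exact_lti_response(mat, impulse, sim_cfg)
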