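"""Bilinear neural dynamics, balloon observation model, and inversion."""

import numpy as np
import pytest

from tdconnect import dcm_engine as dcm
from tdconnect.dcm_engine import DCMSpec, full_model_spec

TR = 2.5


def _streams(T_s=300.0, dt=0.1, seed=0):
    """Simple event streams: choice blocks every 10 s, half accepted."""
    T = int(T_s / dt)
    u = np.zeros((dcm.N_STREAMS, T))
    u[0] = 1.0
    rng = np.random.default_rng(seed)
    for i, onset in enumerate(np.arange(5.0, T_s - 5, 10.0)):
        i0, i1 = int(onset / dt), int((onset + 2.0) / dt)
        u[1, i0:i1] = 1.0
        u[0, i0:i1] = 0.0
        u[3, i0:i1] = rng.normal()
        if i % 2 == 0:
            u[2, i0:i1] = 1.0
            u[4, i0:i1] = 1.0
    return u


class TestNeuralDynamics:
    def test_zero_parameters_zero_derivative(self):
        A = np.zeros((2, 2))
        B = np.zeros((3, 2, 2))
        C = np.zeros((2, 5))
        dz = dcm.neural_dynamics([1.0, -2.0], A, B, C, np.ones(5))
        assert np.allclose(dz, 0.0)

    def test_scalar_closed_form_decay(self):
        """z' = -z integrates to exp(-t)."""
        from scipy.integrate import solve_ivp

        A = np.array([[-1.0]])
        B = np.zeros((3, 1, 1))
        C = np.zeros((1, 5))
        sol = solve_ivp(
            lambda t, z: dcm.neural_dynamics(z, A, B, C, np.zeros(5)),
            (0, 5), [1.0], t_eval=np.linspace(0, 5, 20), rtol=1e-10, atol=1e-12)
        assert np.allclose(sol.y[0], np.exp(-sol.t), atol=1e-7)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(dcm.DCMError):
            dcm.neural_dynamics([1.0], np.zeros((2, 2)), np.zeros((3, 2, 2)),
                                np.zeros((2, 5)), np.ones(5))

    def test_modulation_acts_only_during_condition(self):
        """The bilinear term changes the d->v transfer only while its
        condition stream is on."""
        spec = full_model_spec(1)
        base = np.zeros(spec.n_params)
        base[spec.param_names.index("drive.accept_to_d")] = 0.5
        mod = base.copy()
        mod[spec.param_names.index("later.d_to_v")] = 0.5
        u = _streams()
        n_vol = int(300.0 / TR)
        y0 = dcm.simulate_bold(spec, u, theta=base, n_volumes=n_vol)
        y1 = dcm.simulate_bold(spec, u, theta=mod, n_volumes=n_vol)
        # region v gains signal, and only after the first accepted choice
        first_later_s = 5.0
        pre = np.arange(n_vol) * TR < first_later_s
        assert np.allclose(y0[pre, 1], y1[pre, 1], atol=1e-9)
        assert np.abs(y1[:, 1] - y0[:, 1]).max() > 0.01


class TestHemodynamics:
    def test_zero_neural_constant_bold(self):
        bold = dcm.hemodynamics(np.zeros((2, 200)), dt=0.1)
        assert np.allclose(bold, 0.0, atol=1e-10)

    def test_impulse_response_peaks_seconds_later(self):
        dt = 0.1
        z = np.zeros(400)
        z[10:15] = 1.0  # brief neural burst at 1 s
        bold = dcm.hemodynamics(z, dt=dt)
        peak_t = np.argmax(bold) * dt - 1.0
        assert 3.0 <= peak_t <= 8.0
        assert bold.min() < -0.05 * bold.max()  # undershoot

    def test_integration_step_convergence(self):
        """Halving the RK4 step changes the BOLD output negligibly."""
        spec = full_model_spec(1)
        theta = np.zeros(spec.n_params)
        theta[spec.param_names.index("drive.accept_to_d")] = 0.5
        theta[spec.param_names.index("all.d_to_v")] = 0.3
        u_coarse = _streams(dt=0.25)
        u_fine = np.repeat(u_coarse, 2, axis=1)  # same signal, finer grid
        n_vol = int(300.0 / TR)
        y_coarse = dcm.simulate_bold(spec, u_coarse, theta=theta, dt=0.25, n_volumes=n_vol)
        y_fine = dcm.simulate_bold(spec, u_fine, theta=theta, dt=0.125, n_volumes=n_vol)
        rms = np.sqrt(((y_coarse - y_fine) ** 2).mean())
        assert rms < 1e-4

    def test_forward_model_deterministic(self):
        spec = full_model_spec(1)
        theta = np.full(spec.n_params, 0.1)
        u = _streams()
        n_vol = int(300.0 / TR)
        a = dcm.simulate_bold(spec, u, theta=theta, n_volumes=n_vol)
        b = dcm.simulate_bold(spec, u, theta=theta, n_volumes=n_vol)
        assert np.array_equal(a, b)


class TestSpec:
    def test_requires_driving_input(self):
        with pytest.raises(dcm.DCMError):
            DCMSpec(name="x", param_names=("fixed.d_to_v",))

    def test_self_connections_stable(self):
        spec = full_model_spec(1)
        theta = np.zeros(spec.n_params)
        theta[spec.param_names.index("fixed.d_self")] = 2.0
        A, _, _ = spec.build_matrices(theta)
        assert A[0, 0] == pytest.approx(-0.5 * np.exp(2.0))
        assert A[1, 1] == pytest.approx(-0.5)

    def test_priors_by_parameter_class(self):
        spec = full_model_spec(1)
        var = dict(zip(spec.param_names, spec.prior_var))
        assert var["later.d_to_v"] == pytest.approx(1 / 16)
        assert var["drive.value_to_v"] == pytest.approx(1.0)


class TestInvert:
    @pytest.fixture(scope="class")
    def planted_run(self):
        spec = full_model_spec(1)
        truth = np.zeros(spec.n_params)
        truth[spec.param_names.index("drive.accept_to_d")] = 0.5
        truth[spec.param_names.index("drive.value_to_v")] = 0.3
        truth[spec.param_names.index("all.d_to_v")] = 0.3
        truth[spec.param_names.index("later.d_to_v")] = 0.3
        u = _streams(T_s=500.0)
        n_vol = int(500.0 / TR)
        clean = dcm.simulate_bold(spec, u, theta=truth, n_volumes=n_vol)
        rng = np.random.default_rng(7)
        y = clean + rng.normal(0, 1.0, clean.shape)
        return spec, truth, u, y

    def test_parameter_recovery(self, planted_run):
        spec, truth, u, y = planted_run
        post = dcm.invert(y, spec, u)
        assert post.converged
        i = spec.param_names.index("drive.accept_to_d")
        assert abs(post.mean[i] - truth[i]) < 3 * np.sqrt(post.cov[i, i]) + 0.1

    def test_posterior_probability_consistent_with_mean(self, planted_run):
        spec, truth, u, y = planted_run
        post = dcm.invert(y, spec, u)
        for name in spec.param_names:
            assert (post.prob_positive(name) > 0.5) == (post[name] > 0)

    def test_covariance_psd(self, planted_run):
        spec, _, u, y = planted_run
        post = dcm.invert(y, spec, u)
        w = np.linalg.eigvalsh(post.cov)
        assert np.all(w >= 0)

    def test_free_energy_prefers_generating_input_placement(self, planted_run):
        spec, truth, u, y = planted_run
        f_true = dcm.invert(y, spec, u).free_energy
        f_wrong = dcm.invert(y, full_model_spec(4), u).free_energy
        assert f_true > f_wrong

    def test_complexity_penalty(self):
        """A free parameter without data support lowers F; one matching a
        real effect raises it."""
        drives = ("drive.value_to_v", "drive.accept_to_d")
        base_names = ("fixed.v_to_d", "fixed.d_to_v", "fixed.d_self", "fixed.v_self") + drives
        rich_names = base_names[:4] + ("all.d_to_v", "later.d_to_v") + drives
        small = DCMSpec(name="small", param_names=base_names)
        rich = DCMSpec(name="rich", param_names=rich_names)
        u = _streams(T_s=500.0, seed=3)
        n_vol = int(500.0 / TR)
        rng = np.random.default_rng(8)

        def make_data(with_modulation):
            theta = np.zeros(rich.n_params)
            theta[rich.param_names.index("drive.accept_to_d")] = 0.5
            theta[rich.param_names.index("drive.value_to_v")] = 0.3
            if with_modulation:
                theta[rich.param_names.index("all.d_to_v")] = 0.4
                theta[rich.param_names.index("later.d_to_v")] = 0.4
            clean = dcm.simulate_bold(rich, u, theta=theta, n_volumes=n_vol)
            return clean + rng.normal(0, 1.0, clean.shape)

        y_null = make_data(False)
        assert dcm.invert(y_null, small, u).free_energy > \
               dcm.invert(y_null, rich, u).free_energy
        y_mod = make_data(True)
        assert dcm.invert(y_mod, rich, u).free_energy > \
               dcm.invert(y_mod, small, u).free_energy

    def test_region_relabeling_symmetry(self, planted_run):
        """Swapping the two regions (data, inputs, and spec) leaves F intact."""
        spec, truth, u, y = planted_run
        post = dcm.invert(y, spec, u)
        # mirrored spec: every d<->v edge label swapped
        swap = {"d_to_v": "v_to_d", "v_to_d": "d_to_v",
                "d_self": "v_self", "v_self": "d_self",
                "value_to_v": "value_to_d", "accept_to_d": "accept_to_v"}
        def mirror(name):
            period, edge = name.split(".")
            return f"{period}.{swap[edge]}"
        mirrored = DCMSpec(name="mirror",
                           param_names=tuple(mirror(n) for n in spec.param_names))
        post_m = dcm.invert(y[:, ::-1], mirrored, u)
        assert post_m.free_energy == pytest.approx(post.free_energy, rel=1e-6)
        assert post_m["later.v_to_d"] == pytest.approx(post["later.d_to_v"], abs=1e-6)

    def test_nonfinite_series_rejected(self, planted_run):
        spec, _, u, y = planted_run
        bad = y.copy()
        bad[3, 0] = np.inf
        with pytest.raises(dcm.DCMError):
            dcm.invert(bad, spec, u)
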