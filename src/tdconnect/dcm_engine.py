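"""Two-region dynamic causal model: forward simulation and Bayesian inversion.

The model couples two regions of interest -- ``d`` (left dorsolateral
prefrontal cortex, BA46) and ``v`` (ventromedial prefrontal cortex) --
through bilinear neural dynamics

    dz/dt = (A + sum_j u_j(t) B_j) z + C u(t)

where ``A`` holds fixed (task-independent) coupling, each ``B_j`` scales
couplings during a task condition (fixation, all choice periods, choice
periods where the delayed option is accepted), and ``C`` routes driving
inputs (a trial-wise value-scaled event stream and an accept event
stream) into the regions.  Self-connections are parameterized as
``-0.5 * exp(theta)`` so the uncoupled dynamics are always stable.

Neural activity is observed through a balloon-windkessel hemodynamic
model (vasodilatory signal, inflow, blood volume, deoxyhemoglobin) with
fixed literature constants, producing percent-signal BOLD sampled at the
scanner TR.  Coupling and modulation parameters are in Hz.

Inversion is a variational-Laplace scheme: Gaussian shrinkage priors,
iterated Gauss-Newton updates of the posterior mode with a
Levenberg-style step control, an EM update of the observation noise, and
a free-energy (accuracy minus complexity) approximation to the log model
evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numba
import numpy as np

REGIONS = ("d", "v")  # index 0 = dlPFC-BA46, 1 = vmPFC
CONDITIONS = ("fixation", "all", "later")  # modulatory input streams
DRIVES = ("value", "accept")  # driving input streams
N_STREAMS = 5  # fixation, all, later, value, accept

#: Default microtime integration step, seconds.
DEFAULT_DT = 0.1

#: Baseline self-decay, Hz; self parameters scale this as -0.5 exp(theta).
SELF_DECAY = 0.5

# Balloon-windkessel constants (per-second rates / dimensionless), fixed
# rather than estimated to keep the two-region inversion well conditioned.
HEMO = dict(kappa=0.64, gamma=0.32, tau=2.0, alpha=0.32, E0=0.4, V0=4.0)


class DCMError(RuntimeError):
    pass


def _stream_index(name: str) -> int:
    order = CONDITIONS + DRIVES
    return order.index(name)


@dataclass(frozen=True)
class DCMSpec:
    """Which parameters are free, and the priors placed on them.

    Parameter names follow ``<period>.<edge>`` with periods ``fixed``,
    ``fixation``, ``all``, ``later``, ``drive`` and edges ``d_to_v``,
    ``v_to_d``, ``d_self``, ``v_self``, ``value_to_{d,v}``,
    ``accept_to_{d,v}``.
    """

    name: str
    param_names: tuple[str, ...]
    prior_mean: tuple[float, ...] = ()
    prior_var: tuple[float, ...] = ()
    family: int = 0
    index: int = 0

    def __post_init__(self):
        if not self.param_names:
            raise DCMError("a DCM needs at least one free parameter")
        if not any(p.startswith("drive.") for p in self.param_names):
            raise DCMError("a DCM needs at least one driving input")
        if not self.prior_mean:
            object.__setattr__(self, "prior_mean", tuple(0.0 for _ in self.param_names))
        if not self.prior_var:
            object.__setattr__(
                self,
                "prior_var",
                tuple(1.0 if p.startswith("drive.") else 1.0 / 16.0 for p in self.param_names),
            )
        if len(self.prior_mean) != len(self.param_names) or len(self.prior_var) != len(self.param_names):
            raise DCMError("prior lengths must match parameter names")

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def build_matrices(self, theta: np.ndarray):
        """Map a free-parameter vector to dense (A, B, C) matrices.

        Self-connections (fixed and modulatory) use the stability
        transform ``-SELF_DECAY * exp(theta)`` for the fixed diagonal and
        additive ``theta`` entries for modulatory diagonals.
        """
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise DCMError(f"expected {self.n_params} parameters, got {theta.shape}")
        A = np.diag([-SELF_DECAY, -SELF_DECAY]).astype(float)
        B = np.zeros((len(CONDITIONS), 2, 2))
        C = np.zeros((2, N_STREAMS))
        for value, name in zip(theta, self.param_names):
            period, edge = name.split(".")
            if period == "fixed":
                if edge == "d_self":
                    A[0, 0] = -SELF_DECAY * np.exp(value)
                elif edge == "v_self":
                    A[1, 1] = -SELF_DECAY * np.exp(value)
                elif edge == "d_to_v":
                    A[1, 0] = value
                elif edge == "v_to_d":
                    A[0, 1] = value
                else:
                    raise DCMError(f"unknown edge {name}")
            elif period in CONDITIONS:
                j = CONDITIONS.index(period)
                if edge == "d_self":
                    B[j, 0, 0] = value
                elif edge == "v_self":
                    B[j, 1, 1] = value
                elif edge == "d_to_v":
                    B[j, 1, 0] = value
                elif edge == "v_to_d":
                    B[j, 0, 1] = value
                else:
                    raise DCMError(f"unknown edge {name}")
            elif period == "drive":
                src, _, dst = edge.partition("_to_")
                C[REGIONS.index(dst), _stream_index(src)] = value
            else:
                raise DCMError(f"unknown period in {name}")
        return A, B, C


@dataclass
class DCMPosterior:
    """Gaussian posterior over the free parameters of one run's DCM."""

    spec: DCMSpec
    mean: np.ndarray
    cov: np.ndarray
    free_energy: float
    sigma2: float
    converged: bool
    n_iter: int

    def __getitem__(self, name: str) -> float:
        return float(self.mean[self.spec.param_names.index(name)])

    def sd(self, name: str) -> float:
        i = self.spec.param_names.index(name)
        return float(np.sqrt(self.cov[i, i]))

    def prob_positive(self, name: str) -> float:
        """Posterior probability that the named parameter exceeds zero."""
        from scipy.stats import norm

        i = self.spec.param_names.index(name)
        return float(norm.sf(0.0, loc=self.mean[i], scale=np.sqrt(self.cov[i, i])))

    def credible_interval(self, name: str, level: float = 0.9) -> tuple[float, float]:
        from scipy.stats import norm

        i = self.spec.param_names.index(name)
        return tuple(norm.interval(level, loc=self.mean[i], scale=np.sqrt(self.cov[i, i])))

    def to_dict(self) -> dict:
        return {
            "params": dict(zip(self.spec.param_names, map(float, self.mean))),
            "free_energy": self.free_energy,
            "sigma2": self.sigma2,
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# numba forward integrator


@numba.njit(cache=True, fastmath=True, inline="always")
def _hemo_deriv(z, s, f, v, q, kappa, gamma, tau, ialpha, E0):
    fe = f if f > 1e-6 else 1e-6
    ve = v if v > 1e-6 else 1e-6
    fout = ve ** ialpha
    E = 1.0 - (1.0 - E0) ** (1.0 / fe)
    return (
        z - kappa * s - gamma * (f - 1.0),
        s,
        (f - fout) / tau,
        (f * E / E0 - fout * q / ve) / tau,
    )


@numba.njit(cache=True, fastmath=True)
def _integrate(A, B, C, u, dt, n_keep, keep_every,
               kappa, gamma, tau, ialpha, E0, V0):
    """RK4 integration of the 10-state system; returns BOLD at kept samples."""
    T = u.shape[1]
    z0 = 0.0; z1 = 0.0
    s0 = 0.0; f0 = 1.0; v0 = 1.0; q0 = 1.0
    s1 = 0.0; f1 = 1.0; v1 = 1.0; q1 = 1.0
    bk1 = 7.0 * E0
    bk2 = 2.0
    bk3 = 2.0 * E0 - 0.2
    out = np.zeros((n_keep, 2))
    kidx = 0
    A00 = A[0, 0]; A01 = A[0, 1]; A10 = A[1, 0]; A11 = A[1, 1]
    for t in range(T):
        u0 = u[0, t]; u1 = u[1, t]; u2 = u[2, t]; u3 = u[3, t]; u4 = u[4, t]
        Ae00 = A00 + u0 * B[0, 0, 0] + u1 * B[1, 0, 0] + u2 * B[2, 0, 0]
        Ae01 = A01 + u0 * B[0, 0, 1] + u1 * B[1, 0, 1] + u2 * B[2, 0, 1]
        Ae10 = A10 + u0 * B[0, 1, 0] + u1 * B[1, 1, 0] + u2 * B[2, 1, 0]
        Ae11 = A11 + u0 * B[0, 1, 1] + u1 * B[1, 1, 1] + u2 * B[2, 1, 1]
        c0 = C[0, 0] * u0 + C[0, 1] * u1 + C[0, 2] * u2 + C[0, 3] * u3 + C[0, 4] * u4
        c1 = C[1, 0] * u0 + C[1, 1] * u1 + C[1, 2] * u2 + C[1, 3] * u3 + C[1, 4] * u4
        az0 = z0; az1 = z1
        as0 = s0; af0 = f0; av0 = v0; aq0 = q0
        as1 = s1; af1 = f1; av1 = v1; aq1 = q1
        sz0 = 0.0; sz1 = 0.0
        ss0 = 0.0; sf0 = 0.0; sv0 = 0.0; sq0 = 0.0
        ss1 = 0.0; sf1 = 0.0; sv1 = 0.0; sq1 = 0.0
        dz0 = 0.0; dz1 = 0.0
        ds0 = 0.0; df0 = 0.0; dv0 = 0.0; dq0 = 0.0
        ds1 = 0.0; df1 = 0.0; dv1 = 0.0; dq1 = 0.0
        for stage in range(4):
            if stage == 0:
                h = 0.0; w = 1.0
            elif stage == 3:
                h = dt; w = 1.0
            else:
                h = dt * 0.5; w = 2.0
            tz0 = az0 + h * dz0; tz1 = az1 + h * dz1
            ts0 = as0 + h * ds0; tf0 = af0 + h * df0; tv0 = av0 + h * dv0; tq0 = aq0 + h * dq0
            ts1 = as1 + h * ds1; tf1 = af1 + h * df1; tv1 = av1 + h * dv1; tq1 = aq1 + h * dq1
            dz0 = Ae00 * tz0 + Ae01 * tz1 + c0
            dz1 = Ae10 * tz0 + Ae11 * tz1 + c1
            ds0, df0, dv0, dq0 = _hemo_deriv(tz0, ts0, tf0, tv0, tq0, kappa, gamma, tau, ialpha, E0)
            ds1, df1, dv1, dq1 = _hemo_deriv(tz1, ts1, tf1, tv1, tq1, kappa, gamma, tau, ialpha, E0)
            sz0 += w * dz0; sz1 += w * dz1
            ss0 += w * ds0; sf0 += w * df0; sv0 += w * dv0; sq0 += w * dq0
            ss1 += w * ds1; sf1 += w * df1; sv1 += w * dv1; sq1 += w * dq1
        c6 = dt / 6.0
        z0 = az0 + c6 * sz0; z1 = az1 + c6 * sz1
        s0 = as0 + c6 * ss0; f0 = af0 + c6 * sf0; v0 = av0 + c6 * sv0; q0 = aq0 + c6 * sq0
        s1 = as1 + c6 * ss1; f1 = af1 + c6 * sf1; v1 = av1 + c6 * sv1; q1 = aq1 + c6 * sq1
        if (t + 1) % keep_every == 0 and kidx < n_keep:
            # guard only the exact-zero crossing; unphysical excursions are
            # left large so the inversion's step control rejects them
            ve0 = v0 if abs(v0) > 1e-12 else 1e-12
            ve1 = v1 if abs(v1) > 1e-12 else 1e-12
            out[kidx, 0] = V0 * (bk1 * (1.0 - q0) + bk2 * (1.0 - q0 / ve0) + bk3 * (1.0 - v0))
            out[kidx, 1] = V0 * (bk1 * (1.0 - q1) + bk2 * (1.0 - q1 / ve1) + bk3 * (1.0 - v1))
            kidx += 1
    return out


def neural_dynamics(state: np.ndarray, A: np.ndarray, B: np.ndarray,
                    C: np.ndarray, u: np.ndarray) -> np.ndarray:
    """State derivative of the bilinear neural model at one instant.

    ``dz/dt = (A + sum_j u_j B_j) z + C u``; exposed separately from the
    compiled integrator so the dynamics can be checked against closed
    forms.
    """
    A = np.asarray(A, float)
    z = np.asarray(state, float)
    u = np.asarray(u, float)
    if A.shape[0] != z.shape[0]:
        raise DCMError("state/coupling dimension mismatch")
    Aeff = A + np.tensordot(u[: B.shape[0]], B, axes=1)
    return Aeff @ z + C @ u


def simulate_bold(spec_or_matrices, inputs: np.ndarray, *, theta=None,
                  dt: float = DEFAULT_DT, tr: float = 2.5,
                  n_volumes: int = 323) -> np.ndarray:
    """Integrate the forward model and sample BOLD on the TR grid.

    Parameters
    ----------
    spec_or_matrices
        Either a :class:`DCMSpec` (with ``theta`` giving the free
        parameters) or a prebuilt ``(A, B, C)`` triple.
    inputs
        Microtime input streams, shape (5, n_volumes * tr / dt).
    """
    if isinstance(spec_or_matrices, DCMSpec):
        A, B, C = spec_or_matrices.build_matrices(theta)
    else:
        A, B, C = spec_or_matrices
    keep_every = int(round(tr / dt))
    if abs(keep_every * dt - tr) > 1e-9:
        raise DCMError(f"TR {tr} must be a multiple of microtime step {dt}")
    needed = n_volumes * keep_every
    u = np.asarray(inputs, dtype=float)
    if u.shape[0] != N_STREAMS:
        raise DCMError(f"expected {N_STREAMS} input streams, got {u.shape[0]}")
    if u.shape[1] < needed:
        raise DCMError(
            f"input streams cover {u.shape[1] * dt:.1f}s but "
            f"{n_volumes} volumes at TR={tr} need {needed * dt:.1f}s"
        )
    out = _integrate(
        np.ascontiguousarray(A), np.ascontiguousarray(B), np.ascontiguousarray(C),
        np.ascontiguousarray(u[:, :needed]), dt, n_volumes, keep_every,
        HEMO["kappa"], HEMO["gamma"], HEMO["tau"], 1.0 / HEMO["alpha"],
        HEMO["E0"], HEMO["V0"],
    )
    if not np.all(np.isfinite(out)):
        raise DCMError("hemodynamic integration diverged (non-physical parameters?)")
    return out


def hemodynamics(neural: np.ndarray, dt: float = DEFAULT_DT) -> np.ndarray:
    """Pass a given neural time series through the balloon observation model.

    Integrates the four hemodynamic states per region with the neural
    series as exogenous drive; used for testing the observation model in
    isolation from the coupled neural dynamics.
    """
    from scipy.integrate import solve_ivp

    neural = np.atleast_2d(np.asarray(neural, float))
    if neural.shape[0] not in (1, 2):
        neural = neural.T
    n_reg, T = neural.shape
    tgrid = np.arange(T) * dt
    k = HEMO

    def rhs(t, x, zrow):
        s, f, v, q = x
        idx = min(int(t / dt), T - 1)
        ds, df, dv, dq = _hemo_deriv(
            zrow[idx], s, f, v, q, k["kappa"], k["gamma"], k["tau"],
            1.0 / k["alpha"], k["E0"],
        )
        return [ds, df, dv, dq]

    bold = np.zeros_like(neural)
    bk1, bk2, bk3 = 7.0 * k["E0"], 2.0, 2.0 * k["E0"] - 0.2
    for r in range(n_reg):
        sol = solve_ivp(rhs, (0, tgrid[-1]), [0.0, 1.0, 1.0, 1.0],
                        t_eval=tgrid, args=(neural[r],), max_step=dt, rtol=1e-8, atol=1e-10)
        if not sol.success:
            raise DCMError(f"hemodynamic integration failed: {sol.message}")
        _, f, v, q = sol.y
        bold[r] = k["V0"] * (bk1 * (1 - q) + bk2 * (1 - q / v) + bk3 * (1 - v))
    return bold if bold.shape[0] > 1 else bold[0]


# ---------------------------------------------------------------------------
# inversion


def invert(series: np.ndarray, spec: DCMSpec, inputs: np.ndarray, *,
           dt: float = DEFAULT_DT, tr: float = 2.5,
           max_iter: int = 24, tol: float = 1e-3,
           fd_eps: float = 1e-3) -> DCMPosterior:
    """Variational-Laplace inversion of one run's two-region series.

    Both the data and the model prediction are mean-centered per region,
    so the fit is invariant to baseline offsets.  The observation noise
    variance is re-estimated each iteration by expectation-maximization;
    the returned free energy is the Laplace approximation
    ``accuracy - complexity``.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 2 or 2 not in y.shape:
        raise DCMError(f"series must be (n_volumes, 2), got {y.shape}")
    if y.shape[1] != 2:
        y = y.T
    if not np.all(np.isfinite(y)):
        raise DCMError("non-finite values in series")
    n_vol = y.shape[0]
    yc = (y - y.mean(axis=0)).ravel()
    N = yc.size

    p = spec.n_params
    mu0 = np.asarray(spec.prior_mean, dtype=float)
    P0 = np.diag(1.0 / np.asarray(spec.prior_var, dtype=float))

    def predict(theta):
        g = simulate_bold(spec, inputs, theta=theta, dt=dt, tr=tr, n_volumes=n_vol)
        return (g - g.mean(axis=0)).ravel()

    theta = mu0.copy()
    g = predict(theta)
    r = yc - g
    sigma2 = max(float(r @ r) / N, 1e-8)
    Sigma = np.linalg.inv(P0)
    converged = False
    lam = 0.0  # Levenberg damping

    def penalized(theta, r):
        e = theta - mu0
        return float(r @ r) / sigma2 + float(e @ P0 @ e)

    obj = penalized(theta, r)
    it = 0
    for it in range(1, max_iter + 1):
        # finite-difference Jacobian around the current mode
        J = np.empty((N, p))
        for j in range(p):
            tp = theta.copy()
            tp[j] += fd_eps
            try:
                J[:, j] = (predict(tp) - g) / fd_eps
            except (DCMError, FloatingPointError, ZeroDivisionError):
                tp[j] -= 2 * fd_eps  # backward difference near instability
                J[:, j] = (g - predict(tp)) / fd_eps
        H = J.T @ J / sigma2 + P0
        grad = J.T @ r / sigma2 - P0 @ (theta - mu0)
        step_ok = False
        for _ in range(6):
            Hd = H + lam * np.diag(np.diag(H))
            delta = np.linalg.solve(Hd, grad)
            cand = theta + delta
            try:
                g_c = predict(cand)
                r_c = yc - g_c
                cand_obj = penalized(cand, r_c)
            except (DCMError, FloatingPointError, ZeroDivisionError):
                cand_obj = np.inf  # candidate drove the dynamics unstable
            if cand_obj < obj + 1e-12:
                step_ok = True
                break
            lam = 4.0 * max(lam, 0.25)
        if step_ok:
            lam = lam / 4.0 if lam > 1e-3 else 0.0
            theta, g, r = cand, g_c, r_c
            Sigma = np.linalg.inv(H)
            # EM noise update with the current posterior curvature
            sigma2 = max((float(r @ r) + float(np.sum((J @ Sigma) * J))) / N, 1e-10)
            new_obj = penalized(theta, r)
            if abs(obj - new_obj) < tol * abs(obj + 1e-12) and float(delta @ delta) < tol:
                obj = new_obj
                converged = True
                break
            obj = new_obj
        else:
            break

    Sigma = 0.5 * (Sigma + Sigma.T)
    # guard PSD after symmetrization
    w, V = np.linalg.eigh(Sigma)
    Sigma = (V * np.clip(w, 1e-12, None)) @ V.T
    e = theta - mu0
    sign, logdet_post = np.linalg.slogdet(Sigma)
    _, logdet_prior = np.linalg.slogdet(np.linalg.inv(P0))
    F = (
        -0.5 * N * np.log(2 * np.pi * sigma2)
        - 0.5 * float(r @ r) / sigma2
        - 0.5 * float(e @ P0 @ e)
        + 0.5 * (logdet_post - logdet_prior)
    )
    return DCMPosterior(
        spec=spec, mean=theta, cov=Sigma, free_energy=float(F),
        sigma2=float(sigma2), converged=converged, n_iter=it,
    )


# ---------------------------------------------------------------------------
# input-stream construction

def build_input_streams(trials, run_duration_s: float, rdsv: np.ndarray,
                        dt: float = DEFAULT_DT,
                        decision_window_s: float = 3.0) -> np.ndarray:
    """Microtime input streams for one run.

    Streams (in order): fixation boxcar (inter-trial periods), all-choice
    boxcar (decision onset to response), later-choice boxcar (accepted
    trials only), value stream (all-choice boxcar scaled per trial by the
    standardized relative discounted value), and accept event stream
    (identical support to the later-choice boxcar, used as a driving
    input).  Missed trials contribute the full decision window to the
    choice boxcar but nothing to the later/accept streams.
    """
    T = int(round(run_duration_s / dt))
    u = np.zeros((N_STREAMS, T))
    u[0, :] = 1.0  # fixation, carved out below
    rdsv = np.asarray(rdsv, dtype=float)
    if len(rdsv) != len(trials):
        raise DCMError("rdsv must align with trials")
    scale = rdsv.std() or 1.0
    for t, val in zip(trials, rdsv):
        dur = t.rt if t.rt is not None else decision_window_s
        i0 = int(round(t.onset / dt))
        i1 = min(int(round((t.onset + dur) / dt)), T)
        if i0 >= T:
            raise DCMError(f"trial onset {t.onset}s beyond run duration {run_duration_s}s")
        u[1, i0:i1] = 1.0
        u[0, i0:i1] = 0.0
        if t.choice == "accept":
            u[2, i0:i1] = 1.0
            u[4, i0:i1] = 1.0
        if t.choice in ("accept", "reject"):
            u[3, i0:i1] = val / scale
    return u


def full_model_spec(family: int = 1) -> DCMSpec:
    """The fully connected model: both cross-couplings fixed and modulated
    by all-choices and later-choices (plus self-modulations), with the
    driving-input placement of the given family."""
    from tdconnect.model_space import FAMILY_DRIVES

    drives = FAMILY_DRIVES[family]
    names = (
        "fixed.v_to_d", "fixed.d_to_v", "fixed.d_self", "fixed.v_self",
        "all.v_to_d", "all.v_self", "all.d_to_v", "all.d_self",
        "later.v_to_d", "later.v_self", "later.d_to_v", "later.d_self",
    ) + drives
    return DCMSpec(name=f"family{family}_full", param_names=names, family=family, index=15)
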