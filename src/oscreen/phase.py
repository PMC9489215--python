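"""Floquet/adjoint phase-diffusion analysis.

For an oscillator dx/dt = f(x) + B(x) xi(t) with a stable limit cycle
x_s(t) of period T, the variance of the phase deviation grows linearly,
Var(alpha(t)) = c t, with

    c = (1/T) \\int_0^T  v1(t)^T B(x_s) B(x_s)^T v1(t)  dt,

where v1(t) is the adjoint (left) Floquet mode of the zero exponent,
normalized so v1(t) . dx_s/dt = 1 for all t.  The module finds limit
cycles, computes the monodromy matrix and v1, evaluates c for the
extrinsic (OU parameter fluctuation, white-noise matched) and intrinsic
(chemical-Langevin square-root-of-rates) noise channels, and runs the
timescale-M and amplitude-N rescaling experiments that separate the
roles of period and amplitude in oscillation accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .dynamics import ParameterSet, build_jacobian, build_rhs
from .noise import ExtrinsicNoiseConfig, IntrinsicNoiseConfig
from .topology import SignedTopology


class NoLimitCycleError(RuntimeError):
    """The dynamics converged to a fixed point (or never settled on a
    periodic orbit) from the given initial state."""


@dataclass
class LimitCycle:
    """Periodic solution sampled on one period plus its local linearization.

    ``x_s`` has shape (n_grid + 1, n) with x_s[0] == x_s[-1] to the
    limit-cycle tolerance; ``jacobian(x)`` evaluates A = df/dx.
    """

    times: np.ndarray
    x_s: np.ndarray
    period_T: float
    rhs: callable
    jacobian: callable

    @property
    def n(self) -> int:
        return self.x_s.shape[1]

    def xdot(self) -> np.ndarray:
        """dx_s/dt on the grid."""
        return np.array([self.rhs(x) for x in self.x_s])


def _settle_to_cycle(rhs, jac, x0, transient, t_max, refine_tol, n_grid, rtol, atol):
    n = x0.size

    # transient relaxation
    sol = solve_ivp(
        lambda _t, x: rhs(x), (0.0, transient), x0,
        method="LSODA", jac=lambda _t, x: jac(x), rtol=rtol, atol=atol,
    )
    x = sol.y[:, -1]

    # Poincare section: peaks of node B (f_B crossing zero downward)
    b = 1 if n > 1 else 0

    def event(_t, x_):
        return rhs(x_)[b]

    event.direction = -1.0
    sol = solve_ivp(
        lambda _t, x_: rhs(x_), (0.0, t_max), x,
        method="LSODA", jac=lambda _t, x_: jac(x_), rtol=rtol, atol=atol,
        events=event, dense_output=False,
    )
    ev_t, ev_x = sol.t_events[0], sol.y_events[0]
    if len(ev_t) < 3:
        raise NoLimitCycleError(
            "fewer than three Poincare-section crossings; the orbit has "
            "no sustained oscillation"
        )
    scale = np.abs(ev_x[-1]).max() + 1e-30
    period = None
    for k in range(len(ev_t) - 1, 0, -1):
        gap = np.abs(ev_x[k] - ev_x[k - 1]).max() / scale
        if gap < refine_tol:
            period = ev_t[k] - ev_t[k - 1]
            anchor = ev_x[k]
            break
    if period is None or period <= 0:
        raise NoLimitCycleError(
            "Poincare returns did not converge to a periodic orbit"
        )
    return anchor, period


def find_limit_cycle(
    t: SignedTopology | None,
    p: ParameterSet | None = None,
    x0: np.ndarray | None = None,
    rhs=None,
    jac=None,
    transient: float = 700.0,
    t_max: float = 2000.0,
    n_grid: int = 2000,
    refine_tol: float = 1e-7,
    residual_tol: float = 1e-8,
) -> LimitCycle:
    """Converge onto the attracting limit cycle and sample one period.

    Either a (topology, parameters) pair or explicit ``rhs``/``jac``
    callables may be given.  The orbit is located by transient
    integration followed by Poincare-section (peak of node B) returns;
    the closed orbit must satisfy |x(T) - x(0)| < residual_tol
    (relative) or the cycle is rejected.
    """
    if rhs is None:
        rhs = build_rhs(t, p)
        jac = build_jacobian(t, p)
    if x0 is None:
        x0 = np.zeros(3 if t is None else t.n_nodes)
    x0 = np.asarray(x0, dtype=float)

    rtol, atol = 1e-10, 1e-12
    anchor, period = _settle_to_cycle(
        rhs, jac, x0, transient, t_max, refine_tol, n_grid, rtol, atol
    )

    times = np.linspace(0.0, period, n_grid + 1)
    sol = solve_ivp(
        lambda _t, x: rhs(x), (0.0, period), anchor,
        method="LSODA", jac=lambda _t, x: jac(x), t_eval=times,
        rtol=rtol, atol=atol,
    )
    x_s = sol.y.T
    residual = np.abs(x_s[-1] - x_s[0]).max() / (np.abs(x_s[0]).max() + 1e-30)
    if residual > residual_tol:
        raise NoLimitCycleError(
            f"periodic-orbit residual {residual:.2e} above {residual_tol:.0e}"
        )
    span = x_s.max(axis=0) - x_s.min(axis=0)
    if span.max() < 1e-3 * (np.abs(x_s).max() + 1e-30):
        # a plateau or focus can satisfy the section/closure tests while
        # carrying no real excursion
        raise NoLimitCycleError("orbit excursion negligible; not a limit cycle")
    return LimitCycle(times, x_s, period, rhs, jacobian=jac)


# -- Floquet structure ---------------------------------------------------------


def monodromy_matrix(lc: LimitCycle, rtol: float = 1e-10) -> np.ndarray:
    """State-transition matrix over one period, by integrating the
    variational equation jointly with the orbit."""
    n = lc.n

    def aug(_t, y):
        x = y[:n]
        Phi = y[n:].reshape(n, n)
        return np.concatenate([lc.rhs(x), (lc.jacobian(x) @ Phi).ravel()])

    y0 = np.concatenate([lc.x_s[0], np.eye(n).ravel()])
    sol = solve_ivp(aug, (0.0, lc.period_T), y0, method="LSODA", rtol=rtol, atol=1e-12)
    return sol.y[n:, -1].reshape(n, n)


def floquet_exponents(M: np.ndarray, period: float) -> np.ndarray:
    """mu_i = log(eig_i)/T, sorted with the phase mode (eig closest to 1)
    first."""
    eigs = np.linalg.eigvals(M)
    order = np.argsort(np.abs(eigs - 1.0))
    return np.log(eigs[order].astype(complex)) / period


def adjoint_v1(
    lc: LimitCycle,
    M: np.ndarray | None = None,
    unit_tol: float = 1e-4,
    norm_tol: float = 1e-6,
) -> np.ndarray:
    """Adjoint zero-mode v1(t) on the limit-cycle grid.

    v1(T) is the left eigenvector of the monodromy matrix for the unit
    Floquet multiplier; integrating dv/dt = -A(t)^T v backward over the
    period (the stable direction for the adjoint) fills the grid.  The
    normalization v1 . dx_s/dt = 1 holds identically in exact
    arithmetic; it is checked pointwise and enforced exactly.
    """
    if M is None:
        M = monodromy_matrix(lc)
    eigvals, left = np.linalg.eig(M.T)
    k = int(np.argmin(np.abs(eigvals - 1.0)))
    if np.abs(eigvals[k] - 1.0) > unit_tol:
        raise RuntimeError(
            f"no unit Floquet multiplier: closest eigenvalue {eigvals[k]:.6f}"
        )
    gaps = np.sort(np.abs(eigvals - 1.0))
    if len(gaps) > 1 and gaps[1] < 10 * gaps[0]:
        raise RuntimeError("near-degenerate Floquet spectrum at the unit multiplier")
    w = np.real(left[:, k])
    xdot0 = lc.rhs(lc.x_s[0])
    w = w / float(w @ xdot0)

    T = lc.period_T
    from scipy.interpolate import CubicSpline

    x_closed = lc.x_s.copy()
    x_closed[-1] = x_closed[0]  # close the orbit exactly for the spline
    x_spline = CubicSpline(lc.times, x_closed, axis=0, bc_type="periodic")

    def back(s, v):  # v(t) with t = T - s; dv/ds = +A(t)^T v
        return lc.jacobian(x_spline(T - s)).T @ v

    sol = solve_ivp(
        back, (0.0, T), w, method="LSODA", t_eval=T - lc.times[::-1],
        rtol=1e-10, atol=1e-12,
    )
    v1 = sol.y.T[::-1]  # reorder to t increasing
    dots = np.einsum("ij,ij->i", v1, lc.xdot())
    if np.abs(dots - 1.0).max() > max(norm_tol, 1e3 * np.finfo(float).eps * np.abs(v1).max()):
        # drift beyond tolerance indicates an inaccurate orbit/Jacobian
        if np.abs(dots - 1.0).max() > 1e-3:
            raise RuntimeError(
                f"adjoint normalization drift {np.abs(dots - 1.0).max():.2e}"
            )
    return v1 / dots[:, None]


# -- phase-diffusion coefficient ----------------------------------------------


@dataclass
class PhaseDiffusionResult:
    c: float
    c_over_T: float
    period_T: float
    v1: np.ndarray
    floquet_exponents: np.ndarray
    noise_mode: str


def _production_and_denominator(p: ParameterSet, x: np.ndarray):
    """Per-gene Hill production (without k_basal) and pooled denominator."""
    n = p.n_nodes
    sign, v, K, delta, r = p.arrays()
    num = delta.astype(float).copy()
    den = np.ones(n)
    per_link = {}
    for j in range(n):
        for i in range(n):
            if sign[i, j] != 0:
                h = (x[i] / K[i, j]) ** 3
                den[j] += h
                if sign[i, j] > 0:
                    num[j] += v[i, j] * h
                    per_link[(i, j)] = h
    return num, den, per_link


def extrinsic_noise_columns(
    t: SignedTopology, p: ParameterSet, cfg: ExtrinsicNoiseConfig
):
    """B(x) for the parameter-fluctuation channels, white-noise matched.

    Each OU channel z (stationary variance sigma^2/2, correlation time
    tau_noise = 1) is replaced by white noise of matching spectral
    density at zero frequency, sigma^2, valid when the period is long
    against tau_noise; the per-channel column is eps * sigma times the
    coefficient of the channel in the perturbed vector field.
    """
    n = t.n_nodes
    sign, v, K, delta, r = p.arrays()
    amp = cfg.epsilon * cfg.sigma

    def B(x: np.ndarray) -> np.ndarray:
        num, den, per_link = _production_and_denominator(p, x)
        cols = []
        for i in range(n):
            for j in range(n):
                if sign[i, j] > 0:
                    col = np.zeros(n)
                    col[j] = amp * v[i, j] * per_link[(i, j)] / den[j]
                    cols.append(col)
        for j in range(n):
            if delta[j] > 0:
                col = np.zeros(n)
                col[j] = amp * delta[j] / den[j]
                cols.append(col)
        for j in range(n):
            col = np.zeros(n)
            col[j] = -amp * r[j] * x[j]
            cols.append(col)
        return np.column_stack(cols)

    return B


def phase_diffusion_c(
    lc: LimitCycle, v1: np.ndarray, B) -> float:
    """c by trapezoidal quadrature of v1^T B B^T v1 over one period."""
    g = np.empty(len(lc.times))
    for m, (x, v) in enumerate(zip(lc.x_s, v1)):
        col = B(x).T @ v
        g[m] = float(col @ col)
    return float(np.trapezoid(g, lc.times) / lc.period_T)


def phase_diffusion_extrinsic(
    t: SignedTopology, p: ParameterSet, cfg: ExtrinsicNoiseConfig | None = None,
    lc: LimitCycle | None = None,
) -> PhaseDiffusionResult:
    cfg = cfg or ExtrinsicNoiseConfig()
    lc = lc or find_limit_cycle(t, p)
    M = monodromy_matrix(lc)
    v1 = adjoint_v1(lc, M)
    c = phase_diffusion_c(lc, v1, extrinsic_noise_columns(t, p, cfg))
    return PhaseDiffusionResult(
        c, c / lc.period_T, lc.period_T, v1, floquet_exponents(M, lc.period_T),
        "extrinsic",
    )


def phase_diffusion_intrinsic(
    t: SignedTopology, p: ParameterSet, cfg: IntrinsicNoiseConfig | None = None,
    lc: LimitCycle | None = None,
) -> PhaseDiffusionResult:
    """Intrinsic c in copy-number space.

    The chemical Langevin diffusion is diagonal with B B^T entries
    V (production + r x) (copies^2/time); the copy-space adjoint is
    v1/V, so c = (1/(T V)) \\int sum_j v1_j^2 (prod_j + r_j x_j) dt with
    all quantities in concentration units.
    """
    cfg = cfg or IntrinsicNoiseConfig()
    lc = lc or find_limit_cycle(t, p)
    M = monodromy_matrix(lc)
    v1 = adjoint_v1(lc, M)
    sign, v, K, delta, r = p.arrays()
    g = np.empty(len(lc.times))
    for m, (x, vv) in enumerate(zip(lc.x_s, v1)):
        num, den, _ = _production_and_denominator(p, x)
        prod = p.k_basal + num / den
        g[m] = float(np.sum(vv**2 * (prod + r * x)))
    c = float(np.trapezoid(g, lc.times) / lc.period_T / cfg.volume_V)
    return PhaseDiffusionResult(
        c, c / lc.period_T, lc.period_T, v1, floquet_exponents(M, lc.period_T),
        "intrinsic",
    )


# -- rescaling experiments -----------------------------------------------------


def rescale_timescale_M(p: ParameterSet, M: float) -> ParameterSet:
    """Fold 1/M into the kinetic parameters: v, delta, r, k_basal all
    become 1/M of their values (period scales by M, amplitude fixed)."""
    return ParameterSet(
        p.topology, p.v / M, p.K.copy(), p.delta / M, p.r / M, p.k_basal / M
    )


def rescale_amplitude_N(p: ParameterSet, N: float) -> ParameterSet:
    """Amplitude rescaling: binding affinities, v's, delta's (and the
    basal rate) scale by N while the r's stay unchanged (amplitude
    scales by N, period fixed)."""
    K = np.where(p.K > 0, p.K * N, 0.0)
    return ParameterSet(
        p.topology, p.v * N, K, p.delta * N, p.r.copy(), p.k_basal * N
    )


def scaling_experiment_M(
    t: SignedTopology,
    p: ParameterSet,
    M_values=(1.0, 2.0, 4.0),
    noise_modes=("extrinsic", "intrinsic"),
    extrinsic_cfg: ExtrinsicNoiseConfig | None = None,
    intrinsic_cfg: IntrinsicNoiseConfig | None = None,
) -> pd.DataFrame:
    """Analytic c/T versus the timescale factor M.

    Extrinsic noise magnitudes track the (rescaled) parameters, so c/T
    falls as 1/M; the intrinsic square-root-of-rates noise leaves c/T
    unchanged.
    """
    rows = []
    for M in M_values:
        pM = rescale_timescale_M(p, M)
        lc = find_limit_cycle(t, pM, transient=700.0 * M, t_max=2000.0 * M)
        for mode in noise_modes:
            if mode == "extrinsic":
                res = phase_diffusion_extrinsic(t, pM, extrinsic_cfg, lc=lc)
            else:
                res = phase_diffusion_intrinsic(t, pM, intrinsic_cfg, lc=lc)
            rows.append(
                {
                    "M": M,
                    "noise_mode": mode,
                    "period_T": lc.period_T,
                    "amplitude": float(lc.x_s.max()),
                    "c": res.c,
                    "c_over_T": res.c_over_T,
                }
            )
    return pd.DataFrame(rows)


def scaling_experiment_N(
    t: SignedTopology,
    p: ParameterSet,
    N_values=(1.0, 2.0, 4.0),
    noise_modes=("extrinsic", "intrinsic"),
    extrinsic_cfg: ExtrinsicNoiseConfig | None = None,
    intrinsic_cfg: IntrinsicNoiseConfig | None = None,
) -> pd.DataFrame:
    """Analytic c/T versus the amplitude factor N.

    The variable substitution x -> N x leaves extrinsic accuracy
    unchanged and improves intrinsic accuracy (c/T falls as 1/N).
    """
    rows = []
    for N in N_values:
        pN = rescale_amplitude_N(p, N)
        lc = find_limit_cycle(t, pN)
        for mode in noise_modes:
            if mode == "extrinsic":
                res = phase_diffusion_extrinsic(t, pN, extrinsic_cfg, lc=lc)
            else:
                res = phase_diffusion_intrinsic(t, pN, intrinsic_cfg, lc=lc)
            rows.append(
                {
                    "N": N,
                    "noise_mode": mode,
                    "period_T": lc.period_T,
                    "amplitude": float(lc.x_s.max()),
                    "c": res.c,
                    "c_over_T": res.c_over_T,
                }
            )
    return pd.DataFrame(rows)


# -- Monte-Carlo oracle for Var(alpha(t)) = c t -------------------------------


def simulated_phase_variance_slope(
    t: SignedTopology,
    p: ParameterSet,
    lc: LimitCycle,
    noise_mode: str = "extrinsic",
    extrinsic_cfg: ExtrinsicNoiseConfig | None = None,
    intrinsic_cfg: IntrinsicNoiseConfig | None = None,
    n_runs: int = 200,
    n_periods: int = 30,
    seed: int = 0,
    skip_cycles: int = 2,
) -> float:
    """Monte-Carlo slope of the phase-deviation variance.

    Each stochastic run starts at the B-peak of the limit cycle; the
    phase is read off as the linearly interpolated upward crossings of
    node B through its cycle mean, and the per-cycle crossing-time
    variance across runs is regression-fit against k T.
    """
    from .noise import simulate_cle, simulate_extrinsic, with_seed, derive_seed

    T = lc.period_T
    b_peak = lc.x_s[int(np.argmax(lc.x_s[:, 1]))]
    b_mean = float(lc.x_s[:-1, 1].mean())
    horizon = n_periods * T
    crossings = []
    for run in range(n_runs):
        s = derive_seed(seed, run)
        if noise_mode == "extrinsic":
            cfg = with_seed(extrinsic_cfg or ExtrinsicNoiseConfig(), s)
            traj = simulate_extrinsic(t, p, cfg, horizon, b_peak, 256 * n_periods)
            y = traj.values[:, 1]
        else:
            cfg = with_seed(intrinsic_cfg or IntrinsicNoiseConfig(), s)
            traj = simulate_cle(t, p, cfg, horizon, b_peak, 256 * n_periods)
            y = traj.values[:, 1] / cfg.volume_V
        times = traj.times
        up = np.nonzero((y[:-1] < b_mean) & (y[1:] >= b_mean))[0]
        tc = times[up] + (b_mean - y[up]) / (y[up + 1] - y[up]) * (
            times[up + 1] - times[up]
        )
        # one crossing per cycle: drop crossings closer than half a period
        keep = [tc[0]] if tc.size else []
        for tk in tc[1:]:
            if tk - keep[-1] > 0.5 * T:
                keep.append(tk)
        crossings.append(np.asarray(keep))
    n_cycles = min(len(c) for c in crossings)
    if n_cycles < skip_cycles + 5:
        raise RuntimeError("too few complete cycles for the variance fit")
    mat = np.vstack([c[:n_cycles] for c in crossings])
    var = mat.var(axis=0, ddof=1)
    k = np.arange(n_cycles)
    sel = k >= skip_cycles
    slope = np.polyfit(k[sel] * T, var[sel], 1)[0]
    return float(slope)
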