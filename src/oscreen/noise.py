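"""Stochastic simulation engines.

Extrinsic noise: every kinetic parameter v_ij, delta_i, r_i is multiplied
by (1 + eps * z(t)) with an independent Ornstein-Uhlenbeck channel z per
parameter (tau_noise = 1, so z has zero mean and stationary variance
sigma^2 / 2).  The OU channels advance by the Milstein-style update

    z(n+1) = z(n) - z(n) dt + sigma dW + 1/2 sigma^2 (dW^2 - dt)

and the concentrations by an explicit Euler step of the perturbed vector
field.  Intrinsic noise: copy numbers X = V * concentration evolve either
by the chemical Langevin equation (drift = production - r X, diffusion =
sqrt(production + r X), production in copies/time) or by the exact
Gillespie algorithm over the 2n birth/death reactions.

All engines are reproducible bit-for-bit given (seed, dt, config); each
run consumes a single pseudorandom stream in a fixed channel order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .dynamics import ParameterSet, Trajectory
from .topology import SignedTopology


@dataclass
class ExtrinsicNoiseConfig:
    """Magnitudes of the parameter-fluctuation (extrinsic) noise.

    ``epsilon`` scales the relative perturbation; ``sigma`` drives the OU
    channels (stationary variance sigma^2/2 at tau_noise = 1, so the
    default sigma = sqrt(2) gives unit-variance channels); ``dt`` is the
    Euler step.  ``milstein`` switches the printed second-order OU update
    term; plain Euler-Maruyama when False.
    """

    epsilon: float = 0.1
    sigma: float = math.sqrt(2.0)
    tau_noise: float = 1.0
    dt: float = 0.01
    seed: int = 0
    milstein: bool = True

    def __post_init__(self) -> None:
        if self.tau_noise != 1.0:
            raise ValueError("the update scheme is defined with tau_noise = 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class IntrinsicNoiseConfig:
    """Reaction-stochasticity (intrinsic) noise settings.

    ``volume_V`` converts concentrations to copy numbers (big V means
    weak stochasticity); ``engine`` selects the chemical Langevin
    approximation or the exact Gillespie algorithm.
    """

    volume_V: float = 100.0
    dt: float = 0.005
    seed: int = 0
    engine: str = "cle"
    milstein: bool = True

    def __post_init__(self) -> None:
        if self.volume_V <= 0:
            raise ValueError("volume_V must be positive")
        if self.engine not in ("cle", "ssa"):
            raise ValueError(f"unknown intrinsic engine {self.engine!r}")


def derive_seed(master_seed: int, *indices: int) -> int:
    """Deterministic 31-bit sub-seed for (replicate, parameter-set, ...)."""
    ss = np.random.SeedSequence([int(master_seed), *[int(i) for i in indices]])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


# -- Ornstein-Uhlenbeck channel ------------------------------------------------


def ou_step(
    z: float, dt: float, sigma: float, dW: float, milstein: bool = True
) -> float:
    """One update of an OU channel (tau_noise = 1 folded into the drift)."""
    z_new = z - z * dt + sigma * dW
    if milstein:
        z_new += 0.5 * sigma**2 * (dW * dW - dt)
    return z_new


@njit(cache=True)
def _ou_path(dW, dt, sigma, milstein, z0):  # pragma: no cover - jitted
    n_steps = dW.shape[0]
    out = np.empty(n_steps + 1)
    z = z0
    out[0] = z
    for k in range(n_steps):
        z = z - z * dt + sigma * dW[k]
        if milstein:
            z += 0.5 * sigma * sigma * (dW[k] * dW[k] - dt)
        out[k + 1] = z
    return out


def simulate_ou(
    n_steps: int,
    dt: float,
    sigma: float,
    seed: int = 0,
    milstein: bool = True,
    z0: float = 0.0,
) -> np.ndarray:
    """Sample path of a single OU channel (length n_steps + 1)."""
    rng = np.random.default_rng(seed)
    dW = rng.standard_normal(int(n_steps)) * math.sqrt(dt)
    return _ou_path(dW, float(dt), float(sigma), milstein, float(z0))


# -- extrinsic engine ----------------------------------------------------------


@njit(cache=True)
def _extrinsic_kernel(
    sign, v, K, delta, r, kb, x0, eps, sigma, dt, stride, dW, milstein, out
):  # pragma: no cover - jitted
    """dW has shape (n_steps, n_channels); channel order is fixed:
    eta per activating link (row-major), xi per delta-gene, zeta per
    gene.  Concentrations advance by Euler with the current channel
    values; channels then advance by the printed OU update."""
    n = x0.shape[0]
    n_steps = dW.shape[0]
    x = x0.copy()
    z_eta = np.zeros((n, n))
    z_xi = np.zeros(n)
    z_zeta = np.zeros(n)
    xnew = np.empty(n)
    out[0, :] = x
    rec = 1
    for step in range(n_steps):
        for j in range(n):
            num = delta[j] * (1.0 + eps * z_xi[j])
            den = 1.0
            for i in range(n):
                s = sign[i, j]
                if s != 0:
                    u = x[i] / K[i, j]
                    h = u * u * u
                    den += h
                    if s > 0:
                        num += v[i, j] * (1.0 + eps * z_eta[i, j]) * h
            xnew[j] = x[j] + dt * (
                kb + num / den - r[j] * (1.0 + eps * z_zeta[j]) * x[j]
            )
            if xnew[j] < 0.0:
                xnew[j] = 0.0
        ch = 0
        for i in range(n):
            for j in range(n):
                if sign[i, j] > 0:
                    w = dW[step, ch]
                    ch += 1
                    zn = z_eta[i, j] - z_eta[i, j] * dt + sigma * w
                    if milstein:
                        zn += 0.5 * sigma * sigma * (w * w - dt)
                    z_eta[i, j] = zn
        for j in range(n):
            if delta[j] > 0.0:
                w = dW[step, ch]
                ch += 1
                zn = z_xi[j] - z_xi[j] * dt + sigma * w
                if milstein:
                    zn += 0.5 * sigma * sigma * (w * w - dt)
                z_xi[j] = zn
        for j in range(n):
            w = dW[step, ch]
            ch += 1
            zn = z_zeta[j] - z_zeta[j] * dt + sigma * w
            if milstein:
                zn += 0.5 * sigma * sigma * (w * w - dt)
            z_zeta[j] = zn
        for j in range(n):
            x[j] = xnew[j]
        if not np.isfinite(x[0]):
            return -1
        if (step + 1) % stride == 0:
            out[rec, :] = x
            rec += 1
    return rec


def extrinsic_channel_count(t: SignedTopology, p: ParameterSet) -> int:
    """Independent OU channels: one per activating link (eta), one per
    activator-free gene (xi), one per gene (zeta)."""
    n = t.n_nodes
    n_eta = sum(
        1 for i in range(n) for j in range(n) if t.sign(i, j) > 0
    )
    n_xi = int(np.sum(p.delta > 0))
    return n_eta + n_xi + n


class BlowUpError(RuntimeError):
    """A stochastic run left the finite range and was flagged."""


def simulate_extrinsic(
    t: SignedTopology,
    p: ParameterSet,
    cfg: ExtrinsicNoiseConfig,
    horizon: float,
    x0: np.ndarray,
    record_points: int = 4000,
) -> Trajectory:
    """Concentration dynamics under OU-perturbed parameters on [0, horizon].

    ``x0`` is the deterministic state at the peak of node B; the horizon
    is typically 100 x the deterministic period.
    """
    sign, v, K, delta, r = p.arrays()
    n_steps = int(round(horizon / cfg.dt))
    stride = max(1, n_steps // record_points)
    n_rec = n_steps // stride + 1
    out = np.empty((n_rec, t.n_nodes))
    rng = np.random.default_rng(int(cfg.seed))
    dW = rng.standard_normal(
        (n_steps, extrinsic_channel_count(t, p))
    ) * math.sqrt(cfg.dt)
    rec = _extrinsic_kernel(
        sign, v, K, delta, r, p.k_basal,
        np.asarray(x0, dtype=float), cfg.epsilon, cfg.sigma, cfg.dt,
        stride, dW, cfg.milstein, out,
    )
    if rec < 0:
        raise BlowUpError(f"extrinsic run diverged (seed={cfg.seed})")
    times = np.arange(n_rec) * (stride * cfg.dt)
    return Trajectory(
        times, out[:n_rec],
        {"kind": "extrinsic", "seed": cfg.seed, "epsilon": cfg.epsilon, "dt": cfg.dt},
    )


# -- chemical Langevin engine --------------------------------------------------


@njit(cache=True)
def _cle_kernel(
    sign, v, K, delta, r, kb, X0, V, dt, stride, dW, milstein, out
):  # pragma: no cover - jitted
    n = X0.shape[0]
    n_steps = dW.shape[0]
    X = X0.copy()
    Xnew = np.empty(n)
    out[0, :] = X
    rec = 1
    for step in range(n_steps):
        for j in range(n):
            num = delta[j]
            den = 1.0
            for i in range(n):
                s = sign[i, j]
                if s != 0:
                    u = X[i] / (V * K[i, j])
                    h = u * u * u
                    den += h
                    if s > 0:
                        num += v[i, j] * h
            prod = V * (kb + num / den)  # copies per time
            drift = prod - r[j] * X[j]
            sig = math.sqrt(prod + r[j] * X[j])
            w = dW[step, j]
            Xn = X[j] + drift * dt + sig * w
            if milstein:
                # d(sigma^2)/dX_j ~ r_j (self-regulation term neglected)
                Xn += 0.25 * r[j] * (w * w - dt)
            if Xn < 0.0:
                Xn = 0.0
            Xnew[j] = Xn
        for j in range(n):
            X[j] = Xnew[j]
        if not np.isfinite(X[0]):
            return -1
        if (step + 1) % stride == 0:
            out[rec, :] = X
            rec += 1
    return rec


def simulate_cle(
    t: SignedTopology,
    p: ParameterSet,
    cfg: IntrinsicNoiseConfig,
    horizon: float,
    x0_concentration: np.ndarray,
    record_points: int = 4000,
) -> Trajectory:
    """Copy-number dynamics by the chemical Langevin equation.

    The initial copy numbers are V x the deterministic B-peak state;
    copy numbers are clipped at zero after each step.
    """
    sign, v, K, delta, r = p.arrays()
    X0 = np.asarray(x0_concentration, dtype=float) * cfg.volume_V
    n_steps = int(round(horizon / cfg.dt))
    stride = max(1, n_steps // record_points)
    n_rec = n_steps // stride + 1
    out = np.empty((n_rec, t.n_nodes))
    rng = np.random.default_rng(int(cfg.seed))
    dW = rng.standard_normal((n_steps, t.n_nodes)) * math.sqrt(cfg.dt)
    rec = _cle_kernel(
        sign, v, K, delta, r, p.k_basal, X0, cfg.volume_V, cfg.dt,
        stride, dW, cfg.milstein, out,
    )
    if rec < 0:
        raise BlowUpError(f"CLE run diverged (seed={cfg.seed})")
    times = np.arange(n_rec) * (stride * cfg.dt)
    return Trajectory(
        times, out[:n_rec],
        {"kind": "cle", "seed": cfg.seed, "volume_V": cfg.volume_V, "dt": cfg.dt},
    )


# -- Gillespie engine ----------------------------------------------------------


@njit(cache=True)
def _ssa_kernel(
    sign, v, K, delta, r, kb, X0, V, grid, seed, out
):  # pragma: no cover - jitted
    np.random.seed(seed)
    n = X0.shape[0]
    X = X0.astype(np.float64)
    props = np.empty(2 * n)
    t = 0.0
    t_max = grid[-1]
    g = 0
    n_grid = grid.shape[0]
    while True:
        a0 = 0.0
        for j in range(n):
            num = delta[j]
            den = 1.0
            for i in range(n):
                s = sign[i, j]
                if s != 0:
                    u = X[i] / (V * K[i, j])
                    h = u * u * u
                    den += h
                    if s > 0:
                        num += v[i, j] * h
            props[2 * j] = V * (kb + num / den)  # birth
            props[2 * j + 1] = r[j] * X[j]  # death
            a0 += props[2 * j] + props[2 * j + 1]
        if a0 <= 0.0:
            while g < n_grid:
                out[g, :] = X
                g += 1
            return g
        tau = -math.log(np.random.random()) / a0
        t_next = t + tau
        while g < n_grid and grid[g] < t_next:
            out[g, :] = X
            g += 1
        if g >= n_grid or t_next > t_max:
            return g
        t = t_next
        u = np.random.random() * a0
        acc = 0.0
        for m in range(2 * n):
            acc += props[m]
            if u <= acc:
                j = m // 2
                if m % 2 == 0:
                    X[j] += 1.0
                else:
                    if X[j] > 0.0:
                        X[j] -= 1.0
                break


def simulate_gillespie(
    t: SignedTopology,
    p: ParameterSet,
    cfg: IntrinsicNoiseConfig,
    t_max: float,
    x0_concentration: np.ndarray,
    record_points: int = 4000,
) -> Trajectory:
    """Exact stochastic simulation of the 2n birth/death reactions,
    sampled onto a uniform grid (piecewise-constant between events)."""
    sign, v, K, delta, r = p.arrays()
    X0 = np.round(np.asarray(x0_concentration, dtype=float) * cfg.volume_V)
    grid = np.linspace(0.0, t_max, record_points + 1)
    out = np.empty((grid.size, t.n_nodes))
    _ssa_kernel(
        sign, v, K, delta, r, p.k_basal, X0, cfg.volume_V, grid, int(cfg.seed), out
    )
    return Trajectory(
        grid, out,
        {"kind": "ssa", "seed": cfg.seed, "volume_V": cfg.volume_V},
    )


def with_seed(cfg, seed: int):
    """Copy of a noise config carrying a different seed."""
    return replace(cfg, seed=int(seed))
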