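"""Deterministic competitive-inhibition Hill dynamics.

Each gene's production is a single Hill-form ratio pooling every
regulator of that gene (transcription factors compete for the same
binding sites), with cubic Hill kinetics:

    dx_j/dt = k_basal + [sum_act v_ij (x_i/K_ij)^3 + delta_j]
              / [1 + sum_act (x_i/K_ij)^3 + sum_inh (y_i/K_ij)^3]
              - r_j x_j

delta_j is the activator-independent production rate and is zero exactly
when gene j has at least one activating incoming link.
"""

from __future__ import annotations

import json

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from numba import njit

from .topology import ACTIVATION, NODE_NAMES, SignedTopology

HILL_N = 3


@dataclass
class ParameterSet:
    """Kinetic constants for one topology instance.

    ``v`` and ``K`` are dense (n, n) arrays indexed ``[source, target]``;
    ``v`` is meaningful only on activating links and ``K`` on any existing
    link.  ``delta`` and ``r`` are per-gene.  ``hill_n`` is fixed at 3.
    """

    topology: SignedTopology
    v: np.ndarray
    K: np.ndarray
    delta: np.ndarray
    r: np.ndarray
    k_basal: float
    hill_n: int = HILL_N

    def __post_init__(self) -> None:
        n = self.topology.n_nodes
        self.v = np.asarray(self.v, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.v.shape != (n, n) or self.K.shape != (n, n):
            raise ValueError(f"v and K must have shape ({n}, {n})")
        if self.delta.shape != (n,) or self.r.shape != (n,):
            raise ValueError(f"delta and r must have shape ({n},)")
        if self.hill_n != HILL_N:
            raise ValueError("the model is defined with a cubic Hill exponent")
        if np.any(self.r <= 0):
            raise ValueError("degradation rates must be strictly positive")
        if self.k_basal <= 0:
            raise ValueError("k_basal must be strictly positive")
        for i in range(n):
            for j in range(n):
                s = self.topology.sign(i, j)
                if s != 0 and self.K[i, j] <= 0:
                    raise ValueError(
                        f"missing binding affinity K for link "
                        f"{NODE_NAMES[i]}->{NODE_NAMES[j]}"
                    )
                if s == ACTIVATION and self.v[i, j] <= 0:
                    raise ValueError(
                        f"missing production rate v for activating link "
                        f"{NODE_NAMES[i]}->{NODE_NAMES[j]}"
                    )
        for j in range(n):
            has_act = any(
                self.topology.sign(i, j) == ACTIVATION for i in range(n)
            )
            if has_act and self.delta[j] != 0:
                raise ValueError(
                    f"delta supplied for gene {NODE_NAMES[j]}, which has an activator"
                )
            if not has_act and self.delta[j] <= 0:
                raise ValueError(
                    f"gene {NODE_NAMES[j]} has no activator; delta must be positive"
                )

    def validate_basal(self, ratio: float = 0.2) -> None:
        """Check that k_basal is much smaller than the dominant rates."""
        n = self.topology.n_nodes
        rates = [
            self.v[i, j]
            for i in range(n)
            for j in range(n)
            if self.topology.sign(i, j) == ACTIVATION
        ] + [d for d in self.delta if d > 0]
        if rates and self.k_basal >= ratio * min(rates):
            raise ValueError(
                f"k_basal={self.k_basal} is not << min(v, delta)={min(rates)}"
            )

    @property
    def n_nodes(self) -> int:
        return self.topology.n_nodes

    def arrays(self) -> tuple[np.ndarray, ...]:
        """Packed arrays for the compiled engines: (sign, v, K, delta, r)."""
        n = self.n_nodes
        sign = np.zeros((n, n), dtype=np.int8)
        for i in range(n):
            for j in range(n):
                sign[i, j] = self.topology.sign(i, j)
        K = np.where(self.K > 0, self.K, 1.0)  # dummy on absent links
        return sign, self.v.copy(), K, self.delta.copy(), self.r.copy()

    # -- flat JSON form ("v_AB", "K_AB", "delta_A", "r_A", "k_basal") ---------

    def to_flat_dict(self) -> dict[str, float]:
        n = self.n_nodes
        out: dict[str, float] = {"k_basal": float(self.k_basal)}
        for i in range(n):
            for j in range(n):
                s = self.topology.sign(i, j)
                if s == 0:
                    continue
                pair = NODE_NAMES[i] + NODE_NAMES[j]
                out[f"K_{pair}"] = float(self.K[i, j])
                if s == ACTIVATION:
                    out[f"v_{pair}"] = float(self.v[i, j])
        for j in range(n):
            out[f"r_{NODE_NAMES[j]}"] = float(self.r[j])
            if self.delta[j] > 0:
                out[f"delta_{NODE_NAMES[j]}"] = float(self.delta[j])
        return out

    @classmethod
    def from_flat_dict(
        cls, topology: SignedTopology, flat: dict[str, float]
    ) -> "ParameterSet":
        n = topology.n_nodes
        v = np.zeros((n, n))
        K = np.zeros((n, n))
        delta = np.zeros(n)
        r = np.zeros(n)
        for key, value in flat.items():
            if key == "k_basal":
                continue
            prefix, _, suffix = key.partition("_")
            if prefix in ("v", "K") and len(suffix) == 2:
                i, j = NODE_NAMES.index(suffix[0]), NODE_NAMES.index(suffix[1])
                (v if prefix == "v" else K)[i, j] = value
            elif prefix in ("delta", "r") and len(suffix) == 1:
                j = NODE_NAMES.index(suffix)
                (delta if prefix == "delta" else r)[j] = value
            else:
                raise ValueError(f"unrecognized parameter key {key!r}")
        return cls(topology, v, K, delta, r, k_basal=float(flat["k_basal"]))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_flat_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, topology: SignedTopology, path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_flat_dict(topology, json.load(fh))


# -- vector field --------------------------------------------------------------


def build_rhs(t: SignedTopology, p: ParameterSet) -> Callable[[np.ndarray], np.ndarray]:
    """Right-hand side f(x) of the deterministic model as a closure."""
    if p.topology != t:
        raise ValueError("parameter set was built for a different topology")
    sign, v, K, delta, r = p.arrays()
    kb = p.k_basal

    def rhs(x: np.ndarray) -> np.ndarray:
        out = np.empty_like(x, dtype=float)
        _rhs_into(np.asarray(x, dtype=float), sign, v, K, delta, r, kb, out)
        return out

    return rhs


def build_jacobian(
    t: SignedTopology, p: ParameterSet
) -> Callable[[np.ndarray], np.ndarray]:
    """Analytic Jacobian d f / d x of the deterministic model."""
    if p.topology != t:
        raise ValueError("parameter set was built for a different topology")
    sign, v, K, delta, r = p.arrays()
    n = p.n_nodes

    def jac(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        J = np.zeros((n, n))
        for j in range(n):
            num = delta[j]
            den = 1.0
            h = np.zeros(n)
            dh = np.zeros(n)
            for i in range(n):
                if sign[i, j] != 0:
                    u = x[i] / K[i, j]
                    h[i] = u**3
                    dh[i] = 3.0 * u**2 / K[i, j]
                    den += h[i]
                    if sign[i, j] > 0:
                        num += v[i, j] * h[i]
            for m in range(n):
                if sign[m, j] != 0:
                    dnum = v[m, j] * dh[m] if sign[m, j] > 0 else 0.0
                    J[j, m] += (dnum * den - (num) * dh[m]) / den**2
            J[j, j] -= r[j]
        return J

    return jac


def stability_rate_bound(t: SignedTopology, p: ParameterSet) -> float:
    """Conservative bound on the fastest Jacobian rate of the model,
    used to pick explicit-integrator steps: activating Hill slopes are
    below ~0.9 v/K, pooled inhibitory slopes below ~1.6 prod_max/K."""
    sign, v, K, delta, r = p.arrays()
    act = sign > 0
    inh = sign < 0
    prodmax = (v * act).sum(axis=0) + delta
    lam = (
        (0.9 * v / K * act).sum(axis=0)
        + prodmax * ((1.6 / K) * inh).sum(axis=0)
        + r
    )
    return float(lam.max())


@njit(cache=True)
def _rhs_into(x, sign, v, K, delta, r, kb, out):  # pragma: no cover - jitted
    n = x.shape[0]
    for j in range(n):
        num = delta[j]
        den = 1.0
        for i in range(n):
            s = sign[i, j]
            if s != 0:
                u = x[i] / K[i, j]
                h = u * u * u
                den += h
                if s > 0:
                    num += v[i, j] * h
        out[j] = kb + num / den - r[j] * x[j]


@njit(cache=True)
def _rk4_integrate(
    sign, v, K, delta, r, kb, x0, dt, n_steps, stride, out
):  # pragma: no cover - jitted
    n = x0.shape[0]
    x = x0.copy()
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    tmp = np.empty(n)
    out[0, :] = x
    rec = 1
    for step in range(1, n_steps + 1):
        _rhs_into(x, sign, v, K, delta, r, kb, k1)
        for m in range(n):
            tmp[m] = x[m] + 0.5 * dt * k1[m]
        _rhs_into(tmp, sign, v, K, delta, r, kb, k2)
        for m in range(n):
            tmp[m] = x[m] + 0.5 * dt * k2[m]
        _rhs_into(tmp, sign, v, K, delta, r, kb, k3)
        for m in range(n):
            tmp[m] = x[m] + dt * k3[m]
        _rhs_into(tmp, sign, v, K, delta, r, kb, k4)
        for m in range(n):
            x[m] += dt / 6.0 * (k1[m] + 2.0 * k2[m] + 2.0 * k3[m] + k4[m])
            if x[m] < 0.0:
                x[m] = 0.0
        if step % stride == 0:
            out[rec, :] = x
            rec += 1
    return rec


# -- trajectories --------------------------------------------------------------


@dataclass
class Trajectory:
    """Time series of concentrations (or copy numbers for the intrinsic
    engines).  ``values`` has shape (n_times, n_nodes)."""

    times: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != self.times.shape[0]:
            raise ValueError("times and values lengths differ")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    def node(self, j: int) -> np.ndarray:
        return self.values[:, j]

    def window(self, t0: float, t1: float) -> "Trajectory":
        mask = (self.times >= t0) & (self.times <= t1)
        return Trajectory(self.times[mask], self.values[mask], dict(self.meta))

    def to_csv(self, path) -> None:
        import pandas as pd

        names = [NODE_NAMES[j] for j in range(self.n_nodes)]
        pd.DataFrame(self.values, index=self.times, columns=names).rename_axis(
            "time"
        ).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        import pandas as pd

        df = pd.read_csv(path, index_col="time")
        return cls(df.index.to_numpy(), df.to_numpy())

    def to_hdf5(self, path, name: str = "trajectory") -> None:
        """Binary container for batch runs (one group per trajectory)."""
        import h5py

        with h5py.File(path, "a") as fh:
            if name in fh:
                del fh[name]
            g = fh.create_group(name)
            g.create_dataset("times", data=self.times)
            g.create_dataset("values", data=self.values)
            for key, value in self.meta.items():
                g.attrs[key] = value

    @classmethod
    def from_hdf5(cls, path, name: str = "trajectory") -> "Trajectory":
        import h5py

        with h5py.File(path, "r") as fh:
            g = fh[name]
            return cls(g["times"][...], g["values"][...], dict(g.attrs))


class IntegrationError(RuntimeError):
    """Raised when a deterministic integration fails; callers screening
    parameter sets treat it as non-oscillatory."""


def simulate_deterministic(
    t: SignedTopology,
    p: ParameterSet,
    t_end: float = 1000.0,
    x0: np.ndarray | None = None,
    dt: float = 0.02,
    record_dt: float = 0.1,
    method: str = "rk4",
) -> Trajectory:
    """Integrate the deterministic model on [0, t_end].

    The default engine is a compiled fixed-step RK4 (dt = 0.02), recorded
    on a 0.1-spaced grid — dense enough to resolve peaks.  ``method
    ="lsoda"`` uses scipy's stiff-capable solver instead (rtol 1e-6,
    atol 1e-9) and serves as the accuracy cross-check.
    """
    n = t.n_nodes
    if x0 is None:
        x0 = np.zeros(n)
    x0 = np.asarray(x0, dtype=float)
    if method == "rk4":
        sign, v, K, delta, r = p.arrays()
        stride = max(1, int(round(record_dt / dt)))
        n_steps = int(round(t_end / dt))
        n_rec = n_steps // stride + 1
        out = np.empty((n_rec, n))
        _rk4_integrate(sign, v, K, delta, r, p.k_basal, x0, dt, n_steps, stride, out)
        times = np.arange(n_rec) * (stride * dt)
        values = out
    elif method == "lsoda":
        from scipy.integrate import solve_ivp

        rhs = build_rhs(t, p)
        jac = build_jacobian(t, p)
        times = np.arange(0.0, t_end + 0.5 * record_dt, record_dt)
        sol = solve_ivp(
            lambda _t, x: rhs(x),
            (0.0, t_end),
            x0,
            t_eval=times,
            method="LSODA",
            jac=lambda _t, x: jac(x),
            rtol=1e-6,
            atol=1e-9,
        )
        if not sol.success:
            raise IntegrationError(sol.message)
        values = sol.y.T
    else:
        raise ValueError(f"unknown method {method!r}")
    if not np.all(np.isfinite(values)):
        raise IntegrationError("non-finite state during integration")
    return Trajectory(times, values, {"kind": "deterministic", "method": method})


# -- oscillation detection -----------------------------------------------------


@dataclass
class OscillationCriteria:
    """Thresholds used to call a trajectory oscillatory.

    A node is steady when its max-min over the window falls below
    ``steady_rel`` times its mean (or ``steady_abs`` when the mean is near
    zero).  Oscillation requires every node non-steady and, on every
    node, at least ``min_peaks`` peaks whose heights have relative SD
    below ``peak_rsd`` with no decaying trend (last peak >=
    ``decay_ratio`` x first peak) — together these exclude both steady
    states and damped oscillators.
    """

    window: tuple[float, float] = (700.0, 1000.0)
    steady_rel: float = 1e-3
    steady_abs: float = 1e-6
    min_peaks: int = 4
    peak_rsd: float = 0.05
    decay_ratio: float = 0.95
    prominence_frac: float = 0.01


@dataclass
class OscillationFeatures:
    oscillatory: bool
    period_T: float | None = None
    amplitude: float | None = None
    peak_times: np.ndarray | None = None


def _refined_peaks(
    times: np.ndarray, y: np.ndarray, prominence_frac: float
) -> tuple[np.ndarray, np.ndarray]:
    """Local maxima with quadratic apex refinement; (times, heights)."""
    from scipy.signal import find_peaks

    span = float(y.max() - y.min())
    if span <= 0:
        return np.empty(0), np.empty(0)
    idx, _ = find_peaks(y, prominence=prominence_frac * span)
    if idx.size == 0:
        return np.empty(0), np.empty(0)
    tt = np.empty(idx.size)
    hh = np.empty(idx.size)
    dt = times[1] - times[0]
    for m, k in enumerate(idx):
        ym1, y0, yp1 = y[k - 1], y[k], y[k + 1]
        denom = ym1 - 2.0 * y0 + yp1
        off = 0.5 * (ym1 - yp1) / denom if denom != 0 else 0.0
        tt[m] = times[k] + off * dt
        hh[m] = y0 - 0.25 * (ym1 - yp1) * off
    return tt, hh


def detect_oscillation(
    traj: Trajectory, criteria: OscillationCriteria | None = None
) -> OscillationFeatures:
    """Decide oscillation over the evaluation window and, if oscillatory,
    extract the period (mean successive peak-to-peak interval) and the
    amplitude (maximal peak value among all node series)."""
    crit = criteria or OscillationCriteria()
    t0, t1 = crit.window
    if traj.times[-1] < t1 - 1e-9:
        raise ValueError(
            f"trajectory ends at {traj.times[-1]}, before the evaluation "
            f"window {crit.window}"
        )
    win = traj.window(t0, t1)

    best_period = None
    best_amp = -np.inf
    best_peaks = None
    for j in range(win.n_nodes):
        y = win.node(j)
        mean = float(np.mean(y))
        span = float(y.max() - y.min())
        if span < max(crit.steady_rel * abs(mean), crit.steady_abs):
            return OscillationFeatures(False)  # a steady node
        pt, ph = _refined_peaks(win.times, y, crit.prominence_frac)
        if pt.size < crit.min_peaks:
            return OscillationFeatures(False)
        mean_h = float(np.mean(ph))
        if mean_h <= 0 or float(np.std(ph)) / mean_h >= crit.peak_rsd:
            return OscillationFeatures(False)
        if ph[-1] < crit.decay_ratio * ph[0]:
            return OscillationFeatures(False)  # damped oscillation
        node_amp = float(ph.max())
        if node_amp > best_amp:
            best_amp = node_amp
            best_period = float(np.mean(np.diff(pt)))
            best_peaks = pt
    return OscillationFeatures(True, best_period, best_amp, best_peaks)


def state_at_b_peak(traj: Trajectory, window: tuple[float, float] = (700.0, 1000.0)) -> np.ndarray:
    """Full state at the time node B reaches its highest value in the
    window — the initial condition used by the stochastic engines."""
    win = traj.window(*window)
    k = int(np.argmax(win.node(1)))
    return win.values[k].copy()
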