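"""Oscillation-accuracy metrics.

The accuracy of a noisy oscillation is quantified by the dimensionless
correlation time tau/T = -1/log(c), where c is the normalized
autocorrelation of the trajectory at a lag equal to one deterministic
period T.  For a damped-cosine autocorrelation C(t) = exp(-t/tau)
cos(2 pi t / T), c = C(T) = exp(-T/tau), so -1/log(c) recovers tau/T.
Per trajectory the metric is evaluated on every node series and the
largest value is kept.  A topology's robustness score is the 90th
percentile of tau/T over its oscillatory parameter sets, averaged over
replicate simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import Trajectory

#: cap applied to numerically perfect correlations, where -1/log(c) diverges
C_CAP = 1.0 - 1e-12


@dataclass
class AutocorrelationCurve:
    lags: np.ndarray
    C: np.ndarray
    node: int = 0

    def at(self, lag: float) -> float:
        """Linear interpolation of C at an arbitrary lag."""
        if lag < self.lags[0] or lag > self.lags[-1]:
            raise ValueError(f"lag {lag} outside the estimated range")
        return float(np.interp(lag, self.lags, self.C))


def autocorrelation(
    series: np.ndarray, dt: float, max_lag: float | None = None, node: int = 0
) -> AutocorrelationCurve:
    """Time-averaged, mean-removed, variance-normalized autocorrelation.

    FFT-based estimator with the unbiased (divide by n - k) lag
    normalization, so C(0) = 1 exactly.  ``max_lag`` defaults to a
    quarter of the series length.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 8:
        raise ValueError("series too short for autocorrelation")
    x = x - x.mean()
    var = float(np.dot(x, x)) / n
    if var <= 0:
        raise ValueError("zero-variance series has no autocorrelation")
    if max_lag is None:
        max_lag = 0.25 * n * dt
    n_lags = min(n - 1, int(round(max_lag / dt)))
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[: n_lags + 1]
    acov /= n - np.arange(n_lags + 1)  # unbiased lag normalization
    C = acov / acov[0]
    lags = np.arange(n_lags + 1) * dt
    return AutocorrelationCurve(lags, C, node)


def tau_over_T_from_c(c: float) -> float:
    """Map the lag-T autocorrelation coefficient to tau/T = -1/log(c).

    c <= 0 maps to 0 (decorrelated within one period); c >= 1 is capped
    just below 1 so the metric stays finite.
    """
    if c <= 0.0:
        return 0.0
    c = min(c, C_CAP)
    return float(-1.0 / np.log(c))


def tau_over_T(
    traj: Trajectory, T: float, return_per_node: bool = False
):
    """Dimensionless correlation time -1/log c with c = C(T), maximized
    over the node series (c interpolated at the exact deterministic lag)."""
    dt = float(traj.times[1] - traj.times[0])
    per_node = []
    for j in range(traj.n_nodes):
        curve = autocorrelation(
            traj.node(j), dt,
            max_lag=min(2.0 * T, (traj.times[-1] - traj.times[0]) * 0.45),
            node=j,
        )
        per_node.append(tau_over_T_from_c(curve.at(T)))
    best = float(max(per_node))
    if return_per_node:
        return best, per_node
    return best


@dataclass
class RobustnessScore:
    """Per-topology robustness: replicate-averaged 90th percentile of
    tau/T over oscillatory parameter sets."""

    topology_id: int
    noise_mode: str
    replicates: list[float]
    n_sets: int
    score: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError("at least one replicate required")
        self.score = float(np.mean(self.replicates))

    @property
    def replicate_sd(self) -> float:
        return float(np.std(self.replicates, ddof=1)) if len(self.replicates) > 1 else 0.0


def percentile_90(values) -> float:
    """Linear-interpolation (type-7) 90th percentile."""
    return float(np.percentile(np.asarray(values, dtype=float), 90.0))


def robustness_from_tau_samples(
    topology_id: int, noise_mode: str, tau_by_replicate: list[np.ndarray]
) -> RobustnessScore:
    """Assemble the score from per-replicate tau/T samples."""
    reps = [percentile_90(s) for s in tau_by_replicate]
    n_sets = len(tau_by_replicate[0]) if tau_by_replicate else 0
    return RobustnessScore(topology_id, noise_mode, reps, n_sets)


# -- running the metric over noise simulations --------------------------------


def measure_tau(
    t,
    p,
    period_T: float,
    x0: np.ndarray,
    noise_mode: str,
    extrinsic_cfg=None,
    intrinsic_cfg=None,
    horizon_mult: float = 100.0,
    seed: int = 0,
    steps_per_period: int = 200,
    record_per_period: int = 128,
) -> float:
    """tau/T of one stochastic run for one oscillatory parameter set.

    The run starts from the deterministic B-peak state ``x0``, covers
    ``horizon_mult`` deterministic periods, and uses a time step that
    resolves ``steps_per_period`` points per cycle (clipped so the OU
    channels stay well resolved).  Flagged (diverged) runs score 0.
    """
    from . import noise as _noise

    from .dynamics import stability_rate_bound

    horizon = horizon_mult * period_T
    record_points = int(record_per_period * horizon_mult)
    lam = stability_rate_bound(t, p)
    # the step is period-independent (stiffness-capped only): a
    # period-proportional step would hand short-period systems a
    # slightly weaker discretized noise and bias cross-topology
    # comparisons
    try:
        if noise_mode == "extrinsic":
            cfg = extrinsic_cfg or _noise.ExtrinsicNoiseConfig()
            dt = auto_time_step_for(period_T, steps_per_period, lam, dt_max=0.05)
            cfg = _replace(cfg, dt=dt, seed=seed)
            traj = _noise.simulate_extrinsic(t, p, cfg, horizon, x0, record_points)
        elif noise_mode == "intrinsic":
            cfg = intrinsic_cfg or _noise.IntrinsicNoiseConfig()
            dt = auto_time_step_for(
                period_T, int(1.5 * steps_per_period), lam, dt_max=0.02
            )
            cfg = _replace(cfg, dt=dt, seed=seed)
            if cfg.engine == "ssa":
                traj = _noise.simulate_gillespie(t, p, cfg, horizon, x0, record_points)
            else:
                traj = _noise.simulate_cle(t, p, cfg, horizon, x0, record_points)
        else:
            raise ValueError(f"unknown noise mode {noise_mode!r}")
    except _noise.BlowUpError:
        return 0.0
    try:
        return tau_over_T(traj, period_T)
    except ValueError:
        return 0.0  # e.g. absorbed/zero-variance run


def auto_time_step_for(
    period: float, steps_per_period: int, rate_bound: float, dt_max: float
) -> float:
    """Per-run Euler step: ``dt_max`` (well under the OU correlation
    time tau_noise = 1), tightened only when the fastest kinetic rate
    demands it for explicit stability or when the period is so short
    that ``steps_per_period`` points would not fit a cycle."""
    dt = min(period / steps_per_period, 1.0 / max(rate_bound, 1e-12), dt_max)
    return float(max(dt, 1e-3))


def _replace(cfg, **kw):
    from dataclasses import replace

    return replace(cfg, **kw)


def robustness_90pct(
    t,
    oscillatory_sets,
    noise_mode: str,
    extrinsic_cfg=None,
    intrinsic_cfg=None,
    replicates: int = 5,
    horizon_mult: float = 100.0,
    master_seed: int = 0,
    topology_id_: int | None = None,
) -> RobustnessScore:
    """Replicate-averaged 90th percentile of tau/T for one topology.

    ``oscillatory_sets`` is a sequence of (ParameterSet, period_T,
    b_peak_state) triples found by the deterministic screen (target 1000
    at full scale).  Replicate k reruns every set with seeds derived from
    ``master_seed + k``.
    """
    from .topology import topology_id as _tid
    from .noise import derive_seed

    tid = topology_id_ if topology_id_ is not None else _tid(t)
    tau_by_rep = []
    for k in range(replicates):
        taus = np.empty(len(oscillatory_sets))
        for m, (p, T, x0) in enumerate(oscillatory_sets):
            taus[m] = measure_tau(
                t, p, T, x0, noise_mode,
                extrinsic_cfg, intrinsic_cfg,
                horizon_mult=horizon_mult,
                seed=derive_seed(master_seed + k, m),
            )
        tau_by_rep.append(taus)
    return robustness_from_tau_samples(tid, noise_mode, tau_by_rep)
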