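"""Stochastic recurrent firing-rate network simulation.

Dynamics: ``tau dv_i/dt = -v_i + sum_j W_ij f[v_j] + xi_i(t)`` integrated by
forward Euler from v=0, driven by a stationary Gaussian input with mean mu,
spatial covariance Sigma^in and exponential temporal autocovariance
``exp(-|s|/tau_in)`` (a spatially correlated Ornstein-Uhlenbeck process).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .timeseries import TimeSeries


class SimulationDiverged(RuntimeError):
    """Raised when the membrane potentials exceed the blow-up bound."""


@dataclass
class InputModel:
    """Spatio-temporally separable Gaussian input process."""

    mu: float = 0.1
    Sigma_in: np.ndarray = None      # N x N spatial covariance, PSD
    tau_in: float = 15.0             # ms

    def __post_init__(self):
        self.Sigma_in = np.asarray(self.Sigma_in, dtype=float)
        if self.Sigma_in.ndim != 2 or self.Sigma_in.shape[0] != self.Sigma_in.shape[1]:
            raise ValueError("Sigma_in must be square")
        if not np.allclose(self.Sigma_in, self.Sigma_in.T):
            raise ValueError("Sigma_in must be symmetric")
        if self.tau_in <= 0:
            raise ValueError("tau_in must be positive")

    @property
    def n_units(self) -> int:
        return self.Sigma_in.shape[0]


@dataclass
class NetworkConfig:
    """Integration and nonlinearity settings for the rate network."""

    tau: float = 20.0                # membrane time constant, ms
    dt: float = 1.0                  # Euler step, ms
    T: int = 100_000                 # number of steps
    nonlinearity: str = "linear"     # 'linear' or 'relu_clipped'
    slope: float = 1.0               # ReLU slope (calibrated)
    ceiling: float = 1.0             # ReLU clip level
    target_mean_rate: float = 0.1
    burn_in: float = None            # ms discarded before analysis; None -> 10*tau
    blowup_bound: float = 1e6
    seed: int = None

    def __post_init__(self):
        if self.dt >= self.tau:
            raise ValueError("Euler step dt must be smaller than tau")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.nonlinearity not in ("linear", "relu_clipped"):
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")
        if self.nonlinearity == "relu_clipped" and self.ceiling <= 0:
            raise ValueError("ceiling must be positive")

    def f(self, v: np.ndarray) -> np.ndarray:
        if self.nonlinearity == "linear":
            return v
        return np.minimum(np.maximum(self.slope * v, 0.0), self.ceiling)

    @property
    def burn_in_steps(self) -> int:
        b = 10.0 * self.tau if self.burn_in is None else self.burn_in
        return int(round(b / self.dt))


def _spatial_factor(Sigma: np.ndarray) -> np.ndarray:
    """Matrix L with L L^T = Sigma, via eigendecomposition (PSD required)."""
    w, V = np.linalg.eigh((Sigma + Sigma.T) / 2)
    tol = 1e-10 * max(abs(w[-1]), 1.0)
    if w[0] < -tol:
        raise ValueError(f"Sigma_in is not positive semidefinite "
                         f"(smallest eigenvalue {w[0]:.3g})")
    return V * np.sqrt(np.clip(w, 0.0, None))


def sample_ou_input(model: InputModel, T: int, dt: float, seed=None) -> TimeSeries:
    """Sample the stationary OU input process.

    Uses the exact discretisation ``xi_{t+1} = mu + a (xi_t - mu) + b L eta``
    with ``a = exp(-dt/tau_in)`` and ``b = sqrt(1 - a^2)``, so the sampled
    process has mean mu, instantaneous covariance Sigma^in and lag-s
    autocovariance ``Sigma^in exp(-|s|/tau_in)`` at any step size.
    """
    if T < 1 or dt <= 0:
        raise ValueError("need T >= 1 and dt > 0")
    L = _spatial_factor(model.Sigma_in)
    N = model.n_units
    a = np.exp(-dt / model.tau_in)
    b = np.sqrt(1.0 - a * a)
    rng = np.random.default_rng(seed)
    # recursion dev[:, t] = a * dev[:, t-1] + b * L eta_{t-1}, stationary start
    drive = np.empty((N, T))
    drive[:, 0] = L @ rng.standard_normal(N)
    if T > 1:
        drive[:, 1:] = b * (L @ rng.standard_normal((N, T - 1)))
    dev = lfilter([1.0], [1.0, -a], drive, axis=1)
    return TimeSeries(values=model.mu + dev, dt=dt)


def simulate(W, input_ts: TimeSeries, cfg: NetworkConfig, v0=None):
    """Forward-Euler integration of the rate network.

    Returns ``(v, rates)`` as TimeSeries of the membrane traces and of
    f(v).  Aborts with :class:`SimulationDiverged` (reporting the step and
    suggesting spectral rescaling) if |v| exceeds ``cfg.blowup_bound``.
    """
    W = W.W if hasattr(W, "W") else np.asarray(W, dtype=float)
    N = W.shape[0]
    if input_ts.n_units != N:
        raise ValueError("input dimension does not match W")
    T = cfg.T
    if input_ts.n_steps < T:
        raise ValueError(f"input provides {input_ts.n_steps} steps, need T={T}")
    xi = input_ts.values
    dt_over_tau = cfg.dt / cfg.tau
    v = np.zeros(N) if v0 is None else np.asarray(v0, dtype=float).copy()
    V = np.empty((N, T))
    R = np.empty((N, T))
    for t in range(T):
        r = cfg.f(v)
        V[:, t] = v
        R[:, t] = r
        v = v + dt_over_tau * (-v + W @ r + xi[:, t])
        if t % 1000 == 0 and np.max(np.abs(v)) > cfg.blowup_bound:
            raise SimulationDiverged(
                f"|v| exceeded {cfg.blowup_bound:g} at step {t}; consider "
                f"rescaling W to a smaller spectral abscissa")
    return (TimeSeries(values=V, dt=cfg.dt),
            TimeSeries(values=R, dt=cfg.dt))


def run_network(W, model: InputModel, cfg: NetworkConfig, seed=None,
                discard_burn_in: bool = True):
    """Sample input, integrate, and (optionally) drop the burn-in.

    Returns ``(v, rates, input_ts)`` with the burn-in removed from all
    three when requested.
    """
    seed = cfg.seed if seed is None else seed
    xi = sample_ou_input(model, cfg.T, cfg.dt, seed=seed)
    v, r = simulate(W, xi, cfg)
    if discard_burn_in and cfg.burn_in_steps > 0:
        b = cfg.burn_in_steps
        if b >= cfg.T - 1:
            raise ValueError("burn-in exceeds simulation length")
        v = TimeSeries(v.values[:, b:], v.dt, v.unit_ids)
        r = TimeSeries(r.values[:, b:], r.dt, r.unit_ids)
        xi = TimeSeries(xi.values[:, b:], xi.dt, xi.unit_ids)
    return v, r, xi


def calibrate_relu_slope(W, model: InputModel, cfg: NetworkConfig, seed=0,
                         T_cal: int = 20_000, tol: float = 0.02,
                         max_iter: int = 60) -> float:
    """Slope of the clipped ReLU giving the target mean population output.

    Bisection on the slope until the time-and-population mean of f(v) over a
    calibration run (fixed input realisation, so deterministic given the
    seed) is within ``tol`` (relative) of ``cfg.target_mean_rate``.  The
    mean rate is monotone in the slope.  A no-op (returns 1) for linear
    nonlinearity.
    """
    if cfg.nonlinearity == "linear":
        return 1.0
    target = cfg.target_mean_rate
    T_cal = min(T_cal, cfg.T)
    xi = sample_ou_input(model, T_cal, cfg.dt, seed=seed)

    def mean_rate(slope):
        c = replace(cfg, T=T_cal, slope=slope, seed=seed)
        _, r = simulate(W, xi, c)
        return float(r.values[:, c.burn_in_steps:].mean())

    lo, hi = 1e-4, 1.0
    while mean_rate(hi) < target:
        hi *= 2
        if hi > 1e6:
            raise RuntimeError(
                f"no slope below 1e6 reaches mean rate {target}; achieved "
                f"{mean_rate(1e6):.4g}")
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)
        m = mean_rate(mid)
        if abs(m - target) <= tol * target:
            return float(mid)
        if m < target:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(f"slope calibration did not converge; bracket "
                       f"[{lo:.4g}, {hi:.4g}]")


def poisson_spikes(rates: TimeSeries, seed=None) -> list[tuple[float, str]]:
    """Bernoulli spike generation from rate traces (illustration/testing).

    Each bin emits at most one spike with probability ``rate * dt`` (rates
    in events/ms), a valid approximation of an inhomogeneous Poisson
    process when ``rate * dt << 1``.  All quantitative analyses in this
    package run on the rates themselves.
    """
    if np.any(rates.values < 0):
        raise ValueError("rates must be non-negative")
    p = rates.values * rates.dt
    if np.any(p > 1):
        raise ValueError("rate * dt exceeds 1; decrease dt")
    rng = np.random.default_rng(seed)
    hits = rng.random(p.shape) < p
    events = []
    for i, u in enumerate(rates.unit_ids):
        for t_idx in np.nonzero(hits[i])[0]:
            events.append((float(t_idx * rates.dt), u))
    events.sort()
    return events
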