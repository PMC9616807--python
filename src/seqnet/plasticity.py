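"""Mean-field STDP dynamics on the weight matrix.

The plasticity rule is summarised by an effective kernel k(s) weighting the
pre/post activity covariance at lag s: potentiation ``a_plus exp(-s/tau_plus)``
when the presynaptic cell leads (s >= 0), depression ``-a_minus exp(s/tau_minus)``
when it lags, with the whole kernel sign-reversed for inhibitory presynaptic
units.  Averaged over the fast activity fluctuations (linear dynamics, OU
input), a synapse j -> i drifts as

    dW_ij/dt = (1/tau_s) [ s_j * Integral k(s) C_ij(s) ds  -  lambda W_ij ]

where C is the analytic lagged cross-covariance of the current network,
``s_j`` is the effective presynaptic sign of unit j and lambda a
multiplicative weight decay keeping the weights bounded.  At a fixed point
with non-sequential input, W_ij is proportional to a kernel-weighted (hence
even-in-lag) covariance times a per-column sign: a generalised Hebb-and-Dale
configuration, which erases spurious sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import theory
from .connectivity import ConnectivityMatrix, hebb_dale
from .seqcore import make_lag_grid, sequentiality_raw

MINUTE_MS = 60_000.0


@dataclass
class STDPKernel:
    """Effective STDP kernel parameters.

    Defaults follow a standard excitatory rule with tau_+ = tau_- = 15 ms,
    a_+ = 0.4375/tau_+ and a_- = 0.25/tau_- (per-ms amplitudes), giving a
    net-potentiating area a_+ tau_+ - a_- tau_- = 0.1875 > 0.
    """

    tau_plus: float = 15.0
    tau_minus: float = 15.0
    a_plus: float = 0.4375 / 15.0
    a_minus: float = 0.25 / 15.0
    presyn_sign_rule: bool = True   # flip kernel sign for inhibitory presyn

    def __post_init__(self):
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("kernel timescales must be positive")
        if self.a_plus < 0 or self.a_minus < 0:
            raise ValueError("kernel amplitudes must be non-negative")

    def __call__(self, s, presyn_type: str = "E") -> np.ndarray:
        return stdp_kernel_eval(self, s, presyn_type)

    @property
    def area(self) -> float:
        """Integral of the kernel over all lags (excitatory presyn)."""
        return self.a_plus * self.tau_plus - self.a_minus * self.tau_minus


def stdp_kernel_eval(kernel: STDPKernel, s, presyn_type: str = "E"):
    """Evaluate k(s): LTP for pre-leads-post (s >= 0), LTD for s < 0."""
    s = np.asarray(s, dtype=float)
    out = np.where(s >= 0,
                   kernel.a_plus * np.exp(-s / kernel.tau_plus),
                   -kernel.a_minus * np.exp(s / kernel.tau_minus))
    if presyn_type == "I":
        if kernel.presyn_sign_rule:
            out = -out
    elif presyn_type != "E":
        raise ValueError("presyn_type must be 'E' or 'I'")
    return out if out.ndim else float(out)


@dataclass
class STDPRun:
    """Learning-timescale schedule for the mean-field weight dynamics.

    ``gain_cap`` reflects the saturation of firing rates: the covariance
    entering the plasticity integral is evaluated at an effective coupling
    ``gamma W`` with ``gamma = min(1, gain_cap / abscissa(W))``, so the
    Hebbian drive stays bounded near criticality (with a purely linear
    covariance the drive grows superlinearly with the spectral abscissa and
    the flow from a strongly recurrent start diverges).  Sequentiality along
    the trajectory is always reported at the full W.
    """

    tau_s: float = 10.0 * MINUTE_MS       # learning timescale, ms
    decay_rate: float = None              # multiplicative decay; None -> calibrate
    duration: float = None                # ms; None -> 12 relaxation times
    n_snapshots: int = 25
    max_step: float = None                # ms; None -> tau_s/100 scaled by decay
    gain_cap: float = 0.5                 # effective-coupling saturation
    frozen_signs: np.ndarray = None       # fix presynaptic types (Fig-4C-style)
    seed: int = None

    def __post_init__(self):
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")
        if self.decay_rate is not None and self.decay_rate <= 0:
            raise ValueError("decay_rate must be positive (weights unbounded otherwise)")


@dataclass
class STDPTrajectory:
    times: np.ndarray          # ms
    seq: np.ndarray            # analytic sequentiality at snapshots
    W_snapshots: np.ndarray    # (n_snapshots, N, N)
    dale_fraction: np.ndarray  # fraction of single-signed columns
    norms: np.ndarray          # Frobenius norm of W
    decay_rate: float
    diverged: bool = False

    @property
    def final_W(self) -> np.ndarray:
        return self.W_snapshots[-1]


def effective_presyn_signs(W: np.ndarray) -> np.ndarray:
    """Effective presynaptic type of each unit: sign of its column sum."""
    s = np.sign(W.sum(axis=0))
    s[s == 0] = 1.0
    return s


def dale_fraction(W: np.ndarray, rel_tol: float = 1e-3) -> float:
    """Fraction of columns that are single-signed (tiny entries ignored)."""
    scale = np.abs(W).max()
    if scale == 0:
        return 1.0
    Wz = np.where(np.abs(W) < rel_tol * scale, 0.0, W)
    pos = (Wz > 0).any(axis=0)
    neg = (Wz < 0).any(axis=0)
    return float(1.0 - np.mean(pos & neg))


def _kernel_integral(W, Sigma_in, kernel: STDPKernel, lags, tau, tau_in,
                     gain_cap: float = None):
    """Integral of k(s) C_ij(s) ds on the lag grid (trapezoid rule).

    With ``gain_cap`` the covariance is evaluated at the saturated
    effective coupling gamma*W (rate-saturation bound on the drive).
    """
    Weff = W
    if gain_cap is not None:
        a = float(np.max(np.real(np.linalg.eigvals(W))))
        if a > gain_cap:
            Weff = W * (gain_cap / a)
    cov = theory.analytic_lagged_covariance(Weff, Sigma_in, tau, tau_in, lags)
    k = stdp_kernel_eval(kernel, cov.lags)
    return np.trapezoid(k[None, None, :] * cov.C, cov.lags, axis=2), cov


def stdp_drift(W, Sigma_in, kernel: STDPKernel, run: STDPRun, lags=None,
               tau: float = 20.0, tau_in: float = 15.0,
               presyn_signs=None) -> np.ndarray:
    """Mean-field drift dW/dt (per ms) of the weight matrix."""
    W = W.W if hasattr(W, "W") else np.asarray(W, dtype=float)
    if lags is None:
        lags = make_lag_grid()
    if run.decay_rate is None:
        raise ValueError("run.decay_rate is unset; use calibrate_decay_rate")
    if presyn_signs is None:
        presyn_signs = (run.frozen_signs if run.frozen_signs is not None
                        else effective_presyn_signs(W))
    integ, _ = _kernel_integral(W, Sigma_in, kernel, lags, tau, tau_in,
                                gain_cap=run.gain_cap)
    return (presyn_signs[None, :] * integ - run.decay_rate * W) / run.tau_s


def calibrate_decay_rate(Sigma_in, kernel: STDPKernel = None, lags=None,
                         tau: float = 20.0, tau_in: float = 15.0,
                         alpha: float = 0.9, gain_cap: float = 0.5,
                         seed: int = 0) -> float:
    """Weight-decay coefficient placing the fixed point at the Hebb-and-Dale scale.

    At a fixed point, ``lambda W = s_j Integral k C(W)``.  Taking the direct
    Hebb-and-Dale solution at spectral abscissa alpha as the reference
    configuration, lambda is the least-squares scale aligning the kernel
    integral with the weights; the STDP flow then relaxes toward weights of
    that spectral scale.
    """
    kernel = kernel or STDPKernel()
    if lags is None:
        lags = make_lag_grid()
    Wstar = hebb_dale(Sigma_in, alpha=alpha, seed=seed).W
    s = effective_presyn_signs(Wstar)
    integ, _ = _kernel_integral(Wstar, Sigma_in, kernel, lags, tau, tau_in,
                                gain_cap=gain_cap)
    F = s[None, :] * integ
    lam = float(np.sum(F * Wstar) / np.sum(Wstar * Wstar))
    if lam <= 0:
        raise RuntimeError("calibration produced a non-positive decay rate")
    return lam


def run_stdp(W0, Sigma_in, kernel: STDPKernel = None, run: STDPRun = None,
             lags=None, tau: float = 20.0, tau_in: float = 15.0,
             input_schedule=None) -> STDPTrajectory:
    """Integrate the mean-field STDP flow and track sequentiality.

    Explicit Euler on the slow timescale with snapshots of (t, W, analytic
    seq, Dale fraction).  ``input_schedule`` is an optional list of
    ``(switch_time_ms, Sigma_in)`` pairs applied mid-run (sudden changes of
    input statistics).  Aborts (returning the trajectory so far with
    ``diverged=True``) if the closed loop becomes unstable or the weight
    norm blows up.
    """
    W = (W0.W if hasattr(W0, "W") else np.asarray(W0, dtype=float)).copy()
    kernel = kernel or STDPKernel()
    run = run or STDPRun()
    if lags is None:
        lags = make_lag_grid()
    Sigma = np.asarray(Sigma_in, dtype=float)
    schedule = sorted(input_schedule or [], key=lambda x: x[0])

    if run.decay_rate is None:
        lam = calibrate_decay_rate(Sigma, kernel, lags, tau, tau_in,
                                   gain_cap=run.gain_cap, seed=run.seed or 0)
    else:
        lam = run.decay_rate
    # decay relaxation time is tau_s/lam; default run covers 12 of them with
    # an Euler step of 5% of the relaxation time (the decay rate carries the
    # flow's timescale, so the step is tied to it rather than to tau_s alone)
    duration = run.duration if run.duration is not None else 12.0 * run.tau_s / lam
    h = run.max_step if run.max_step is not None else 0.05 * run.tau_s / lam
    snap_times = np.linspace(0.0, duration, run.n_snapshots)

    times, seqs, snaps, dales, norms = [], [], [], [], []
    t = 0.0
    next_snap = 0
    diverged = False
    w_bound = 1e3 * max(np.linalg.norm(W), 1.0)
    while True:
        while schedule and t >= schedule[0][0]:
            Sigma = np.asarray(schedule.pop(0)[1], dtype=float)
        signs = (run.frozen_signs if run.frozen_signs is not None
                 else effective_presyn_signs(W))
        try:
            integ, cov_eff = _kernel_integral(W, Sigma, kernel, lags, tau,
                                              tau_in, gain_cap=run.gain_cap)
        except theory.UnstableNetwork:
            diverged = True
            break
        if next_snap < len(snap_times) and t >= snap_times[next_snap] - 1e-9:
            try:
                s_now = theory.analytic_seq(W, Sigma, tau, tau_in, lags)
            except theory.UnstableNetwork:
                # W transiently unstable: report at the saturated coupling
                s_now = sequentiality_raw(cov_eff)
            times.append(t)
            seqs.append(s_now)
            snaps.append(W.copy())
            dales.append(dale_fraction(W))
            norms.append(np.linalg.norm(W))
            next_snap += 1
        if t >= duration:
            break
        drift = (signs[None, :] * integ - lam * W) / run.tau_s
        step = min(h, duration - t)
        W = W + step * drift
        t += step
        if not np.isfinite(W).all() or np.linalg.norm(W) > w_bound:
            diverged = True
            break
    return STDPTrajectory(times=np.asarray(times), seq=np.asarray(seqs),
                          W_snapshots=np.asarray(snaps),
                          dale_fraction=np.asarray(dales),
                          norms=np.asarray(norms), decay_rate=lam,
                          diverged=diverged)


def hebb_dale_similarity(W: np.ndarray, Sigma_in: np.ndarray) -> float:
    """Correlation of W with the closest direct Hebb-and-Dale solution.

    The per-column sign D_j is chosen optimally (sign of the projection of
    column j onto the corresponding covariance column); the similarity is
    the Pearson correlation between the flattened matrices.
    """
    W = W.W if hasattr(W, "W") else np.asarray(W, dtype=float)
    S = np.asarray(Sigma_in, dtype=float)
    D = np.sign(np.sum(W * S, axis=0))
    D[D == 0] = 1.0
    ref = S * D[None, :]
    return float(np.corrcoef(W.ravel(), ref.ravel())[0, 1])
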