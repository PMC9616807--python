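"""Closed-form covariance and sequentiality for linearised networks.

For linear dynamics ``tau dv/dt = (W - I) v + xi`` with OU input (spatial
covariance Sigma^in, timescale tau_in), the joint process z = (v, dxi) is a
linear SDE

    dz = A z dt + B dBt,   A = [[(W-I)/tau, I/tau], [0, -I/tau_in]]

whose stationary covariance P solves the continuous-time Lyapunov equation
``A P + P A^T + Q = 0`` with Q carrying the white-noise intensity
(2/tau_in) Sigma^in in the input block.  Lagged covariances follow by
matrix-exponential propagation, ``C_z(s) = expm(A s) P`` for s >= 0 and
``C_z(-s) = C_z(s)^T`` exactly, from which the v-block gives the lagged
cross-covariances entering the sequentiality ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .seqcore import (LaggedCovariance, make_lag_grid, sequentiality_raw,
                      DEFAULT_MAX_LAG, DEFAULT_LAG_STEP)


class UnstableNetwork(ValueError):
    """Closed-loop dynamics are not stable (spectral abscissa of W >= 1)."""


def _augmented_system(W: np.ndarray, Sigma_in: np.ndarray, tau: float,
                      tau_in: float):
    W = W.W if hasattr(W, "W") else np.asarray(W, dtype=float)
    Sigma_in = np.asarray(Sigma_in, dtype=float)
    N = W.shape[0]
    if Sigma_in.shape != (N, N):
        raise ValueError("Sigma_in shape does not match W")
    abscissa = float(np.max(np.real(np.linalg.eigvals(W))))
    if abscissa >= 1.0:
        raise UnstableNetwork(
            f"spectral abscissa of W is {abscissa:.4f} >= 1: the linearised "
            f"network (W - I)/tau is unstable")
    I = np.eye(N)
    A = np.block([[(W - I) / tau, I / tau],
                  [np.zeros((N, N)), -I / tau_in]])
    Q = np.zeros((2 * N, 2 * N))
    Q[N:, N:] = (2.0 / tau_in) * Sigma_in
    return A, Q, N


def analytic_lagged_covariance(W, Sigma_in, tau: float = 20.0,
                               tau_in: float = 15.0,
                               lags=None) -> LaggedCovariance:
    """Exact stationary lagged covariance of the linear network.

    Returns C with ``C[j, k, s] = cov(v_j(t + lags[s]), v_k(t))``; the
    stationarity identity ``C(-s) = C(s)^T`` holds exactly by construction.
    """
    if lags is None:
        lags = make_lag_grid(DEFAULT_MAX_LAG, DEFAULT_LAG_STEP)
    lags = np.asarray(lags, dtype=float)
    A, Q, N = _augmented_system(W, Sigma_in, tau, tau_in)
    P = linalg.solve_continuous_lyapunov(A, -Q)
    P = (P + P.T) / 2

    pos = np.sort(np.unique(np.abs(lags)))
    C = np.empty((N, N, lags.size))
    # propagate along the positive lags; grid is uniform so one step matrix
    by_lag = {}
    Cz = P
    prev = 0.0
    for s in pos:
        if s > prev:
            Cz = linalg.expm(A * (s - prev)) @ Cz
            prev = s
        by_lag[s] = Cz[:N, :N]
    for idx, s in enumerate(lags):
        blk = by_lag[abs(s)]
        C[:, :, idx] = blk if s >= 0 else blk.T
    return LaggedCovariance(C=C, lags=lags)


def analytic_seq(W, Sigma_in, tau: float = 20.0, tau_in: float = 15.0,
                 lags=None) -> float:
    """Raw sequentiality ratio on the analytic lagged covariance.

    No noise floor is needed: the analytic covariance has no estimation
    noise, so the raw Frobenius ratio is the sequentiality itself.
    """
    return sequentiality_raw(analytic_lagged_covariance(W, Sigma_in, tau,
                                                        tau_in, lags))


@dataclass
class TwoUnitMotifs:
    """The two elementary causes of spurious sequences in a 2-unit motif.

    motif_A: unequal input variances entrain one unit by the other,
    ``(Sigma_22 - Sigma_11) * W_12``.  motif_B: unequal self-connections
    give the units different effective time constants,
    ``(W_11 - W_22) * Sigma_12``.  The total anti-symmetric covariance
    energy is proportional to |motif_A + motif_B|.
    """

    motif_A: float
    motif_B: float

    @property
    def total(self) -> float:
        return abs(self.motif_A + self.motif_B)


def two_unit_prediction(W, Sigma_in) -> TwoUnitMotifs:
    """Motif decomposition of the anti-symmetry for 2-unit symmetric circuits."""
    W = W.W if hasattr(W, "W") else np.asarray(W, dtype=float)
    S = np.asarray(Sigma_in, dtype=float)
    if W.shape != (2, 2) or S.shape != (2, 2):
        raise ValueError("two_unit_prediction requires 2x2 matrices")
    if not np.isclose(W[0, 1], W[1, 0]):
        raise ValueError("W must be symmetric (the theory covers symmetric "
                         "2-unit circuits)")
    return TwoUnitMotifs(motif_A=float((S[1, 1] - S[0, 0]) * W[0, 1]),
                         motif_B=float((W[0, 0] - W[1, 1]) * S[0, 1]))


def asymmetric_energy(W, Sigma_in, tau: float = 20.0, tau_in: float = 15.0,
                      lags=None) -> float:
    """Total anti-symmetric singular energy sum_{k in asym} sigma_k^2.

    Computed as the squared Frobenius norm of the odd-in-lag part of the
    analytic covariance (the quantity the two-unit motif formula predicts
    up to a global proportionality constant).
    """
    cov = analytic_lagged_covariance(W, Sigma_in, tau, tau_in, lags)
    order = np.argsort(cov.lags)
    Cs = cov.C[:, :, order]
    return float(np.sum((0.5 * (Cs - Cs[:, :, ::-1])) ** 2))
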