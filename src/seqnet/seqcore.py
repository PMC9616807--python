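"""Sequentiality index from time-lagged cross-covariances.

The measure works on the full set of pairwise lagged cross-covariances

    C_jk(s) = (1/T) * sum_t (X_{j,t+s} - mu_j) (X_{k,t} - mu_k)

arranged into an (N^2 x S) matrix Gamma with one row per unit pair and one
column per lag.  Every right singular vector of Gamma is, for a stationary
process, either an even (non-sequential) or an odd (sequential) function of
the lag, so the singular spectrum splits into "sym" and "asym" components.
Sequentiality is the root-ratio of anti-symmetric to symmetric singular
energy,

    seq = sqrt( sum_{k in asym} sigma_k^2 / sum_{k in sym} sigma_k^2 ),

equal to ||C_asy||_F / ||C_sym||_F and bounded in [0, 1].  Estimation error
puts a floor under the singular values; it is estimated by splitting the
recording into M epochs and resampling rescaled epoch differences, and all
components below mean + ``multiplier`` * SD of that floor are discarded
before the ratio is formed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator

from .timeseries import TimeSeries, spikes_to_rate

DEFAULT_MAX_LAG = 200.0    # ms
DEFAULT_LAG_STEP = 2.0     # ms
DEFAULT_N_EPOCHS = 10
DEFAULT_MULTIPLIER = 7.0


class UndefinedSequentiality(Warning):
    """Emitted when the sequentiality ratio is undefined (zero denominator
    or no component of either parity surviving the noise floor)."""


@dataclass
class LaggedCovariance:
    """All-pairs lagged cross-covariances on a symmetric lag grid.

    ``C[j, k, s]`` estimates cov(X_j(t + lags[s]), X_k(t)).  The per-epoch
    estimates whose mean is ``C`` are retained for noise-floor resampling.
    """

    C: np.ndarray                      # (N, N, S)
    lags: np.ndarray                   # (S,) in ms, symmetric about 0
    epoch_estimates: np.ndarray = None  # (M, N, N, S) or None (analytic)
    means: np.ndarray = None           # per-unit means mu_j
    dt: float = None

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        self.lags = np.asarray(self.lags, dtype=float)
        if self.C.ndim != 3 or self.C.shape[0] != self.C.shape[1]:
            raise ValueError("C must have shape (N, N, S)")
        if self.C.shape[2] != self.lags.size:
            raise ValueError("lag grid does not match C")
        check_symmetric_lags(self.lags)

    @property
    def n_units(self) -> int:
        return self.C.shape[0]

    @property
    def n_lags(self) -> int:
        return self.lags.size

    @property
    def n_epochs(self) -> int:
        return 0 if self.epoch_estimates is None else self.epoch_estimates.shape[0]


@dataclass
class NoiseFloor:
    """Singular-value distribution expected from finite-sample noise.

    Draws are singular values of epoch-difference matrices rescaled by
    1/sqrt(2M): a difference of two epochs has twice the per-epoch noise
    covariance, while the mean over M epochs has 1/M of it.
    """

    sample_sigmas: np.ndarray
    mu: float
    sd: float
    n_epochs: int

    def threshold(self, multiplier: float = DEFAULT_MULTIPLIER) -> float:
        return self.mu + multiplier * self.sd


@dataclass
class SeqSpectrum:
    """Singular spectrum of the Gamma matrix with parity labels."""

    sigmas: np.ndarray                  # nonincreasing
    parities: np.ndarray                # 'sym' / 'asym' per component
    lags: np.ndarray
    spatial_components: np.ndarray = None   # (K, N, N)
    temporal_components: np.ndarray = None  # (K, S)
    noise_mu: float = None
    noise_sd: float = None
    threshold_multiplier: float = DEFAULT_MULTIPLIER
    seq: float = None

    def surviving(self, floor: NoiseFloor = None, multiplier: float = None) -> np.ndarray:
        """Boolean mask of components above the noise floor."""
        if floor is not None:
            mu, sd = floor.mu, floor.sd
        elif self.noise_mu is not None:
            mu, sd = self.noise_mu, self.noise_sd
        else:
            raise ValueError("no noise floor attached to this spectrum")
        m = self.threshold_multiplier if multiplier is None else multiplier
        return self.sigmas >= mu + m * sd


# --------------------------------------------------------------------- lags
def check_symmetric_lags(lags: np.ndarray) -> None:
    lags = np.asarray(lags, dtype=float)
    if lags.ndim != 1 or lags.size < 1:
        raise ValueError("lag grid must be a 1-D array")
    if not np.allclose(np.sort(lags), np.sort(-lags)):
        raise ValueError("lag grid must be symmetric about 0 (closed under negation)")
    if 0.0 not in lags and not np.isclose(np.min(np.abs(lags)), 0.0):
        raise ValueError("lag grid must contain 0")
    steps = np.diff(np.sort(lags))
    if lags.size > 1 and not np.allclose(steps, steps[0]):
        raise ValueError("lag grid must be equally spaced")


def make_lag_grid(max_lag: float = DEFAULT_MAX_LAG, lag_step: float = DEFAULT_LAG_STEP) -> np.ndarray:
    """Symmetric lag grid -max_lag..+max_lag (ms) in lag_step bins."""
    n = int(round(max_lag / lag_step))
    if not np.isclose(n * lag_step, max_lag):
        raise ValueError("max_lag must be an integer multiple of lag_step")
    return np.arange(-n, n + 1) * float(lag_step)


# --------------------------------------------------------- covariance estimate
def estimate_lagged_covariance(
    X: TimeSeries,
    max_lag: float = DEFAULT_MAX_LAG,
    lag_step: float = DEFAULT_LAG_STEP,
    n_epochs: int = DEFAULT_N_EPOCHS,
    global_means: bool = False,
    per_lag_normalization: bool = False,
) -> LaggedCovariance:
    """Epoch-averaged lagged cross-covariance estimate.

    The series is divided into ``n_epochs`` contiguous, equal, non-overlapping
    epochs (trailing remainder dropped); the covariance is estimated in each
    epoch with its own mean removed (``global_means=True`` switches to the
    whole-series mean) and the estimates are averaged.  Within an epoch the
    time index runs over a common window valid for every lag, and the sums
    are normalised by a lag-constant count (``per_lag_normalization=True``
    instead divides each lag by its own maximal valid count).

    Raises
    ------
    ValueError
        If an epoch is not longer than twice the maximum lag.
    """
    lags = make_lag_grid(max_lag, lag_step)
    dt = X.dt
    offs = lags / dt
    if not np.allclose(offs, np.round(offs)):
        raise ValueError("lag grid must be a multiple of the sampling step dt")
    offs = np.round(offs).astype(int)
    L = int(np.max(np.abs(offs)))

    n_epochs = int(n_epochs)
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1 (>= 2 for noise estimation)")
    T_ep = X.n_steps // n_epochs
    min_len = 2 * L + 1
    if T_ep < min_len:
        raise ValueError(
            f"epoch length {T_ep} samples is too short for max_lag={max_lag} ms: "
            f"need at least {min_len} samples per epoch "
            f"({min_len * n_epochs} in total for {n_epochs} epochs)"
        )

    N = X.n_units
    vals = X.values
    global_mu = vals[:, : T_ep * n_epochs].mean(axis=1)
    est = np.empty((n_epochs, N, N, offs.size))
    mus = np.empty((n_epochs, N))
    for m in range(n_epochs):
        seg = vals[:, m * T_ep : (m + 1) * T_ep]
        mu = global_mu if global_means else seg.mean(axis=1)
        mus[m] = mu
        D = seg - mu[:, None]
        base = D[:, L : T_ep - L]
        for si, k in enumerate(offs):
            shifted = D[:, L + k : T_ep - L + k]
            norm = (T_ep - abs(k)) if per_lag_normalization else (T_ep - 2 * L)
            est[m, :, :, si] = shifted @ base.T / norm

    return LaggedCovariance(C=est.mean(axis=0), lags=lags, epoch_estimates=est,
                            means=mus.mean(axis=0), dt=dt)


# ------------------------------------------------------------- Gamma matrix
def build_gamma(C) -> np.ndarray:
    """Arrange a covariance tensor into the (N^2 x S) Gamma matrix.

    Row ``i + j*N`` holds the lag profile of the pair (i, j):
    ``Gamma[i + j*N, s] = C[i, j, s]``.
    """
    if isinstance(C, LaggedCovariance):
        C = C.C
    C = np.asarray(C, dtype=float)
    N, N2, S = C.shape
    if N != N2:
        raise ValueError("C must be (N, N, S)")
    return C.transpose(1, 0, 2).reshape(N * N, S)


def unflatten_gamma(Gamma: np.ndarray, n_units: int) -> np.ndarray:
    """Inverse of :func:`build_gamma`."""
    Gamma = np.asarray(Gamma, dtype=float)
    if Gamma.shape[0] != n_units * n_units:
        raise ValueError("row count is not n_units**2")
    return Gamma.reshape(n_units, n_units, -1).transpose(1, 0, 2)


def _even_odd_split(Gamma: np.ndarray, lags: np.ndarray):
    """Split Gamma into even and odd parts along the lag axis.

    Assumes the grid is symmetric; columns are paired s <-> -s by index
    reversal after sorting.
    """
    order = np.argsort(lags)
    G = Gamma[:, order]
    Ge = 0.5 * (G + G[:, ::-1])
    Go = 0.5 * (G - G[:, ::-1])
    inv = np.empty_like(order)
    inv[order] = np.arange(order.size)
    return Ge[:, inv], Go[:, inv]


def decompose_spectrum(Gamma: np.ndarray, lags: np.ndarray,
                       compute_components: bool = False) -> SeqSpectrum:
    """Singular spectrum of Gamma with symmetric/anti-symmetric parity labels.

    Rather than classifying singular vectors post hoc (fragile under
    degenerate singular values), Gamma is split into its even and odd parts
    along the lag axis and each part is decomposed separately; by parity
    orthogonality the union of the two spectra carries the total energy
    ``sum sigma^2 = ||Gamma||_F^2``.
    """
    Gamma = np.asarray(Gamma, dtype=float)
    lags = np.asarray(lags, dtype=float)
    check_symmetric_lags(lags)
    if Gamma.shape[1] != lags.size:
        raise ValueError("Gamma column count does not match lag grid")
    Ge, Go = _even_odd_split(Gamma, lags)

    sig, par = [], []
    spat, temp = [], []
    N = int(round(np.sqrt(Gamma.shape[0])))
    for part, label in ((Ge, "sym"), (Go, "asym")):
        if compute_components:
            U, s, Vt = linalg.svd(part, full_matrices=False)
        else:
            s = linalg.svdvals(part)
            U = Vt = None
        sig.append(s)
        par.append(np.full(s.size, label, dtype=object))
        if compute_components:
            spat.append(U.T.reshape(s.size, N, N).transpose(0, 2, 1))
            temp.append(Vt)
    sigmas = np.concatenate(sig)
    parities = np.concatenate(par)
    order = np.argsort(-sigmas, kind="stable")
    spec = SeqSpectrum(sigmas=sigmas[order], parities=parities[order].astype(str), lags=lags)
    if compute_components:
        spec.spatial_components = np.concatenate(spat)[order]
        spec.temporal_components = np.concatenate(temp)[order]
    return spec


# --------------------------------------------------------------- noise floor
def estimate_noise_floor(C: LaggedCovariance, max_pairs: int = None,
                         rng=None) -> NoiseFloor:
    """Noise singular-value distribution from rescaled epoch differences.

    Differences of epoch pairs cancel the common signal, leaving twice the
    per-epoch noise; dividing by sqrt(2M) matches the distribution to the
    noise in the M-epoch mean.  Each pair difference contributes the full
    singular spectrum of the rescaled Gamma-shaped difference matrix.
    """
    M = C.n_epochs
    if M < 2:
        raise ValueError("noise floor requires at least 2 epochs")
    pairs = list(itertools.combinations(range(M), 2))
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = np.random.default_rng(rng)
        pairs = [pairs[i] for i in rng.choice(len(pairs), max_pairs, replace=False)]
    draws = []
    scale = 1.0 / np.sqrt(2.0 * M)
    for i, j in pairs:
        dG = build_gamma(C.epoch_estimates[i] - C.epoch_estimates[j]) * scale
        draws.append(linalg.svdvals(dG))
    sample = np.concatenate(draws)
    return NoiseFloor(sample_sigmas=sample, mu=float(sample.mean()),
                      sd=float(sample.std(ddof=1)), n_epochs=M)


# ------------------------------------------------------------- sequentiality
def sequentiality_raw(C) -> float:
    """Frobenius-ratio sequentiality without denoising.

    ``||C_asy||_F / ||C_sym||_F`` with ``C_asy/sym`` the anti-symmetric and
    symmetric parts of C in the lag.  Returns NaN (with a warning) when the
    symmetric part vanishes.
    """
    if isinstance(C, LaggedCovariance):
        lags, C = C.lags, C.C
    else:
        raise TypeError("sequentiality_raw expects a LaggedCovariance")
    order = np.argsort(lags)
    Cs = C[:, :, order]
    num = np.linalg.norm(Cs - Cs[:, :, ::-1])
    den = np.linalg.norm(Cs + Cs[:, :, ::-1])
    if den == 0.0:
        warnings.warn("symmetric covariance part is zero: sequentiality undefined",
                      UndefinedSequentiality)
        return float("nan")
    return float(num / den)


def sequentiality_denoised(spectrum: SeqSpectrum, floor: NoiseFloor,
                           multiplier: float = DEFAULT_MULTIPLIER) -> float:
    """Sequentiality over components surviving the noise floor.

    Components with sigma below ``floor.mu + multiplier * floor.sd`` are
    discarded.  If no anti-symmetric component survives while at least one
    symmetric one does, the result is exactly 0.  If no component of either
    parity survives the result is undefined (NaN, with a warning), mirroring
    the exclusion rule used for recordings whose sequentiality cannot be
    estimated from the available sample.
    """
    if multiplier < 0:
        raise ValueError("multiplier must be non-negative")
    keep = spectrum.sigmas >= floor.threshold(multiplier)
    sym = keep & (spectrum.parities == "sym")
    asym = keep & (spectrum.parities == "asym")
    e_sym = float(np.sum(spectrum.sigmas[sym] ** 2))
    e_asym = float(np.sum(spectrum.sigmas[asym] ** 2))
    if not sym.any():
        warnings.warn("no symmetric component survives the noise floor: "
                      "sequentiality undefined", UndefinedSequentiality)
        return float("nan")
    return float(np.sqrt(e_asym / e_sym))


def sequentiality(
    X: TimeSeries,
    max_lag: float = DEFAULT_MAX_LAG,
    lag_step: float = DEFAULT_LAG_STEP,
    n_epochs: int = DEFAULT_N_EPOCHS,
    multiplier: float = DEFAULT_MULTIPLIER,
) -> float:
    """Denoised sequentiality of a time series with default parameters."""
    cov = estimate_lagged_covariance(X, max_lag=max_lag, lag_step=lag_step,
                                     n_epochs=n_epochs)
    spec = decompose_spectrum(build_gamma(cov), cov.lags)
    floor = estimate_noise_floor(cov)
    return sequentiality_denoised(spec, floor, multiplier)


# ------------------------------------------------------- sklearn-style front
class SequentialityAnalysis(BaseEstimator):
    """Estimator computing the sequentiality index of a population recording.

    Follows the scikit-learn estimator protocol: ``fit(X)`` accepts either a
    :class:`~seqnet.timeseries.TimeSeries` or an ``(n_timepoints, n_units)``
    array sampled at ``dt``, and exposes the fitted spectrum, noise floor and
    index as trailing-underscore attributes.

    Parameters
    ----------
    max_lag, lag_step : float
        Lag window and bin (ms); defaults +/-200 ms in 2 ms bins.
    n_epochs : int
        Number of contiguous epochs for averaging and noise resampling.
    multiplier : float
        Noise threshold is ``mu + multiplier * sd`` of the noise singular
        values; default 7.
    dt : float
        Sampling step (ms) assumed when ``X`` is a bare array.
    compute_components : bool
        Whether to retain spatial/temporal singular components.

    Attributes
    ----------
    seq_ : float
        Denoised sequentiality (NaN when undefined).
    seq_raw_ : float
        Raw Frobenius-ratio sequentiality, no denoising.
    spectrum_ : SeqSpectrum
    covariance_ : LaggedCovariance
    noise_floor_ : NoiseFloor
    n_surviving_ : int
        Number of components above the noise floor.
    """

    def __init__(self, max_lag=DEFAULT_MAX_LAG, lag_step=DEFAULT_LAG_STEP,
                 n_epochs=DEFAULT_N_EPOCHS, multiplier=DEFAULT_MULTIPLIER,
                 dt=1.0, global_means=False, per_lag_normalization=False,
                 compute_components=False):
        self.max_lag = max_lag
        self.lag_step = lag_step
        self.n_epochs = n_epochs
        self.multiplier = multiplier
        self.dt = dt
        self.global_means = global_means
        self.per_lag_normalization = per_lag_normalization
        self.compute_components = compute_components

    def _as_series(self, X) -> TimeSeries:
        if isinstance(X, TimeSeries):
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_timepoints, n_units)")
        return TimeSeries(values=X.T, dt=self.dt)

    def fit(self, X, y=None):
        ts = self._as_series(X)
        self.covariance_ = estimate_lagged_covariance(
            ts, max_lag=self.max_lag, lag_step=self.lag_step,
            n_epochs=self.n_epochs, global_means=self.global_means,
            per_lag_normalization=self.per_lag_normalization)
        self.spectrum_ = decompose_spectrum(
            build_gamma(self.covariance_), self.covariance_.lags,
            compute_components=self.compute_components)
        self.noise_floor_ = estimate_noise_floor(self.covariance_)
        self.spectrum_.noise_mu = self.noise_floor_.mu
        self.spectrum_.noise_sd = self.noise_floor_.sd
        self.spectrum_.threshold_multiplier = self.multiplier
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UndefinedSequentiality)
            self.seq_ = sequentiality_denoised(self.spectrum_, self.noise_floor_,
                                               self.multiplier)
            self.seq_raw_ = sequentiality_raw(self.covariance_)
        self.spectrum_.seq = self.seq_
        self.n_surviving_ = int(self.spectrum_.surviving().sum())
        return self

    def score(self, X=None, y=None) -> float:
        """Return the fitted denoised sequentiality."""
        if not hasattr(self, "seq_"):
            raise AttributeError("estimator is not fitted")
        return self.seq_

    def fit_from_spikes(self, events, unit_ids=None, kernel_width=10.0,
                        t_stop=None):
        """Smooth spike events into rates at ``dt`` and fit."""
        ts = spikes_to_rate(events, dt=self.dt, kernel_width=kernel_width,
                            unit_ids=unit_ids, t_stop=t_stop)
        return self.fit(ts)
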