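"""Synthetic fixtures with known ground-truth sequentiality.

Includes the perfect cyclic sequence (the seq = 1 reference case), a
white-noise null (the seq = 0 / false-positive control), and named
scenario bundles reproducing each figure-style generative setup used
throughout the package (network + input covariance + integration config).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import (ConnectivityMatrix, draw_dale_signs, hebb_dale,
                           make_input_covariance, random_ensemble)
from .netsim import InputModel, NetworkConfig
from .timeseries import TimeSeries

SCENARIO_NAMES = ("fig1", "fig2a", "fig2b", "fig2c", "fig3a", "fig3b", "fig3c",
                  "fig4b", "fig4c", "perfect", "whitenoise")


# ------------------------------------------------------------ perfect sequence
def profile(kind: str, period: int, width: int = None) -> np.ndarray:
    """Periodic activity profile over one period (in samples)."""
    if width is None:
        width = max(2, period // 4)
    width = min(width, period)
    k = np.arange(period)
    if kind == "raised_cosine":
        f = np.zeros(period)
        f[:width] = 0.5 * (1 - np.cos(2 * np.pi * np.arange(width) / width))
    elif kind == "gaussian":
        c = period / 2
        f = np.exp(-0.5 * ((k - c) / (width / 2)) ** 2)
    elif kind == "triangle":
        f = np.maximum(0.0, 1.0 - np.abs(k - width) / width)
    else:
        raise ValueError(f"unknown profile {kind!r}")
    return f


def perfect_sequence(n_units: int, n_periods: int, profile_f=None,
                     dt: float = 1.0) -> TimeSeries:
    """Perfect cyclic sequence: ``X[j, t] = f((t - j) mod N)``.

    Each row is the one-step circular shift of the previous one, the
    idealised synfire-chain-like pattern whose sequentiality equals 1 when
    measured over a symmetric lag grid tiling one full period (exact for
    odd N; for even N the symmetric integer grid cannot tile the cycle and
    a small parity residue of order 1/N remains).
    """
    if n_units < 2:
        raise ValueError("a sequence needs at least 2 units")
    if n_periods < 1:
        raise ValueError("need at least one period")
    if profile_f is None:
        profile_f = profile("raised_cosine", n_units)
    f = np.asarray(profile_f, dtype=float)
    if f.shape != (n_units,):
        raise ValueError("profile must have one sample per unit (period N)")
    T = n_units * n_periods
    t = np.arange(T)
    X = np.empty((n_units, T))
    for j in range(n_units):
        X[j] = f[(t - j) % n_units]
    return TimeSeries(values=X, dt=dt)


def white_noise(n_units: int, n_steps: int, dt: float = 1.0,
                seed=None) -> TimeSeries:
    """Iid Gaussian series: the non-sequential null for false-positive tests."""
    rng = np.random.default_rng(seed)
    return TimeSeries(values=rng.standard_normal((n_units, n_steps)), dt=dt)


# ------------------------------------------------------------------ scenarios
@dataclass
class ScenarioBundle:
    """Self-describing generative setup for one named scenario."""

    name: str
    Sigma_in: np.ndarray
    W: ConnectivityMatrix
    input_model: InputModel
    config: NetworkConfig
    seed: int
    meta: dict = field(default_factory=dict)


def _streams(seed: int, n: int):
    return np.random.SeedSequence(seed).spawn(n)


def scenario(name: str, N: int = 50, seed: int = 0, **overrides) -> ScenarioBundle:
    """Build the generative bundle for a named figure-style scenario.

    All bundles share dt=1 ms, tau=20 ms, tau_in=15 ms, T=1e5 steps and
    input mean mu=0.1; randomness is namespaced per object (variances,
    Dale signs, weights draw from separate seed streams), so the same
    (name, seed) is bit-reproducible and changing N does not silently
    change unrelated draws.

    Scenarios
    ---------
    fig1     random symmetric network, fixed-correlation input (spurious
             sequences from non-sequential input)
    fig2a/b/c  two-unit motif circuits with printed parameters
    fig3a    Hebb-and-Dale network matched to fixed-correlation input (seq 0)
    fig3b    the fig3a network driven by spatially decaying covariance with
             the same per-unit variances (mismatch -> spurious sequences)
    fig3c    weights rebuilt on the fig3b covariance (readapted -> seq 0)
    fig4b    = fig1 start for the STDP erasure run
    fig4c    = fig3b input for the post-switch STDP run
    perfect / whitenoise  handled by :func:`perfect_sequence` /
             :func:`white_noise`; here they return trivial bundles
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    base = dict(tau=20.0, dt=1.0, T=100_000, nonlinearity="linear")
    base.update({k: v for k, v in overrides.items() if k in
                 ("tau", "dt", "T", "nonlinearity", "slope", "burn_in")})
    mu, tau_in, alpha = (overrides.get("mu", 0.1), overrides.get("tau_in", 15.0),
                        overrides.get("alpha", 0.9))
    s_var, s_signs, s_w = _streams(seed, 3)

    def bundle(Sigma, W, meta=None):
        cfg = NetworkConfig(seed=seed, **base)
        return ScenarioBundle(name=name, Sigma_in=Sigma, W=W,
                              input_model=InputModel(mu=mu, Sigma_in=Sigma,
                                                     tau_in=tau_in),
                              config=cfg, seed=seed, meta=meta or {})

    if name in ("fig2a", "fig2b", "fig2c"):
        W2 = {"fig2a": [[0.0, 0.5], [0.5, 0.0]],
              "fig2b": [[-0.5, 0.0], [0.0, 0.5]],
              "fig2c": [[-0.5, 0.4], [-0.4, 0.5]]}[name]
        S2 = {"fig2a": [[25.0, 0.0], [0.0, 1.0]],
              "fig2b": [[1.0, 0.9], [0.9, 1.0]],
              "fig2c": [[1.0, 0.9], [0.9, 1.0]]}[name]
        return bundle(np.array(S2), ConnectivityMatrix(np.array(W2),
                                                       construction=name))

    if name in ("perfect", "whitenoise"):
        S = np.eye(N)
        return bundle(S, ConnectivityMatrix(np.zeros((N, N)), construction=name))

    # the mismatched covariance redraws its variances ("again random
    # variances"): both the correlations and the variance profile change
    rng = np.random.default_rng(s_var)
    s = rng.exponential(1.0, size=N)
    S_fixed = 0.5 * np.outer(s, s)
    np.fill_diagonal(S_fixed, s**2)
    s2 = rng.exponential(1.0, size=N)
    i = np.arange(N)
    S_decay = np.outer(s2, s2) * np.exp(-np.abs(i[:, None] - i[None, :]) / 10.0)

    if name in ("fig1", "fig4b"):
        W = random_ensemble("symmetric", N, alpha=alpha, seed=s_w)
        return bundle(S_fixed, W)
    D = draw_dale_signs(N, s_signs)
    if name == "fig3a":
        return bundle(S_fixed, hebb_dale(S_fixed, D, alpha=alpha))
    if name in ("fig3b", "fig4c"):
        # mismatch: same weights as fig3a, new input covariance
        return bundle(S_decay, hebb_dale(S_fixed, D, alpha=alpha),
                      meta={"weights_built_on": "fixed_corr"})
    if name == "fig3c":
        return bundle(S_decay, hebb_dale(S_decay, D, alpha=alpha))
    raise AssertionError("unreachable")
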