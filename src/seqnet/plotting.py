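"""Diagnostic plots: sequentiality spectrum bars and cross-covariance rasters."""

from __future__ import annotations

import numpy as np


def plot_spectrum(spectrum, floor=None, ax=None, n_show: int = 20):
    """Bar plot of singular values, colored by parity, with the noise band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    k = min(n_show, spectrum.sigmas.size)
    colors = ["tab:red" if p == "sym" else "tab:green"
              for p in spectrum.parities[:k]]
    ax.bar(np.arange(k), spectrum.sigmas[:k], color=colors)
    mu = floor.mu if floor is not None else spectrum.noise_mu
    sd = floor.sd if floor is not None else spectrum.noise_sd
    if mu is not None:
        thr = mu + spectrum.threshold_multiplier * sd
        ax.axhline(thr, color="gray", ls="--", lw=1,
                   label=f"noise mu + {spectrum.threshold_multiplier:g} sd")
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("component (rank order)")
    ax.set_ylabel("singular value")
    return ax


def plot_cc_raster(cov, ax=None, normalize: bool = True):
    """Image of all pairwise lagged cross-covariances, pairs ordered by CC peak."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    from .seqcore import build_gamma

    G = build_gamma(cov)
    if normalize:
        m = np.abs(G).max(axis=1, keepdims=True)
        m[m == 0] = 1.0
        G = G / m
    order = np.argsort(np.argmax(G, axis=1))
    ax.imshow(G[order], aspect="auto", cmap="RdBu_r", vmin=-1, vmax=1,
              extent=(cov.lags[0], cov.lags[-1], G.shape[0], 0))
    ax.set_xlabel("lag (ms)")
    ax.set_ylabel("unit pair (ordered by CC peak)")
    return ax
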