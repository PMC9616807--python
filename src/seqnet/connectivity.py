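"""Connectivity matrices and input spatial covariances.

Constructions used throughout the package: random Gaussian / symmetric /
anti-symmetric / Dale ensembles, the Hebb-and-Dale construction
``W_ij = Sigma^in_ij * D_j`` (Hebbian factor times a per-presynaptic-unit
sign) that provably produces zero sequentiality for non-sequential input,
and its robustness perturbations (sparsification, inverse-Wishart noise in
the Hebbian factor, negative input covariances with Dale-preserving
pruning).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

DEFAULT_ALPHA = 0.9


@dataclass
class ConnectivityMatrix:
    """Weight matrix with construction metadata.

    ``W[i, j]`` is the strength of the connection from unit j to unit i.
    When ``dale_signs`` is present, every nonzero entry of column j has the
    sign ``dale_signs[j]`` (Dale's law: all efferent connections of a cell
    share one sign).
    """

    W: np.ndarray
    construction: str = "explicit"
    alpha: float = None
    dale_signs: np.ndarray = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ValueError("W must be square")
        if not np.isfinite(self.W).all():
            raise ValueError("W contains non-finite entries")
        if self.dale_signs is not None:
            self.dale_signs = np.asarray(self.dale_signs)
            if self.dale_signs.shape != (self.W.shape[0],):
                raise ValueError("dale_signs must have one entry per column")

    @property
    def n_units(self) -> int:
        return self.W.shape[0]

    def obeys_dale(self, atol: float = 0.0) -> bool:
        """True if every column is single-signed (zeros allowed)."""
        W = np.where(np.abs(self.W) <= atol, 0.0, self.W)
        pos = (W > 0).any(axis=0)
        neg = (W < 0).any(axis=0)
        return not np.any(pos & neg)


def spectral_abscissa(W: np.ndarray) -> float:
    """Maximum real part of the eigenvalues."""
    return float(np.max(np.real(np.linalg.eigvals(W))))


def rescale_spectrum(W, alpha: float = DEFAULT_ALPHA) -> ConnectivityMatrix:
    """Scale W by a positive scalar so its spectral abscissa equals alpha.

    For symmetric matrices this sets the top eigenvalue to alpha.  Matrices
    whose spectral abscissa is not positive cannot be brought to a positive
    alpha by positive scaling and are rejected.
    """
    cm = W if isinstance(W, ConnectivityMatrix) else ConnectivityMatrix(W)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if not np.any(cm.W):
        raise ValueError("cannot rescale an all-zero matrix")
    a = spectral_abscissa(cm.W)
    if a <= 0:
        raise ValueError(
            f"spectral abscissa {a:.3g} is not positive: positive rescaling "
            f"cannot reach alpha={alpha}")
    return ConnectivityMatrix(W=cm.W * (alpha / a), construction=cm.construction,
                              alpha=alpha, dale_signs=cm.dale_signs,
                              meta=dict(cm.meta))


# -------------------------------------------------------- input covariances
def _psd_repair(S: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    w, V = np.linalg.eigh((S + S.T) / 2)
    if w.min() < -tol * max(abs(w.max()), 1.0):
        warnings.warn(f"covariance had negative eigenvalue {w.min():.3g}; "
                      "clipped at 0")
    w = np.clip(w, 0.0, None)
    return (V * w) @ V.T


def make_input_covariance(kind: str, N: int = None, params: dict = None,
                          seed=None) -> np.ndarray:
    """Build an input spatial-covariance matrix Sigma^in.

    Kinds
    -----
    fixed_corr
        Correlations fixed to 0.5 with random variances:
        ``Sigma_ij = 0.5 s_i s_j`` off-diagonal, ``Sigma_ii = s_i^2``,
        s_i ~ Exp(mean 1).
    spatial_decay
        ``Sigma_ij = s_i s_j exp(-|i-j| / length)`` with ``length=10``.
    explicit
        ``params["Sigma"]`` passed through (after a symmetry/PSD check).
    wishart
        Wishart draw with mean the identity; ``params: dof`` (default 2).
    neg_mix
        ``c * ones + U diag(exp(-i/10)) U^T`` with Haar-random U; a fraction
        of off-diagonal covariances comes out negative depending on c.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "explicit":
        S = np.asarray(params["Sigma"], dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("explicit Sigma must be square")
        if not np.allclose(S, S.T):
            raise ValueError("explicit Sigma must be symmetric")
        return _psd_repair(S)
    if N is None:
        raise ValueError(f"kind {kind!r} requires N")
    if kind == "fixed_corr":
        s = rng.exponential(1.0, size=N)
        S = 0.5 * np.outer(s, s)
        np.fill_diagonal(S, s**2)
    elif kind == "spatial_decay":
        length = float(params.get("length", 10.0))
        s = rng.exponential(1.0, size=N)
        i = np.arange(N)
        S = np.outer(s, s) * np.exp(-np.abs(i[:, None] - i[None, :]) / length)
    elif kind == "wishart":
        dof = int(params.get("dof", 2))
        G = rng.standard_normal((N, dof))
        S = G @ G.T / dof
    elif kind == "neg_mix":
        c = float(params["c"])
        if not 0.0 <= c <= 0.2:
            raise ValueError("c must lie in [0, 0.2]")
        U = stats.ortho_group.rvs(N, random_state=rng)
        lam = np.exp(-np.arange(1, N + 1) / 10.0)
        S = c * np.ones((N, N)) + (U * lam) @ U.T
    else:
        raise ValueError(f"unknown covariance kind {kind!r}")
    return _psd_repair(S)


# ------------------------------------------------------------ random ensembles
def random_ensemble(kind: str, N: int, alpha: float = DEFAULT_ALPHA,
                    seed=None) -> ConnectivityMatrix:
    """Random connectivity ensembles at spectral scale alpha.

    All start from iid Gaussian entries with variance alpha^2/N.  The
    ``symmetric`` kind applies (W + W^T)/(2 sqrt 2), whose top eigenvalue is
    then already close to alpha; ``antisymmetric`` applies (W - W^T)/(2 sqrt 2)
    and is rescaled by spectral radius (its abscissa is 0); ``dale`` applies
    ``W_ij -> |W_ij| sign(sum_i W_ij)`` making each column single-signed.
    A final exact rescale brings the spectral measure to alpha.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    rng = np.random.default_rng(seed)
    W = rng.normal(0.0, alpha / np.sqrt(N), size=(N, N))
    dale_signs = None
    if kind == "gaussian":
        pass
    elif kind == "symmetric":
        W = (W + W.T) / (2 * np.sqrt(2))
    elif kind == "antisymmetric":
        W = (W - W.T) / (2 * np.sqrt(2))
    elif kind == "dale":
        signs = np.sign(W.sum(axis=0))
        signs[signs == 0] = 1.0
        W = np.abs(W) * signs[None, :]
        dale_signs = signs
    else:
        raise ValueError(f"unknown ensemble kind {kind!r}")

    if kind == "antisymmetric":
        rho = np.max(np.abs(np.linalg.eigvals(W)))
        W = W * (alpha / rho)
        out = ConnectivityMatrix(W=W, construction=kind, alpha=alpha)
    else:
        out = rescale_spectrum(ConnectivityMatrix(W=W, construction=kind,
                                                  dale_signs=dale_signs), alpha)
        out.construction = kind
    return out


# --------------------------------------------------------------- Hebb + Dale
def draw_dale_signs(N: int, seed=None) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.choice([-1.0, 1.0], size=N)


def hebb_dale(Sigma_in: np.ndarray, dale_signs=None, alpha: float = DEFAULT_ALPHA,
              seed=None, rescale: bool = True) -> ConnectivityMatrix:
    """Hebb-and-Dale construction: ``W_ij = Sigma^in_ij * D_j``.

    ``D_j`` is +/-1 per presynaptic unit (drawn with equal probability when
    not supplied); the result is rescaled so the maximum real eigenvalue
    equals alpha.  For non-negative Sigma^in the columns are single-signed,
    i.e. the network satisfies Dale's law.
    """
    S = np.asarray(Sigma_in, dtype=float)
    if not np.allclose(S, S.T):
        raise ValueError("Sigma_in must be symmetric")
    N = S.shape[0]
    D = draw_dale_signs(N, seed) if dale_signs is None else np.asarray(dale_signs, float)
    if D.shape != (N,) or not np.all(np.isin(D, (-1.0, 1.0))):
        raise ValueError("dale_signs must be a length-N vector of +/-1")
    W = S * D[None, :]
    cm = ConnectivityMatrix(W=W, construction="hebb_dale", dale_signs=D)
    if rescale:
        cm = rescale_spectrum(cm, alpha)
        cm.construction = "hebb_dale"
    return cm


def sparsify(W, p: float) -> ConnectivityMatrix:
    """Zero the floor(p*N^2) smallest-magnitude entries of W.

    Ties are broken by row-major index order.  Zeroing never flips a sign,
    so the Dale property is preserved.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError("sparseness p must lie in [0, 1)")
    cm = W if isinstance(W, ConnectivityMatrix) else ConnectivityMatrix(W)
    N = cm.n_units
    k = int(np.floor(p * N * N))
    out = cm.W.copy()
    if k > 0:
        flat = np.abs(out).ravel()
        idx = np.argsort(flat, kind="stable")[:k]
        out.ravel()[idx] = 0.0
    return ConnectivityMatrix(W=out, construction=f"{cm.construction}+sparse",
                              alpha=cm.alpha, dale_signs=cm.dale_signs,
                              meta={**cm.meta, "sparseness": p})


def perturb_hebb(Sigma_in: np.ndarray, dof: int, dale_signs=None,
                 alpha: float = DEFAULT_ALPHA, seed=None,
                 strict_dale: bool = False) -> ConnectivityMatrix:
    """Replace the Hebbian factor by an inverse-Wishart draw centred on Sigma^in.

    The inverse-Wishart scale is ``Sigma_in * (dof - N - 1)`` so the mean of
    the draw equals Sigma^in; smaller ``dof`` means a noisier Hebbian factor.
    The achieved noise-to-signal ratio (relative Frobenius deviation of the
    draw from Sigma^in) is recorded in ``meta``.  Entries whose sign
    conflicts with D are kept as drawn by default (the construction measures
    tolerance to Hebbian imprecision); ``strict_dale=True`` prunes them.
    """
    S = np.asarray(Sigma_in, dtype=float)
    N = S.shape[0]
    if dof <= N + 1:
        raise ValueError(f"dof must exceed N+1={N + 1} for the mean to exist")
    rng = np.random.default_rng(seed)
    D = draw_dale_signs(N, rng) if dale_signs is None else np.asarray(dale_signs, float)
    H = stats.invwishart.rvs(df=dof, scale=S * (dof - N - 1), random_state=rng)
    H = (H + H.T) / 2
    nsr = float(np.linalg.norm(H - S) / np.linalg.norm(S))
    W = H * D[None, :]
    if strict_dale:
        W[np.sign(W) != D[None, :]] = 0.0
    cm = rescale_spectrum(ConnectivityMatrix(W=W, dale_signs=D), alpha)
    cm.construction = "hebb_dale+invwishart"
    cm.meta.update({"dof": dof, "noise_to_signal": nsr})
    return cm


def invwishart_dof_for_noise(Sigma_in: np.ndarray, target_nsr: float,
                             seed=0, n_draws: int = 20) -> int:
    """Degrees of freedom whose mean noise-to-signal ratio is ~ target.

    The expected relative Frobenius deviation of an inverse-Wishart draw
    from its mean decreases monotonically with dof; bisect on dof using a
    small Monte-Carlo average.
    """
    S = np.asarray(Sigma_in, dtype=float)
    N = S.shape[0]

    def mean_nsr(dof):
        rng = np.random.default_rng(seed)
        draws = stats.invwishart.rvs(df=dof, scale=S * (dof - N - 1),
                                     random_state=rng, size=n_draws)
        return float(np.mean([np.linalg.norm(H - S) / np.linalg.norm(S)
                              for H in draws]))

    lo, hi = N + 2, N + 2
    while mean_nsr(hi) > target_nsr:
        hi = 2 * hi
        if hi > 10**7:
            raise RuntimeError("could not bracket target noise-to-signal ratio")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if mean_nsr(mid) > target_nsr:
            lo = mid
        else:
            hi = mid
    return hi


def negative_cov_scenario(c: float, N: int, seed=None,
                          alpha: float = DEFAULT_ALPHA):
    """Mixed-sign input covariance with Dale-preserving pruning.

    Sigma^in is a uniform offset c plus a random PSD matrix with
    exponentially decaying spectrum; some off-diagonal covariances are
    negative (the more, the smaller c).  The Hebb-and-Dale weights built on
    it would violate Dale's law at those entries, so they are pruned (set to
    zero) before the spectral rescale.

    Returns ``(Sigma_in, ConnectivityMatrix)``; the fraction of negative
    off-diagonal covariances is recorded in ``meta["negative_fraction"]``.
    """
    ss = np.random.SeedSequence(seed)
    s_cov, s_signs = ss.spawn(2)
    S = make_input_covariance("neg_mix", N=N, params={"c": c}, seed=s_cov)
    D = draw_dale_signs(N, s_signs)
    off = ~np.eye(N, dtype=bool)
    neg_frac = float(np.mean(S[off] < 0))
    W = S * D[None, :]
    W[S < 0] = 0.0  # entries whose sign would oppose D_j
    cm = rescale_spectrum(ConnectivityMatrix(W=W, dale_signs=D), alpha)
    cm.construction = "hebb_dale+neg_pruned"
    cm.meta.update({"c": c, "negative_fraction": neg_frac})
    return S, cm


# --------------------------------------------------------------------- I/O
def save_matrix(path, M: np.ndarray, header: str = "") -> None:
    np.savetxt(path, np.asarray(M, float), header=header)


def load_matrix(path) -> np.ndarray:
    return np.loadtxt(path)
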