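# Methods

This note documents the models, estimator conventions, numerical choices and
known limitations of `seqnet`, in the order a user meets them.

## Network model

The circuit is a stochastic rate network of `N` units,

    tau dv_i/dt = -v_i + sum_j W_ij f[v_j] + xi_i(t),

integrated by forward Euler from `v = 0` (defaults `tau = 20 ms`,
`dt = 1 ms`, `T = 1e5` steps). The external input `xi` is a stationary
Gaussian process with mean `mu = 0.1`, spatial covariance `Sigma_in` and
exponential temporal autocovariance `exp(-|s|/tau_in)` with
`tau_in = 15 ms` — a spatially correlated Ornstein–Uhlenbeck process. The
input sampler uses the exact discretisation (decay factor `exp(-dt/tau_in)`,
stationary start), so the input statistics are exact at any step size while
the network itself remains Euler-integrated.

Two response functions are provided. `linear` (`f[v] = v`) is the default
for all covariance analyses: it is the regime in which the closed-form
theory below is exact, and the regime in which the simulated and analytic
sequentiality values agree (we verified element-wise agreement of simulated
and analytic lagged covariances to within 5 SE). `relu_clipped`
(`f[v] = min(max(slope*v, 0), 1)`) with the slope calibrated by bisection so
the mean population output hits a target (default 0.1, tolerance 2%) is
available for studies of saturating rate dynamics; note that the calibrated
slope rescales the *effective* recurrent gain (`slope * W`), so sequentiality
measured in that regime is systematically weaker than the linear analysis of
the same weight matrix and should not be compared against it. A first
10 `tau` of each run is discarded before analysis by default (configurable,
including 0) to remove the transient from the zero initial condition.

Spike generation (`poisson_spikes`) is Bernoulli per bin with probability
`rate * dt` — a valid inhomogeneous-Poisson approximation at
`rate * dt << 1`, at most one spike per bin — and exists for building
synthetic recordings and illustrations; all quantitative analyses run on
rates or membrane traces.

## The sequentiality estimator

**Covariance.** `C_jk(s) = mean_t (X_{j,t+s} - mu_j)(X_{k,t} - mu_k)` on a
symmetric lag grid (default ±200 ms in 2 ms bins). The series is split into
`M = 10` contiguous equal epochs (trailing remainder dropped); means are
removed per epoch (a global-mean switch exists); within an epoch the time
index runs over the common window valid for every lag and the sum is
normalised by that window's (lag-independent) length, so the estimator is
identically biased across lags. A per-lag normalisation variant is exposed
as an option. The per-epoch estimates are averaged and retained.

**Decomposition.** The covariances are arranged into
`Gamma[i + j*N, s] = C_ij(s)` (an invertible mapping; `unflatten_gamma` is
the inverse). Parity classification is structural: `Gamma` is split into its
even and odd parts along the lag axis and each part is decomposed by SVD
separately. This is mathematically equivalent to classifying singular
vectors of the full matrix (for stationary covariances each singular vector
has definite parity) but robust to degenerate singular values; the union of
the two spectra carries the total energy `sum sigma^2 = ||Gamma||_F^2`
exactly. Lag 0 belongs to the even part only.

**Noise floor.** Differences of epoch pairs cancel the common signal;
`Delta Gamma / sqrt(2M)` has the singular-value distribution of the noise in
the M-epoch mean (a pair difference carries twice the per-epoch noise
covariance; the mean carries 1/M of it — verified against a direct
Monte-Carlo oracle). All M(M−1)/2 pair draws are pooled; components of the
signal spectrum below `mu + 7*sd` of the pooled draws are discarded. The
pooled draws are the **full-matrix** singular values of each difference:
pooling parity-split halves instead places the threshold at the mean of the
top odd-part noise singular value for strongly correlated inputs and
produces ~50% spurious detections on non-sequential input, while the
full-matrix floor eliminates them without affecting true detections.

**Index.** Raw: `||C_asy||_F / ||C_sym||_F` over the grid. Denoised: the
root-ratio of surviving anti-symmetric to symmetric singular energy. If no
anti-symmetric component survives while a symmetric one does, the result is
exactly 0. If no component of either parity survives (or the symmetric norm
vanishes), the result is *undefined* — returned as NaN with an
`UndefinedSequentiality` warning, not as 0, mirroring the exclusion rule
used for recordings too short to estimate the index. The index is invariant
under unit permutation, common rescaling, and (up to estimator edge effects)
time reversal, and lies in [0, 1] for stationary series whose covariance
decays inside the lag window. Deterministic cyclic signals measured on a
grid that does not tile their period can exceed 1 by a grid-parity residue
(see "Perfect sequences" below).

`SequentialityAnalysis` wraps the full chain as a scikit-learn estimator
(`fit`, fitted attributes `seq_`, `seq_raw_`, `spectrum_`, `noise_floor_`,
`get_params`/`set_params`), accepting a `TimeSeries` or a
`(n_timepoints, n_units)` array.

**Spike smoothing.** Recordings enter as (time, unit) events, binned at 2 ms
and filtered with a causal exponential kernel; the stated 10 ms "width" is
interpreted as the exponential time constant, and the kernel is normalised
to unit area so a homogeneous train of rate r averages to r.

## Closed-form theory

For linear dynamics the joint process (v, xi) is a linear SDE; its
stationary covariance solves a continuous-time Lyapunov equation, and lagged
covariances follow by matrix-exponential propagation (`C(-s) = C(s)^T` holds
exactly). An independent quadrature oracle (spectral-density integral for
the one-unit case) cross-checks the implementation. The analytic
sequentiality is the raw ratio on the analytic covariance — no noise floor
is involved — computed on the same ±200 ms grid as the estimator so the two
are directly comparable.

Two elementary motifs generate sequences in two-unit symmetric circuits:
unequal input variances times the coupling, `(Sigma_22 - Sigma_11) W_12`,
and unequal self-connections times the input covariance,
`(W_11 - W_22) Sigma_12`. The magnitude of their sum predicts the
anti-symmetric covariance energy up to a global constant — but only to
leading order: empirically the energy scales as the *square* of the motif
total, and the residual scatter is almost entirely explained by
near-instability prefactors (regressing the log energy on the motif total
plus `log(1 - lambda_max)` and `log(1 - lambda_min)` raises the log-log
correlation from ~0.86 to ~0.997 over random two-unit ensembles). The
package exposes both the motif decomposition and the exact energy.

**Hebb-and-Dale.** `W_ij = Sigma_in_ij * D_j` with per-presynaptic signs
`D_j = ±1`, rescaled so the maximum real eigenvalue is `alpha = 0.9`,
produces analytic sequentiality at numerical zero (< 1e-8 across seeded
ensembles) when driven by input with that same spatial covariance — the
erasure condition at the heart of the package. The same holds when the
Hebbian factor is the *output* covariance of such a network. Perturbed
ensembles (90% sparsification, inverse-Wishart Hebbian noise at a target
noise-to-signal ratio, mixed-sign covariances with Dale-preserving pruning)
quantify the robustness envelope; the inverse-Wishart scale is chosen so the
draw's mean equals `Sigma_in` (`scale = Sigma_in * (dof - N - 1)`), and a
helper bisects the degrees of freedom to reach a requested noise-to-signal
ratio. Sparsified matrices are not re-rescaled (matching the construction
they perturb) unless sparsification pushes the spectral abscissa past 0.95,
in which case they are rescaled back to 0.9 for stability of the analytic
route. The mixed-sign scenario prunes (rather than sign-flips) offending
synapses, then rescales.

Ensemble conventions: random matrices start from iid Gaussian entries of
variance `alpha^2/N`; the symmetric and anti-symmetric ensembles apply
`(W ± W^T)/(2*sqrt(2))` (the constant that preserves the semicircle radius);
the anti-symmetric ensemble has spectral abscissa 0 and is therefore
rescaled by spectral *radius* to `alpha`; the Dale ensemble applies
`|W_ij| * sign(column sum)`.

## Mean-field STDP

The plasticity kernel is `k(s) = a_+ exp(-s/tau_+)` for pre-leads-post
(s ≥ 0) and `-a_- exp(s/tau_-)` for s < 0, sign-reversed for inhibitory
presynaptic units (defaults `tau_± = 15 ms`, `a_+ = 0.4375/tau_+`,
`a_- = 0.25/tau_-`, interpreted per ms; net area +0.1875). Averaged over the
fast dynamics, a synapse drifts as

    dW_ij/dt = (1/tau_s) [ s_j * Int k(s) C_ij(s) ds  -  lambda W_ij ],

with `tau_s = 10 min`, trapezoid integration on the lag grid, and
multiplicative decay `lambda`. The effective presynaptic sign `s_j` is by
default the sign of column j's sum (so signs can flip and Dale's law can
*emerge*); a frozen-signs mode serves post-convergence continuation runs.

Two numerical choices matter here:

- **Saturation of the drive.** With a purely linear covariance the Hebbian
  term grows superlinearly as the spectral abscissa approaches 1 and outruns
  the linear decay — flows started from strongly recurrent matrices diverge.
  Biologically the covariance is bounded by rate saturation; the package
  models this by evaluating the plasticity integral at the saturated
  effective coupling `gamma W`, `gamma = min(1, gain_cap/abscissa(W))`
  (default `gain_cap = 0.5`), while the *reported* sequentiality along the
  trajectory is always that of the full W.
- **Decay calibration and integrator.** `lambda` defaults to the
  least-squares scale aligning the kernel integral with the direct
  Hebb-and-Dale solution at `alpha = 0.9`, so the flow relaxes toward
  weights of that spectral scale. The flow's relaxation time is
  `tau_s/lambda`; the Euler step is 5% of it and the default run covers 12
  relaxation times, with ~25 snapshots of (t, W, analytic seq, Dale
  fraction).

With these defaults, runs from the random-symmetric start erase
sequentiality (initial ~0.2–0.3 decaying below 1e-3), converge to weights
correlated ≥ 0.98 with the direct Hebb-and-Dale solution (optimal per-column
signs), and end with every column single-signed; after a sudden input
switch, sequentiality jumps and is erased again with the Dale structure
preserved.

## Synthetic data

`perfect_sequence` builds `X[j, t] = f((t - j) mod N)` — each row a one-step
circular shift of the previous, the idealised synfire-like pattern. Its raw
sequentiality over a symmetric lag grid spanning one period equals 1
*exactly when the grid tiles the cycle*, i.e. for odd N with
`max_lag = (N-1)/2` (verified to 1e-6 for raised-cosine, Gaussian and
triangular profiles). For even N no symmetric integer grid tiles the period
and a residue of order 1/N remains (0.953 at N = 20); sub-period grids can
even push the ratio slightly above 1. `white_noise` provides the
false-positive control (≤ 2% spurious nonzero denoised seq over 100 seeds).
Named scenarios bundle the figure-style generative setups (random symmetric;
two-unit motifs; matched / mismatched / readapted Hebb-and-Dale; STDP
starts) with per-object seed streams so the same (name, seed) is
bit-reproducible and changing N does not shift unrelated draws. In the
mismatched scenario both the correlation structure and the per-unit
variances of the input are redrawn; with variances held fixed the mismatch
signal (~0.04 analytic) falls below the 7σ floor at the study duration and
the measured index collapses to zero.

## Pipeline and statistics

`analyze_recording` smooths events once over the full recording, excises the
declared per-condition trial windows, concatenates them (covariances are
never computed across condition gaps), and runs the estimator per condition,
optionally on early/late halves of the concatenated time. Cohort
comparisons: a two-tailed paired t-test on log seq, excluding (and
reporting) subjects with zero or undefined seq in either member — the log is
undefined for them — or a Wilcoxon signed-rank test on raw values with no
exclusions. No multiple-testing correction is applied by default (single
planned comparisons); channel inclusion defaults to all channels present in
the event file.

## Problem sizes used in the shipped checks

Simulated replications run at the study conditions (N = 50, T = 1e5 steps);
stochastic medians use 5–10 seeds; the robustness envelope uses 20 networks
per condition (analytic route); the randomized bound fleet uses 500 small
cases; property checks on the estimator run at N ≤ 10 with T ≤ 1e5, sizes at
which the Monte-Carlo error bands quoted above were computed.

## Known limitations

- The index sees only second-order statistics: a circuit generating a
  sequence equally often forward and backward appears non-sequential, and
  the index does not identify *which* sequences are present.
- The analytic module requires stable linear dynamics (spectral abscissa of
  W below 1) and inherits the ±200 ms lag truncation; modes with time
  constants near `tau/(1-alpha)` are only partially captured.
- The denoised index is conservative by construction: weak sequential
  structure (raw ratio below roughly 0.05 at the default duration and floor)
  is reported as 0, and the early/late split halves the data and raises the
  floor accordingly.
- The mean-field STDP scheme is a rate-based average with a saturation bound
  standing in for the full nonlinear dynamics; it makes no claims about
  spike-based weight trajectories, only about their average flow and fixed
  points.
- Recordings must be converted to the simple (time, unit) event format;
  proprietary electrophysiology containers are out of scope.
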