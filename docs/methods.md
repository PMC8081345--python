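# Methods

`metapac` detects *metastable phase–amplitude-coupling (PAC) states* in
multichannel oscillatory signals and models their transition dynamics with
a noise-driven coupled-oscillator network.  This note documents the models,
the estimation procedures, the tunable parameters, and the design choices
made where the methodology was genuinely open.

## The detection problem

A nested oscillation — a slow rhythm at `f1` whose phase modulates the
amplitude of a faster rhythm at `f2` — lives on a torus in state space.  If
the *strength* of that modulation switches among a small repertoire of
levels, the system makes transitions between d-dimensional oscillatory
states that cannot be seen as clusters in the raw signal.  The detection
pipeline collapses one torus dimension per step:

1. **Multi-step envelope analysis.**  The instantaneous amplitude
   (modulus of the complex Morlet transform,
   `Psi(t) = f exp(i 2 pi f t) exp(-t^2 / 2 sigma^2)`, with
   `n_co = 6 f sigma = 3` cycles) is computed `d` times, from the fastest
   peak frequency `f_d` down to `f_1`.  Each step trims `n_co / (2f)`
   seconds per edge, which exactly matches the ±3σ kernel support, so no
   retained sample mixes with zero padding.  Peak frequencies come from
   channel-averaged Welch spectra (window ≥ 10 cycles of the band floor,
   50% overlap); for the raw broad band (1–45 Hz) each channel's log-power
   is detrended against log-frequency first to remove the `1/f^beta`
   background.
2. **State labeling.**  The final envelopes `A_0(t)` are clustered by
   Euclidean k-means with a deterministic PCA-partitioning initialization
   (recursively split the cluster of largest within-scatter at its centroid
   along its first principal axis).  The number of states `K in {2..10}` is
   chosen by the Calinski–Harabasz index, ties toward smaller K.  No
   kernelization.  Empty clusters during Lloyd steps are reseeded at the
   point farthest from its centroid, keeping the labeling bitwise
   reproducible — important because the surrogate test re-clusters hundreds
   of data sets and any run-to-run jitter would contaminate the null.
3. **Attracting-state test.**  The labeled envelopes are projected by
   Fisher LDA onto `m = min(2, K-1)` axes; on a shared histogram grid
   (Freedman–Diaconis widths, anchored at the pooled minimum) the statistic
   `E = min_k max-bin-count(state k)` measures how tightly every state
   concentrates.  The null — `A_0` is linearly correlated Gaussian noise —
   is represented by 200 multivariate Fourier-transform surrogates (one
   shared random phase sequence, all cross-spectra preserved), each
   re-clustered at the same K and binned with the same fitted geometry.
   One-sided `p = (1 + #{E' >= E}) / (1 + n_surrogates)`; reject at 0.05.

**Top-level frequency rule.**  Within the chain each frequency is the
argmax of the preceding envelope's spectrum, but the *top* of the hierarchy
is chosen as the **fastest prominent spectral peak** (local maxima of the
detrended log-spectrum with prominence ≥ 1 natural-log unit, sideband peaks
within a quarter octave of the fastest merged into one group, strongest
group member returned).  A plain argmax would select a slow narrowband
carrier whenever it is stronger than the fast rhythm — and the envelope
transform only exposes structure *slower* than the analyzed frequency, so
starting from the slow rhythm terminates the hierarchy immediately.  For
1/f-background spectra the two rules coincide.

## The generative model

N PAC oscillators, each with slow-band phase `phi_i` and fast-band
amplitude `r_i`:

    dr_i/dt   = r_i (1 - r_i^2) + k_ad * sum_j J_ad_ij cos(phi_j + b_ad_ij)
    dphi_i/dt = omega + k_d * sum_j J_d_ij sin(phi_j - phi_i + b_d_ij) + D eta_i(t)

with `omega = 2 pi f1`, `k_d = k_ad = 0.1`, and `eta ~ N(0, Sigma)`.
Integration is Euler–Maruyama (noise increment `D sqrt(dt) eta`), default
`dt = 0.01 s`; trajectories are reproducible given a seed, and noiseless
runs are seed-independent.  The phase subsystem is a noisy
Kuramoto–Sakaguchi network; the `j = i` term is kept as a bias inherited
from the connectivity estimation; with all couplings and noise off every
node is an independent Stuart–Landau oscillator relaxing to `r = 1`.

A repertoire of K synchronous states is *embedded* via the pseudoinverse
rule `C_d = P P^+`, `P_ij = exp(i theta_i^j)`: the orthogonal projector
onto the pattern phasors, which makes every pattern a fixed direction of
the noiseless flow.  The fluctuation covariance
`Sigma_ij = (1/K) |sum_mu exp(i(theta_i^mu - theta_j^mu))|` (projected to
the nearest SPSD matrix by eigenvalue clipping) correlates the noise at
node pairs whose relative phase is conserved across patterns, so the noise
preferentially drives motion *between* patterns.

**PAC connectivity.**  `C_ad` cannot affect the transition dynamics and is
arbitrary in that sense; the package default is magnitude `1/N` with fixed
i.i.d. uniform phase lags.  The lags must be heterogeneous: with identical
lags every amplitude receives the same drive, the simulated scalp
amplitudes are spatially uniform, and the closed-loop validation carries no
state information.

## Estimation from labeled dynamics

- **Phase patterns** (per state): circular means of all pairwise phase
  differences give a synchrony index `R_ij^mu` and mean difference
  `psi_ij^mu`; the pattern is reconstructed by a greedy chain over channels
  ordered once by the state-averaged index (most reliable pair seeds the
  chain; each hop assigns `theta_j = theta_i - psi_ij`; argmax ties break
  toward the lowest channel index).  Patterns are defined up to a global
  rotation; recovery is scored by the rotation-invariant similarity
  `(1/N) |sum_j exp(i(a_j - b_j))|`.
- **Connectivity**: the pseudoinverse rule applied to the reconstructed
  patterns.
- **Fluctuation level**: grid search `D in {0, 0.02, ..., 1}`.  For each
  candidate the phase-only network is simulated (coarse `dt = 0.2 s`,
  default 100 repetitions), labeled by pattern overlaps
  `M_mu = (1/N) |sum_j exp(i(phi_j - theta_j^mu))|`, and the per-state
  maximum/median/minimum dwell times (run lengths between transitions,
  truncated edge runs excluded, in seconds) are compared with the data's by
  RMSE; the repetition-averaged curve is minimized.

Two procedural choices matter here and were left open by the methodology:

- **Burn-in.**  From scattered initial phases the network needs on the
  order of `1/k_d` (empirically ~100 s at `k = 0.1`, N = 63) to lock onto
  its attractor manifold.  All analysis simulations therefore discard a
  120 s burn-in; estimating patterns from a window that includes the
  transient biases the per-state circular means heavily.
- **Dwell-time resolution.**  The data's labels live at the fine simulation
  step while the grid-search simulations are quantized at 0.2 s; comparing
  run lengths across that gap truncates the data's long dwells (sample-
  scale overlap flicker) on one side only and biases the estimate upward.
  Target dwell statistics are therefore extracted from labels subsampled to
  the estimation step.  Inside the grid search a state without interior
  runs falls back to edge-inclusive runs (zero if unvisited): low noise
  levels legitimately produce single-state windows and must remain
  comparable.

## Current source density and observation

Scalp-to-source sharpening uses the spherical-spline surface Laplacian
(spline order m = 4, 50 Legendre terms, smoothing `lambda = 1e-5`):
per sample the mean-subtracted potentials are fitted by the regularized
spline system with a sum-to-zero constraint and mapped through the
Laplacian matrix H.  The observation operator `h = G H^{-1}` (pseudoinverse
fallback above condition number 1e12) maps simulated source amplitudes back
to scalp space, where one envelope pass around `f1` yields the simulated
final envelopes for the closed-loop test.  The bundled montage is a
63-channel 10/10 unit-sphere table derived from the standard template cap.

## Synthetic study conditions

The package is exercised entirely on synthetic data with fixed study
conditions:

- **Toy PAC ensemble** (the detection demonstration):
  `x_i = cos(2 pi f1 t + psi_i) + 0.5 [1 + b(t) cos(2 pi f1 t + psi_i)] sin(2 pi f2 t) + xi_i`,
  with `f1 = 1 Hz`, `f2 = 10 Hz`, noise SD 0.3, and `b(t)` cycling through
  {0.15, 0.5, 0.85} in 20 s segments shared across channels.  Defaults:
  63 channels, 180 s at 250 Hz; channel phase offsets `psi_i` i.i.d.
  uniform.  What this emulates: a global three-state PAC transition
  dynamics.  What it does not: real-EEG artifacts, drift, a 1/f background
  with broadband delta (its slow rhythm is a pure line — see the top-level
  frequency rule above), or inter-channel source mixing.
- **Correlated pattern ensemble** (the estimation validation): one uniform
  reference pattern, P = 3 copies perturbed by wrapped Gaussian noise with
  `sigma = 0.5`, N = 63, network simulated 180 s at the true `D = 0.5`.
- Trait tables for the correlation suite are synthesized with planted
  population correlations and Gaussian residuals.

A trajectory that never visits one of the embedded states carries no
information about that state's pattern; the validation redraws the
simulation seed (bounded retries) until every state is visited, and the
closed-loop test additionally requires a minimum per-state occupancy.

## Group and behavioral statistics

Modified z-scores (`0.6745 (x - median)/MAD`); PCA of state topographies
with a channel-shuffle permutation null (plain empirical p so a Bonferroni
correction across components remains attainable at 200 permutations);
sliding mean-vector modulation index (window = one slow period, hop = one
sample) with Benjamini–Hochberg control across channels; partial Pearson
correlations of each dynamics statistic with each trait subscore adjusting
the remaining statistics, Bonferroni-corrected across the pair grid, plus a
post-hoc multiple-correlation regression reporting F on (k, n-k-1) degrees
of freedom and factor loadings; and the pooled two-proportion z test.

## Numerical choices and problem sizes

- Wavelet kernels truncate at ±3σ (<1.2% Gaussian mass lost).
- LDA within-class scatter receives a ridge `1e-8 tr(S_w)/N` when its
  condition number exceeds 1e10.
- The depth-0 analysis band-passes 1–45 Hz with a zero-phase 4th-order
  Butterworth filter.
- Unit tests run on reduced ensembles (8–16 channels, 60–120 s) whose
  statistical behavior matches the full-size conditions; the acceptance
  checks use the full 63-channel configurations.  The grid search in the
  test suite uses 10–20 repetitions of the RMSE calculation; the validation
  script uses the full 100.

## Known limitations

- The fluctuation-level estimator's RMSE curve is shallow around its
  minimum, so `D_hat` scatters by roughly ±0.1 across realizations even at
  100 repetitions; it recovers the true level at that accuracy, not better.
- The phase-lag (argument) part of the re-estimated connectivity is
  ill-conditioned where coupling magnitudes are small — tiny angular errors
  flip signs — so its cosine similarity is intrinsically noisier than the
  magnitude part.
- The top-level frequency rule assumes the fast rhythm produces a prominent
  spectral peak; a PAC hierarchy whose carrier is buried in broadband noise
  will not be detected.
- Overlap-based labels flicker at the sample scale near state boundaries;
  dwell-time statistics therefore depend on the label resolution, which is
  why the estimator harmonizes it explicitly.
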