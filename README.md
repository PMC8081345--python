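# metapac

Detection of **metastable phase–amplitude-coupling (PAC) states** in
multichannel oscillatory signals, and modeling of their transition dynamics
with a noise-driven coupled-oscillator network.

Resting-state brain signals (and nested oscillations in general) often
consist of a slow rhythm at `f1` whose phase modulates the amplitude of a
faster rhythm at `f2`, with the modulation strength itself switching among
a small repertoire of levels.  Such dynamics live on a torus in state
space and are invisible to ordinary clustering of the raw signal.
`metapac` implements:

- **Metastable-states clustering** — repeated Morlet-envelope extraction
  (one torus dimension collapsed per step), deterministic k-means with
  Calinski–Harabasz selection of the number of states, LDA projection, and
  a multivariate Fourier-transform surrogate test of the attracting
  statistic `E = min_k max-bin-count(state k)` against the linear-Gaussian
  null.
- **A coupled delta–alpha PAC oscillator network** — Kuramoto–Sakaguchi
  phases driving Stuart–Landau amplitudes,
  `dphi_i/dt = omega + k sum_j J_ij sin(phi_j - phi_i + beta_ij) + D eta_i(t)`,
  with a repertoire of synchronous phase patterns embedded through the
  pseudoinverse connectivity `C = P P^+` and pattern-structured noise
  covariance; plus the full estimation stack (per-state circular phase
  statistics, greedy pattern reconstruction, connectivity re-estimation,
  dwell-time RMSE grid search for the fluctuation level `D`).
- **Current source density** (spherical-spline surface Laplacian) and the
  observation operator mapping simulated sources back to scalp space.
- **Group/behavioral statistics** — modified z-scores, permutation-tested
  PCA of state topographies, a sliding modulation index, partial-correlation
  trait analysis, and two-proportion tests.
- Synthetic generators for every input the analyses need, so the whole
  pipeline runs without any recorded data.

It is aimed at researchers analyzing multichannel oscillatory recordings
(EEG-like layouts) or studying metastability in coupled-oscillator models.

## Worked example

Generate the three-state toy ensemble (slow 1 Hz carrier, amplitude-
modulated 10 Hz component, modulation depth cycling through
0.15 / 0.5 / 0.85) and run the depth-2 analysis:

```python
from metapac import ToySpec, gen_toy_pac_signals, run_label

series, true_labels, b = gen_toy_pac_signals(ToySpec(seed=0))
report = run_label(series, d=2, n_surrogates=200, seed=0)
print(report.summary())
```

```
{'d': 2, 'peak_frequencies_hz': [10.0, 1.0], 'K': 3, 'E': 738,
 'p': 0.004975124378109453, 'reject': True,
 'dwell_max_s': [19.732, 19.956, 19.724],
 'dwell_median_s': [19.72, 19.936, 19.69],
 'dwell_min_s': [19.708000000000002, 0.632, 19.656]}
```

Reading this: the chain estimated the fast and slow peak frequencies at
10 Hz and 1 Hz, found `K = 3` states whose labels track the three
modulation levels, and the attracting statistic `E` of the projected state
histograms beat all 200 phase-randomized surrogates (`p = 1/201`), so the
dynamics are identified as two-dimensional metastable PAC states.  The
dwell times essentially recover the generator's 20 s switching schedule
(each run loses the two wavelet trims; one brief mislabeled interval shows
up as a 0.6 s minimum dwell for state 2).

The same can be done from the shell:

```sh
metapac toy --out toy.tsv --seed 0
metapac label toy.tsv --d 2 --seed 0 --out report.json
```

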