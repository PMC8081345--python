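"""End-to-end pipelines: labeling, model estimation, simulation, and the
synthetic parameter-recovery validation.

``run_label`` is the full metastable-states analysis for one recording at
one or several envelope depths d; ``run_estimate`` fits the coupled
PAC-oscillator model from a labeled recording; ``run_simulate`` closes the
loop by simulating the fitted model, observing it at the scalp and testing
the simulated dynamics the same way as the data.  ``validate_recovery`` checks
the whole estimation stack on a ground-truth synthetic ensemble: build a
repertoire of correlated phase patterns, design the connectivity that
embeds them, simulate the noisy phase network, then re-estimate patterns,
connectivity and noise level and score the recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MultichannelSeries, StateLabeling
from .csd import Montage, csd_transform
from .envelopes import bandpass, envelope_chain, peak_frequency
from .estimation import (
    D_GRID_DEFAULT,
    DwellStats,
    dwell_statistics,
    estimate_fluctuation_level,
    extract_phases,
    fluctuation_covariance,
    ppc_from_patterns,
    reconstruct_patterns,
    state_phase_stats,
)
from .fixtures import PatternGenSpec, gen_phase_pattern_set
from .labeling import select_num_states
from .metastability import lda_project, metastability_test
from .simulator import PPCModel, overlap_labels, simulate_observation, simulate_pac


@dataclass
class LabelReport:
    """Machine-readable outcome of the labeling analysis at one depth d."""

    d: int
    peak_frequencies: list[float]
    K: int
    labeling: StateLabeling
    A0: MultichannelSeries
    p: float
    reject: bool
    E: int
    dwell: DwellStats | None

    def summary(self) -> dict:
        out = {
            "d": self.d,
            "peak_frequencies_hz": [round(f, 4) for f in self.peak_frequencies],
            "K": self.K,
            "E": self.E,
            "p": self.p,
            "reject": self.reject,
        }
        if self.dwell is not None:
            out["dwell_max_s"] = self.dwell.table[0].tolist()
            out["dwell_median_s"] = self.dwell.table[1].tolist()
            out["dwell_min_s"] = self.dwell.table[2].tolist()
        return out


def run_label(
    series: MultichannelSeries,
    d: int,
    K_range: tuple[int, ...] = tuple(range(2, 11)),
    n_surrogates: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> LabelReport:
    """Label one recording as metastable states at envelope depth d.

    For d >= 1 the envelope chain supplies the final envelopes A_0 and the
    peak frequencies f_d..f_1; for d = 0 the raw series is band-pass
    filtered 1-45 Hz and clustered directly.
    """
    if d == 0:
        A0 = bandpass(series)
        freqs: list[float] = []
    else:
        chain = envelope_chain(series, d)
        A0 = chain.final
        freqs = list(chain.peak_frequencies)
    labeling = select_num_states(A0.data.T, K_range=K_range)
    projection, _ = lda_project(A0.data.T, labeling)
    verdict = metastability_test(
        A0, labeling, projection, n_surrogates=n_surrogates, alpha=alpha, seed=seed
    )
    try:
        dwell = dwell_statistics(labeling, dt=1.0 / A0.sample_rate)
    except ValueError:
        dwell = None
    return LabelReport(
        d=d,
        peak_frequencies=freqs,
        K=labeling.K,
        labeling=labeling,
        A0=A0,
        p=verdict.p,
        reject=verdict.reject,
        E=verdict.E_observed,
        dwell=dwell,
    )


def run_estimate(
    series: MultichannelSeries,
    labeling: StateLabeling,
    montage: Montage,
    f1: float,
    grid: np.ndarray = D_GRID_DEFAULT,
    reps: int = 100,
    est_duration: float = 180.0,
    seed: int = 0,
) -> tuple[PPCModel, np.ndarray, np.ndarray]:
    """Fit the coupled PAC-oscillator model from a labeled recording.

    Returns (model, patterns, rmse_curve).  Phases are extracted from the
    CSD of the raw series around f1; the labeling must share the phase
    series' time base (both are aligned to A_0's trimmed support upstream).
    """
    csd = csd_transform(series, montage)
    theta = extract_phases(csd, f1)
    n = min(theta.n_samples, labeling.n_samples)
    stats = state_phase_stats(
        theta.data[:, :n], StateLabeling(labeling.labels[:n], K=labeling.K)
    )
    stats = reconstruct_patterns(stats)
    patterns = stats.patterns
    C_delta = ppc_from_patterns(patterns)
    Sigma = fluctuation_covariance(patterns)
    model = PPCModel(C_delta=C_delta, omega=2.0 * np.pi * f1, Sigma=Sigma)
    # harmonize the label resolution with the coarse estimation simulations
    est_dt = 0.2
    stride = max(1, int(round(est_dt * series.sample_rate)))
    target = dwell_statistics(
        StateLabeling(labeling.labels[:n:stride], K=labeling.K),
        dt=stride / series.sample_rate,
    )
    D_hat, rmse = estimate_fluctuation_level(
        model,
        patterns,
        target,
        grid=grid,
        reps=reps,
        duration=est_duration,
        dt=est_dt,
        seed=seed,
    )
    model.D = D_hat
    return model, patterns, rmse


def run_simulate(
    model: PPCModel,
    patterns: np.ndarray,
    montage: Montage,
    f1: float,
    duration: float = 180.0,
    dt: float = 0.01,
    n_surrogates: int = 200,
    seed: int = 0,
    D_schedule: np.ndarray | None = None,
):
    """Simulate the fitted model, observe at the scalp and test the loop.

    Returns (result, verdict); the verdict re-runs the labeling analysis on
    the simulated scalp envelopes with overlap-based labels, mirroring the
    treatment of the recorded data.
    """
    result = simulate_pac(
        model, duration=duration, dt=dt, seed=seed, D_schedule=D_schedule
    )
    M, labels = overlap_labels(result.phases, patterns)
    result.overlaps, result.labels = M, labels
    _, A0 = simulate_observation(result, montage, f1)
    # align overlap labels to the trimmed envelope support
    offset = int(round((A0.t0 - 0.0) / result.dt))
    lab = StateLabeling(
        labels.labels[offset : offset + A0.n_samples], K=labels.K
    )
    projection, _ = lda_project(A0.data.T, lab)
    verdict = metastability_test(
        A0, lab, projection, n_surrogates=n_surrogates, seed=seed
    )
    return result, verdict


def closed_loop_validation(
    n_channels: int = 63,
    n_patterns: int = 3,
    sigma: float = 0.5,
    D: float = 0.5,
    f1: float = 1.0,
    duration: float = 180.0,
    dt: float = 0.01,
    burn_in: float = 120.0,
    n_surrogates: int = 50,
    min_occupancy: int = 500,
    seed: int = 0,
    montage: Montage | None = None,
) -> dict:
    """Simulate the full PAC network and test the observed dynamics.

    The fitted-model analogue of the experimental analysis: simulate phases
    and amplitudes, map the source amplitudes to scalp space, take one
    envelope around f1 (the depth-2 analysis of dynamics whose first
    envelope level is implicit in the amplitude variables), label by
    pattern overlaps and run the surrogate test.  The depth-1 analogue
    tests the scalp amplitude series itself, without the envelope step.
    Trajectories that leave some state underpopulated (fewer than
    ``min_occupancy`` samples) are redrawn; the attracting statistic of a
    barely-visited state is uninformative.

    Returns a dict with the two verdicts and the occupancy used.
    """
    from .csd import standard_montage_1010

    if montage is None:
        montage = standard_montage_1010()
    rng = np.random.default_rng(seed)
    _, patterns = gen_phase_pattern_set(
        PatternGenSpec(
            n_channels=n_channels,
            n_patterns=n_patterns,
            sigma=sigma,
            seed=int(rng.integers(2**31 - 1)),
        )
    )
    model = PPCModel(
        C_delta=ppc_from_patterns(patterns),
        omega=2.0 * np.pi * f1,
        Sigma=fluctuation_covariance(patterns),
        D=D,
    )
    for _attempt in range(20):
        result = simulate_pac(
            model,
            duration=duration,
            dt=dt,
            seed=int(rng.integers(2**31 - 1)),
            burn_in=burn_in,
        )
        _, labels = overlap_labels(result.phases, patterns)
        if labels.counts().min() >= min_occupancy:
            break
    else:
        raise RuntimeError("no trajectory populated every state sufficiently")

    A1, A0 = simulate_observation(result, montage, f1)
    offset = int(round((A0.t0 - A1.t0) / result.dt))
    lab0 = StateLabeling(labels.labels[offset : offset + A0.n_samples], K=labels.K)
    proj2, _ = lda_project(A0.data.T, lab0)
    verdict_d2 = metastability_test(
        A0, lab0, proj2, n_surrogates=n_surrogates, seed=int(rng.integers(2**31 - 1))
    )
    proj1, _ = lda_project(A1.data.T, labels)
    verdict_d1 = metastability_test(
        A1, labels, proj1, n_surrogates=n_surrogates, seed=int(rng.integers(2**31 - 1))
    )
    return {
        "occupancy": labels.counts(),
        "d2": verdict_d2,
        "d1": verdict_d1,
    }


@dataclass
class RecoveryReport:
    """Recovery scores of the synthetic parameter-estimation validation."""

    similarities: np.ndarray          # per-pattern circular similarity
    cosine_magnitude: float
    cosine_argument: float
    D_hat: float
    rmse_curve: np.ndarray
    true_D: float
    n_channels: int

    def summary(self) -> dict:
        return {
            "pattern_similarities": [round(s, 4) for s in self.similarities],
            "cosine_similarity_magnitude": round(self.cosine_magnitude, 4),
            "cosine_similarity_argument": round(self.cosine_argument, 4),
            "estimated_fluctuation_level": self.D_hat,
            "true_fluctuation_level": self.true_D,
            "n_channels": self.n_channels,
        }


def circular_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """(1/N) |sum_j exp(i(a_j - b_j))| — 1 iff a and b agree up to rotation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.abs(np.exp(1j * (a - b)).mean()))


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def validate_recovery(
    n_channels: int = 63,
    n_patterns: int = 3,
    sigma: float = 0.5,
    true_D: float = 0.5,
    f1: float = 1.0,
    duration: float = 180.0,
    dt_data: float = 0.01,
    dt_estimation: float = 0.2,
    burn_in: float = 120.0,
    grid: np.ndarray = D_GRID_DEFAULT,
    reps: int = 100,
    seed: int = 0,
) -> RecoveryReport:
    """Ground-truth validation of the whole estimation stack.

    1. Draw one uniform reference phase pattern and ``n_patterns``
       correlated copies (Gaussian perturbation of scale ``sigma``).
    2. Design the embedding connectivity and fluctuation covariance, and
       simulate the noisy phase network at the true fluctuation level
       (an initial ``burn_in`` is discarded so the analyzed window samples
       the attractor regime).
    3. Label the trajectory by pattern overlaps, re-estimate the patterns
       from per-state mean phase differences, re-estimate the connectivity,
       and grid-search the fluctuation level by dwell-time RMSE.
    4. Score pattern recovery (circular similarity per pattern) and
       connectivity recovery (cosine similarity of the vectorized magnitude
       and phase-lag parts).

    A trajectory that never visits one of the embedded states carries no
    information about that state's pattern, so the data simulation is
    redrawn with a fresh seed until every state is visited (bounded retries).
    """
    rng = np.random.default_rng(seed)
    _, generated = gen_phase_pattern_set(
        PatternGenSpec(
            n_channels=n_channels,
            n_patterns=n_patterns,
            sigma=sigma,
            seed=int(rng.integers(2**31 - 1)),
        )
    )
    C_true = ppc_from_patterns(generated)
    Sigma_true = fluctuation_covariance(generated)
    model_true = PPCModel(
        C_delta=C_true, omega=2.0 * np.pi * f1, Sigma=Sigma_true, D=true_D
    )
    for _attempt in range(20):
        sim = simulate_pac(
            model_true,
            duration=duration,
            dt=dt_data,
            seed=int(rng.integers(2**31 - 1)),
            with_amplitudes=False,
            burn_in=burn_in,
        )
        _, labels = overlap_labels(sim.phases, generated)
        if np.all(labels.counts() > 0):
            break
    else:
        raise RuntimeError("no simulated trajectory visited all embedded states")

    stats = state_phase_stats(sim.phases, labels)
    stats = reconstruct_patterns(stats)
    estimated = stats.patterns
    similarities = np.array(
        [circular_similarity(generated[mu], estimated[mu]) for mu in range(n_patterns)]
    )

    C_est = ppc_from_patterns(estimated)
    cos_mag = cosine_similarity(np.abs(C_true), np.abs(C_est))
    cos_arg = cosine_similarity(np.angle(C_true), np.angle(C_est))

    Sigma_est = fluctuation_covariance(estimated)
    model_est = PPCModel(
        C_delta=C_est, omega=2.0 * np.pi * f1, Sigma=Sigma_est
    )
    # dwell statistics are compared against simulations at the coarse
    # estimation step; evaluate the target at the same label resolution so
    # run lengths are not truncated by sample-scale flicker on one side only
    stride = max(1, int(round(dt_estimation / dt_data)))
    target = dwell_statistics(
        StateLabeling(labels.labels[::stride], K=labels.K), dt=dt_data * stride
    )
    D_hat, rmse = estimate_fluctuation_level(
        model_est,
        estimated,
        target,
        grid=grid,
        reps=reps,
        duration=duration,
        dt=dt_estimation,
        burn_in=burn_in,
        seed=int(rng.integers(2**31 - 1)),
    )
    return RecoveryReport(
        similarities=similarities,
        cosine_magnitude=cos_mag,
        cosine_argument=cos_arg,
        D_hat=D_hat,
        rmse_curve=rmse,
        true_D=true_D,
        n_channels=n_channels,
    )
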