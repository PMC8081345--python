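"""Stochastic coupled delta-alpha PAC oscillator network.

Each of N nodes carries a slow (delta-band) phase phi_i and a fast
(alpha-band) amplitude r_i:

    dr_i/dt   = r_i (1 - r_i^2) + k_ad * sum_j J_ad_ij cos(phi_j + b_ad_ij)
    dphi_i/dt = omega + k_d * sum_j J_d_ij sin(phi_j - phi_i + b_d_ij)
                + D eta_i(t)

The phase subsystem is a noisy Kuramoto-Sakaguchi network; with all
couplings and noise off, every node is an independent Stuart-Landau
oscillator whose radius relaxes to 1.  Complex coupling matrices
C_ij = J_ij exp(i b_ij) hold magnitudes and lags together; the diagonal
j = i term of the phase sum is retained as a bias inherited from the
connectivity estimation.  Integration is Euler-Maruyama: the noise
increment per step is sqrt(dt) * D * eta with eta drawn from N(0, Sigma),
where Sigma couples fluctuations at nodes whose relative phase varies
little across the embedded patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MultichannelSeries, StateLabeling, wrap_phase
from .csd import Montage, observe_scalp
from .envelopes import wavelet_envelope


@dataclass
class PPCModel:
    """Coupled-oscillator network parameters.

    C_delta is the phase-phase (PPC) connectivity, C_alphadelta the
    phase-amplitude (PAC) connectivity; omega is the common frequency in
    rad/s, Sigma the fluctuation covariance and D its level.
    """

    C_delta: np.ndarray
    omega: float
    C_alphadelta: np.ndarray | None = None
    k_delta: float = 0.1
    k_alphadelta: float = 0.1
    Sigma: np.ndarray | None = None
    D: float = 0.0

    def __post_init__(self) -> None:
        self.C_delta = np.asarray(self.C_delta, dtype=complex)
        n = self.C_delta.shape[0]
        if self.C_delta.shape != (n, n):
            raise ValueError("C_delta must be square")
        if self.C_alphadelta is None:
            # PAC connectivity is arbitrary by design (it cannot affect the
            # transition dynamics), but its lags must be heterogeneous: with
            # zero lags every amplitude receives the same drive and the
            # observed envelopes carry no state information.  Fixed-seed
            # random lags with uniform magnitude 1/N.
            lag_rng = np.random.default_rng(12345)
            beta = lag_rng.uniform(-np.pi, np.pi, size=(n, n))
            self.C_alphadelta = np.exp(1j * beta) / n
        self.C_alphadelta = np.asarray(self.C_alphadelta, dtype=complex)
        if self.Sigma is None:
            self.Sigma = np.eye(n)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        if self.D < 0:
            raise ValueError("fluctuation level D must be >= 0")

    @property
    def n_oscillators(self) -> int:
        return self.C_delta.shape[0]


@dataclass
class SimulationResult:
    """Trajectory of the coupled PAC system."""

    phases: np.ndarray               # N x T, wrapped to (-pi, pi]
    amplitudes: np.ndarray | None    # N x T or None for phase-only runs
    dt: float
    seed: int | None = None
    overlaps: np.ndarray | None = None   # K x T
    labels: StateLabeling | None = None

    @property
    def n_steps(self) -> int:
        return self.phases.shape[1]


def _noise_factor(Sigma: np.ndarray) -> np.ndarray:
    """Square root of an SPSD covariance via eigendecomposition.

    Cholesky would reject the rank-deficient covariances that arise when
    embedded patterns share their full difference structure.
    """
    w, V = np.linalg.eigh((Sigma + Sigma.T) / 2.0)
    return V * np.sqrt(np.clip(w, 0.0, None))


def simulate_pac(
    model: PPCModel,
    duration: float,
    dt: float = 0.01,
    init_phases: np.ndarray | None = None,
    init_amplitudes: np.ndarray | None = None,
    seed: int | None = 0,
    with_amplitudes: bool = True,
    D_schedule: np.ndarray | None = None,
    burn_in: float = 0.0,
) -> SimulationResult:
    """Integrate the network by the Euler-Maruyama method.

    ``D_schedule`` optionally overrides the constant fluctuation level with
    a per-step level (length = number of retained steps); ``anneal_fluctuations``
    is a convenience wrapper for that case.  Initial phases default to
    i.i.d. uniform(-pi, pi] and initial amplitudes to 1.  ``burn_in``
    seconds are integrated and discarded before the retained window: from
    scattered initial phases the network needs on the order of 1/k_delta
    seconds to reach its attractor manifold, and analyses that assume the
    trajectory samples the attractors should not see that transient.
    """
    n = model.n_oscillators
    n_steps = int(round(duration / dt))
    n_burn = int(round(burn_in / dt))
    if n_steps < 1:
        raise ValueError("duration shorter than one time step")
    rng = np.random.default_rng(seed)
    phi = (
        rng.uniform(-np.pi, np.pi, size=n)
        if init_phases is None
        else np.array(init_phases, dtype=float)
    )
    r = (
        np.ones(n)
        if init_amplitudes is None
        else np.array(init_amplitudes, dtype=float)
    )
    if D_schedule is None:
        D_per_step = np.full(n_steps, model.D)
    else:
        D_per_step = np.asarray(D_schedule, dtype=float)
        if D_per_step.size != n_steps:
            raise ValueError("D_schedule length must equal the number of steps")
        if np.any(D_per_step < 0):
            raise ValueError("fluctuation levels must be >= 0")
    # the burn-in phase runs at the constant model level
    D_per_step = np.concatenate([np.full(n_burn, model.D), D_per_step])
    total_steps = n_burn + n_steps

    if np.any(D_per_step > 0):
        L = _noise_factor(model.Sigma)
        noise = rng.standard_normal((total_steps, n)) @ L.T
    else:
        noise = np.zeros((total_steps, n))
    sqrt_dt = np.sqrt(dt)

    phases = np.empty((n, n_steps))
    amplitudes = np.empty((n, n_steps)) if with_amplitudes else None
    Cd = model.C_delta
    Cad = model.C_alphadelta
    for t in range(total_steps):
        if t >= n_burn:
            phases[:, t - n_burn] = phi
            if amplitudes is not None:
                amplitudes[:, t - n_burn] = r
        z = np.exp(1j * phi)
        coupling = model.k_delta * np.imag(np.conj(z) * (Cd @ z))
        dphi = (model.omega + coupling) * dt + D_per_step[t] * sqrt_dt * noise[t]
        if amplitudes is not None:
            drive = model.k_alphadelta * np.real(Cad @ z)
            r = r + dt * (r * (1.0 - r**2) + drive)
        phi = phi + dphi
        if not (np.all(np.isfinite(phi)) and np.all(np.isfinite(r))):
            raise FloatingPointError(f"non-finite state at step {t}")
    return SimulationResult(
        phases=wrap_phase(phases),
        amplitudes=amplitudes,
        dt=dt,
        seed=seed,
    )


def overlap_labels(
    phases: np.ndarray, patterns: np.ndarray
) -> tuple[np.ndarray, StateLabeling]:
    """Overlap of instantaneous phases with each stored pattern, and labels.

    M_mu(t) = (1/N) |sum_j exp(i(phi_j(t) - theta_j^mu))| lies in [0, 1]
    and equals 1 at perfect alignment up to a global rotation; the label is
    the argmax over patterns.
    """
    phases = np.atleast_2d(phases)
    patterns = np.atleast_2d(patterns)
    if patterns.shape[1] != phases.shape[0]:
        raise ValueError("patterns and phases disagree on the number of channels")
    n = phases.shape[0]
    M = np.abs(np.exp(-1j * patterns) @ np.exp(1j * phases)) / n
    labels = StateLabeling(labels=np.argmax(M, axis=0) + 1, K=patterns.shape[0])
    return M, labels


def simulate_observation(
    result: SimulationResult, montage: Montage, f1: float
) -> tuple[MultichannelSeries, MultichannelSeries]:
    """Map simulated source amplitudes to scalp space and take one envelope.

    Returns (A1, A0): the simulated scalp amplitude series and its
    instantaneous amplitude around the slow peak frequency f1.
    """
    if result.amplitudes is None:
        raise ValueError("simulation was run without the amplitude subsystem")
    sample_rate = 1.0 / result.dt
    source = MultichannelSeries(
        data=result.amplitudes,
        sample_rate=sample_rate,
        channel_names=list(montage.channel_names),
    )
    A1 = observe_scalp(source, montage)
    A0 = wavelet_envelope(A1, f1)
    return A1, A0


def anneal_fluctuations(
    model: PPCModel,
    D_schedule: np.ndarray,
    dt: float = 0.01,
    seed: int | None = 0,
    **kwargs,
) -> SimulationResult:
    """Simulate with a time-varying fluctuation level.

    ``D_schedule`` gives the level at every step; a decreasing schedule
    freezes the network into a single synchronous state whose identity
    depends on the initial condition.
    """
    duration = D_schedule.size * dt
    return simulate_pac(
        model, duration=duration, dt=dt, seed=seed, D_schedule=D_schedule, **kwargs
    )
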