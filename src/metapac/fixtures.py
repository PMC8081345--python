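"""Synthetic inputs: the toy PAC transition ensemble, correlated phase
patterns, and planted-correlation trait tables.

The toy generator produces a multichannel signal in which a slow carrier
(frequency ``f_slow``) phase-amplitude modulates a fast component
(``f_fast``), with the modulation depth ``b(t)`` switching among a small
set of levels on a piecewise-constant schedule.  Each channel ``i`` is

    x_i(t) = cos(2*pi*f1*t + psi_i)
             + 0.5 * [1 + b(t) * cos(2*pi*f1*t + psi_i)] * sin(2*pi*f2*t)
             + xi_i(t)

with channel-specific phase offsets ``psi_i`` and i.i.d. Gaussian noise
``xi_i``.  The schedule of ``b(t)`` is shared across channels, so the
ground-truth state at any instant is global — exactly the structure the
downstream clustering is meant to recover.

The phase-pattern generator builds P correlated patterns from one uniform
reference pattern by adding wrapped Gaussian perturbations of scale
``sigma``; it is the standard construction for embedding a repertoire of
nearby synchronous states in a phase-oscillator network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MultichannelSeries, StateLabeling, wrap_phase


@dataclass
class ToySpec:
    """Parameters of the toy PAC transition ensemble."""

    n_channels: int = 63
    duration: float = 180.0
    sample_rate: float = 250.0
    f_slow: float = 1.0
    f_fast: float = 10.0
    modulation_levels: tuple[float, ...] = (0.15, 0.5, 0.85)
    segment_length: float = 20.0
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.f_slow < self.f_fast < self.sample_rate / 2):
            raise ValueError("need f_slow < f_fast < Nyquist")
        if any(not 0.0 <= b <= 1.0 for b in self.modulation_levels):
            raise ValueError("modulation levels must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_channels < 1 or self.duration <= 0 or self.segment_length <= 0:
            raise ValueError("n_channels, duration, segment_length must be positive")


@dataclass
class PatternGenSpec:
    """Parameters of the correlated phase-pattern ensemble."""

    n_channels: int = 63
    n_patterns: int = 3
    sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patterns < 1:
            raise ValueError("n_patterns must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def modulation_schedule(spec: ToySpec) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant b(t) cycling through the modulation levels.

    Returns (b, state_index) where state_index is 1-based and indexes the
    active level.
    """
    n = round(spec.duration * spec.sample_rate)
    t = np.arange(n) / spec.sample_rate
    seg = np.floor(t / spec.segment_length).astype(int)
    state = seg % len(spec.modulation_levels)
    b = np.asarray(spec.modulation_levels, dtype=float)[state]
    return b, state + 1


def gen_toy_pac_signals(
    spec: ToySpec,
) -> tuple[MultichannelSeries, StateLabeling, np.ndarray]:
    """Generate the toy PAC transition ensemble.

    Returns
    -------
    series : MultichannelSeries
    true_labels : StateLabeling
        Index of the active modulation level at each sample.
    true_modulation : ndarray
        The per-sample modulation strength b(t).
    """
    if spec.segment_length >= spec.duration:
        raise ValueError(
            "segment_length must be shorter than duration so that more than "
            "one state is visited"
        )
    rng = np.random.default_rng(spec.seed)
    n = round(spec.duration * spec.sample_rate)
    t = np.arange(n) / spec.sample_rate
    b, state = modulation_schedule(spec)
    psi = rng.uniform(-np.pi, np.pi, size=spec.n_channels)

    slow = np.cos(2 * np.pi * spec.f_slow * t[np.newaxis, :] + psi[:, np.newaxis])
    fast = np.sin(2 * np.pi * spec.f_fast * t)[np.newaxis, :]
    data = slow + 0.5 * (1.0 + b[np.newaxis, :] * slow) * fast
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)

    series = MultichannelSeries(data=data, sample_rate=spec.sample_rate)
    labels = StateLabeling(labels=state, K=len(spec.modulation_levels))
    return series, labels, b


def gen_phase_pattern_set(spec: PatternGenSpec) -> tuple[np.ndarray, np.ndarray]:
    """Build P correlated phase patterns from one uniform reference.

    Pattern mu is the reference plus i.i.d. N(0, sigma^2) perturbations,
    wrapped to (-pi, pi].

    Returns
    -------
    reference : ndarray, shape (n_channels,)
    patterns : ndarray, shape (n_patterns, n_channels)
    """
    rng = np.random.default_rng(spec.seed)
    reference = rng.uniform(-np.pi, np.pi, size=spec.n_channels)
    noise = rng.standard_normal((spec.n_patterns, spec.n_channels))
    patterns = wrap_phase(reference[np.newaxis, :] + spec.sigma * noise)
    return wrap_phase(reference), patterns


def gen_trait_scores(
    dynamics_stat: np.ndarray,
    planted_r: float,
    seed: int = 0,
) -> np.ndarray:
    """Synthesize one trait subscore per individual with a planted
    population correlation against ``dynamics_stat``.

    The score is ``planted_r * z + sqrt(1 - r^2) * e`` where z is the
    standardized statistic and e is standard normal, so the population
    Pearson correlation equals ``planted_r`` exactly.
    """
    x = np.asarray(dynamics_stat, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 individuals")
    if not -1.0 < planted_r < 1.0:
        raise ValueError("planted_r must lie strictly inside (-1, 1)")
    sd = x.std()
    if sd == 0:
        raise ValueError("dynamics_stat is constant; correlation undefined")
    z = (x - x.mean()) / sd
    rng = np.random.default_rng(seed)
    e = rng.standard_normal(x.size)
    return planted_r * z + np.sqrt(1.0 - planted_r**2) * e
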