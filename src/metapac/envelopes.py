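"""Multi-step Morlet envelope analysis.

A nested oscillation — a slow rhythm whose phase modulates the amplitude of
a faster one — can be unwrapped one timescale at a time by repeatedly
taking instantaneous amplitudes: the envelope of the fast component
oscillates at the slow frequency, its envelope in turn tracks the (even
slower) modulation depth, and so on.  ``envelope_chain`` performs ``d``
such steps, estimating the working peak frequency from the averaged power
spectrum before each step, so that a d-dimensional torus of oscillatory
states collapses to a point cloud the clustering stage can label.

The analytic kernel is the complex Morlet wavelet

    Psi(t) = f * exp(i*2*pi*f*t) * exp(-t^2 / (2*sigma^2)),

with sigma fixed by the number of cycles n_co via n_co = 6*f*sigma.  A
short wavelet (n_co = 3 by default) trades frequency resolution for the
temporal resolution needed to follow state transitions.  After each
convolution, n_co/(2f) seconds are dropped at both edges to remove the
kernel's edge artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import MultichannelSeries

#: Number of wavelet cycles used throughout the analysis chain.
DEFAULT_N_CYCLES = 3.0


@dataclass
class WaveletSpec:
    """Complex Morlet wavelet parameterized by center frequency and cycles."""

    center_frequency: float
    n_cycles: float = DEFAULT_N_CYCLES
    sample_rate: float = 250.0

    def __post_init__(self) -> None:
        if self.n_cycles <= 0:
            raise ValueError("n_cycles must be positive")
        if not 0 < self.center_frequency < self.sample_rate / 2:
            raise ValueError("center_frequency must lie in (0, Nyquist)")

    @property
    def sigma(self) -> float:
        """Gaussian width in seconds: n_co = 6 * f * sigma."""
        return self.n_cycles / (6.0 * self.center_frequency)

    @property
    def edge_seconds(self) -> float:
        """Edge trim per side after convolution: n_co / (2 f)."""
        return self.n_cycles / (2.0 * self.center_frequency)


@dataclass
class EnvelopeChain:
    """Result of the repeated envelope computation.

    ``levels[0]`` is the first envelope A_{d-1} (around f_d) and
    ``levels[-1]`` is the final envelope A_0 (around f_1).
    ``peak_frequencies`` holds (f_d, f_{d-1}, ..., f_1).
    """

    levels: list[MultichannelSeries] = field(default_factory=list)
    peak_frequencies: list[float] = field(default_factory=list)
    trims: list[float] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.levels)

    @property
    def final(self) -> MultichannelSeries:
        return self.levels[-1]

    @property
    def f1(self) -> float:
        return self.peak_frequencies[-1]


def morlet_kernel(spec: WaveletSpec) -> np.ndarray:
    """Sample the complex Morlet wavelet on a symmetric +-3 sigma grid."""
    half = int(np.floor(3.0 * spec.sigma * spec.sample_rate))
    t = np.arange(-half, half + 1) / spec.sample_rate
    if t.size < 3:
        raise ValueError("kernel support shorter than 3 samples; raise n_cycles or sample_rate")
    return (
        spec.center_frequency
        * np.exp(1j * 2.0 * np.pi * spec.center_frequency * t)
        * np.exp(-(t**2) / (2.0 * spec.sigma**2))
    )


def _convolve_trim(
    x: MultichannelSeries, spec: WaveletSpec
) -> tuple[np.ndarray, float]:
    """Convolve all channels with the wavelet and trim the edge artifact.

    Returns the complex analytic signal (channels x trimmed samples) and the
    trim duration per side in seconds.  The convolution approximates the
    continuous integral (discrete sum times dt) and is evaluated in 'full'
    mode so that no retained sample mixes with zero padding after trimming.
    """
    kernel = morlet_kernel(spec)
    dt = 1.0 / x.sample_rate
    n_trim = int(round(spec.edge_seconds * x.sample_rate))
    half = (kernel.size - 1) // 2
    if x.n_samples <= 2 * n_trim or x.n_samples <= kernel.size:
        raise ValueError("series too short for wavelet convolution and edge trimming")
    full = sps.fftconvolve(x.data, kernel[np.newaxis, :], mode="full", axes=1) * dt
    # index of the output sample aligned with input sample 0
    aligned = full[:, half : half + x.n_samples]
    return aligned[:, n_trim : x.n_samples - n_trim], n_trim * dt


def wavelet_envelope(
    x: MultichannelSeries, f: float, n_cycles: float = DEFAULT_N_CYCLES
) -> MultichannelSeries:
    """Instantaneous amplitude |x * Psi| around frequency f, edge-trimmed."""
    spec = WaveletSpec(center_frequency=f, n_cycles=n_cycles, sample_rate=x.sample_rate)
    analytic, trim = _convolve_trim(x, spec)
    return x.copy_with(np.abs(analytic), t0=x.t0 + trim)


def wavelet_phase(
    x: MultichannelSeries, f: float, n_cycles: float = DEFAULT_N_CYCLES
) -> MultichannelSeries:
    """Instantaneous phase arg(x * Psi) around frequency f, edge-trimmed."""
    spec = WaveletSpec(center_frequency=f, n_cycles=n_cycles, sample_rate=x.sample_rate)
    analytic, trim = _convolve_trim(x, spec)
    return x.copy_with(np.angle(analytic), t0=x.t0 + trim)


def _band_spectrum(
    x: MultichannelSeries,
    band: tuple[float, float],
    detrend_loglog: bool,
    min_window_cycles: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Channel-averaged (optionally log-log detrended) in-band spectrum.

    Returns (frequencies, mean spectrum); the mean is over per-channel
    detrended log-power when detrending, otherwise over raw power.
    """
    f_lo, f_hi = band
    nyquist = x.sample_rate / 2.0
    if not 0 < f_lo < f_hi <= nyquist:
        raise ValueError("band must satisfy 0 < f_lo < f_hi <= Nyquist")
    if np.ptp(x.data) == 0:
        raise ValueError("constant input has no peak frequency")

    nperseg = min(x.n_samples, int(round(min_window_cycles / f_lo * x.sample_rate)))
    freqs, psd = sps.welch(
        x.data, fs=x.sample_rate, nperseg=nperseg, noverlap=nperseg // 2, axis=1
    )
    in_band = (freqs >= f_lo) & (freqs < f_hi)
    if not np.any(in_band):
        raise ValueError("band contains no spectral bins; series too short")
    fb = freqs[in_band]
    pb = psd[:, in_band]

    if detrend_loglog:
        logf = np.log(fb)
        # per-channel least-squares line in log-log coordinates
        logp = np.log(np.maximum(pb, np.finfo(float).tiny))
        design = np.vstack([logf, np.ones_like(logf)]).T
        coef, *_ = np.linalg.lstsq(design, logp.T, rcond=None)
        resid = logp - (design @ coef).T
        return fb, resid.mean(axis=0)
    return fb, pb.mean(axis=0)


def peak_frequency(
    x: MultichannelSeries,
    band: tuple[float, float],
    detrend_loglog: bool = False,
    min_window_cycles: float = 10.0,
) -> float:
    """Peak frequency of the channel-averaged power spectrum within a band.

    Welch periodograms are computed per channel (window of at least
    ``min_window_cycles / band[0]`` seconds, 50% overlap).  With
    ``detrend_loglog`` the linear trend of log-power versus log-frequency is
    removed per channel before averaging, which suppresses the 1/f^beta
    background that would otherwise pull the argmax toward low frequencies.
    """
    fb, spectrum = _band_spectrum(x, band, detrend_loglog, min_window_cycles)
    return float(fb[np.argmax(spectrum)])


def carrier_frequency(
    x: MultichannelSeries,
    band: tuple[float, float] = (1.0, 45.0),
    prominence: float = 1.0,
    merge_octaves: float = 0.25,
    min_window_cycles: float = 10.0,
) -> float:
    """Fastest prominent rhythm of the broad-band spectrum.

    The top of a nested-oscillation hierarchy must be analyzed at its
    FASTEST rhythmic component — the envelope transform only exposes
    structure slower than the analyzed frequency, so starting from a slow
    in-band rhythm would terminate the hierarchy immediately.  For
    1/f-background spectra (real EEG) the strongest peak after detrending is
    also the fastest prominent one, but a slow narrowband carrier would win
    a plain argmax; this estimator therefore (i) detrends log-power in
    log-log coordinates, (ii) finds local maxima whose prominence exceeds
    ``prominence`` natural-log units, and (iii) merges peaks closer than
    ``merge_octaves`` octaves to the fastest one (phase-amplitude
    modulation puts sidebands at the carrier +- the modulating frequency)
    before returning the strongest member of the fastest peak group.
    """
    fb, spectrum = _band_spectrum(x, band, True, min_window_cycles)
    peaks, _ = sps.find_peaks(spectrum, prominence=prominence)
    # an in-band maximum at the very first/last bin has no left/right base;
    # include the global argmax as a fallback candidate
    if peaks.size == 0:
        return float(fb[np.argmax(spectrum)])
    f_peaks = fb[peaks]
    fastest = f_peaks.max()
    group = peaks[f_peaks >= fastest * 2.0 ** (-merge_octaves)]
    return float(fb[group[np.argmax(spectrum[group])]])


def bandpass(
    x: MultichannelSeries, f_lo: float = 1.0, f_hi: float = 45.0, order: int = 4
) -> MultichannelSeries:
    """Zero-phase Butterworth band-pass, used as the d = 0 front end."""
    sos = sps.butter(order, [f_lo, f_hi], btype="bandpass", fs=x.sample_rate, output="sos")
    return x.copy_with(sps.sosfiltfilt(sos, x.data, axis=1))


def envelope_chain(
    x: MultichannelSeries,
    d: int,
    n_cycles: float = DEFAULT_N_CYCLES,
    broad_band: tuple[float, float] = (1.0, 45.0),
    envelope_band_floor: float = 0.1,
) -> EnvelopeChain:
    """Run the d-step envelope analysis.

    The fastest peak frequency f_d is estimated from the raw series on the
    broad band (fastest prominent peak of the detrended spectrum, see
    ``carrier_frequency``); each subsequent frequency f_j is the argmax of
    the previous envelope's spectrum on [envelope_band_floor, f_{j+1}).
    """
    if d < 1:
        raise ValueError("d must be >= 1 (use bandpass() for the d = 0 analysis)")
    chain = EnvelopeChain()
    f_next = carrier_frequency(x, band=broad_band)
    chain.peak_frequencies.append(f_next)
    current = x
    for level in range(d):
        try:
            env = wavelet_envelope(current, f_next, n_cycles=n_cycles)
        except ValueError as err:
            raise ValueError(f"envelope level {level} failed: {err}") from err
        chain.levels.append(env)
        chain.trims.append(n_cycles / (2.0 * f_next))
        if level < d - 1:
            f_next = peak_frequency(env, band=(envelope_band_floor, f_next))
            chain.peak_frequencies.append(f_next)
        current = env
    return chain
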