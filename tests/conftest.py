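import numpy as np
import pytest

from metapac import (
    PatternGenSpec,
    ToySpec,
    gen_phase_pattern_set,
    gen_toy_pac_signals,
)


@pytest.fixture(scope="session")
def small_toy():
    """Desk-size toy PAC ensemble: 8 channels, 120 s at 100 Hz."""
    spec = ToySpec(
        n_channels=8,
        duration=120.0,
        sample_rate=100.0,
        segment_length=10.0,
        seed=1,
    )
    series, labels, b = gen_toy_pac_signals(spec)
    return spec, series, labels, b


@pytest.fixture(scope="session")
def clean_toy():
    """Noiseless toy ensemble for oracle-style checks."""
    spec = ToySpec(
        n_channels=4,
        duration=120.0,
        sample_rate=100.0,
        segment_length=10.0,
        noise_sd=0.0,
        seed=2,
    )
    series, labels, b = gen_toy_pac_signals(spec)
    return spec, series, labels, b


@pytest.fixture(scope="session")
def pattern_set():
    """Three correlated 63-channel phase patterns (sigma = 0.5)."""
    spec = PatternGenSpec(n_channels=63, n_patterns=3, sigma=0.5, seed=7)
    reference, patterns = gen_phase_pattern_set(spec)
    return spec, reference, patterns


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
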