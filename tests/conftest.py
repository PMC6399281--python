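from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from difc import ChannelTrace, ProcessedTrace

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def gaussian_pulse_samples(
    n: int,
    rate: float,
    apexes,
    amplitudes,
    fwhms,
    baseline: float = 0.0,
) -> np.ndarray:
    """Sum of Gaussian pulses on a flat baseline (independent of simulator)."""
    t = np.arange(n) / rate
    y = np.full(n, baseline, dtype=float)
    for t0, a, w in zip(np.atleast_1d(apexes), np.atleast_1d(amplitudes),
                        np.atleast_1d(fwhms)):
        sigma = w * FWHM_TO_SIGMA
        y += a * np.exp(-0.5 * ((t - t0) / sigma) ** 2)
    return y


def processed(samples, rate: float = 1000.0, channel: int = 1) -> ProcessedTrace:
    """Wrap raw samples as an already-preprocessed trace (zero background)."""
    samples = np.asarray(samples, dtype=float)
    return ProcessedTrace(
        channel_id=channel,
        sample_rate=rate,
        samples=samples,
        background=np.zeros_like(samples),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_trace():
    return ChannelTrace(1, 1000.0, np.full(5000, 10_000.0))
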