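"""Detector-current time series containers and plain-text trace I/O.

A DiFC scan produces one photodetector current trace per fiber probe,
uniformly sampled (nominally 1000 samples/s) and expressed in nA.  Traces
travel on disk as delimited text with the header ``time_s,ch1_nA,ch2_nA``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["ChannelTrace", "ProcessedTrace", "write_traces", "read_traces"]


@dataclass
class ChannelTrace:
    """Uniformly sampled detector-current series for one probe channel.

    Parameters
    ----------
    channel_id : int
        Probe channel, 1 or 2.
    sample_rate : float
        Sampling rate in Hz.
    samples : numpy.ndarray
        Detector current in nA, one value per sample.
    t0 : float
        Time of the first sample in seconds.
    """

    channel_id: int
    sample_rate: float
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.channel_id not in (1, 2):
            raise ValueError(f"channel_id must be 1 or 2, got {self.channel_id}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Scan duration in seconds."""
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.n_samples) / self.sample_rate


@dataclass
class ProcessedTrace(ChannelTrace):
    """A :class:`ChannelTrace` after background subtraction and smoothing.

    ``samples`` holds the background-subtracted, smoothed (and possibly
    rescaled) signal; ``background`` the estimated autofluorescence baseline
    in nA; ``scale_factor`` the inter-channel normalization applied.
    """

    background: np.ndarray = field(default_factory=lambda: np.array([]))
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        super().__post_init__()
        self.background = np.asarray(self.background, dtype=float)
        if self.background.size and self.background.size != self.samples.size:
            raise ValueError("background must have same length as samples")
        if self.background.size and not np.all(np.isfinite(self.background)):
            raise ValueError("background must be finite")

    def rescaled(self, factor: float) -> "ProcessedTrace":
        return replace(
            self,
            samples=self.samples * factor,
            scale_factor=self.scale_factor * factor,
        )


def write_traces(trace1: ChannelTrace, trace2: ChannelTrace, path) -> None:
    """Write a two-channel scan as delimited text ``time_s,ch1_nA,ch2_nA``."""
    if trace1.n_samples != trace2.n_samples:
        raise ValueError("channel traces must have equal length")
    if trace1.sample_rate != trace2.sample_rate:
        raise ValueError("channel traces must share a sample rate")
    df = pd.DataFrame(
        {
            "time_s": trace1.times,
            "ch1_nA": trace1.samples,
            "ch2_nA": trace2.samples,
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_traces(path) -> tuple[ChannelTrace, ChannelTrace]:
    """Read a two-channel scan written by :func:`write_traces`."""
    df = pd.read_csv(path)
    expected = ["time_s", "ch1_nA", "ch2_nA"]
    if list(df.columns) != expected:
        raise ValueError(f"expected columns {expected}, found {list(df.columns)}")
    if len(df) < 2:
        raise ValueError("trace file must contain at least two samples")
    t = df["time_s"].to_numpy()
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("trace is not uniformly sampled")
    rate = 1.0 / dt.mean()
    return (
        ChannelTrace(1, rate, df["ch1_nA"].to_numpy(), t0=t[0]),
        ChannelTrace(2, rate, df["ch2_nA"].to_numpy(), t0=t[0]),
    )
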