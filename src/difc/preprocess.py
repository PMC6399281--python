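"""Trace preprocessing: background estimation, smoothing, normalization.

The autofluorescence background (~10 uA, slowly varying) is estimated by a
2.5 s running median followed by a 7-point moving average, subtracted from
the raw trace, and the residual is smoothed with a 3-point (3 ms at 1 kHz)
moving average.  Channel 2 is then rescaled so both channels report
comparable peak amplitudes despite small differences in probe coupling
efficiency.  All filters are centered and use reflection padding at the
trace edges.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .trace import ChannelTrace, ProcessedTrace

__all__ = [
    "PreprocessConfig",
    "estimate_background",
    "subtract_and_smooth",
    "preprocess_trace",
    "normalize_channels",
]


@dataclass
class PreprocessConfig:
    """Background-estimation and smoothing parameters.

    ``median_window`` is in seconds (converted to an odd sample count);
    the moving-average point counts are in samples and must be odd so the
    filters are centered.
    """

    median_window: float = 2.5
    background_ma_points: int = 7
    smooth_ma_points: int = 3
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.median_window <= 0:
            raise ValueError("median_window must be positive")
        for name in ("background_ma_points", "smooth_ma_points"):
            v = getattr(self, name)
            if v < 1 or v % 2 == 0:
                raise ValueError(f"{name} must be a positive odd integer")


def _odd_window_samples(seconds: float, sample_rate: float) -> int:
    w = int(round(seconds * sample_rate))
    if w % 2 == 0:
        w += 1
    return max(w, 1)


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running median with reflection padding, O(N log W)."""
    if window == 1:
        return x.copy()
    pad = window // 2
    xp = np.concatenate([x[pad:0:-1], x, x[-2 : -pad - 2 : -1]])
    med = (
        pd.Series(xp)
        .rolling(window, center=True, min_periods=window)
        .median()
        .to_numpy()
    )
    return med[pad : pad + x.size]


def _moving_average(x: np.ndarray, points: int) -> np.ndarray:
    if points == 1:
        return x.copy()
    # mirror padding (no edge repeat), consistent with the median filter
    return uniform_filter1d(x, points, mode="mirror")


def estimate_background(
    trace: ChannelTrace, cfg: PreprocessConfig | None = None
) -> np.ndarray:
    """Estimate the slowly varying autofluorescence baseline (nA).

    Running median over ``median_window`` seconds, then a centered
    ``background_ma_points``-point moving average.  The median window is
    long relative to cell-transit pulses (~10 ms), so transients are
    rejected and only the baseline remains.
    """
    cfg = cfg or PreprocessConfig()
    window = _odd_window_samples(cfg.median_window, trace.sample_rate)
    if trace.n_samples < window:
        raise ValueError(
            f"trace ({trace.n_samples} samples) shorter than the "
            f"{window}-sample median window"
        )
    med = _running_median(trace.samples, window)
    return _moving_average(med, cfg.background_ma_points)


def subtract_and_smooth(
    trace: ChannelTrace,
    background: np.ndarray,
    cfg: PreprocessConfig | None = None,
) -> ProcessedTrace:
    """Subtract the background and apply the short moving-average smoother."""
    cfg = cfg or PreprocessConfig()
    background = np.asarray(background, dtype=float)
    if background.size != trace.n_samples:
        raise ValueError("background length must match trace length")
    smoothed = _moving_average(trace.samples - background, cfg.smooth_ma_points)
    return ProcessedTrace(
        channel_id=trace.channel_id,
        sample_rate=trace.sample_rate,
        samples=smoothed,
        t0=trace.t0,
        background=background,
    )


def preprocess_trace(
    trace: ChannelTrace, cfg: PreprocessConfig | None = None
) -> ProcessedTrace:
    """Background estimation and subtraction + smoothing in one call."""
    cfg = cfg or PreprocessConfig()
    return subtract_and_smooth(trace, estimate_background(trace, cfg), cfg)


def normalize_channels(
    p1: ProcessedTrace,
    p2: ProcessedTrace,
    provisional_threshold: float = 250.0,
) -> tuple[ProcessedTrace, ProcessedTrace]:
    """Rescale channel 2 so both channels report comparable amplitudes.

    The scale s is the ratio of median provisional peak-candidate
    amplitudes (channel 1 over channel 2) found at ``provisional_threshold``.
    With fewer than 5 candidates on either channel the ratio of mean
    backgrounds is used instead — coupling efficiency affects signal and
    autofluorescence alike.
    """
    from .detect import DetectionConfig, find_candidates

    det = DetectionConfig(threshold=provisional_threshold)
    c1 = find_candidates(p1, det)
    c2 = find_candidates(p2, det)
    if len(c1) >= 5 and len(c2) >= 5:
        num = float(np.median([c.amplitude for c in c1]))
        den = float(np.median([c.amplitude for c in c2]))
    else:
        num = float(np.mean(p1.background))
        den = float(np.mean(p2.background))
    if den == 0:
        raise ValueError("cannot normalize: zero channel-2 statistic")
    s = num / den
    return replace(p1), p2.rescaled(s)
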