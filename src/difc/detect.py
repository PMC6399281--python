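"""Cell-candidate detection on preprocessed traces.

Candidates are local maxima of the background-subtracted trace exceeding a
fixed amplitude threshold with topographic prominence of at least half the
threshold.  For each candidate the apex time, amplitude, full width at half
maximum (FWHM, by linear interpolation of the half-maximum crossings) and a
width-derived speed estimate v = FOV / FWHM are recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .trace import ProcessedTrace

__all__ = ["DetectionConfig", "PeakCandidate", "find_candidates", "far_candidates"]


@dataclass
class DetectionConfig:
    """Peak-detection parameters.

    threshold : nA — minimum apex amplitude (default 250 nA, the
        bead-calibrated counting threshold).
    prominence_fraction : minimum topographic prominence as a fraction of
        the threshold (default 0.5).
    fov_fwhm : mm — probe field of view used for the width-derived speed.
    min_separation : samples — minimum apex separation; closer secondary
        maxima are suppressed.
    """

    threshold: float = 250.0
    prominence_fraction: float = 0.5
    fov_fwhm: float = 1.1
    min_separation: int = 3

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if not 0.0 < self.prominence_fraction <= 1.0:
            raise ValueError("prominence_fraction must lie in (0, 1]")
        if self.min_separation < 1:
            raise ValueError("min_separation must be >= 1 sample")


@dataclass
class PeakCandidate:
    """One detected peak on a single channel."""

    channel: int
    index: int  # apex sample index
    t: float  # apex time, s
    amplitude: float  # apex amplitude above baseline, nA
    fwhm: float  # full width at half maximum, s
    v_width: float  # width-derived speed fov_fwhm / fwhm, mm/s
    width_flagged: bool = False  # True if a half-max crossing was unresolved


def _half_width_left(y: np.ndarray, apex: int, level: float, bound: int):
    """Distance (samples, interpolated) from apex to the left half-max crossing."""
    for j in range(apex - 1, bound - 1, -1):
        if y[j] < level:
            frac = (y[j + 1] - level) / (y[j + 1] - y[j])
            return apex - (j + 1) + frac
    return None


def _half_width_right(y: np.ndarray, apex: int, level: float, bound: int):
    for j in range(apex + 1, bound + 1):
        if y[j] < level:
            frac = (y[j - 1] - level) / (y[j - 1] - y[j])
            return (j - 1) - apex + frac
    return None


def _measure_fwhm(
    y: np.ndarray, apexes: np.ndarray, i: int, sample_rate: float
) -> tuple[float, bool]:
    """FWHM of peak ``apexes[i]`` in seconds, half-max relative to zero baseline.

    The crossing search is bounded by the adjacent candidate apexes; when a
    side does not resolve (merged shoulder) the resolvable side is doubled
    and the width flagged.
    """
    apex = apexes[i]
    level = y[apex] / 2.0
    left_bound = apexes[i - 1] if i > 0 else 0
    right_bound = apexes[i + 1] if i < apexes.size - 1 else y.size - 1
    lw = _half_width_left(y, apex, level, left_bound)
    rw = _half_width_right(y, apex, level, right_bound)
    flagged = lw is None or rw is None
    if lw is None and rw is None:
        # fully merged: fall back to the inter-apex span
        width = max(right_bound - left_bound, 1.0)
    elif lw is None:
        width = 2.0 * rw
    elif rw is None:
        width = 2.0 * lw
    else:
        width = lw + rw
    return max(width, 0.5) / sample_rate, flagged


def find_candidates(
    trace: ProcessedTrace, cfg: DetectionConfig | None = None
) -> list[PeakCandidate]:
    """Detect cell candidates on one preprocessed channel, sorted by time."""
    cfg = cfg or DetectionConfig()
    y = trace.samples
    apexes, _ = find_peaks(
        y,
        height=cfg.threshold,
        distance=cfg.min_separation,
        prominence=cfg.prominence_fraction * cfg.threshold,
    )
    out: list[PeakCandidate] = []
    for i, apex in enumerate(apexes):
        fwhm, flagged = _measure_fwhm(y, apexes, i, trace.sample_rate)
        out.append(
            PeakCandidate(
                channel=trace.channel_id,
                index=int(apex),
                t=trace.t0 + apex / trace.sample_rate,
                amplitude=float(y[apex]),
                fwhm=fwhm,
                v_width=cfg.fov_fwhm / fwhm,
                width_flagged=flagged,
            )
        )
    return out


def far_candidates(
    control_trace: ProcessedTrace,
    thresholds,
    cfg: DetectionConfig | None = None,
) -> np.ndarray:
    """Single-channel candidate rate (per minute) at each threshold.

    Intended for traces believed cell-free (sham controls or noise-only
    simulations); the rate is then the single-fiber false-alarm rate.
    Rates are monotonically non-increasing in the threshold.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("thresholds must be a non-empty list")
    cfg = cfg or DetectionConfig()
    minutes = control_trace.duration / 60.0
    rates = np.empty(thresholds.size)
    for k, th in enumerate(thresholds):
        det = DetectionConfig(
            threshold=float(th),
            prominence_fraction=cfg.prominence_fraction,
            fov_fwhm=cfg.fov_fwhm,
            min_separation=cfg.min_separation,
        )
        rates[k] = len(find_candidates(control_trace, det)) / minutes
    return rates
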