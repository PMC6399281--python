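"""Downstream quantities: count rates, SNR, FAR, depth, concentration.

Converts pipeline output into the numbers a flow-cytometry study reports:
per-interval count rates by channel and direction, detection SNR in dB,
matched-event false-alarm rates on cell-free scans, signal depth inferred
from the apparent field of view, and the count-rate <-> concentration
conversion through the sampled blood-volume rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .detect import DetectionConfig, PeakCandidate, find_candidates
from .match import MatchConfig, MatchedEvent, match_candidates
from .pipeline import process_scan
from .preprocess import PreprocessConfig
from .trace import ChannelTrace

__all__ = [
    "ScanSummary",
    "SensitivityProfile",
    "default_sensitivity_profile",
    "summarize",
    "snr_db",
    "matched_far",
    "depth_from_event",
    "concentration_from_rate",
    "rate_from_concentration",
    "vessel_flow_rate",
    "calibration_regression",
    "SAMPLED_FLOW_RATE_ML_MIN",
]

#: Default sampled blood-volume rate, mL/min (one count per 3.52 min at
#: 1 cell/mL in the arterial direction).
SAMPLED_FLOW_RATE_ML_MIN = 0.284


@dataclass
class ScanSummary:
    """Binned counts and per-direction statistics for one scan.

    ``counts`` has one row per interval with columns ``t_start_s, ch1,
    ch2, forward, reverse``.  The per-direction means are scan-wide;
    they are NaN (and flagged via ``means_defined``) when a direction has
    no events.
    """

    interval: float
    counts: pd.DataFrame
    matched_fraction_forward: float
    matched_fraction_reverse: float
    mean_amp_forward: float
    mean_amp_reverse: float
    mean_fwhm_forward: float  # ms
    mean_fwhm_reverse: float  # ms
    mean_speed_forward: float  # mm/s, delay-derived
    mean_speed_reverse: float
    means_defined: dict


def _direction_stats(events: list[MatchedEvent]) -> tuple[float, float, float]:
    if not events:
        return math.nan, math.nan, math.nan
    amps = [0.5 * (e.c1.amplitude + e.c2.amplitude) for e in events]
    fwhms = [0.5 * (e.c1.fwhm + e.c2.fwhm) * 1000.0 for e in events]
    speeds = [e.v_c3 for e in events]
    return float(np.mean(amps)), float(np.mean(fwhms)), float(np.mean(speeds))


def summarize(
    events: list[MatchedEvent],
    candidates1: list[PeakCandidate],
    candidates2: list[PeakCandidate],
    interval: float,
    duration: float,
) -> ScanSummary:
    """Bin candidate and matched-event counts and summarize per direction."""
    if interval <= 0:
        raise ValueError("interval must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    edges = np.arange(0.0, duration + interval, interval)
    fwd = [e for e in events if e.direction == "forward"]
    rev = [e for e in events if e.direction == "reverse"]
    counts = pd.DataFrame(
        {
            "t_start_s": edges[:-1],
            "ch1": np.histogram([c.t for c in candidates1], edges)[0],
            "ch2": np.histogram([c.t for c in candidates2], edges)[0],
            "forward": np.histogram([e.t for e in fwd], edges)[0],
            "reverse": np.histogram([e.t for e in rev], edges)[0],
        }
    )
    n_cand = len(candidates1) + len(candidates2)
    amp_f, fwhm_f, spd_f = _direction_stats(fwd)
    amp_r, fwhm_r, spd_r = _direction_stats(rev)
    return ScanSummary(
        interval=interval,
        counts=counts,
        matched_fraction_forward=2 * len(fwd) / n_cand if n_cand else math.nan,
        matched_fraction_reverse=2 * len(rev) / n_cand if n_cand else math.nan,
        mean_amp_forward=amp_f,
        mean_amp_reverse=amp_r,
        mean_fwhm_forward=fwhm_f,
        mean_fwhm_reverse=fwhm_r,
        mean_speed_forward=spd_f,
        mean_speed_reverse=spd_r,
        means_defined={"forward": bool(fwd), "reverse": bool(rev)},
    )


def snr_db(amplitude: float, sigma: float) -> float:
    """Detection signal-to-noise ratio, 20*log10(I/sigma) in dB."""
    if amplitude <= 0 or sigma <= 0:
        raise ValueError("amplitude and sigma must be positive")
    return 20.0 * math.log10(amplitude / sigma)


def matched_far(
    trace1: ChannelTrace,
    trace2: ChannelTrace,
    thresholds,
    pre_cfg: PreprocessConfig | None = None,
    det_cfg: DetectionConfig | None = None,
    match_cfg: MatchConfig | None = None,
) -> np.ndarray:
    """Matched-event false-alarm rate (per minute) on a cell-free scan.

    Runs the full preprocess -> detect -> match pipeline at each threshold
    and reports (forward + reverse events) / scan minutes.  Preprocessing
    is threshold-independent and done once.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("thresholds must be a non-empty list")
    pre_cfg = pre_cfg or PreprocessConfig()
    det_cfg = det_cfg or DetectionConfig()
    match_cfg = match_cfg or MatchConfig()
    base = process_scan(trace1, trace2, pre_cfg, det_cfg, match_cfg)
    minutes = trace1.duration / 60.0
    rates = np.empty(thresholds.size)
    for k, th in enumerate(thresholds):
        det = DetectionConfig(
            threshold=float(th),
            prominence_fraction=det_cfg.prominence_fraction,
            fov_fwhm=det_cfg.fov_fwhm,
            min_separation=det_cfg.min_separation,
        )
        c1 = find_candidates(base.processed1, det)
        c2 = find_candidates(base.processed2, det)
        m = match_candidates(c1, c2, match_cfg, trace1.sample_rate)
        rates[k] = (len(m.forward) + len(m.reverse)) / minutes
    return rates


class SensitivityProfile:
    """Depth -> apparent field of view (FWHM, mm) lookup table.

    The probe's effective FOV broadens with the depth of the moving cell;
    a table of (depth mm, fov mm) pairs, strictly increasing in both
    columns, lets the measured FOV (pulse width x speed) be inverted to a
    depth of origin.  Tables typically come from photon-transport
    simulations of the probe in tissue; any user-supplied monotone table
    is accepted.
    """

    def __init__(self, depth_mm, fov_mm):
        self.depth = np.asarray(depth_mm, dtype=float)
        self.fov = np.asarray(fov_mm, dtype=float)
        if self.depth.size != self.fov.size or self.depth.size < 2:
            raise ValueError("profile needs >= 2 (depth, fov) pairs")
        if not (np.all(np.diff(self.depth) > 0) and np.all(np.diff(self.fov) > 0)):
            raise ValueError("profile must be strictly increasing")

    def depth_at(self, fov: float) -> float:
        """Inverse lookup by linear interpolation; clamps out-of-range FOV."""
        if fov < self.fov[0] or fov > self.fov[-1]:
            warnings.warn(
                f"FOV {fov:.3g} mm outside profile range "
                f"[{self.fov[0]:.3g}, {self.fov[-1]:.3g}]; depth clamped",
                stacklevel=2,
            )
        return float(np.interp(fov, self.fov, self.depth))


def default_sensitivity_profile() -> SensitivityProfile:
    """Synthetic stand-in depth->FOV table for the first 2 mm of tissue.

    A linear broadening model anchored so a 1.29 mm apparent FOV (the
    product of the typical arterial pulse width and speed) maps to 1.1 mm
    depth — the depth of the ventral caudal bundle.  It approximates the
    monotone shape of a photon-transport sensitivity curve and should be
    replaced by a simulation-derived table for quantitative depth work.
    """
    depth = np.linspace(0.0, 2.0, 21)
    fov = 0.4 + (1.29 - 0.4) / 1.1 * depth
    return SensitivityProfile(depth, fov)


def depth_from_event(
    mean_fwhm: float, mean_speed: float, profile: SensitivityProfile
) -> float:
    """Depth of signal origin from pulse width and speed.

    The apparent FOV is mean_fwhm (s) x mean_speed (mm/s); the profile
    inverts it to a tissue depth in mm.
    """
    if mean_fwhm <= 0 or mean_speed <= 0:
        raise ValueError("mean_fwhm and mean_speed must be positive")
    return profile.depth_at(mean_fwhm * mean_speed)


def concentration_from_rate(
    count_rate: float, sampling_rate: float = SAMPLED_FLOW_RATE_ML_MIN
) -> float:
    """Cells/mL from a count rate (per min) and the sampled mL/min."""
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    return count_rate / sampling_rate


def rate_from_concentration(
    concentration: float, sampling_rate: float = SAMPLED_FLOW_RATE_ML_MIN
) -> float:
    """Expected count rate (per min) at a concentration in cells/mL."""
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    return concentration * sampling_rate


def vessel_flow_rate(speed: float, diameter: float) -> float:
    """Volumetric flow (uL/s) in a cylindrical vessel under plug flow.

    speed in mm/s, diameter in mm; pi (d/2)^2 v in mm^3/s = uL/s.
    """
    if speed <= 0 or diameter <= 0:
        raise ValueError("speed and diameter must be positive")
    return math.pi * (diameter / 2.0) ** 2 * speed


def calibration_regression(blood_counts, difc_rates):
    """OLS of scan count rate (per min) on blood concentration (cells/mL).

    Returns (slope, intercept, r2); the slope estimates the sampled
    blood-volume rate in mL/min.
    """
    x = np.asarray(blood_counts, dtype=float)
    y = np.asarray(difc_rates, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length lists with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate input: zero variance")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
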