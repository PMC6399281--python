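"""Synthetic dual-channel DiFC scan generator with ground truth.

Emulates the signal structure of a two-probe diffuse fluorescence flow
cytometer: a slowly drifting ~10 uA autofluorescence baseline, additive
white detector noise, and Gaussian cell-transit pulses that appear on both
channels with an inter-channel apex delay of +-d/v set by the probe
separation d and the cell speed v (positive delay for forward/arterial
flow, negative for reverse/venous).  The temporal pulse width follows the
probe field of view: FWHM_t = fov_fwhm / v.  Cell arrivals are a Poisson
process with rate concentration x sampled-volume flow rate.  Single-channel
and coincident artifact spikes can be injected to exercise the downstream
artifact-rejection rules.

Every drawn quantity is recorded in a :class:`SimTruth` so the detection
and matching pipeline can be scored against known events.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Callable, Union

import numpy as np

from .trace import ChannelTrace

__all__ = [
    "SimConfig",
    "SimEvent",
    "SimArtifact",
    "SimTruth",
    "simulate_scan",
    "write_truth",
    "read_truth",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

ConcentrationLike = Union[float, Callable[[np.ndarray], np.ndarray]]


@dataclass
class SimConfig:
    """Parameters of a simulated two-probe scan.

    Defaults reflect the instrument and mouse-tail conditions the model
    emulates: 1000 samples/s acquisition, 3 mm fiber separation, 1.1 mm
    field of view (FWHM), 0.284 mL/min sampled blood flow, arterial /
    venous speeds of 112.3 / 76.6 mm/s, ~10 uA background and 40 nA
    detector noise.

    Parameters
    ----------
    duration : float
        Scan length in seconds.
    sample_rate : float
        Samples per second (Hz).
    concentration : float or callable
        Circulating cell concentration in cells/mL; a callable of time
        (seconds, vectorized) models clearance kinetics.
    sampled_flow_rate : float
        Blood volume interrogated per minute, mL/min.
    fiber_separation : float
        Center-to-center probe separation d, mm.
    fov_fwhm : float
        Probe field of view along the vessel, mm FWHM.
    arterial_fraction : float
        Probability that a cell travels in the forward (arterial) direction.
    amplitude_median, amplitude_log_sd : float
        Log-normal peak-amplitude model (nA; unitless log-sd).
    channel_jitter_log_sd : float
        Per-channel multiplicative amplitude jitter (log-normal sd), so the
        two channels see slightly different amplitudes for the same cell.
    noise_sigma : float
        White detector noise, nA.
    baseline_level : float
        Static autofluorescence background, uA.
    baseline_drift_amplitude, baseline_drift_period : float
        Sinusoidal baseline drift (nA; seconds).
    artifact_rate_single, artifact_rate_coincident : float
        Artifact spike rates, events/min.  Single-channel artifacts land on
        one randomly chosen channel; coincident ones hit both channels at
        the identical apex sample.
    artifact_amplitude_ref : float
        Artifact amplitudes are drawn uniformly in 1-10x this value (nA).
    seed : int
        Seed of the single random stream; identical configs give bitwise
        identical output.
    """

    duration: float = 60.0
    sample_rate: float = 1000.0
    concentration: ConcentrationLike = 0.0
    sampled_flow_rate: float = 0.284
    fiber_separation: float = 3.0
    fov_fwhm: float = 1.1
    arterial_fraction: float = 0.9
    arterial_speed_mean: float = 112.3
    arterial_speed_sd: float = 25.0
    venous_speed_mean: float = 76.6
    venous_speed_sd: float = 20.0
    amplitude_median: float = 530.0
    amplitude_log_sd: float = 0.5
    channel_jitter_log_sd: float = 0.15
    noise_sigma: float = 40.0
    baseline_level: float = 10.0
    baseline_drift_amplitude: float = 200.0
    baseline_drift_period: float = 60.0
    artifact_rate_single: float = 0.0
    artifact_rate_coincident: float = 0.0
    artifact_amplitude_ref: float = 250.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not 0.0 <= self.arterial_fraction <= 1.0:
            raise ValueError("arterial_fraction must lie in [0, 1]")
        for name in ("arterial_speed_mean", "venous_speed_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.fiber_separation <= 0 or self.fov_fwhm <= 0:
            raise ValueError("fiber_separation and fov_fwhm must be positive")
        if not callable(self.concentration) and self.concentration < 0:
            raise ValueError("concentration must be non-negative")


@dataclass
class SimEvent:
    """One simulated cell transit (ground truth)."""

    arrival_time: float  # apex time on channel 1, s
    direction: str  # "forward" (arterial) or "reverse" (venous)
    speed: float  # mm/s
    amplitude_ch1: float  # nA
    amplitude_ch2: float  # nA


@dataclass
class SimArtifact:
    """One simulated artifact spike (ground truth)."""

    time: float  # apex time, s
    kind: str  # "single_ch1" | "single_ch2" | "coincident"
    amplitude: float  # nA


@dataclass
class SimTruth:
    """Ground-truth record of a simulated scan."""

    events: list[SimEvent] = field(default_factory=list)
    artifacts: list[SimArtifact] = field(default_factory=list)


def _draw_arrival_times(
    rng: np.random.Generator, cfg: SimConfig
) -> np.ndarray:
    """Poisson arrivals at rate concentration x sampled_flow_rate.

    A callable concentration is handled by thinning against its maximum
    over the scan (inhomogeneous Poisson process).
    """
    per_ml_rate = cfg.sampled_flow_rate / 60.0  # mL sampled per second
    if callable(cfg.concentration):
        grid = np.linspace(0.0, cfg.duration, 1001)
        conc = np.asarray(cfg.concentration(grid), dtype=float)
        if np.any(conc < 0):
            raise ValueError("concentration function must be non-negative")
        lam_max = float(conc.max()) * per_ml_rate
        if lam_max == 0.0:
            return np.empty(0)
        n = rng.poisson(lam_max * cfg.duration)
        times = np.sort(rng.uniform(0.0, cfg.duration, n))
        accept = (
            rng.uniform(0.0, 1.0, n) * lam_max
            <= np.asarray(cfg.concentration(times), dtype=float) * per_ml_rate
        )
        return times[accept]
    lam = cfg.concentration * per_ml_rate
    if lam == 0.0:
        return np.empty(0)
    n = rng.poisson(lam * cfg.duration)
    return np.sort(rng.uniform(0.0, cfg.duration, n))


def _add_gaussian(samples: np.ndarray, rate: float, t_apex: float,
                  amplitude: float, fwhm: float) -> None:
    sigma = fwhm * _FWHM_TO_SIGMA
    lo = max(0, int(np.floor((t_apex - 5 * sigma) * rate)))
    hi = min(samples.size, int(np.ceil((t_apex + 5 * sigma) * rate)) + 1)
    if hi <= lo:
        return
    t = np.arange(lo, hi) / rate
    samples[lo:hi] += amplitude * np.exp(-0.5 * ((t - t_apex) / sigma) ** 2)


def _add_rectangle(samples: np.ndarray, rate: float, t_apex: float,
                   amplitude: float, width: float) -> None:
    lo = max(0, int(np.round((t_apex - width / 2) * rate)))
    hi = min(samples.size, int(np.round((t_apex + width / 2) * rate)) + 1)
    if hi > lo:
        samples[lo:hi] += amplitude


def simulate_scan(cfg: SimConfig) -> tuple[ChannelTrace, ChannelTrace, SimTruth]:
    """Generate a two-channel synthetic scan and its ground truth.

    Returns channel-1 and channel-2 traces (nA) plus a :class:`SimTruth`
    listing every cell transit and artifact injected.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.sample_rate))
    sig1 = np.zeros(n)
    sig2 = np.zeros(n)
    truth = SimTruth()

    # --- cell transits, in arrival order -------------------------------
    arrivals = _draw_arrival_times(rng, cfg)
    for t in arrivals:
        forward = rng.uniform() < cfg.arterial_fraction
        if forward:
            speed = rng.normal(cfg.arterial_speed_mean, cfg.arterial_speed_sd)
        else:
            speed = rng.normal(cfg.venous_speed_mean, cfg.venous_speed_sd)
        speed = max(speed, 1.0)  # truncate unphysical draws
        amp = cfg.amplitude_median * np.exp(
            rng.normal(0.0, cfg.amplitude_log_sd)
        )
        amp1 = amp * np.exp(rng.normal(0.0, cfg.channel_jitter_log_sd))
        amp2 = amp * np.exp(rng.normal(0.0, cfg.channel_jitter_log_sd))
        delay = cfg.fiber_separation / speed
        fwhm = cfg.fov_fwhm / speed
        _add_gaussian(sig1, cfg.sample_rate, t, amp1, fwhm)
        t2 = t + delay if forward else t - delay
        _add_gaussian(sig2, cfg.sample_rate, t2, amp2, fwhm)
        truth.events.append(
            SimEvent(t, "forward" if forward else "reverse", speed, amp1, amp2)
        )

    # --- artifact spikes ----------------------------------------------
    for rate_per_min, coincident in (
        (cfg.artifact_rate_single, False),
        (cfg.artifact_rate_coincident, True),
    ):
        if rate_per_min <= 0:
            continue
        n_art = rng.poisson(rate_per_min / 60.0 * cfg.duration)
        times = np.sort(rng.uniform(0.0, cfg.duration, n_art))
        for t in times:
            amp = cfg.artifact_amplitude_ref * rng.uniform(1.0, 10.0)
            width = rng.uniform(0.001, 0.005)  # brief spikes, 1-5 ms
            rectangular = rng.uniform() < 0.5
            add = _add_rectangle if rectangular else _add_gaussian
            if coincident:
                # identical apex sample on both channels
                t_snap = np.round(t * cfg.sample_rate) / cfg.sample_rate
                add(sig1, cfg.sample_rate, t_snap, amp, width)
                add(sig2, cfg.sample_rate, t_snap, amp, width)
                truth.artifacts.append(SimArtifact(t_snap, "coincident", amp))
            else:
                on_ch1 = rng.uniform() < 0.5
                add(sig1 if on_ch1 else sig2, cfg.sample_rate, t, amp, width)
                kind = "single_ch1" if on_ch1 else "single_ch2"
                truth.artifacts.append(SimArtifact(t, kind, amp))
    truth.artifacts.sort(key=lambda a: a.time)

    # --- baseline and detector noise ----------------------------------
    t_axis = np.arange(n) / cfg.sample_rate
    baseline = cfg.baseline_level * 1000.0 + (
        cfg.baseline_drift_amplitude
        * np.sin(2.0 * np.pi * t_axis / cfg.baseline_drift_period)
        if cfg.baseline_drift_amplitude > 0
        else 0.0
    )
    sig1 += baseline
    sig2 += baseline
    if cfg.noise_sigma > 0:
        sig1 += rng.normal(0.0, cfg.noise_sigma, n)
        sig2 += rng.normal(0.0, cfg.noise_sigma, n)

    return (
        ChannelTrace(1, cfg.sample_rate, sig1),
        ChannelTrace(2, cfg.sample_rate, sig2),
        truth,
    )


_TRUTH_HEADER = ["time_s", "kind", "direction", "speed_mm_s", "amp1_nA", "amp2_nA"]


def write_truth(truth: SimTruth, path) -> None:
    """Write ground truth as delimited text (lossless round trip)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_TRUTH_HEADER)
        for e in truth.events:
            w.writerow(
                [repr(e.arrival_time), "cell", e.direction, repr(e.speed),
                 repr(e.amplitude_ch1), repr(e.amplitude_ch2)]
            )
        for a in truth.artifacts:
            amp2 = repr(a.amplitude) if a.kind == "coincident" else ""
            w.writerow([repr(a.time), a.kind, "", "", repr(a.amplitude), amp2])


class TruthParseError(ValueError):
    """Raised when a ground-truth file cannot be parsed; names the line."""


def _parse_float(text: str, lineno: int, col: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise TruthParseError(
            f"line {lineno}: cannot parse {col} value {text!r}"
        ) from None


def read_truth(path) -> SimTruth:
    """Read a ground-truth file written by :func:`write_truth`."""
    truth = SimTruth()
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _TRUTH_HEADER:
            raise TruthParseError(
                f"line 1: expected header {','.join(_TRUTH_HEADER)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(_TRUTH_HEADER):
                raise TruthParseError(f"line {lineno}: expected 6 fields")
            t = _parse_float(row[0], lineno, "time_s")
            kind = row[1]
            if kind == "cell":
                if row[2] not in ("forward", "reverse"):
                    raise TruthParseError(
                        f"line {lineno}: bad direction {row[2]!r}"
                    )
                truth.events.append(
                    SimEvent(
                        t,
                        row[2],
                        _parse_float(row[3], lineno, "speed_mm_s"),
                        _parse_float(row[4], lineno, "amp1_nA"),
                        _parse_float(row[5], lineno, "amp2_nA"),
                    )
                )
            elif kind in ("single_ch1", "single_ch2", "coincident"):
                truth.artifacts.append(
                    SimArtifact(t, kind, _parse_float(row[4], lineno, "amp1_nA"))
                )
            else:
                raise TruthParseError(f"line {lineno}: unknown kind {kind!r}")
    return truth
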