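"""Pair cell candidates across the two probe channels.

A cell flowing under both probes produces a peak on each channel separated
by the transit delay d/v (probe separation over cell speed).  Candidates
are paired in the forward (channel 1 -> 2, arterial) and reverse (channel
2 -> 1, venous) directions when their amplitudes and three speed estimates
agree within a similarity factor; the inter-channel delay yields a third,
delay-derived speed v_c3 = d / |t2 - t1|.  Candidates without an acceptable
partner are discarded as likely capillary-bed cells or artifacts, and
candidate pairs at the identical apex time on both channels are discarded
as movement artifacts (a real cell cannot be under both probes at once).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .detect import PeakCandidate
from .simulate import SimTruth

__all__ = [
    "MatchConfig",
    "MatchedEvent",
    "MatchResult",
    "match_candidates",
    "MatchMetrics",
    "evaluate_against_truth",
]


@dataclass
class MatchConfig:
    """Matching parameters.

    fiber_separation : mm — probe separation d (default 3 mm).
    v_max : mm/s — assumed maximum cell speed (default 400 mm/s); sets the
        minimum credible inter-channel delay d / v_max.
    similarity_factor : maximum mean max/min ratio over the amplitude and
        speed comparisons for a pair to be accepted (default 2.5).
    coincidence_window : samples — apexes on the two channels within this
        many samples of each other are treated as coincident artifacts.
    """

    fiber_separation: float = 3.0
    v_max: float = 400.0
    similarity_factor: float = 2.5
    coincidence_window: int = 1
    window_delays: float = 10.0  # search-window length in transit delays

    def __post_init__(self) -> None:
        if self.fiber_separation <= 0 or self.v_max <= 0:
            raise ValueError("fiber_separation and v_max must be positive")
        if self.similarity_factor < 1:
            raise ValueError("similarity_factor must be >= 1")
        if self.coincidence_window < 0:
            raise ValueError("coincidence_window must be >= 0")


@dataclass
class MatchedEvent:
    """A forward- or reverse-paired pair of candidates (one cell transit).

    ``c1`` is the candidate on the channel the cell reached first, ``c2``
    the later one: channel 1 then 2 for forward (arterial) events, channel
    2 then 1 for reverse (venous) events.
    """

    direction: str  # "forward" | "reverse"
    c1: PeakCandidate
    c2: PeakCandidate
    v_c3: float  # delay-derived speed d/|t2-t1|, mm/s
    v_consensus: float  # mean of the three speed estimates, mm/s
    score: float  # mean max/min similarity ratio, lower is better

    @property
    def delta_t(self) -> float:
        return abs(self.c2.t - self.c1.t)

    @property
    def t(self) -> float:
        """Event time: apex time on channel 1 (the reference channel)."""
        return self.c1.t if self.c1.channel == 1 else self.c2.t


@dataclass
class MatchResult:
    forward: list[MatchedEvent] = field(default_factory=list)
    reverse: list[MatchedEvent] = field(default_factory=list)
    unmatched: list[PeakCandidate] = field(default_factory=list)
    coincident: list[tuple[PeakCandidate, PeakCandidate]] = field(
        default_factory=list
    )

    @property
    def events(self) -> list[MatchedEvent]:
        return sorted(self.forward + self.reverse, key=lambda e: e.t)


def _check_sorted(cands: list[PeakCandidate], name: str) -> None:
    for a, b in zip(cands, cands[1:]):
        if b.t < a.t:
            raise ValueError(f"{name} candidates must be sorted by time")


def _ratio(a: float, b: float) -> float:
    return max(a, b) / min(a, b)


def _score_pair(
    first: PeakCandidate, second: PeakCandidate, cfg: MatchConfig
) -> tuple[float, float]:
    """Similarity score and v_c3 for a candidate pair (first hit earlier)."""
    dt = second.t - first.t
    v_c3 = cfg.fiber_separation / dt
    r_amp = _ratio(first.amplitude, second.amplitude)
    r_width = _ratio(first.v_width, second.v_width)
    v_width_mean = 0.5 * (first.v_width + second.v_width)
    r_delay = _ratio(v_width_mean, v_c3)
    return (r_amp + r_width + r_delay) / 3.0, v_c3


def _directional_pass(
    first_list: list[PeakCandidate],
    second_list: list[PeakCandidate],
    direction: str,
    cfg: MatchConfig,
) -> list[MatchedEvent]:
    """Greedy one-directional pairing in time order.

    For each candidate on the first-hit channel, partners on the other
    channel are sought in the adaptive delay window
    [d/v_max, window_delays * d/v_width]; the best-scoring acceptable
    partner is consumed.
    """
    events: list[MatchedEvent] = []
    used_second: set[int] = set()
    times2 = np.array([c.t for c in second_list])
    for c in first_list:
        lo = c.t + cfg.fiber_separation / cfg.v_max
        hi = c.t + cfg.window_delays * cfg.fiber_separation / c.v_width
        if hi <= lo:
            continue
        i0, i1 = np.searchsorted(times2, [lo, hi])
        best = None
        for j in range(int(i0), int(i1)):
            if j in used_second:
                continue
            score, v_c3 = _score_pair(c, second_list[j], cfg)
            if score > cfg.similarity_factor:
                continue
            dt = second_list[j].t - c.t
            key = (score, dt)
            if best is None or key < best[0]:
                best = (key, j, score, v_c3)
        if best is not None:
            _, j, score, v_c3 = best
            partner = second_list[j]
            used_second.add(j)
            v_cons = (c.v_width + partner.v_width + v_c3) / 3.0
            events.append(
                MatchedEvent(direction, c, partner, v_c3, v_cons, score)
            )
    return events


def match_candidates(
    list1: list[PeakCandidate],
    list2: list[PeakCandidate],
    cfg: MatchConfig | None = None,
    sample_rate: float = 1000.0,
) -> MatchResult:
    """Pair channel-1 and channel-2 candidates into directional events.

    Procedure: (a) coincident apex pairs are removed from both lists as
    movement artifacts; (b) a forward (1->2) greedy pass pairs each channel
    -1 candidate with its best acceptable channel-2 partner in the delay
    window; (c) a mirrored reverse (2->1) pass; (d) a candidate claimed by
    both directions keeps only its lower-score event.  Every input
    candidate ends in exactly one of forward / reverse / unmatched /
    coincident.
    """
    cfg = cfg or MatchConfig()
    _check_sorted(list1, "channel-1")
    _check_sorted(list2, "channel-2")
    result = MatchResult()

    # (a) coincidence removal: nearest unused apex within the window
    removed1: set[int] = set()
    removed2: set[int] = set()
    idx2 = np.array([c.index for c in list2])
    for i, c in enumerate(list1):
        j0, j1 = np.searchsorted(
            idx2, [c.index - cfg.coincidence_window, c.index + cfg.coincidence_window + 1]
        )
        best = None
        for j in range(int(j0), int(j1)):
            if j in removed2:
                continue
            gap = abs(list2[j].index - c.index)
            if best is None or gap < best[0]:
                best = (gap, j)
        if best is not None:
            removed1.add(i)
            removed2.add(best[1])
            result.coincident.append((c, list2[best[1]]))
    l1 = [c for i, c in enumerate(list1) if i not in removed1]
    l2 = [c for j, c in enumerate(list2) if j not in removed2]

    # (b) forward and (c) reverse passes, run independently
    forward = _directional_pass(l1, l2, "forward", cfg)
    reverse = _directional_pass(l2, l1, "reverse", cfg)

    # (d) resolve candidates claimed in both directions: keep the closer
    # (lower-score) match, best events first
    taken: set[int] = set()
    for ev in sorted(forward + reverse, key=lambda e: (e.score, e.delta_t)):
        ka, kb = id(ev.c1), id(ev.c2)
        if ka in taken or kb in taken:
            continue
        taken.add(ka)
        taken.add(kb)
        (result.forward if ev.direction == "forward" else result.reverse).append(ev)
    result.forward.sort(key=lambda e: e.c1.t)
    result.reverse.sort(key=lambda e: e.c1.t)

    result.unmatched = [c for c in l1 + l2 if id(c) not in taken]
    result.unmatched.sort(key=lambda c: c.t)
    return result


@dataclass
class MatchMetrics:
    """Pipeline scores against simulation ground truth.

    Fractions are NaN when their denominator is empty and the companion
    ``*_defined`` flag is False; in the fully degenerate no-truth/no-event
    case they are reported as 1.0 (nothing to find, nothing found).
    """

    direction_accuracy: float
    sensitivity: float
    precision: float
    speed_rmse: float
    n_events: int
    n_truth_detectable: int
    n_true_positive: int
    defined: bool = True


def evaluate_against_truth(
    events: list[MatchedEvent],
    unmatched: list[PeakCandidate],
    truth: SimTruth,
    tol: float = 0.05,
    amplitude_threshold: float | None = None,
) -> MatchMetrics:
    """Score matched events against the simulator's ground truth.

    Events are associated to truth cell transits greedily by apex-time
    proximity (one-to-one, within ``tol`` seconds, on the channel-1 apex).
    ``amplitude_threshold`` restricts the sensitivity denominator to truth
    events detectable on both channels (both amplitudes at or above it).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    detectable = [
        e
        for e in truth.events
        if amplitude_threshold is None
        or min(e.amplitude_ch1, e.amplitude_ch2) >= amplitude_threshold
    ]
    if not events and not detectable:
        return MatchMetrics(1.0, 1.0, 1.0, math.nan, 0, 0, 0, defined=False)

    pairs = []
    for i, ev in enumerate(events):
        for j, te in enumerate(truth.events):
            dt = abs(ev.t - te.arrival_time)
            if dt <= tol:
                pairs.append((dt, i, j))
    pairs.sort()
    used_e: set[int] = set()
    used_t: set[int] = set()
    assoc: list[tuple[int, int]] = []
    for _, i, j in pairs:
        if i in used_e or j in used_t:
            continue
        used_e.add(i)
        used_t.add(j)
        assoc.append((i, j))

    n_correct_dir = sum(
        1 for i, j in assoc if events[i].direction == truth.events[j].direction
    )
    detectable_ids = {id(e) for e in detectable}
    n_detected = sum(
        1 for _, j in assoc if id(truth.events[j]) in detectable_ids
    )
    sq_err = [
        (events[i].v_c3 - truth.events[j].speed) ** 2 for i, j in assoc
    ]
    return MatchMetrics(
        direction_accuracy=n_correct_dir / len(assoc) if assoc else math.nan,
        sensitivity=n_detected / len(detectable) if detectable else math.nan,
        precision=len(assoc) / len(events) if events else math.nan,
        speed_rmse=float(np.sqrt(np.mean(sq_err))) if sq_err else math.nan,
        n_events=len(events),
        n_truth_detectable=len(detectable),
        n_true_positive=len(assoc),
    )
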