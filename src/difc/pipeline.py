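"""End-to-end scan processing: preprocess -> detect -> match."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .detect import DetectionConfig, PeakCandidate, find_candidates
from .match import MatchConfig, MatchResult, match_candidates
from .preprocess import PreprocessConfig, normalize_channels, preprocess_trace
from .trace import ChannelTrace, ProcessedTrace

__all__ = ["PipelineResult", "process_scan", "events_to_frame"]


@dataclass
class PipelineResult:
    processed1: ProcessedTrace
    processed2: ProcessedTrace
    candidates1: list[PeakCandidate]
    candidates2: list[PeakCandidate]
    match: MatchResult = field(default=None)  # type: ignore[assignment]

    @property
    def events(self):
        return self.match.events


def process_scan(
    trace1: ChannelTrace,
    trace2: ChannelTrace,
    pre_cfg: PreprocessConfig | None = None,
    det_cfg: DetectionConfig | None = None,
    match_cfg: MatchConfig | None = None,
) -> PipelineResult:
    """Run the full two-channel analysis on a raw scan."""
    pre_cfg = pre_cfg or PreprocessConfig()
    det_cfg = det_cfg or DetectionConfig()
    match_cfg = match_cfg or MatchConfig()
    p1 = preprocess_trace(trace1, pre_cfg)
    p2 = preprocess_trace(trace2, pre_cfg)
    if pre_cfg.normalize:
        p1, p2 = normalize_channels(p1, p2, det_cfg.threshold)
    c1 = find_candidates(p1, det_cfg)
    c2 = find_candidates(p2, det_cfg)
    m = match_candidates(c1, c2, match_cfg, sample_rate=trace1.sample_rate)
    return PipelineResult(p1, p2, c1, c2, m)


def events_to_frame(result: PipelineResult) -> pd.DataFrame:
    """Tabulate matched events as one row per event."""
    rows = []
    for ev in result.events:
        a, b = ev.c1, ev.c2
        first_ch1 = a.channel == 1
        ch1, ch2 = (a, b) if first_ch1 else (b, a)
        rows.append(
            {
                "direction": ev.direction,
                "t1_s": ch1.t,
                "t2_s": ch2.t,
                "amp1_nA": ch1.amplitude,
                "amp2_nA": ch2.amplitude,
                "vc1_mm_s": ch1.v_width,
                "vc2_mm_s": ch2.v_width,
                "vc3_mm_s": ev.v_c3,
                "score": ev.score,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "direction", "t1_s", "t2_s", "amp1_nA", "amp2_nA",
            "vc1_mm_s", "vc2_mm_s", "vc3_mm_s", "score",
        ],
    )
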