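"""False-alarm rates on a cell-free scan: single fiber vs matched.

Simulates a 60-minute control scan containing only detector noise and
artifact spikes, then compares the single-channel candidate rate with the
matched-event rate across detection thresholds.  Matching should suppress
false alarms by at least an order of magnitude.
"""

from difc import (
    SimConfig,
    far_candidates,
    matched_far,
    preprocess_trace,
    simulate_scan,
)

cfg = SimConfig(
    duration=3600.0,
    concentration=0.0,
    artifact_rate_single=2.0,
    artifact_rate_coincident=0.5,
    seed=7,
)
trace1, trace2, _ = simulate_scan(cfg)

thresholds = [150.0, 250.0, 500.0]
single = far_candidates(preprocess_trace(trace1), thresholds)
matched = matched_far(trace1, trace2, thresholds)

print("threshold_nA  single_fiber_FAR/min  matched_FAR/min")
for th, s, m in zip(thresholds, single, matched):
    print(f"{th:12g}  {s:20.3f}  {m:15.3f}")
# Single-channel artifacts can only ever appear on one fiber and coincident
# artifacts arrive at the identical sample on both, so the pairing rules
# reject both kinds and the matched false-alarm rate collapses.
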