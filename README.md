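# difc

Analysis toolkit for **diffuse in vivo flow cytometry (DiFC)** — counting
extremely rare fluorescently labeled cells (such as circulating tumor
cells) directly in the bloodstream of a living animal, without drawing
blood. A DiFC instrument places two fiber-optic probes, a few millimetres
apart, on the skin over a major vascular bundle; each labeled cell passing
through a probe's diffuse-light field of view produces a fluorescence peak
in that probe's photodetector current trace.

This package implements the complete two-channel signal-processing chain:

1. **Preprocessing** — the slowly varying autofluorescence background
   (~10 µA against ~500 nA cell peaks) is estimated with a 2.5 s running
   median plus 7-point moving average, subtracted, and the residual smoothed
   with a 3 ms moving average; channel amplitudes are then normalized.
2. **Detection** — cell candidates are local maxima above a fixed counting
   threshold (default 250 nA) with topographic prominence of at least half
   the threshold. Each candidate's apex time *t*, amplitude *A*, FWHM, and
   width-derived speed *v* = FOV / FWHM are measured.
3. **Matching** — candidates are paired across channels in the forward
   (arterial, probe 1 → 2) and reverse (venous) directions. A pair is
   accepted when the amplitudes, the two width-derived speeds, and the
   delay-derived speed *v*₍c3₎ = *d* / (*t*₂ − *t*₁) agree within a factor
   2.5 on average, searching delays between *d*/*v*\_max and ten transit
   times. Unpaired candidates and same-instant (coincident) peaks are
   rejected as artifacts — this suppresses the false-alarm rate by more
   than an order of magnitude versus a single fiber.
4. **Quantification** — per-interval count rates, SNR = 20 log₁₀(*I*/σ),
   false-alarm rates, cell depth from the apparent field of view
   (FWHM × speed) via a monotone depth→FOV sensitivity profile, and the
   conversion between count rate and circulating concentration through the
   sampled blood-volume rate (0.284 mL/min).
5. **Calibration** — bead-referenced counting thresholds (50 % of the FR4
   reference-bead intensity; in vivo recovered through the 23× brighter
   circulating CS beads) and cell counting in drawn blood samples.
6. **Simulation** — a synthetic dual-channel scan generator with Poisson
   cell arrivals, Gaussian transit pulses with the correct inter-channel
   delay ±*d*/*v*, log-normal amplitudes, baseline drift, detector noise and
   injectable artifacts, returning full ground truth for validation.

## Worked example

```sh
python examples/simulate_and_match.py
```

```
simulated cell transits : 284
candidates (ch1 / ch2)  : 260 / 259
matched forward/reverse : 220 / 30
unmatched / coincident  : 19 / 0
mean arterial speed     : 114.0 mm/s (delay-derived)
direction accuracy      : 1.000
sensitivity / precision : 0.988 / 1.000
speed RMSE              : 4.0 mm/s
```

A 10-minute simulated scan at 100 cells/mL yields 284 true transits; the
pipeline recovers 250 matched events, calls every direction correctly, and
estimates each cell's speed from the inter-probe delay to ~4 mm/s RMS. The
unmatched candidates are mostly cells whose amplitude fell below the
250 nA counting threshold on one channel.

Other examples: `false_alarm_rate.py` (single-fiber vs matched FAR on a
cell-free control scan), `calibration_thresholds.py` (bead threshold
arithmetic and blood-sample counting), `depth_speed_concentration.py`
(SNR, depth, vessel flow, concentration conversion).

A thin CLI wraps the same functions:

```sh
difc simulate --duration 60 --concentration 100 --seed 1 --out-prefix run1
difc process run1_trace.csv --out events.csv
difc quantify events.csv --interval 10 --duration 60
difc calibrate --fr4-mean 500
```

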