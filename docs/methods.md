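# Methods

## Signal model

A DiFC probe integrates fluorescence from a diffuse sensing volume whose
extent along the vessel is characterized by a field of view (FOV) of
~1.1 mm FWHM. A labeled cell moving at speed *v* therefore produces a
smooth unimodal pulse of temporal width FWHM_t = FOV / *v* on each
channel, riding on a large (~10 µA) and slowly varying autofluorescence
background with additive white detector noise (σ ≈ 40 nA). With two probes
separated by *d* = 3 mm along the vessel, the same cell appears on the
second channel after a delay *d*/*v* — positive (channel 1 first) for
arterial flow, negative for venous.

The simulator implements exactly this model. Cell arrivals are a Poisson
process with rate λ = concentration × sampled-volume rate (default
0.284 mL/min, so 100 cells/mL ≙ 28.4 counts/min); a callable concentration
is supported through thinning, for clearance-kinetics studies. Pulses are
Gaussian — the field's instruments record smooth unimodal transits and no
stronger shape model is justified — and amplitudes are log-normal (median
530 nA, log-sd 0.5) with an independent per-channel log-normal jitter
(sd 0.15) representing unequal probe coupling. Speeds are normal:
112.3 ± 25 mm/s arterial, 76.6 ± 20 mm/s venous, truncated at 1 mm/s.
Artifacts are brief (1–5 ms) rectangular or Gaussian spikes with
amplitudes uniform in 1–10× the 250 nA counting threshold: single-channel
artifacts model electronic pickup on one detector; coincident artifacts
land on the identical apex sample of both channels, as limb motion does.
The artifact width ceiling (5 ms) is below the minimum credible transit
delay *d*/*v*_max = 7.5 ms, so a plateau apex ambiguity cannot masquerade
as a transit. All draws come from one seeded generator in arrival order,
making scans bitwise reproducible.

What the simulator does **not** emulate: non-Gaussian pulse shapes from
off-axis trajectories, amplitude–depth correlation, probe drift or slow
coupling changes, heartbeat/breathing modulation of the baseline, and
overlapping multi-cell transits are generated but not deconvolved.
Passing tests therefore demonstrate the correctness of the algorithmic
chain under the stated signal model, not instrument-level performance on
animals.

## Preprocessing

Background = running median (window 2.5 s, rounded to an odd sample
count) followed by a centered 7-point moving average; the residual is
smoothed with a centered 3-point (3 ms at 1 kHz) moving average. All
filters use mirror (reflection without edge repeat) padding; this is a
package choice where any convention would do, fixed so the filters are
exactly reproducible — the suite checks them against naive O(N·W)
re-implementations. The running median uses an O(N log W) rolling
implementation so hour-long 1 kHz traces process in seconds.

Channel normalization multiplies channel 2 by
s = median(candidate amplitudes, ch1) / median(candidate amplitudes, ch2)
using provisional candidates at the operating threshold; medians resist
the log-normal amplitude tail. With fewer than 5 candidates on either
channel the ratio of mean estimated backgrounds is used instead, on the
grounds that coupling efficiency scales signal and autofluorescence alike.

## Detection

`scipy.signal.find_peaks` with height = threshold (default 250 nA),
topographic prominence ≥ 0.5 × threshold, and minimum separation
3 samples. FWHM is measured by linear interpolation of the half-maximum
crossings on each side of the apex, with the half level taken relative to
the zero (background-subtracted) baseline and the crossing search bounded
by the adjacent candidate apexes. If one side does not resolve (merged
shoulder) the resolvable side is doubled and the candidate flagged; if
neither resolves the inter-apex span is used, flagged. Merged transits are
a documented limitation — no deconvolution is attempted. The width-derived
speed is FOV / FWHM with FOV an input parameter (default 1.1 mm), not a
fitted quantity.

## Matching

Order of operations: coincidence removal first, then directional passes,
then conflict resolution.

1. **Coincidence removal.** Any cross-channel candidate pair whose apexes
   lie within `coincidence_window` samples (default 1) is removed and
   logged. Real transits need at least *d*/*v*_max = 7.5 ms; same-instant
   peaks are motion artifacts. The window is configurable because real
   apex jitter may warrant 2–3 samples.
2. **Directional passes.** For each channel-1 candidate (forward pass,
   in time order) partners on channel 2 are considered in the window
   [t + d/v_max, t + 10·d/v_width] — from the fastest credible transit to
   ten transit delays at the candidate's own width-derived speed. Three
   max/min ratios are formed: amplitudes, the two width-derived speeds,
   and mean width-speed vs delay-speed v_c3; a pair is accepted when their
   mean is ≤ 2.5 and the lowest-scoring acceptable partner (ties: smallest
   delay) is consumed greedily. The reverse pass mirrors this with the
   channels swapped. Comparing v_c3 against the *mean* of the width speeds
   is a package choice (the natural symmetric option) and configurable in
   principle via the scoring helper.
3. **Conflict resolution.** The two passes run independently, so a
   candidate may be claimed by both directions; events are then accepted
   best-score-first and a candidate can appear in at most one event.
   Remaining candidates are reported unmatched — every input candidate
   ends in exactly one of forward / reverse / unmatched / coincident.

Greedy time-ordered assignment (not global/Hungarian) is deliberate: it
follows the sequential description of the procedure and its failure mode
(rare suboptimal pairings in dense traffic) is visible in the evaluation
metrics rather than hidden.

A useful symmetry: reversing the time axis of both traces maps arterial
transits onto venous ones and vice versa (the channel order of arrival
flips), and the matcher preserves this one-to-one.

## Quantification and calibration

- SNR = 20·log₁₀(I/σ) dB, with I a mean peak amplitude and σ the system
  noise.
- Count rate ↔ concentration through the sampled-volume rate
  Q = 0.284 mL/min (equivalently one count per 3.52 min at 1 cell/mL):
  concentration = rate / Q. The two printed variants 0.283/0.284 mL/min
  differ by 0.35 %; 0.284 is the package constant and tests accept both.
- Vessel flow under plug flow: π (D/2)² v, in µL/s for mm and mm/s inputs.
- Depth: the apparent FOV (mean FWHM × mean speed) is inverted through a
  strictly monotone depth→FOV table by linear interpolation, clamping with
  a warning outside the table. The bundled default table is a synthetic
  linear stand-in anchored so a 1.29 mm FOV maps to 1.1 mm depth (the
  ventral caudal bundle); quantitative depth work should supply a
  photon-transport-derived table, which the API accepts unchanged.
- Calibration thresholds: in vitro, fraction × FR4 bead mean (fraction
  default 0.5); in vivo, fraction × CS in vivo mean / CS:FR4 ratio
  (defaults 0.5 × 11 300 / 23 = 245.7 nA), with rounding to the nearest
  10 nA kept as a separate optional step so the exact value remains
  inspectable. Bead "mean intensity" is the mean of peak apexes.
  Intensities are nA throughout; `ua()` tags µA inputs.
- Blood-sample counting preprocesses the single tube-flow trace, counts
  peaks above 0.5 × FR4 mean (smaller peaks are debris), and divides by
  the drawn volume. No matching applies — one tube, one probe.
- The calibration regression is ordinary least squares of count rate on
  blood concentration; r² is the squared Pearson correlation, reported
  without a confidence interval at small n.

## Numerical and testing choices

Problem sizes in the test suite are chosen to keep the full run around a
minute while leaving the statistical margins wide: the false-alarm
property uses one 60-minute cell-free scan (artifact rates 2/min single +
0.5/min coincident); linearity uses six 10-minute scans at 1–1000
cells/mL; slope recovery uses 100 cohorts of 17 synthetic animals;
the exponential-clearance recovery demonstration uses a 30-minute scan
with an 8-minute time constant, binned in 5-minute intervals. Noiseless
fidelity checks assert direction accuracy of exactly 1.0 and bound the
delay-speed error by the ±1-sample delay quantization v²·Δt/d.

Known limitations: no multi-peak deconvolution; no tracking of a cell
across circulation passes; greedy matching can mispair in very dense
traffic (≫10³ cells/mL); the default depth table is qualitative; trace
files are text-only (no binary container).
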