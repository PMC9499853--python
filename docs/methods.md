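# Methods

This note documents the models, defaults and numerical choices behind
`nacloop`, and what its synthetic experiments do and do not establish.

## The experimental design being modeled

Two recording modalities feed two analyses. In-lab ("buffet") sessions
yield video-annotated bite times under two conditions — loss-of-control
(LOC) eating and standard meals — and the quantity of interest is band
power in the 2 s before each bite. Ambulatory recording yields
patient-initiated magnet swipes labeled craving, hunger or control, plus
scheduled awake/sleep snapshots; the quantity of interest is the power
spectral density of the 60 s before each swipe. The biomarker in both is
the combined delta–theta band, 2–8 Hz.

The closed-loop side mirrors a responsive neurostimulator: an "area"
detector computes a short-term AUC every 2 s, compares it with the mean of
the trailing 2 min, fires at a programmed percent excess (the clinically
used range is 63–100%), requires left/right coincidence, and triggers
10-s stimulation bouts (two 5-s bursts at 125 Hz) subject to awake-hours
gating (07:00–22:00) and a 700-bout (~117 min) daily cap.

## Synthetic data model

**Background.** Each channel is independent Gaussian noise shaped to a
1/f^β spectrum (β = 1.5 by default, testable via the log-log slope of the
averaged periodogram over 2–40 Hz). The spectrum flattens below 1 Hz;
without that floor the total-variance normalization would push an
arbitrarily large share of the variance below the 1 Hz analysis corner as
recordings get longer, making in-band effect sizes depend on duration.
`background_scale_uv` (default 10 µV RMS) sets the overall amplitude;
absolute microvolts are arbitrary — no calibration to true NAc voltages is
claimed — and only the burst/background and sleep-delta/background ratios
matter.

**Event-locked bursts.** Craving swipes and LOC bites receive a burst of
band-limited noise occupying `[t − burst_lead_s, t]` on the ventral
channel(s) of the configured sides (bilateral by default), with a Hann
envelope. Two realism choices matter:

- the burst is noise, not a sinusoid, so the wavelet stage is exercised on
  realistic bandwidth;
- within the 2–8 Hz band the burst spectrum is tilted 1/f^2.5
  (delta-dominant). A spectrally flat 2–8 Hz burst would put substantial
  energy at 7–8 Hz, which wavelets centered at 8–12 Hz genuinely pick up;
  the result would be a robust alpha "effect" that contradicts the
  expected band specificity of the biomarker. Ambulatory observations of
  this signal class are delta-dominated, so the tilt is the more faithful
  model as well as the cleaner one.

The default amplitude (12 µV at the envelope peak, 8th-order bandpassed)
was fixed once so that the mean pre-LOC low-frequency elevation lands
around 3.5–4 dB — the few-dB scale reported for in-lab bite-locked
contrasts in this preparation (subject-level means of roughly 2.4–5.6 dB
against ~0.3–0.6 dB for standard meals). Hunger events get no burst by
default (`hunger_burst_amplitude_uv = 0`), making hunger ≈ control the
null contrast; a reduced hunger burst is configurable.

**Sleep delta.** Sleep hours (22:00–07:00 by default) carry a sustained
1–4 Hz oscillation on all channels (25 µV RMS, 30-s cosine ramps). The
oscillation has a *constant envelope* (narrowband noise whose Hilbert
envelope is normalized away, leaving a frequency-wandering tone). This is
deliberate: the area detector's sleep-suppression rationale assumes sleep
delta is sustained, so the long-term trend absorbs it. Amplitude-
fluctuating narrowband noise has a coherence time near the 2-s short-term
window and fires the detector constantly, which is neither the intended
physiology ("sustained high-amplitude delta") nor compatible with the
device's design logic. With the constant-envelope model, residual sleep
detections come from instantaneous-frequency excursions through the 2–8 Hz
detector band — a realistic, non-zero floor.

**Event schedule.** Counts per kind are Poisson with mean rate × eligible
hours; times are uniform over the eligible intervals (awake hours for all
behavioral kinds, sleep hours for scheduled sleep snapshots), kept
`event_margin_s` (62 s by default) clear of the recording edges so that
60-s pre-event windows always fit. The buffet profile uses 30 bites/hour
per condition, putting per-condition group sizes in the mid-teens — the
scale of an in-lab meal assessment. Matching that n matters statistically:
at much larger n, even sub-0.1-dB systematic residues (e.g. wavelet
sidelobe leakage) become "significant", which would misrepresent the
negative results expected outside the biomarker band.

**Determinism.** All randomness flows from `rng_seed` through fixed-role
seed sequences; identical configs give bit-identical signals and logs.
Stimulation windows are blanked (masked), never synthesized — no artifact
waveform modeling.

## Signal processing

**Cleaning.** Per channel: linear detrend; IIR notch (Q = 30) at 60 Hz and
each harmonic below Nyquist; 4th-order Butterworth bandpass 1–90 Hz. All
filters run forward–backward (zero phase) so event latencies are
preserved. The chain is idempotent on the passband to within 0.5 dB.

**Epoching.** Windows are relative to event time and half-open in samples
(`n = round((end − start)·fs)` samples ending at `round((t + end)·fs)`);
a window of (−2, 0) at 250 Hz is exactly 500 samples ending at the event
sample. Events whose window leaves the recording are dropped and counted,
never padded. The ambulatory pre-swipe window defaults to 60 s; the
device-storage description spans 1–2 min, and the shorter end is used
because it is the figure quoted for the craving analyses; it is
configurable (`pre_window_s`).

**Morlet transform.** Complex Morlet wavelets truncated at ±3.5 σ_t,
amplitude-calibrated so a unit sinusoid at a grid frequency yields power
1/2 (its variance) at that bin — band power is then directly comparable to
bandpassed-variance oracles. The default frequency grid is 1-Hz-spaced
over the analyzed bands. Cycle counts are `max(5, f/2)`: 5 cycles through
the low-frequency band, then a spectral bandwidth capped near 2 Hz, so
narrowband low-frequency energy is not smeared into beta and above (a
constant-cycle wavelet bank at 1-Hz spacing leaks measurably at 13–30 Hz).
A scalar or per-frequency `n_cycles` can be passed to restore the
constant-5-cycles convention. Epochs are reflection-padded by the longest
half-wavelet; each frequency's contaminated outer margin is flagged and
excluded from band averages. Analyses that quantify a 2-s window therefore
extract a wider epoch (window ± pad) and average only the requested window.

**Band averaging and dB.** Band edges are inclusive on the grid, so the
2–8 Hz low-frequency average equals the average of the delta and theta
bins. dB change is `10·log10(P/P0)`. For the buffet analysis the default
baseline P0 is the mean linear power of the standard-meal epochs of the
same channel and band (standard bites then average ≈ 0 dB); a per-epoch
pre-window baseline is selectable (`baseline="epoch_pre"`). The choice
shifts absolute dB levels but not the LOC-vs-standard contrast; both modes
are exposed because the convention is a genuine free parameter of such
analyses.

**PSD.** Welch, Hann windows of 2 s with 50% overlap; the integral over
frequency recovers the variance (checked via Parseval on white noise and
sinusoids). The ambulatory per-event metric is the mean density over
2–8 Hz in µV²/Hz.

## Detector semantics

AUC is operationalized as the mean rectified amplitude of the (optionally
2–8 Hz filtered) 2-s window — the area under the rectified trace per unit
time. It is scale-equivariant, so the detection set is invariant to global
signal scaling. Windows are non-overlapping and aligned to the recording
start. The long-term trend is the arithmetic mean of the trailing
unblanked short-term values (capacity 60 at the defaults), excluding the
current window; the detector arms once one history value exists
(`min_history_windows` raises that), and a strict inequality
`st > lt·(1 + pct/100)` fires. Stimulation-blanked windows neither fire
nor enter the history. An optional refractory period suppresses fires
within a configured time of the last one. `fixed_lt` replaces the adaptive
trend with a constant — used to demonstrate that the adaptation is what
suppresses sleep detections. Whether the device's trend is a trailing or
exponentially weighted mean is not public; the trailing mean is the
simplest semantics consistent with "average of the past 2 min".

Bilateral gating pairs left and right detections whose window indices
differ by at most `coincidence_tolerance_windows` (0 = same window),
greedily in time order, consuming each unilateral detection at most once.

Detector defaults (2 s / 120 s / 63% / 2–8 Hz / bilateral) follow the
clinical programming range, with 63% chosen as the sensitive end.

## Stimulation policy

One bout per qualifying bilateral detection: 10 s (two 5-s bursts),
counted against a daily cap of 700 bouts per *local calendar day*
(midnight boundary — the natural reading of a per-day limit on a
wall-clock device). Detections during an ongoing bout are dropped, not
queued; detections with local time outside [07:00, 22:00) are ignored.
The 117 min/day budget is derived (700 × 10 s / 60), not independent; the
bout cap is primary. Charge density (0.5–1.5 µC/cm²) is carried as
metadata only — no tissue model. Blanking masks cover each bout plus an
optional guard margin and feed both epoch exclusion and the detector's
trend exclusion.

## Statistics

Pooled-variance (classic Student) two-sample t-test, two-sided — not
Welch — matching the convention for these clinical comparisons; degenerate
zero-variance inputs return t = 0 when means agree and raise otherwise.
One-way ANOVA (F = MS_between/MS_within, df (2, N−3)) followed by pairwise
pooled t-tests with a fixed Bonferroni factor of 3 (the three condition
contrasts), capped at 1. Pearson χ² on 2×2 tables without continuity
correction by default (flag available). All match textbook closed forms to
1e−9 on hand-computable inputs, and the buffet test's null rejection rate
calibrates to ≈5% over hundreds of null simulations.

Detection performance: a positive event (craving swipe / LOC bite) is a
hit if at least one gated detection falls within `match_window_s` (default
60 s, the pre-swipe window) before it; sensitivity = hits/positives.
Detections unmatched to any positive are spurious; specificity = 1 −
spurious/eligible-negative-windows, where the eligible negatives are the
control-class events (control swipes and scheduled awake snapshots).
Specificity denominator conventions vary and are rarely stated in reports;
this one is explicit and configurable. Day-level evaluations score
awake-hour detections, matching the window in which the device acts.

## Problem sizes in the test and acceptance suites

Simulated experiments are sized to what the inference needs: buffet runs
use half-hour sessions (n ≈ 15 bites/condition, the in-lab scale); null
calibration uses 10-minute sessions at higher bite rates over 500 (tests)
or 200 (script) seeds; the ambulatory contrast uses 4 awake hours with ~16
events/condition on the ventral channels; the circadian/suppression checks
use one full 24-h day. The acceptance script reports each quantity with
the n it used.

## What passing does and does not show

The generator matches the analyses' *assumptions* (stationary 1/f
background, additive narrowband bursts, sustained sleep delta, Poisson
events). Passing therefore shows the pipeline is correct and calibrated
under those assumptions, with effect sizes anchored to the reported
few-dB / ~2× scale. It does not show robustness to what real recordings
add: nonstationary backgrounds, movement and electrical artifacts,
imperfect event labels (diary/annotation error), amplitude drift,
device-specific AUC hardware details, or true between-subject variability.
Subject-level statistics from the original recordings are not reproducible
here and are not targets.

## Known limitations

- The Morlet bank at 1-Hz spacing with inclusive band edges makes the
  alpha band share its 8 Hz bin with the biomarker band; strong 2–8 Hz
  effects therefore echo faintly in alpha. This is a property of any such
  band partition, documented rather than hidden.
- The detector processes the cleaned offline signal; no streaming/online
  implementation or firmware timing model is provided.
- `exclude_stim_overlap` is the only artifact handling; no amplitude-based
  rejection is implemented.
- The long-term trend alternative (exponentially weighted mean) is not
  implemented.
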