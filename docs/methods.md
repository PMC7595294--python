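# Methods

## Signal model

The package treats an in-hive electrostatic-field (ESF) recording as a
multi-channel, dimensionless waveform sampled at audio rate (field
hardware: 44.1 kHz, four sensors per comb side, 5 cm apart). Three
behaviors are modeled, each by the simplest waveform that realizes its
published spectro-temporal signature:

* **Waggle run.** Two physical components: the body waggle, a direct
  low-frequency oscillation at the pulse rate *p* ∈ [10, 25] Hz, and the
  wing-vibration carrier at *f₀* ∈ [190, 230] Hz amplitude-modulated by
  the raised-cosine pulse train ½(1 − cos 2π p t). The rectified
  high-band envelope therefore peaks at *p*, and the raw spectrum carries
  energy in both class bands. Durations 0.5–1.5 s (one run per straight
  dance segment; the return phase separates runs).
* **Fanning.** A single tone at *f₀* ∈ [90, 120] Hz lasting > 10 s with a
  slow (< 5 %) multiplicative amplitude jitter; the envelope's
  coefficient of variation stays well below 0.2.
* **Stop signal.** A pulse shorter than 0.5 s at *f₀* ∈ [250, 400] Hz
  with harmonics at 2f₀, 3f₀, … decaying geometrically (ratio 0.5).

All events receive 10 ms tapered-cosine (Tukey) edges so their energy
stays in-band; rectangular onsets would leak broadband energy and blur
the class boundaries the detector relies on. Noise is white Gaussian per
channel. Amplitudes are arbitrary units — only the ratio to the noise
floor (SNR) is meaningful; the helper `amplitude_for_snr` sets the event
amplitude for a nominal in-band-RMS-over-noise-RMS target, treating the
event as a tone (RMS = A/√2).

What the generator does **not** emulate: hive hum and non-stationary
background (combs transmit many overlapping vibrations), amplitude decay
with bee–sensor distance, dance-direction/duration encoding of the food
site, or individual bee identity. Perfect scores on synthetic recordings
therefore demonstrate the correctness of the band/duration decision
logic, not field-grade performance on real hives, where the noise floor
is structured and events overlap.

Random schedules draw per-class Poisson counts (mean rate × duration),
uniform frequencies and durations inside each class's legal range, and
rejection-sample placements. By default every pair of events keeps
≥ 0.5 s clearance across *all* channels, so each event is individually
resolvable after cross-sensor fusion; setting `min_separation=0` allows
concurrent events on different sensors (distinct bees), which the fusion
stage will deliberately merge when their overlap is near-total —
indistinguishable, by design, from one bee seen on two sensors.

## Detector

Two STFT resolutions (Hann window, half-window hop):

* short window, default 46 ms (≈ 21.7 Hz bins): the 90–120, 190–230 and
  250–400 Hz bands, time resolution adequate for 0.1 s stop pulses;
* long window, default 0.5 s (2 Hz bins): the 10–25 Hz band and the
  segmentation of fanning bouts, whose > 10 s duration gate then makes
  noise-driven candidates essentially impossible.

A band envelope is the per-frame sum of squared magnitudes over the
band's bins. Before thresholding, envelopes are smoothed by a 50 ms
moving average (suppresses single-frame noise spikes).

**Threshold.** Per band, per recording: `exp(median + k·MAD)` of the
log-envelope, default k = 5. Working on the log scale matters: with only
1–7 bins per band the noise band-energy is gamma-distributed with a heavy
right tail, and the same robust rule on the *linear* scale fires on
roughly 1–2 % of frames (measured on pure-noise recordings), which would
swamp the precision of any counting analysis. On the log scale the tail
is light (false alarms ≈ 0 per half-hour recording) while genuine events
sit orders of magnitude above the floor — a coherent tone concentrates
its energy in one or two bins, whereas the same noise power spreads over
the whole spectrum. The rule is exactly invariant to global amplitude
rescaling, so no absolute calibration of the recording chain is assumed.

**Segmentation.** Above-threshold frames become intervals (half-open, in
seconds from recording start); gaps < 0.1 s merge; intervals < 0.05 s are
dropped. Window smear widens raw intervals by roughly one hop per side,
so candidate boundaries are pulled back in by one hop (never more than a
quarter of the span) before classification.

**Classification.** Duration gates first, then dominant per-bin band
energy, precedence stop > fanning > waggle:

* *stop*: duration < 0.5 s, stop band dominant and above threshold. The
  harmonic score (E(2f₀)+E(3f₀))/E(f₀), with f₀ the in-band peak and
  energies summed over ±1 bin, is computed always but only *enforced*
  (≥ 0.1) when `require_harmonics` is set — harmonics support the call
  but are not mandatory evidence.
* *fanning*: duration > 10 s, 90–120 Hz band dominant.
* *waggle*: duration between the stop and fanning gates, high band
  dominant and above threshold, and the pulse train verified on one of
  two paths. Default (`modulation`): band-pass 190–230 Hz, Hilbert
  envelope, FFT; the modulation peak (4–60 Hz search) must fall in
  10–25 Hz ± 2 Hz (finite segments limit rate resolution). Alternative
  (`stft`): concurrent above-threshold energy in the long-window
  10–25 Hz envelope. The modulation path is the default because the
  low-frequency component *is* physically the same pulse train as the
  carrier's AM.

Rejected candidates are simply dropped — a 5 s stable 100 Hz tone is not
fanning (duration gate) and is not reassigned to another class.

**Fusion and summary.** Same-class events on different channels merge
transitively when their temporal IoU ≥ 0.5, attributed to the channel
with the largest in-band energy. Waggle intervals closer than the run
split gap (0.3 s, about a return phase) count as one run. Reported
per-recording quantities: waggle runs/h, stop signals/h, and fanning
fraction (union of fanning intervals over duration — the fused-union
convention; a per-channel average is the obvious alternative but double
counts bouts seen by several sensors). Events touching the recording
edges are kept and flagged. Evaluation matches detections to truth
greedily by descending IoU, one-to-one within class, channel-agnostic
(fusion may reattribute channels).

All detector settings live in `DetectionParams` (YAML-roundtrippable,
printed by `show-config`); none are hard-coded. Defaults were chosen on
synthetic data as described and should be revisited for real recordings.

## Field statistics

* **Foraging span**: days between marking and the last day of
  uninterrupted daily visiting. On broken continuity the default reports
  the longest consecutive prefix from the marking day (strict mode drops
  the bee, matching protocols that require continuity). Group summaries
  use the lower-middle median for even n — the convention is stated
  because printed medians in field tables rarely say which they use.
* **Visits per hour**: min(entries, exits)/hours; the reflective sensor
  cannot resolve direction errors, so completed pairs are the
  conservative count.
* **Dose accounting**: ppb is operationalized as ng of compound per mL of
  final solution (density ≈ 1 ignored; a correction can be applied by
  scaling the concentration). Daily dose = volume × concentration /
  active bees; per-trip dose divides by trips/day; ng ↔ µl conversions
  are exact inverses. The crop-assimilation bound is linear in waiting
  time: (wait/50 min) × 8 µl × concentration. Note that at 9 ng/mL this
  gives 0.072 ng for 50 min — reports sometimes round such a figure up
  to 0.08; the package always returns the exact product.
* **Fisher exact test** (two-sided, probability-mass criterion): the
  hypergeometric support is enumerated in log-space via `gammaln`, and
  probabilities ≤ P(observed)·(1+10⁻⁷) are summed (the tolerance guards
  floating-point ties). When the observed cell is the hypergeometric
  mode every table qualifies and p = 1 exactly — which is precisely the
  situation for the 90/104 vs 128/149 homing table.
* **Kaplan-Meier / log-rank**: product-limit estimator with returns as
  events and non-returners right-censored at the 120-min waiting cutoff
  (their recorded flight time *is* 120 by construction, enforced by the
  record type). The log-rank statistic is the per-event-time
  (O−E)²/V tabulation with the hypergeometric variance, df = 1. Both are
  implemented in-repo and cross-checked against lifelines in the tests;
  Cox regression and post-hoc comparisons are out of scope — the release
  CSV retains the covariates (temperature, foraging days, experiment) so
  external statistical software can fit them.

## Problem sizes and numerical choices

Synthetic validation runs use a 4410 Hz sample rate — every signal
component, including the third stop-signal harmonic at ≤ 1200 Hz, lies
far below the 2205 Hz Nyquist, so the band structure is identical to the
44.1 kHz field configuration while recordings are ten times smaller.
Library defaults remain 44.1 kHz. The standard benchmark is ten seeded
half-hour two-channel recordings with ≈ 50 events each (50 waggle, 40
stop, 10 fanning per hour); campaign validation uses 22 days × two
colonies × 600 s sessions. All randomness flows from explicit seeds
through `numpy.random.SeedSequence` spawns, so every pipeline output is
bit-reproducible.

Known limitations: white-noise-only background; detector parameters
validated on synthetic signatures only; no real-time operation; fanning
fraction convention and the visit-pairing rule are decisions, stated
above, not measurements.
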