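# hivesignals

Detection and counting of honey-bee in-hive social signals — **waggle
runs**, **fanning**, and **stop signals** — from multi-channel
electrostatic-field (ESF) recordings, together with the field statistics
that accompany such studies: foraging spans, feeder visit rates,
insecticide dose accounting, and homing-success survival analysis.

A charged bee moving behind the hive glass induces a time-varying electric
field in membrane-less microphone capsules. The three behaviors occupy
distinct spectro-temporal niches:

| behavior    | signature                                                              |
|-------------|------------------------------------------------------------------------|
| waggle run  | rhythmic pulses: 10–25 Hz body waggle + 190–230 Hz wing vibration, AM-modulated at the waggle rate |
| fanning     | stable 90–120 Hz tone lasting > 10 s                                   |
| stop signal | pulse < 0.5 s, 250–400 Hz fundamental with pronounced harmonics        |

The detector computes short-time spectra at two resolutions (46 ms window
for the 90–400 Hz bands, 0.5 s for the 10–25 Hz band), forms per-band
energy envelopes, thresholds them adaptively at
`exp(median + k · MAD)` of the log-envelope (scale-free and robust to the
heavy-tailed band energies of broadband noise), and classifies candidate
intervals by duration gates, dominant band, harmonic score
`(E(2f₀)+E(3f₀))/E(f₀)`, and the modulation spectrum of the rectified
high-band envelope. Same-class events seen on neighboring sensors are
fused by temporal intersection-over-union. Because no raw hive recordings
of this kind are publicly deposited, the package ships a synthetic ESF
generator that renders scheduled events with these signatures into white
noise and returns exact ground-truth annotations, making the whole
pipeline testable end to end.

The statistics half implements the quantities such field studies report:
foraging span (consecutive visiting days from marking), completed feeder
visits per hour, daily dose per bee (`volume · concentration / n bees`,
with ppb read as ng/mL), dose per trip and its µl equivalent, a
crop-assimilation upper bound, exact two-sided Fisher tests from
log-factorials, and Kaplan-Meier / log-rank time-to-return analysis with
right-censoring at the 120-min waiting cutoff.

## Worked example

```bash
python analysis/01_simulate_recordings.py
python analysis/02_detect_signals.py
```

prints, for a 300 s two-channel recording with 9 scheduled events at
20 dB SNR:

```
summary: {
  "waggle_runs_per_hour": 36.0,
  "stop_signals_per_hour": 48.0,
  "fanning_fraction": 0.1116145124716554,
  "recording_duration": 300.0,
  "n_waggle_runs": 3,
  "n_stop_signals": 4,
  "n_fanning_bouts": 2
}
waggle_run   P=1.00 R=1.00 F1=1.00
fanning      P=1.00 R=1.00 F1=1.00
stop_signal  P=1.00 R=1.00 F1=1.00
```

i.e. all 3 waggle runs, 2 fanning bouts and 4 stop signals were recovered
exactly; 11.2 % of the recording is fanning time. The remaining drivers
cover campaign simulation (`03`), dose accounting (`04`) and homing
statistics (`05`); the same operations are available from the shell via
the `hivesignals` CLI (`simulate`, `detect`, `evaluate`, `foraging`,
`homing`, `campaign`, `show-config`).

```bash
python analysis/05_homing_stats.py
```

```
control: 90/104 returned (87%)
treated: 128/149 returned (86%)
Fisher exact test on [[90,14],[128,21]]: p = 1.0000
log-rank: chi2(1) = 0.01, p = 0.937
```

The return/loss table of those two groups sits exactly at the
hypergeometric mode, so the two-sided exact test gives p = 1: no
detectable difference in homing success.

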