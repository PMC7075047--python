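# startlekit

Quantifying the acoustic startle reflex in marine mammals — from raw
triaxial accelerometer and calibrated hydrophone recordings to
dose–response startle thresholds.

The acoustic startle reflex is a rapid flexor-muscle flinch triggered by
sounds with fast onsets, mediated by a short brainstem reflex arc. In
hoop-station playback experiments with trained odontocetes (bottlenose
dolphins, false killer whales), the flinch is measured with a
tag-mounted triaxial accelerometer while a hydrophone at the station
monitors received levels. `startlekit` implements the complete analysis
for such experiments, plus a synthetic-data generator so the entire
pipeline is testable without animal data.

## What it computes

**Startle-magnitude metrics** (after a 2 Hz high-pass FIR, in a 1-s
window from stimulus onset):

- *p–p VeDBA* = √(x² + y² + z²), with x, y, z the per-axis
  peak-to-peak accelerations (m s⁻²);
- *max norm jerk* = max over the window of ‖d**A**/dt‖ (m s⁻³);
- flinch latency, and no-sound control baselines from five
  pseudorandomly placed 1-s windows.

**Received levels** from calibrated recordings, SPL = |Tₓ| − Gain +
20 log₁₀(V), compensated to the animal's acoustic window by spherical
spreading (or fixed per-animal offsets), plus sound exposure levels and
synthesis of the playback stimuli (third-octave 50-ms pulses; broadband
pulses with 2/20/100-ms rise times at matched plateau RMS and SEL).
Echolocation clicks on the two monitoring hydrophones are attributed to
the stationing animal by a three-criterion rule (amplitude ratio,
off-axis waveform, time-difference-of-arrival).

**Dose–response models**: gamma GLMs (log / inverse / identity links)
for the continuous metrics and a logistic GLM for video-scored startle
occurrence, with candidate terms (received level or rise time, session,
trial or ln trial, echolocation covariates) selected by small-sample
AICc, Wald intervals, Nagelkerke pseudo-R², and t-quantile prediction
intervals on a 0.1 dB grid.

**Thresholds**: the received level at which the fitted curve first
exceeds the no-sound baseline (or the 50% point for binary responses);
rise-time thresholds where the curve drops below baseline (flagged when
extrapolated); sensation levels against audiograms; and the
threshold-versus-frequency trend.

## Worked example

```bash
python examples/dose_response_threshold.py
```

simulates three 12-trial playback sessions in which startle magnitude
grows 9.4% per dB of received level above a 2 m s⁻² movement baseline,
then runs the full analysis:

```
generator truth threshold :  139.1 dB re 1 uPa

pp_vedba:
  selected model          : log link, terms ['RL']
  e^beta(RL)              : 1.111 per dB
  no-sound baseline       :     1.99
  startle threshold       :    140.3 dB re 1 uPa

max_norm_jerk:
  selected model          : log link, terms ['RL']
  e^beta(RL)              : 1.110 per dB
  no-sound baseline       :   123.91
  startle threshold       :    140.3 dB re 1 uPa
```

The recovered per-dB multiplier (1.111) and threshold (140.3 dB) sit
close to the generator's truth (1.094, 139.1 dB), and the two
independent metrics agree — the behaviour expected of a well-calibrated
pipeline. The other scripts in `examples/` demonstrate metric
extraction, rise-time thresholds, stimulus synthesis, click attribution
and sensation levels, each printing a short explanation of its output.

A thin CLI wraps the same calls:

```bash
startlekit simulate /tmp/sess --preset bj10-vedba --seed 3
startlekit thresholds /tmp/sess --seed 3 --out /tmp/report
```

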