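"""Synthesize the playback stimuli and verify their calibration.

Builds a 50-ms third-octave noise pulse at 10 kHz and the three
broadband rise-time variants (2/20/100 ms), SEL-normalised, and checks
their levels through the calibrated SPL/SEL formulas.
"""

import numpy as np

from startlekit import HydrophoneCal, StimulusSpec, sel_of_waveform, spl_from_waveform, synth_pulse

fs = 96_000.0
# measurement chain matching the synthesis convention: digital amplitude
# 1.0 <-> 180 dB re 1 uPa, i.e. |Tx| - Gain = 180 dB
cal = HydrophoneCal({10.0: -180.0}, gain_db=0.0, fs=fs)

tone = StimulusSpec("third_octave_pulse", center_freq_khz=10.0,
                    rise_ms=1.5, fall_ms=1.5, plateau_ms=47.0, target_spl=150.0)
pulse = synth_pulse(tone, fs, seed=0)
print(f"third-octave pulse: {len(pulse) / fs * 1e3:.0f} ms, "
      f"SPL {spl_from_waveform(pulse, cal, 10.0):.1f} dB re 1 uPa (target 150.0)")

print("\nbroadband rise-time variants (SEL-normalised to 140 dB re 1 uPa^2 s):")
for rise, plateau in [(2, 136), (20, 118), (100, 38)]:
    spec = StimulusSpec("broadband_pulse", rise_ms=rise, fall_ms=rise,
                        plateau_ms=plateau)
    x = synth_pulse(spec, fs, seed=1, normalise_sel_to=140.0)
    sel = sel_of_waveform(x, cal, fs, 10.0)
    print(f"  rise {rise:3d} ms, duration {len(x) / fs * 1e3:3.0f} ms, "
          f"SEL {sel:6.1f} dB re 1 uPa^2 s")

print("\nMatching SEL across rise times means the variants differ only in")
print("onset steepness, isolating rise time as the experimental variable.")
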