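"""Sensation levels and the threshold-versus-frequency trend.

Uses the reported startle thresholds as inputs: computes threshold
differences across frequencies and scoring methods, fits the
frequency-trend gamma GLM (link chosen by AICc), and converts a
threshold to a sensation level against a masked-AEP-style audiogram.
"""

import numpy as np

from startlekit import Audiogram, frequency_trend, sensation_level
from startlekit.reference import (
    method_difference,
    pp_vedba_thresholds,
    threshold_difference,
)

print("threshold arithmetic on the reported values:")
print(f"  Boris 1 vs 25 kHz      : {threshold_difference('Boris', 1.0, 25.0):5.1f} dB")
print(f"  BJ    1 vs 32 kHz      : {threshold_difference('BJ', 1.0, 32.0):5.1f} dB")
print(f"  BJ video vs VeDBA      : {method_difference('BJ', 10.0, 'video', 'vedba'):5.1f} dB")

fit, curve, delta = frequency_trend(pp_vedba_thresholds(), f_query=(1.0, 32.0))
print(f"\nfrequency trend ({fit.spec.link} link): "
      f"fitted decrease 1 -> 32 kHz = {delta:.1f} dB")

aud = Audiogram(np.array([1.0, 10.0, 32.0]), np.array([99.0, 92.0, 86.0]),
                kind="masked_AEP")
sl = sensation_level(139.1, aud, 10.0)
print(f"\nsensation level of a 139.1 dB threshold at 10 kHz: {sl:.1f} dB")
print("(startle threshold minus the interpolated hearing threshold --")
print(" startle needs the stimulus well above what the animal can just hear)")
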