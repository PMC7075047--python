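"""Reported startle thresholds and effect sizes from a hoop-station
playback study of two bottlenose dolphins (BJ, Boris) and a false killer
whale (Kina), used as reference inputs: threshold arithmetic, the
threshold-versus-frequency trend, and truth values for the simulation
presets all start from these numbers.
"""

from __future__ import annotations

import pandas as pd

# Startle thresholds in dB re 1 uPa by animal, test frequency and
# threshold-determination method ("vedba" = p-p VeDBA curve crossing the
# no-sound baseline, "jerk" = max norm jerk ditto, "video" = 50%
# response probability from visually scored videos).
STARTLE_THRESHOLDS = pd.DataFrame(
    [
        ("BJ", 1.0, "vedba", 146.1),
        ("BJ", 10.0, "vedba", 139.1),
        ("BJ", 10.0, "jerk", 138.1),
        ("BJ", 10.0, "video", 151.4),
        ("BJ", 32.0, "vedba", 130.9),
        ("Boris", 1.0, "vedba", 150.7),
        ("Boris", 10.0, "vedba", 142.6),
        ("Boris", 25.0, "vedba", 131.5),
        ("Kina", 10.0, "vedba", 153.3),
    ],
    columns=["animal", "frequency_khz", "method", "threshold_db"],
)

# Fitted multiplicative effect sizes (per dB of received level, per ms of
# rise time, or per unit ln(trial)) with reported 95% Wald intervals.
EFFECT_SIZES = {
    "bj10_vedba_rl": {"exp_beta": 1.094, "ci": (1.076, 1.113)},
    "bj10_jerk_rl": {"exp_beta": 1.126, "ci": (1.096, 1.156)},
    "boris10_vedba_rl": {"exp_beta": 1.078, "ci": (1.058, 1.097)},
    "video_rl_odds": {"exp_beta": 1.385, "ci": (1.168, 1.837)},
    "ln_trial_habituation": {"exp_beta": 0.693, "ci": (0.571, 0.838)},
    "boris_risetime_per_ms": {"exp_beta": 0.989, "ci": (0.985, 0.994)},
}

# Identity-link rise-time slope for BJ, m s^-2 per ms.
BJ_RISETIME_SLOPE = {"beta": -0.135, "ci": (-0.244, -0.033)}

# Monitoring-hydrophone voltage sensitivity, dB re 1 V uPa^-1, at the
# calibration frequencies.
HYDROPHONE_SENSITIVITY_DB = {1.0: -211.63, 10.0: -211.55, 25.0: -211.0, 32.0: -211.3}

# Spherical-spreading compensation from the hoop hydrophone to the
# animal's acoustic window, dB, per animal and frequency band.
EAR_OFFSETS_DB = {
    ("BJ", "low"): 0.6,  # 1 & 10 kHz trials
    ("Boris", "low"): 0.7,
    ("Kina", "low"): 1.95,
    ("BJ", "high"): 1.3,  # 25 & 32 kHz trials
    ("Boris", "high"): 1.4,
    ("Kina", "high"): 1.95,
}

# Rise-time thresholds (ms) at which fitted startle magnitude drops
# below the no-sound baseline.
RISETIME_THRESHOLDS_MS = {"BJ": 220.0, "Boris": 141.0,
                          "Boris_per_session": (189.0, 94.0)}


def pp_vedba_thresholds() -> list[tuple[float, float]]:
    """The seven (frequency kHz, threshold dB) pairs from the p-p VeDBA
    method, the input to the threshold-versus-frequency trend fit."""
    df = STARTLE_THRESHOLDS[STARTLE_THRESHOLDS["method"] == "vedba"]
    return list(zip(df["frequency_khz"], df["threshold_db"]))


def threshold_difference(
    animal: str, f1: float, f2: float, method: str = "vedba"
) -> float:
    """Difference (dB) between one animal's thresholds at two
    frequencies, ``threshold(f1) - threshold(f2)``."""
    df = STARTLE_THRESHOLDS
    sel = df[(df["animal"] == animal) & (df["method"] == method)]
    t1 = sel[sel["frequency_khz"] == f1]["threshold_db"]
    t2 = sel[sel["frequency_khz"] == f2]["threshold_db"]
    if t1.empty or t2.empty:
        raise KeyError(f"no {method} threshold for {animal} at {f1} or {f2} kHz")
    return float(t1.iloc[0] - t2.iloc[0])


def method_difference(animal: str, freq: float, m1: str, m2: str) -> float:
    """Difference (dB) between two threshold-determination methods for
    the same animal and frequency, ``threshold(m1) - threshold(m2)``."""
    df = STARTLE_THRESHOLDS
    sel = df[(df["animal"] == animal) & (df["frequency_khz"] == freq)]
    t1 = sel[sel["method"] == m1]["threshold_db"]
    t2 = sel[sel["method"] == m2]["threshold_db"]
    if t1.empty or t2.empty:
        raise KeyError(f"no {m1}/{m2} thresholds for {animal} at {freq} kHz")
    return float(t1.iloc[0] - t2.iloc[0])
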