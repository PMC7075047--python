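"""Startle thresholds, rise-time thresholds, sensation levels and the
threshold-versus-frequency trend.

The startle threshold is the received level at which the fitted
dose-response curve first exceeds the no-sound-control baseline; for
binary (video-scored) responses it is the 50%-probability point.  The
rise-time threshold is the rise time at which the fitted curve drops
below the baseline, extrapolating (flagged) beyond the tested range.
Sensation level expresses a threshold relative to the subject's
audiogram, interpolated at the stimulus frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glm import FittedGlm, ModelSpec, PredictionCurve, fit_glm

__all__ = [
    "ThresholdEstimate",
    "Audiogram",
    "startle_threshold",
    "probability_threshold",
    "rise_time_threshold",
    "sensation_level",
    "frequency_trend",
]


@dataclass
class ThresholdEstimate:
    """A threshold read off a fitted dose-response curve.

    ``value`` is in dB re 1 uPa for level thresholds or ms for rise-time
    thresholds; undefined (None) when ``valid`` is False, in which case
    ``reason_invalid`` says why.  ``baseline`` is the no-sound control
    level the curve was compared against (metric units), and
    ``extrapolated`` flags a rise-time threshold beyond the tested range.
    """

    value: float | None
    baseline: float | None = None
    baseline_scope: str = "pooled"  # {"pooled", "per_session"}
    valid: bool = True
    reason_invalid: str = ""
    extrapolated: bool = False


def startle_threshold(
    curve: PredictionCurve,
    baseline: float,
    rl_significant: bool = True,
    baseline_scope: str = "pooled",
) -> ThresholdEstimate:
    """Smallest grid RL whose fitted response exceeds the no-sound
    control baseline.

    Invalid (no value) if the RL effect was not significant at 0.05, or
    if the curve never crosses the baseline within the grid.
    """
    if not rl_significant:
        return ThresholdEstimate(
            None, baseline, baseline_scope, valid=False,
            reason_invalid="RL p >= 0.05",
        )
    above = np.nonzero(curve.fitted > baseline)[0]
    if above.size == 0:
        return ThresholdEstimate(
            None, baseline, baseline_scope, valid=False,
            reason_invalid="curve never crosses baseline",
        )
    return ThresholdEstimate(float(curve.grid[above[0]]), baseline, baseline_scope)


def probability_threshold(curve: PredictionCurve) -> ThresholdEstimate:
    """First grid RL with fitted response probability >= 0.5 (for
    logistic video-score curves)."""
    f = curve.fitted
    if np.any((f < -1e-9) | (f > 1 + 1e-9)):
        raise ValueError("probability_threshold needs predictions in [0, 1]")
    if f[-1] < f[0]:
        return ThresholdEstimate(
            None, valid=False, reason_invalid="non-increasing dose-response"
        )
    above = np.nonzero(f >= 0.5)[0]
    if above.size == 0:
        return ThresholdEstimate(
            None, valid=False, reason_invalid="probability never reaches 0.5"
        )
    return ThresholdEstimate(float(curve.grid[above[0]]))


def rise_time_threshold(
    curve: PredictionCurve,
    baseline: float,
    observed_max: float | None = None,
    baseline_scope: str = "pooled",
) -> ThresholdEstimate:
    """Smallest grid rise time at which the fitted startle magnitude
    drops below the no-sound control baseline.

    The curve must be decreasing in rise time.  Values beyond
    ``observed_max`` (the largest tested rise time) are permitted --
    rise-time thresholds are routinely extrapolations -- and flagged.
    The caller bounds the grid; by convention it extends to at most five
    times the largest tested rise time.
    """
    if curve.fitted[-1] > curve.fitted[0]:
        return ThresholdEstimate(
            None, baseline, baseline_scope, valid=False,
            reason_invalid="startle magnitude increases with rise time",
        )
    below = np.nonzero(curve.fitted < baseline)[0]
    if below.size == 0:
        return ThresholdEstimate(
            None, baseline, baseline_scope, valid=False,
            reason_invalid="curve never drops below baseline within grid",
        )
    value = float(curve.grid[below[0]])
    extrap = observed_max is not None and value > observed_max
    return ThresholdEstimate(value, baseline, baseline_scope, extrapolated=extrap)


@dataclass
class Audiogram:
    """Hearing thresholds (dB re 1 uPa) at a set of frequencies (kHz).

    ``kind`` distinguishes masked AEP audiograms (elevated by ambient
    noise) from behavioural audiograms.
    """

    freqs_khz: np.ndarray
    thresholds_db: np.ndarray
    kind: str = "masked_AEP"

    def __post_init__(self) -> None:
        self.freqs_khz = np.asarray(self.freqs_khz, dtype=float)
        self.thresholds_db = np.asarray(self.thresholds_db, dtype=float)
        if self.freqs_khz.size < 2:
            raise ValueError("audiogram needs at least 2 points")
        if not np.all(np.diff(self.freqs_khz) > 0):
            raise ValueError("audiogram frequencies must be strictly increasing")
        if self.freqs_khz.size != self.thresholds_db.size:
            raise ValueError("frequency and threshold arrays differ in length")

    @classmethod
    def from_csv(cls, path, kind: str | None = None) -> "Audiogram":
        df = pd.read_csv(path)
        k = kind or (df["kind"].iloc[0] if "kind" in df else "masked_AEP")
        df = df.sort_values("freq_khz")
        return cls(df["freq_khz"].to_numpy(), df["threshold_db"].to_numpy(), k)

    def interpolate(self, freq_khz: float, axis: str = "log2") -> float:
        """Hearing threshold at ``freq_khz`` by linear interpolation,
        on a log2-frequency axis by default (audiograms are
        conventionally log-frequency; pass ``axis="linear"`` for
        interpolation linear in kHz)."""
        f0, f1 = self.freqs_khz[0], self.freqs_khz[-1]
        if not (f0 <= freq_khz <= f1):
            raise ValueError(
                f"{freq_khz} kHz outside audiogram span [{f0}, {f1}] kHz"
            )
        if axis == "log2":
            return float(
                np.interp(np.log2(freq_khz), np.log2(self.freqs_khz), self.thresholds_db)
            )
        if axis == "linear":
            return float(np.interp(freq_khz, self.freqs_khz, self.thresholds_db))
        raise ValueError(f"unknown interpolation axis {axis!r}")


def sensation_level(
    startle: ThresholdEstimate | float,
    audiogram: Audiogram,
    freq_khz: float,
    axis: str = "log2",
) -> float:
    """Startle threshold minus the interpolated hearing threshold: the
    number of dB by which the startling stimulus exceeded the subject's
    hearing threshold at that frequency."""
    value = startle.value if isinstance(startle, ThresholdEstimate) else float(startle)
    if value is None:
        raise ValueError("cannot compute sensation level for an invalid threshold")
    return value - audiogram.interpolate(freq_khz, axis=axis)


def frequency_trend(
    thresholds: list[tuple[float, float]],
    f_query: tuple[float, float] = (1.0, 32.0),
    links: tuple[str, ...] = ("log", "inverse"),
) -> tuple[FittedGlm, PredictionCurve, float]:
    """Fit the threshold-versus-frequency trend and report the fitted
    change between two query frequencies.

    A gamma GLM with frequency (kHz) as the single predictor is fitted
    under each candidate link; the lowest-AICc fit wins.  Returns
    ``(fit, curve, delta)`` where ``delta = fitted(f1) - fitted(f2)`` in
    dB.  Degenerate (constant-threshold) input yields a flat curve and
    delta 0.
    """
    if len(thresholds) < 3:
        raise ValueError("need at least 3 (frequency, threshold) pairs")
    df = pd.DataFrame(thresholds, columns=["RL", "threshold"])  # RL col = freq
    df = df.rename(columns={"RL": "frequency"})
    data = pd.DataFrame(
        {"RL": df["frequency"].to_numpy(), "threshold": df["threshold"].to_numpy()}
    )

    if np.allclose(data["threshold"], data["threshold"].iloc[0]):
        flat = float(data["threshold"].iloc[0])
        grid = np.arange(min(f_query), max(f_query) + 0.1, 0.1)
        curve = PredictionCurve(
            var="RL", grid=grid, fitted=np.full_like(grid, flat),
            interval_lo=np.full_like(grid, flat),
            interval_hi=np.full_like(grid, flat), held_at={},
        )
        return None, curve, 0.0

    best = None
    for link in links:
        spec = ModelSpec("gamma", link, "threshold", ("RL",))
        try:
            fit = fit_glm(spec, data)
        except Exception:
            continue
        if best is None or fit.aicc < best.aicc:
            best = fit
    if best is None:
        raise RuntimeError("no frequency-trend model converged")

    lo = min(min(f_query), float(data["RL"].min()))
    hi = max(max(f_query), float(data["RL"].max()))
    from .glm import predict_with_intervals

    curve = predict_with_intervals(best, {"var": "RL", "lo": lo, "hi": hi, "step": 0.1})
    f1, f2 = f_query

    def fitted_at(f: float) -> float:
        i = int(np.argmin(np.abs(curve.grid - f)))
        return float(curve.fitted[i])

    delta = fitted_at(f1) - fitted_at(f2)
    return best, curve, delta
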