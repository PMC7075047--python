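"""Triaxial accelerometer records and startle-magnitude metrics.

The startle reflex appears in accelerometer data as a brief impulsive wave
on all three axes.  Two scalar metrics summarise its magnitude within a
1-s analysis window following stimulus onset:

* **p-p VeDBA** -- the root-sum-square of the per-axis peak-to-peak
  (max - min) accelerations, in m s^-2.
* **max norm jerk** -- the window maximum of the pointwise Euclidean norm
  of the per-axis time derivatives of acceleration, in m s^-3.

Records are high-pass filtered at 2 Hz (linear-phase FIR) before metrics
are computed, removing gravity and slow body movement while preserving
flinch timing.  "No-sound control" baselines are the mean metric over
five pseudorandomly placed 1-s windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

G = 9.80665  # m s^-2 per g

__all__ = [
    "AccelRecord",
    "AnalysisWindow",
    "StartleMetrics",
    "AccelParseError",
    "read_accel",
    "highpass",
    "extract_window",
    "pp_vedba",
    "max_norm_jerk",
    "norm_jerk",
    "response_latency",
    "control_baseline",
    "startle_metrics",
]


class AccelParseError(ValueError):
    """Raised when an accelerometer CSV cannot be parsed."""


@dataclass
class AccelRecord:
    """A timestamped triaxial acceleration trace.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz (the field-standard logger samples at 320).
    ax, ay, az : ndarray
        Per-axis acceleration in m s^-2, equal length >= 2.
    t0 : float
        Record start on the session clock, seconds.
    dynamic_range : float
        Saturation level of the sensor in m s^-2 (+-6 g by default).
    resolution_bits : int
        ADC resolution; used only for provenance.
    """

    fs: float
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    t0: float = 0.0
    dynamic_range: float = 58.8
    resolution_bits: int = 16

    def __post_init__(self) -> None:
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        n = len(self.ax)
        if len(self.ay) != n or len(self.az) != n:
            raise ValueError("axes must have identical length")
        if n < 2:
            raise ValueError("record needs at least 2 samples")

    @property
    def n(self) -> int:
        return len(self.ax)

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def xyz(self) -> np.ndarray:
        """(n, 3) view of the three axes."""
        return np.column_stack([self.ax, self.ay, self.az])

    @property
    def clipped(self) -> bool:
        """True if any sample sits at the sensor's saturation level."""
        return bool((np.abs(self.xyz) >= self.dynamic_range).any())

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs


@dataclass(frozen=True)
class AnalysisWindow:
    """A fixed-duration analysis window, aligned to stimulus onset for
    stimulus trials or pseudorandomly placed for no-sound controls."""

    start: float
    duration: float = 1.0
    kind: str = "stimulus"  # {"stimulus", "control"}

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("window duration must be positive")


@dataclass
class StartleMetrics:
    """Metrics for one analysis window."""

    pp_vedba: float
    max_norm_jerk: float
    latency: float | None
    window: AnalysisWindow
    clipped: bool = False


def read_accel(
    path,
    fs: float = 320.0,
    scale_g_per_count: float | None = None,
) -> AccelRecord:
    """Read a triaxial accelerometer CSV into an :class:`AccelRecord`.

    Accepts either columns ``time_s, ax, ay, az`` or three bare numeric
    columns.  If ``scale_g_per_count`` is given the stored values are raw
    ADC counts and are converted via ``counts * scale * 9.80665`` to
    m s^-2 (e.g. 0.00006 g/count for a 16-bit +-6 g logger).  The static
    gravity offset is *not* removed here; :func:`highpass` does that.
    """
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise AccelParseError(f"cannot read {path}: {exc}") from exc

    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if {"ax", "ay", "az"}.issubset(cols):
        data = df[["ax", "ay", "az"]]
        t0 = float(df["time_s"].iloc[0]) if "time_s" in cols else 0.0
    elif df.shape[1] >= 3:
        data = df.iloc[:, :3]
        t0 = 0.0
    else:
        raise AccelParseError(f"{path}: need three numeric columns")

    arr = data.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.where(~np.isfinite(arr).all(axis=1))[0]
    if bad.size:
        raise AccelParseError(
            f"{path}: non-numeric value in data row {int(bad[0])}"
        )
    if arr.shape[0] < 2:
        raise ValueError(f"{path}: fewer than 2 samples")
    if scale_g_per_count is not None:
        arr = arr * scale_g_per_count * G
    return AccelRecord(fs=fs, ax=arr[:, 0], ay=arr[:, 1], az=arr[:, 2], t0=t0)


def design_highpass(fs: float, cutoff: float = 2.0, transition: float = 1.0) -> np.ndarray:
    """Design the windowed-sinc (Hamming) high-pass FIR used throughout.

    The order is chosen so the transition band is at most ``transition``
    Hz wide around the cutoff, which keeps flinch transients sharp while
    attenuating the DC (gravity) component by well over 40 dB.
    """
    if cutoff >= fs / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    # Hamming-window transition width ~= 3.3 / N normalised frequency.
    numtaps = int(np.ceil(3.3 * fs / transition))
    if numtaps % 2 == 0:
        numtaps += 1  # odd length -> integer group delay, type-I
    return signal.firwin(numtaps, cutoff, window="hamming", pass_zero=False, fs=fs)


def _apply_fir(x: np.ndarray, taps: np.ndarray, zero_phase: bool) -> np.ndarray:
    if zero_phase:
        # Linear-phase FIR: reflect-pad, convolve, drop the group delay.
        pad = len(taps) // 2
        xp = np.pad(x, pad, mode="reflect")
        return np.convolve(xp, taps, mode="same")[pad:-pad]
    return signal.lfilter(taps, 1.0, x)


def highpass(
    record: AccelRecord,
    cutoff: float = 2.0,
    zero_phase: bool = True,
) -> AccelRecord:
    """High-pass filter all three axes at ``cutoff`` Hz (default 2 Hz).

    Uses a linear-phase windowed-sinc FIR; with ``zero_phase=True`` (the
    default) the group delay is compensated so transient timing is
    preserved.  Gravity and slow swimming movement are removed.
    """
    taps = design_highpass(record.fs, cutoff)
    return replace(
        record,
        ax=_apply_fir(record.ax, taps, zero_phase),
        ay=_apply_fir(record.ay, taps, zero_phase),
        az=_apply_fir(record.az, taps, zero_phase),
    )


def extract_window(record: AccelRecord, window: AnalysisWindow) -> AccelRecord:
    """Return the sub-record of round(duration * fs) samples starting at
    the first sample at-or-after ``window.start`` (session clock)."""
    i0 = int(np.ceil((window.start - record.t0) * record.fs - 1e-9))
    n = int(round(window.duration * record.fs))
    if i0 < 0 or i0 + n > record.n:
        raise IndexError(
            f"window [{window.start}, {window.start + window.duration}) s "
            f"outside record of {record.duration:.3f} s"
        )
    return replace(
        record,
        ax=record.ax[i0 : i0 + n],
        ay=record.ay[i0 : i0 + n],
        az=record.az[i0 : i0 + n],
        t0=record.t0 + i0 / record.fs,
    )


def pp_vedba(segment: AccelRecord) -> float:
    """Peak-to-peak VeDBA: sqrt(x^2 + y^2 + z^2) of the per-axis
    (max - min) spans within the segment, in m s^-2.

    The per-axis peak-to-peak values are taken independently before the
    root-sum-square; the segment is assumed high-pass filtered.
    """
    spans = segment.xyz.max(axis=0) - segment.xyz.min(axis=0)
    return float(np.sqrt((spans**2).sum()))


def norm_jerk(segment: AccelRecord) -> np.ndarray:
    """Pointwise norm of the triaxial jerk d**A**/dt, in m s^-3.

    First differences scaled by the sampling rate; length n - 1.
    """
    if segment.n < 2:
        raise ValueError("need at least 2 samples to differentiate")
    j = np.diff(segment.xyz, axis=0) * segment.fs
    return np.sqrt((j**2).sum(axis=1))


def max_norm_jerk(segment: AccelRecord) -> float:
    """Window maximum of the norm jerk, in m s^-3."""
    return float(norm_jerk(segment).max())


def response_latency(
    segment: AccelRecord,
    baseline_mad: float,
    k: float = 8.0,
) -> float | None:
    """Time (s from segment start) at which the norm jerk first exceeds
    ``k`` times the baseline median absolute deviation; ``None`` if it
    never does.

    Startle onsets typically fall within 100-200 ms of stimulus onset;
    the k*MAD rule is a simple robust detector for that transient.
    """
    if baseline_mad <= 0:
        raise ValueError("baseline_mad must be positive")
    nj = norm_jerk(segment)
    above = np.nonzero(nj > k * baseline_mad)[0]
    if above.size == 0:
        return None
    return float(above[0] / segment.fs)


def _draw_nonoverlapping_starts(
    rng: np.random.Generator,
    total: float,
    duration: float,
    n_windows: int,
    max_tries: int = 10_000,
) -> list[float]:
    starts: list[float] = []
    for _ in range(max_tries):
        if len(starts) == n_windows:
            break
        s = rng.uniform(0.0, total - duration)
        if all(abs(s - t) >= duration for t in starts):
            starts.append(s)
    if len(starts) < n_windows:  # dense packing fallback: jittered slots
        slots = np.linspace(0.0, total - duration, n_windows)
        starts = list(slots)
    return sorted(starts)


def control_baseline(
    record: AccelRecord,
    n_windows: int = 5,
    duration: float = 1.0,
    seed: int | np.random.Generator = 0,
    metric: str = "pp_vedba",
) -> float:
    """No-sound control baseline: the mean metric over ``n_windows``
    non-overlapping pseudorandom windows of ``duration`` seconds.

    ``metric`` selects ``"pp_vedba"`` (m s^-2), ``"max_norm_jerk"``
    (m s^-3) or ``"jerk_mad"`` (MAD of the norm jerk, for latency
    detection).
    """
    if record.duration < n_windows * duration:
        raise ValueError(
            f"record of {record.duration:.2f} s too short for "
            f"{n_windows} x {duration} s control windows"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    funcs = {
        "pp_vedba": pp_vedba,
        "max_norm_jerk": max_norm_jerk,
        "jerk_mad": lambda seg: float(np.median(np.abs(norm_jerk(seg) - np.median(norm_jerk(seg))))),
    }
    try:
        func = funcs[metric]
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}") from None
    starts = _draw_nonoverlapping_starts(rng, record.duration, duration, n_windows)
    vals = [
        func(extract_window(record, AnalysisWindow(record.t0 + s, duration, "control")))
        for s in starts
    ]
    return float(np.mean(vals))


def startle_metrics(
    record: AccelRecord,
    window: AnalysisWindow,
    baseline_jerk_mad: float | None = None,
    k: float = 8.0,
) -> StartleMetrics:
    """Compute all startle metrics for one analysis window of an
    already high-pass-filtered record."""
    seg = extract_window(record, window)
    lat = None
    if baseline_jerk_mad is not None and baseline_jerk_mad > 0:
        lat = response_latency(seg, baseline_jerk_mad, k)
    return StartleMetrics(
        pp_vedba=pp_vedba(seg),
        max_norm_jerk=max_norm_jerk(seg),
        latency=lat,
        window=window,
        clipped=seg.clipped,
    )
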