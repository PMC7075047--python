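"""Hydrophone calibration, stimulus synthesis and click attribution.

Received levels are computed from calibrated hydrophone recordings as

    SPL = |Tx| - Gain + 20 log10(V)

with |Tx| the magnitude of the hydrophone voltage sensitivity (dB re
1 V uPa^-1), Gain the recording-chain gain in dB, and V the RMS voltage
on a linear scale.  Levels at the hydrophone are compensated to the
animal's acoustic window assuming spherical spreading, or with fixed
per-animal offsets.

Stimuli are band-limited noise pulses: 50-ms third-octave pulses for the
level experiment, and broadband pulses whose raised-cosine rise/fall
times (2, 20, 100 ms) are varied at matched plateau RMS and sound
exposure level for the rise-time experiment.

Echolocation clicks recorded on the two monitoring hydrophones are
attributed to the stationing (focal) animal only if (1) the projector
hydrophone peak exceeds the hoop peak by >= 30 dB, (2) the hoop waveform
shows off-axis character (long -10 dB duration), and (3) the arrival-time
difference matches the geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "HydrophoneCal",
    "StimulusSpec",
    "ClickEvent",
    "spl_from_waveform",
    "compensate_to_ear",
    "sel_of_waveform",
    "synth_pulse",
    "detect_clicks",
    "attribute_clicks",
]

# Amplitude 1.0 in a synthesized/recorded waveform maps to this many dB
# re 1 uPa through a unity-sensitivity chain; the convention only matters
# for round-trips between synthesis and measurement and is configurable.
DEFAULT_FULL_SCALE_DB = 180.0


@dataclass
class HydrophoneCal:
    """Hydrophone + recording-chain calibration.

    ``sensitivity_db`` maps calibration frequency (kHz) to voltage
    sensitivity in dB re 1 V uPa^-1 (negative values, e.g. -211.55 at
    10 kHz).  Lookup between calibration points is nearest-neighbour:
    the points are sparse (typically 1, 10, 25, 32 kHz).
    """

    sensitivity_db: dict[float, float]
    gain_db: float = 0.0
    fs: float = 300_000.0

    def __post_init__(self) -> None:
        if not self.sensitivity_db:
            raise ValueError("at least one calibration point required")
        for f, s in self.sensitivity_db.items():
            if not (-250.0 < s < -150.0):
                raise ValueError(
                    f"sensitivity {s} dB at {f} kHz outside plausible band"
                )

    def sensitivity_at(self, freq_khz: float) -> float:
        freqs = np.array(sorted(self.sensitivity_db))
        nearest = freqs[np.argmin(np.abs(freqs - freq_khz))]
        return self.sensitivity_db[float(nearest)]


@dataclass
class StimulusSpec:
    """Band-limited noise pulse specification.

    ``kind`` is ``"third_octave_pulse"`` (centred on ``center_freq_khz``)
    or ``"broadband_pulse"`` (band edges = -20 dB points, defaults near
    6.8 and 19 kHz).  Total duration = rise + plateau + fall.
    """

    kind: str = "third_octave_pulse"
    center_freq_khz: float = 10.0
    rise_ms: float = 1.5
    fall_ms: float = 1.5
    plateau_ms: float = 47.0
    band_edges_khz: tuple[float, float] = (6.8, 19.0)
    target_spl: float = 150.0

    def __post_init__(self) -> None:
        if self.rise_ms <= 0:
            raise ValueError("rise time must be positive")
        if not np.isfinite(self.target_spl):
            raise ValueError("target SPL must be finite")

    @property
    def total_duration_ms(self) -> float:
        return self.rise_ms + self.plateau_ms + self.fall_ms


@dataclass
class ClickEvent:
    """One echolocation click seen on the two monitoring hydrophones."""

    time_s: float
    peak_db: float
    duration_us: float
    channel: str = "hoop"  # {"hoop", "projector"}
    attribution: str | None = None  # {"FA", "OA", "ambiguous"}


def _rms_window(samples: np.ndarray, mode: str) -> float:
    """RMS of the waveform over the full duration or over the central
    90%-cumulative-energy window."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty waveform")
    e = np.cumsum(x**2)
    if e[-1] <= 0:
        raise ValueError("all-zero waveform: level undefined")
    if mode == "full":
        return float(np.sqrt(np.mean(x**2)))
    if mode == "rms_90pct_energy":
        lo = np.searchsorted(e, 0.05 * e[-1])
        hi = np.searchsorted(e, 0.95 * e[-1])
        hi = max(hi, lo + 1)
        seg = x[lo : hi + 1]
        return float(np.sqrt(np.mean(seg**2)))
    raise ValueError(f"unknown RMS window mode {mode!r}")


def spl_from_waveform(
    samples: np.ndarray,
    cal: HydrophoneCal,
    freq_khz: float = 10.0,
    window: str = "rms_90pct_energy",
) -> float:
    """Sound pressure level, dB re 1 uPa: |Tx| - Gain + 20 log10(V_rms)."""
    v = _rms_window(samples, window)
    tx = abs(cal.sensitivity_at(freq_khz))
    return tx - cal.gain_db + 20.0 * np.log10(v)


def compensate_to_ear(
    spl: float,
    d_hydrophone: float | None = None,
    d_ear: float | None = None,
    offset_db: float | None = None,
) -> float:
    """Compensate a measured SPL to the animal's acoustic window.

    Either pass the two distances (spherical spreading:
    ``spl + 20 log10(d_hydrophone / d_ear)``) or a fixed per-animal
    ``offset_db`` (e.g. +0.6 to +1.95 dB) that bypasses geometry.
    """
    if offset_db is not None:
        return spl + offset_db
    if d_hydrophone is None or d_ear is None:
        raise ValueError("need either offset_db or both distances")
    if d_hydrophone <= 0 or d_ear <= 0:
        raise ValueError("distances must be positive")
    return spl + 20.0 * np.log10(d_hydrophone / d_ear)


def sel_of_waveform(
    samples: np.ndarray,
    cal: HydrophoneCal,
    fs: float,
    freq_khz: float = 10.0,
) -> float:
    """Sound exposure level, dB re 1 uPa^2 s: the (discrete) integral of
    the squared pressure over the pulse, i.e. SPL_rms + 10 log10(T)."""
    x = np.asarray(samples, dtype=float)
    energy = float(np.sum(x**2) / fs)  # V^2 s
    if energy <= 0:
        raise ValueError("all-zero waveform: level undefined")
    tx = abs(cal.sensitivity_at(freq_khz))
    return tx - cal.gain_db + 10.0 * np.log10(energy)


def _raised_cosine_envelope(
    n: int, fs: float, rise_ms: float, plateau_ms: float, fall_ms: float
) -> np.ndarray:
    t = np.arange(n) / fs * 1e3  # ms
    env = np.ones(n)
    r, p, f = rise_ms, plateau_ms, fall_ms
    rising = t < r
    env[rising] = 0.5 * (1 - np.cos(np.pi * t[rising] / r))
    falling = t >= r + p
    tf = np.clip((t[falling] - r - p) / f, 0.0, 1.0)
    env[falling] = 0.5 * (1 + np.cos(np.pi * tf))
    return env


def synth_pulse(
    spec: StimulusSpec,
    fs: float,
    seed: int | np.random.Generator = 0,
    full_scale_db: float = DEFAULT_FULL_SCALE_DB,
    normalise_sel_to: float | None = None,
) -> np.ndarray:
    """Synthesize a band-limited noise pulse.

    White noise is band-filtered (third-octave around the centre
    frequency, or broadband with -20 dB points at ``band_edges_khz``), a
    raised-cosine rise/plateau/fall envelope is applied, and the plateau
    RMS is scaled so the pulse plays back at ``spec.target_spl`` under
    the digital full-scale convention (amplitude 1.0 <-> ``full_scale_db``
    dB re 1 uPa).  If ``normalise_sel_to`` is given (dB re 1 uPa^2 s under
    the same convention), the whole pulse is instead rescaled to that
    sound exposure level, which matches rise-time variants in energy.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nyq = fs / 2.0
    if spec.kind == "third_octave_pulse":
        fc = spec.center_freq_khz * 1e3
        lo, hi = fc * 2 ** (-1 / 6), fc * 2 ** (1 / 6)
    elif spec.kind == "broadband_pulse":
        lo, hi = (e * 1e3 for e in spec.band_edges_khz)
    else:
        raise ValueError(f"unknown stimulus kind {spec.kind!r}")
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz at or above Nyquist {nyq} Hz")

    n = int(round(spec.total_duration_ms * 1e-3 * fs))
    noise = rng.standard_normal(n + int(0.01 * fs))  # pad for filter settle
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, noise)[-n:]
    env = _raised_cosine_envelope(n, fs, spec.rise_ms, spec.plateau_ms, spec.fall_ms)
    x = x * env

    # scale the plateau RMS to the target level
    i0 = int(round(spec.rise_ms * 1e-3 * fs))
    i1 = int(round((spec.rise_ms + spec.plateau_ms) * 1e-3 * fs))
    plateau_rms = np.sqrt(np.mean(x[i0:max(i1, i0 + 1)] ** 2))
    target_amp = 10 ** ((spec.target_spl - full_scale_db) / 20.0)
    x = x * (target_amp / plateau_rms)

    if normalise_sel_to is not None:
        sel = full_scale_db + 10 * np.log10(np.sum(x**2) / fs)
        x = x * 10 ** ((normalise_sel_to - sel) / 20.0)
    return x


def _click_duration_us(
    samples: np.ndarray, peak_idx: int, fs: float, drop_db: float = 10.0
) -> float:
    """-10 dB envelope duration around a click peak, in microseconds."""
    peak = abs(samples[peak_idx])
    thr = peak * 10 ** (-drop_db / 20.0)
    span = int(2e-3 * fs)  # search +-2 ms
    lo = max(0, peak_idx - span)
    hi = min(len(samples), peak_idx + span)
    region = np.abs(samples[lo:hi]) >= thr
    idx = np.nonzero(region)[0]
    if idx.size == 0:
        return 0.0
    return float((idx[-1] - idx[0] + 1) / fs * 1e6)


def detect_clicks(
    samples: np.ndarray,
    cal: HydrophoneCal,
    fs: float,
    threshold_db: float,
    freq_khz: float = 50.0,
    dead_time_s: float = 2e-3,
    channel: str = "hoop",
) -> list[ClickEvent]:
    """Detect echolocation clicks as local amplitude peaks above a
    calibrated threshold with >= ``dead_time_s`` separation.

    Returns unattributed :class:`ClickEvent` objects with peak level
    (dB re 1 uPa, peak convention) and -10 dB duration.
    """
    x = np.asarray(samples, dtype=float)
    tx = abs(cal.sensitivity_at(freq_khz))
    thr_lin = 10 ** ((threshold_db - tx + cal.gain_db) / 20.0)
    peaks, _ = signal.find_peaks(
        np.abs(x), height=thr_lin, distance=max(1, int(dead_time_s * fs))
    )
    events = []
    for p in peaks:
        peak_db = tx - cal.gain_db + 20 * np.log10(abs(x[p]))
        events.append(
            ClickEvent(
                time_s=p / fs,
                peak_db=peak_db,
                duration_us=_click_duration_us(x, p, fs),
                channel=channel,
            )
        )
    return events


def attribute_clicks(
    hoop_events: list[ClickEvent],
    projector_events: list[ClickEvent],
    geometry: dict,
    c: float = 1500.0,
    amp_criterion_db: float = 30.0,
    offaxis_duration_us: float = 40.0,
    tdoa_tol_s: float = 2e-4,
    pairing_window_s: float = 5e-3,
) -> list[ClickEvent]:
    """Attribute clicks to the focal animal (FA) or other animals (OA).

    A hoop/projector event pair is labelled FA only if all of:

    1. the projector-hydrophone peak is >= ``amp_criterion_db`` above the
       hoop-hydrophone peak (the focal animal faces the projector);
    2. the hoop waveform has off-axis character: -10 dB duration >=
       ``offaxis_duration_us``;
    3. the observed arrival-time difference matches the one predicted
       from the geometry within ``tdoa_tol_s``.

    ``geometry`` needs ``d_focal_to_projector`` and ``d_focal_to_hoop``
    in metres.  Unpaired events are labelled ``"ambiguous"``.  Returns
    the hoop events, attributed, in time order.
    """
    try:
        d_fp = geometry["d_focal_to_projector"]
        d_fh = geometry["d_focal_to_hoop"]
    except (KeyError, TypeError):
        raise ValueError(
            "geometry must provide d_focal_to_projector and d_focal_to_hoop"
        ) from None
    predicted_tdoa = (d_fp - d_fh) / c

    proj_times = np.array([e.time_s for e in projector_events])
    out = []
    for ev in sorted(hoop_events, key=lambda e: e.time_s):
        ev = replace(ev)
        if proj_times.size == 0:
            ev.attribution = "ambiguous"
            out.append(ev)
            continue
        j = int(np.argmin(np.abs(proj_times - ev.time_s)))
        mate = projector_events[j]
        if abs(mate.time_s - ev.time_s) > pairing_window_s:
            ev.attribution = "ambiguous"
            out.append(ev)
            continue
        amp_ok = mate.peak_db >= ev.peak_db + amp_criterion_db
        offaxis_ok = ev.duration_us >= offaxis_duration_us
        tdoa_ok = abs((mate.time_s - ev.time_s) - predicted_tdoa) <= tdoa_tol_s
        ev.attribution = "FA" if (amp_ok and offaxis_ok and tdoa_ok) else "OA"
        out.append(ev)
    return out
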