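"""Calibration, level metrics, stimulus synthesis and click attribution."""

import numpy as np
import pytest

from startlekit import (
    HydrophoneCal,
    StimulusSpec,
    attribute_clicks,
    compensate_to_ear,
    detect_clicks,
    sel_of_waveform,
    spl_from_waveform,
    synth_pulse,
)
from startlekit.acoustics import ClickEvent


class TestSpl:
    def test_unit_rms_gives_sensitivity(self, cal):
        x = np.ones(1000)
        assert spl_from_waveform(x, cal, freq_khz=10.0, window="full") == pytest.approx(211.55)

    def test_doubling_amplitude_adds_6db(self, cal, rng):
        x = rng.normal(size=5000)
        s1 = spl_from_waveform(x, cal)
        s2 = spl_from_waveform(2 * x, cal)
        assert s2 - s1 == pytest.approx(20 * np.log10(2), abs=1e-9)

    def test_gain_subtracts(self, rng):
        x = rng.normal(size=5000)
        c0 = HydrophoneCal({10.0: -211.55}, gain_db=0.0)
        c20 = HydrophoneCal({10.0: -211.55}, gain_db=20.0)
        assert spl_from_waveform(x, c20) == pytest.approx(spl_from_waveform(x, c0) - 20)

    def test_all_zero_raises(self, cal):
        with pytest.raises(ValueError, match="undefined"):
            spl_from_waveform(np.zeros(100), cal)

    def test_nearest_neighbour_sensitivity(self, cal):
        assert cal.sensitivity_at(26.0) == -211.0  # nearest point is 25 kHz
        assert cal.sensitivity_at(2.0) == -211.63


class TestEarCompensation:
    def test_equal_distances_identity(self):
        assert compensate_to_ear(140.0, 1.5, 1.5) == pytest.approx(140.0)

    def test_distance_ratio(self):
        assert compensate_to_ear(140.0, 1.122, 1.0) == pytest.approx(141.0, abs=0.01)

    def test_fixed_offset_mode(self):
        assert compensate_to_ear(140.0, offset_db=1.95) == pytest.approx(141.95)

    def test_nonpositive_distance(self):
        with pytest.raises(ValueError):
            compensate_to_ear(140.0, 0.0, 1.0)


class TestSel:
    def test_one_second_pulse_equals_spl(self, cal):
        x = np.ones(96_000)  # 1 s at 96 kHz, RMS 1
        spl = spl_from_waveform(x, cal, window="full")
        sel = sel_of_waveform(x, cal, fs=96_000.0)
        assert sel == pytest.approx(spl, abs=1e-9)

    def test_duration_times_ten_adds_10db(self, cal):
        x = np.ones(9600)
        s1 = sel_of_waveform(x, cal, fs=96_000.0)
        s2 = sel_of_waveform(np.ones(96_000), cal, fs=96_000.0)
        assert s2 - s1 == pytest.approx(10.0, abs=1e-9)

    def test_risetime_variants_sel_matched(self, cal):
        """The three rise-time pulses, SEL-normalised, agree in SEL
        within 0.5 dB (direct integration)."""
        fs = 96_000.0
        specs = [
            StimulusSpec("broadband_pulse", rise_ms=2, fall_ms=2, plateau_ms=136),
            StimulusSpec("broadband_pulse", rise_ms=20, fall_ms=20, plateau_ms=118),
            StimulusSpec("broadband_pulse", rise_ms=100, fall_ms=100, plateau_ms=38),
        ]
        sels = [
            sel_of_waveform(synth_pulse(s, fs, seed=7, normalise_sel_to=140.0), cal, fs)
            for s in specs
        ]
        assert max(sels) - min(sels) < 0.5


class TestSynthPulse:
    def test_total_duration(self):
        fs = 96_000.0
        spec = StimulusSpec("broadband_pulse", rise_ms=100, fall_ms=100, plateau_ms=38)
        x = synth_pulse(spec, fs, seed=0)
        assert len(x) == int(round(0.238 * fs))

    def test_third_octave_band_energy(self):
        """>= 90% of pulse energy inside the third-octave band around
        10 kHz (periodogram integration)."""
        fs = 96_000.0
        spec = StimulusSpec("third_octave_pulse", center_freq_khz=10.0,
                            rise_ms=1.5, fall_ms=1.5, plateau_ms=47.0)
        x = synth_pulse(spec, fs, seed=1)
        freqs = np.fft.rfftfreq(len(x), 1 / fs)
        psd = np.abs(np.fft.rfft(x)) ** 2
        lo, hi = 10e3 * 2 ** (-1 / 6), 10e3 * 2 ** (1 / 6)
        inband = psd[(freqs >= lo) & (freqs <= hi)].sum()
        assert inband / psd.sum() >= 0.90

    def test_fast_rise_envelope(self):
        """A 2 ms rise reaches 90% of the plateau RMS within 3 ms."""
        fs = 96_000.0
        spec = StimulusSpec("broadband_pulse", rise_ms=2, fall_ms=2, plateau_ms=136)
        x = synth_pulse(spec, fs, seed=2)
        plateau = x[int(0.01 * fs) : int(0.1 * fs)]
        rms_plateau = np.sqrt(np.mean(plateau**2))
        early = x[int(0.003 * fs) : int(0.005 * fs)]
        assert np.sqrt(np.mean(early**2)) >= 0.9 * rms_plateau

    def test_plateau_rms_matched_across_rise_times(self):
        fs = 96_000.0
        rms = []
        for r, p in [(2, 136), (20, 118), (100, 38)]:
            spec = StimulusSpec("broadband_pulse", rise_ms=r, fall_ms=r,
                                plateau_ms=p, target_spl=150.0)
            x = synth_pulse(spec, fs, seed=3)
            i0, i1 = int(r * 1e-3 * fs), int((r + p) * 1e-3 * fs)
            rms.append(20 * np.log10(np.sqrt(np.mean(x[i0:i1] ** 2))))
        assert max(rms) - min(rms) < 0.5

    def test_band_above_nyquist_raises(self):
        spec = StimulusSpec("third_octave_pulse", center_freq_khz=32.0)
        with pytest.raises(ValueError, match="Nyquist"):
            synth_pulse(spec, fs=48_000.0, seed=0)


def _click_train(fs, times, amps, sigma_s=10e-6):
    total = int((max(times) + 0.01) * fs)
    x = np.zeros(total)
    half = int(6 * sigma_s * fs)
    t = np.arange(-half, half + 1) / fs
    shape = np.exp(-(t**2) / (2 * sigma_s**2)) * np.cos(2 * np.pi * 50e3 * t)
    for tt, a in zip(times, amps):
        i = int(tt * fs)
        x[i : i + len(shape)] += a * shape[: len(x) - i]
    return x


class TestDetectClicks:
    FS = 400_000.0

    def test_silence_empty(self, cal):
        assert detect_clicks(np.zeros(1000), cal, self.FS, threshold_db=120) == []

    def test_known_times_recovered(self, cal, rng):
        times = 0.005 + 0.005 * np.arange(10)
        x = _click_train(self.FS, times, np.full(10, 1e-3))
        x += rng.normal(0, 1e-6, len(x))
        events = detect_clicks(x, cal, self.FS, threshold_db=140)
        assert len(events) == 10
        got = np.array([e.time_s for e in events])
        assert np.all(np.abs(np.sort(got) - times) < 0.5e-3)

    def test_dead_time_merges_close_clicks(self, cal):
        x = _click_train(self.FS, [0.005, 0.006], [1e-3, 0.8e-3])
        events = detect_clicks(x, cal, self.FS, threshold_db=140)
        assert len(events) == 1


class TestAttributeClicks:
    GEOM = {"d_focal_to_projector": 1.5, "d_focal_to_hoop": 0.3}

    @staticmethod
    def _pair(amp_diff_db=35.0, tdoa_err_s=0.0, hoop_dur_us=80.0):
        tdoa = (1.5 - 0.3) / 1500.0
        hoop = ClickEvent(time_s=0.01, peak_db=150.0, duration_us=hoop_dur_us)
        proj = ClickEvent(time_s=0.01 + tdoa + tdoa_err_s,
                          peak_db=150.0 + amp_diff_db, duration_us=25.0,
                          channel="projector")
        return [hoop], [proj]

    def test_focal_click_all_criteria(self):
        hoop, proj = self._pair()
        out = attribute_clicks(hoop, proj, self.GEOM)
        assert out[0].attribution == "FA"

    def test_amplitude_criterion_fails(self):
        hoop, proj = self._pair(amp_diff_db=20.0)
        assert attribute_clicks(hoop, proj, self.GEOM)[0].attribution == "OA"

    def test_tdoa_criterion_fails(self):
        hoop, proj = self._pair(tdoa_err_s=2e-3)
        assert attribute_clicks(hoop, proj, self.GEOM)[0].attribution == "OA"

    def test_offaxis_criterion_fails(self):
        hoop, proj = self._pair(hoop_dur_us=20.0)
        assert attribute_clicks(hoop, proj, self.GEOM)[0].attribution == "OA"

    def test_unmatched_is_ambiguous(self):
        hoop, _ = self._pair()
        assert attribute_clicks(hoop, [], self.GEOM)[0].attribution == "ambiguous"

    def test_missing_geometry(self):
        hoop, proj = self._pair()
        with pytest.raises(ValueError, match="geometry"):
            attribute_clicks(hoop, proj, {})

    def test_order_independent(self, rng):
        hoops, projs = [], []
        for i in range(5):
            h, p = self._pair(amp_diff_db=35 if i % 2 else 10)
            h[0].time_s += i * 0.1
            p[0].time_s += i * 0.1
            hoops += h
            projs += p
        a = attribute_clicks(hoops, projs, self.GEOM)
        order = rng.permutation(5)
        b = attribute_clicks([hoops[i] for i in order], [projs[i] for i in order], self.GEOM)
        assert [e.attribution for e in a] == [e.attribution for e in b]
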