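"""Component quantification: LRP algebra, fractional-area latency, peaks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gonogo_erp.components import (
    ComponentSpec, LrpWaveform, UndefinedLatencyError, derive_lrp,
    fractional_area_latency, lowpass_lrp, mean_amplitude, peak_measure,
)
from gonogo_erp.preprocess import ErpWaveform


def _erp(values_by_channel, time_ms, **kw):
    channels = list(values_by_channel)
    values = np.vstack([values_by_channel[c] for c in channels])
    return ErpWaveform(values=values, time_ms=np.asarray(time_ms, float),
                       channels=channels, zero_event="target", n_trials=kw.pop("n_trials", 10),
                       condition=kw)


class TestMeanAmplitude:
    def test_constant_waveform(self):
        t = np.arange(0, 600, 2.0)
        erp = _erp({"Cz": np.full_like(t, -5.0)}, t)
        assert mean_amplitude(erp, "Cz", (100, 500)) == pytest.approx(-5.0)

    def test_linear_ramp_reads_midpoint(self):
        t = np.arange(0.0, 201.0)
        erp = _erp({"Cz": -10.0 * t / 200.0}, t)
        assert mean_amplitude(erp, "Cz", (0, 200)) == pytest.approx(-5.0)

    def test_window_outside_epoch_errors(self):
        t = np.arange(0.0, 100.0)
        erp = _erp({"Cz": t}, t)
        with pytest.raises(ValueError, match="outside"):
            mean_amplitude(erp, "Cz", (50, 300))


class TestPeak:
    def test_gaussian_bump_amplitude_and_latency(self):
        t = np.arange(0.0, 600.0)
        wave = 10.0 * np.exp(-0.5 * ((t - 350.0) / 40.0) ** 2)
        erp = _erp({"Pz": wave}, t)
        amp, lat = peak_measure(erp, "Pz", (200, 500), "positive")
        assert amp == pytest.approx(10.0, abs=1e-6)
        assert lat == pytest.approx(350.0)

    def test_monotone_waveform_peaks_at_window_boundary(self):
        t = np.arange(0.0, 600.0)
        erp = _erp({"Pz": t / 100.0}, t)
        amp, lat = peak_measure(erp, "Pz", (200, 500), "positive")
        assert lat == pytest.approx(500.0)

    def test_tie_broken_by_earliest(self):
        t = np.arange(0.0, 600.0)
        wave = np.zeros_like(t)
        wave[300] = wave[400] = 7.0
        erp = _erp({"Pz": wave}, t)
        _, lat = peak_measure(erp, "Pz", (200, 500), "positive")
        assert lat == pytest.approx(300.0)

    def test_negative_polarity(self):
        t = np.arange(0.0, 600.0)
        wave = -3.0 * np.exp(-0.5 * ((t - 250.0) / 30.0) ** 2)
        erp = _erp({"Cz": wave}, t)
        amp, lat = peak_measure(erp, "Cz", (100, 500), "negative")
        assert amp == pytest.approx(-3.0, abs=1e-6)
        assert lat == pytest.approx(250.0)


def _hand_waves(c3_l, c4_l, c3_r, c4_r, t):
    left = _erp({"C3": c3_l, "C4": c4_l}, t, hand="L")
    right = _erp({"C3": c3_r, "C4": c4_r}, t, hand="R")
    return {"L": left, "R": right}


class TestLrpDerivation:
    t = np.arange(0.0, 10.0)

    def test_double_subtraction_arithmetic(self):
        z = np.zeros_like(self.t)
        waves = _hand_waves(c3_l=z + 3.0, c4_l=z, c3_r=z - 5.0, c4_r=z, t=self.t)
        # (C4-C3)_L = -3, (C3-C4)_R = -5 -> LRP = -4
        lrp = derive_lrp(waves)
        assert np.allclose(lrp.values, -4.0)

    def test_hand_invariant_activity_cancels(self):
        # activity that does not depend on the responding hand (same C3
        # and C4 waveforms for both hands) carries no lateralization
        a = np.sin(self.t)
        b = np.cos(self.t)
        waves = _hand_waves(c3_l=a, c4_l=b, c3_r=a, c4_r=b, t=self.t)
        lrp = derive_lrp(waves)
        assert np.allclose(lrp.values, 0.0, atol=1e-12)

    def test_swapping_channel_labels_flips_sign(self):
        rngv = np.random.default_rng(1)
        c3l, c4l, c3r, c4r = rngv.normal(size=(4, len(self.t)))
        lrp = derive_lrp(_hand_waves(c3l, c4l, c3r, c4r, self.t))
        flipped = derive_lrp(_hand_waves(c4l, c3l, c4r, c3r, self.t))
        assert np.allclose(lrp.values, -flipped.values)

    def test_mismatched_time_bases_error(self):
        z = np.zeros(10)
        left = _erp({"C3": z, "C4": z}, np.arange(10.0))
        right = _erp({"C3": z, "C4": z}, np.arange(10.0) + 5.0)
        with pytest.raises(ValueError, match="time base"):
            derive_lrp({"L": left, "R": right})


class TestLrpLowpass:
    fs = 256.0

    def _lrp(self, wave):
        t = np.arange(len(wave)) / self.fs * 1000.0
        return LrpWaveform(values=wave, time_ms=t, zero_event="target")

    def test_slow_component_preserved(self):
        t = np.arange(1024) / self.fs
        lrp = self._lrp(np.sin(2 * np.pi * 5 * t))
        out = lowpass_lrp(lrp, 30.0)
        mid = slice(256, 768)
        assert np.abs(out.values[mid]).max() == pytest.approx(1.0, rel=0.05)

    def test_fast_component_attenuated(self):
        t = np.arange(1024) / self.fs
        lrp = self._lrp(np.sin(2 * np.pi * 60 * t))
        out = lowpass_lrp(lrp, 30.0)
        assert np.abs(out.values[256:768]).max() < 0.1

    def test_peak_latency_unchanged(self):
        t = np.arange(512) / self.fs * 1000.0
        wave = -np.exp(-0.5 * ((t - 800.0) / 80.0) ** 2)
        lrp = self._lrp(wave)
        out = lowpass_lrp(lrp, 30.0)
        assert abs(t[np.argmin(out.values)] - t[np.argmin(wave)]) \
            <= 1000.0 / self.fs

    def test_cutoff_beyond_nyquist_rejected(self):
        lrp = self._lrp(np.zeros(128))
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_lrp(lrp, 200.0)


class TestFractionalAreaLatency:
    """Rectangular-pulse fixture: -4 uV spanning 200-400 ms inside the
    100-600 ms window.  Threshold = mean = -1.6 uV; suprathreshold
    deviation 2.4 uV over 200 ms; total area 480 uV*ms; the 25% point
    falls 50 ms into the pulse, at 250 ms."""

    t = np.arange(0.0, 700.0, 0.25)

    def _pulse(self):
        w = np.zeros_like(self.t)
        w[(self.t >= 200.0) & (self.t < 400.0)] = -4.0
        return w

    def test_rectangular_pulse_closed_form(self):
        lat = fractional_area_latency(self.t, self._pulse(), (100, 600),
                                      0.25, "negative")
        assert lat == pytest.approx(250.0, abs=0.5)

    def test_fraction_limits_approach_pulse_edges(self):
        w = self._pulse()
        early = fractional_area_latency(self.t, w, (100, 600), 1e-4, "negative")
        late = fractional_area_latency(self.t, w, (100, 600), 1 - 1e-4, "negative")
        assert early == pytest.approx(200.0, abs=1.0)
        assert late == pytest.approx(400.0, abs=1.0)

    @settings(max_examples=30, deadline=None)
    @given(f1=st.floats(0.05, 0.95), f2=st.floats(0.05, 0.95),
           seed=st.integers(0, 1000))
    def test_latency_is_monotone_in_fraction(self, f1, f2, seed):
        rngv = np.random.default_rng(seed)
        t = np.arange(0.0, 700.0, 2.0)
        w = rngv.normal(0, 1, size=len(t))
        lo, hi = sorted((f1, f2))
        a = fractional_area_latency(t, w, (100, 600), lo, "negative")
        b = fractional_area_latency(t, w, (100, 600), hi, "negative")
        assert a <= b + 1e-9

    def test_scale_invariance_and_shift_equivariance(self):
        w = self._pulse()
        base = fractional_area_latency(self.t, w, (100, 600), 0.25, "negative")
        scaled = fractional_area_latency(self.t, 7.3 * w, (100, 600), 0.25,
                                         "negative")
        assert scaled == pytest.approx(base, abs=1e-9)
        shifted = fractional_area_latency(self.t + 40.0, w,
                                          (140, 640), 0.25, "negative")
        assert shifted == pytest.approx(base + 40.0, abs=1e-9)

    def test_no_suprathreshold_area_raises(self):
        w = np.zeros_like(self.t)
        with pytest.raises(UndefinedLatencyError):
            fractional_area_latency(self.t, w, (100, 600), 0.25, "negative")

    def test_positive_polarity_mirrors_negative(self):
        w = -self._pulse()
        lat = fractional_area_latency(self.t, w, (100, 600), 0.25, "positive")
        assert lat == pytest.approx(250.0, abs=0.5)

    def test_zero_reference_convention(self):
        # relative to zero the threshold is 0, so all of the pulse counts:
        # 25% of 800 uV*ms accumulates 50 ms into the pulse as well
        w = self._pulse()
        lat = fractional_area_latency(self.t, w, (100, 600), 0.25, "negative",
                                      area_reference="zero")
        assert lat == pytest.approx(250.0, abs=0.5)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            fractional_area_latency(self.t, self._pulse(), (100, 600), 0.0)


class TestComponentSpec:
    def test_fraction_only_for_latency_statistic(self):
        with pytest.raises(ValueError, match="fraction"):
            ComponentSpec("CNV", "Cz", (1300, 1500), (-700, -500),
                          "negative", "mean_amplitude", fraction=0.25)
        with pytest.raises(ValueError, match="fraction"):
            ComponentSpec("tLRP", None, (100, 600), (-200, 0),
                          "negative", "fractional_area_latency")

    def test_measure_all_shapes(self):
        t = np.arange(-300.0, 800.0)
        from gonogo_erp.components import measure_all
        cells = {}
        for cue in ("directional", "nondirectional"):
            for hand in ("L", "R"):
                wave = 8.0 * np.exp(-0.5 * ((t - 350.0) / 45.0) ** 2)
                cells[(cue, hand)] = _erp({"Pz": wave}, t)
        lrp = {}
        for cue in ("directional", "nondirectional"):
            w = np.zeros_like(t)
            w[(t >= 250) & (t < 450)] = -3.0
            lrp[(cue,)] = LrpWaveform(values=w, time_ms=t, zero_event="target")
        specs = [
            ComponentSpec("P300", "Pz", (200, 500), (-200, 0), "positive",
                          "peak"),
            ComponentSpec("tLRP", None, (100, 600), (-200, 0), "negative",
                          "fractional_area_latency", 0.25),
        ]
        table = measure_all({"P300": cells, "tLRP": lrp}, specs,
                            subject="s0", stimulation="sham")
        # P300 yields amp+lat per cue x hand (8 rows), tLRP one per cue (2)
        assert len(table) == 10
        assert set(table.measure) == {"p300_amp", "p300_lat", "tlrp_onset"}
        assert (table.loc[table.measure == "tlrp_onset", "hand"]
                == "collapsed").all()

    def test_unresolvable_spec_errors(self):
        from gonogo_erp.components import measure_all
        spec = ComponentSpec("CNV", "Cz", (1300, 1500), (-700, -500),
                             "negative", "mean_amplitude")
        with pytest.raises(ValueError, match="CNV"):
            measure_all({}, [spec], "s0", "sham")
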