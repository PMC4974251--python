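"""Signal chain: referencing, filtering, epoching, baselining, rejection."""

import numpy as np
import pandas as pd
import pytest

from gonogo_erp.io import ContinuousRecording, AVG_MASTOID
from gonogo_erp.montage import Montage, compact_montage
from gonogo_erp.preprocess import (
    average_condition, baseline, behavioral_measures, extract_epochs,
    filter_recording, parse_trials, reject_artifacts, rereference_mastoids,
)
from gonogo_erp.simulate import inject_artifacts

FS = 256.0


def _sine_recording(freqs_amps, dur_s=70.0, fs=FS):
    """Multi-channel recording of summed sinusoids (short enough that the
    filter stage takes its documented detrend + low-pass fallback)."""
    mont = compact_montage()
    t = np.arange(int(dur_s * fs)) / fs
    wave = np.zeros_like(t)
    for f, a in freqs_amps:
        wave = wave + a * np.sin(2 * np.pi * f * t)
    data = np.tile(wave, (len(mont.channels), 1))
    events = pd.DataFrame({"onset_ms": [1000.0], "code": ["FIX"]})
    return ContinuousRecording(data=data, fs=fs, montage=mont, events=events)


class TestRereference:
    def test_mastoid_mean_is_zero_after(self, noisy_recording):
        out = rereference_mastoids(noisy_recording)
        m = (out.channel("M1") + out.channel("M2")) / 2
        assert np.allclose(m, 0.0, atol=1e-12)
        assert out.reference_state == AVG_MASTOID

    def test_rereferencing_twice_rejected(self, noisy_recording):
        once = rereference_mastoids(noisy_recording)
        with pytest.raises(ValueError, match="already referenced"):
            rereference_mastoids(once)

    def test_common_mode_rejection(self, noisy_recording):
        shifted = noisy_recording.copy_with(data=noisy_recording.data + 42.0)
        a = rereference_mastoids(noisy_recording)
        b = rereference_mastoids(shifted)
        assert np.allclose(a.data, b.data, atol=1e-9)


class TestFilter:
    def test_line_frequency_notched_at_least_20db(self):
        rec = _sine_recording([(50.0, 10.0)])
        out = filter_recording(rec)
        mid = slice(int(10 * FS), int(60 * FS))
        att = np.abs(out.data[0, mid]).max() / 10.0
        assert att < 0.1  # >= 20 dB

    def test_passband_tone_preserved_without_phase_shift(self):
        rec = _sine_recording([(10.0, 5.0)])
        out = filter_recording(rec)
        mid = slice(int(10 * FS), int(60 * FS))
        amp = np.abs(out.data[0, mid]).max()
        assert amp == pytest.approx(5.0, rel=0.05)
        # zero phase: cross-correlation peak at lag 0 (< 1 sample shift)
        x = rec.data[0, mid] - rec.data[0, mid].mean()
        y = out.data[0, mid] - out.data[0, mid].mean()
        lags = [np.dot(np.roll(x, k), y) for k in (-1, 0, 1)]
        assert np.argmax(lags) == 1

    def test_dc_removed(self):
        rec = _sine_recording([])
        rec = rec.copy_with(data=np.full_like(rec.data, 7.0))
        out = filter_recording(rec)
        mid = slice(int(10 * FS), int(60 * FS))
        assert np.abs(out.data[:, mid]).max() < 0.2

    def test_band_edges_validated(self, noisy_recording):
        with pytest.raises(ValueError, match="Nyquist"):
            filter_recording(noisy_recording, band=(0.02, 200.0))

    def test_designed_band_pass_frequency_response(self):
        """Oracle on the designed filter itself: unity in the passband,
        3 dB at the corners, strong attenuation beyond."""
        from scipy import signal as sps
        sos = sps.butter(4, [0.02, 30.0], btype="bandpass", fs=FS,
                         output="sos")
        freqs = [0.02, 1.0, 10.0, 30.0, 50.0]
        _, h = sps.sosfreqz(sos, worN=freqs, fs=FS)
        gain = np.abs(h) ** 2  # forward-backward application
        assert gain[1] == pytest.approx(1.0, abs=0.01)
        assert gain[2] == pytest.approx(1.0, abs=0.01)
        assert gain[0] == pytest.approx(0.5, abs=0.05)
        assert gain[3] == pytest.approx(0.5, abs=0.05)
        assert gain[4] < 0.1  # >= 20 dB down at the line frequency
        b, a = sps.iirnotch(50.0, 30.0, fs=FS)
        _, hn = sps.freqz(b, a, worN=[50.0, 10.0], fs=FS)
        assert np.abs(hn[0]) ** 2 < 1e-4
        assert np.abs(hn[1]) ** 2 == pytest.approx(1.0, abs=0.02)


class TestEpochs:
    def test_sample_count_follows_half_open_convention(self, noiseless_recording):
        ep = extract_epochs(noiseless_recording, "target", -500.0, 1000.0)
        assert ep.data.shape[2] == 384  # 1500 ms at 256 Hz
        assert ep.time_ms[0] == pytest.approx(-500.0, abs=1000 / FS)
        assert 0.0 in ep.time_ms

    def test_response_locked_zero_aligns_to_target_plus_rt(self, noiseless_recording):
        ep = extract_epochs(noiseless_recording, "response", -200.0, 200.0)
        meta = ep.trial_meta
        # zero sample of each epoch must equal the recording at the
        # response's onset sample
        i0 = int(np.where(np.isclose(ep.time_ms, 0.0))[0][0])
        for k in range(min(5, ep.n_trials)):
            s = noiseless_recording.sample_of(meta.response_onset_ms.iloc[k])
            assert np.allclose(ep.data[k, :, i0],
                               noiseless_recording.data[:, s])

    def test_trials_without_anchor_are_excluded(self, noiseless_recording):
        ep = extract_epochs(noiseless_recording, "response", -100.0, 100.0)
        assert (ep.trial_meta.target_type == "go").all()
        full = parse_trials(noiseless_recording.events)
        assert ep.n_trials == int((full.target_type == "go").sum())

    def test_missing_anchor_code_errors(self, noiseless_recording):
        with pytest.raises(ValueError, match="zero_event"):
            extract_epochs(noiseless_recording, "blink", -100.0, 100.0)


class TestBaseline:
    def test_baselined_interval_mean_is_zero_and_idempotent(self, noisy_recording):
        ep = extract_epochs(noisy_recording, "target", -300.0, 500.0)
        b1 = baseline(ep, (-200.0, 0.0))
        mask = (b1.time_ms >= -200) & (b1.time_ms < 0)
        assert np.allclose(b1.data[:, :, mask].mean(axis=2), 0.0, atol=1e-10)
        b2 = baseline(b1, (-200.0, 0.0))
        assert np.allclose(b1.data, b2.data, atol=1e-10)

    def test_linear_ramp_closed_form(self):
        # ramp a*t + b with baseline [-200, 0): subtracted mean is the
        # ramp's mean over the interval midpoint => output a*t + a*100
        mont = compact_montage()
        fs = 1000.0
        t = np.arange(-300, 300)  # ms grid at 1 kHz
        a, b = 0.05, 3.0
        data = np.tile(a * t + b, (len(mont.channels), 1))[None, :, :]
        from gonogo_erp.preprocess import EpochSet
        ep = EpochSet(data=data.astype(float), fs=fs, time_ms=t.astype(float),
                      zero_event="target", montage=mont,
                      trial_meta=pd.DataFrame([{"trial": 0}]))
        out = baseline(ep, (-200.0, 0.0))
        # mean of a*t over [-200, -1] sample grid = a * (-100.5)
        expected = a * t + a * 100.5
        assert np.allclose(out.data[0, 0], expected, atol=1e-9)

    def test_interval_outside_epoch_errors(self, noisy_recording):
        ep = extract_epochs(noisy_recording, "target", -100.0, 300.0)
        with pytest.raises(ValueError, match="no samples"):
            baseline(ep, (-900.0, -800.0))


class TestRejection:
    def test_known_contamination_is_masked_exactly(self, small_task,
                                                   noiseless_params):
        from gonogo_erp.task import make_schedule
        from gonogo_erp.simulate import simulate_subject
        sched = make_schedule(small_task, seed=9)
        rec = simulate_subject(sched, noiseless_params,
                               montage=compact_montage(), fs=FS, seed=9)
        targets = parse_trials(rec.events).target_onset_ms.to_numpy()
        spiked_trials = [3, 7, 20, 33, 48]
        rec2 = inject_artifacts(rec, [targets[i] + 100 for i in spiked_trials],
                                amplitude=500.0)
        ep = extract_epochs(rec2, "target", -300.0, 800.0)
        ep, flagged = reject_artifacts(ep, abs_threshold=100.0)
        assert sorted(np.where(ep.reject_mask)[0]) == spiked_trials
        assert not flagged

    def test_infinite_threshold_rejects_nothing(self, noisy_recording):
        ep = extract_epochs(noisy_recording, "target", -300.0, 800.0)
        ep, _ = reject_artifacts(ep, abs_threshold=np.inf)
        assert not ep.reject_mask.any()

    def test_mastoids_ignored_by_scalp_threshold(self, noiseless_recording):
        ep = extract_epochs(noiseless_recording, "target", -100.0, 100.0)
        data = ep.data.copy()
        data[:, ep.montage.index("M1"), :] = 500.0
        ep = ep.copy_with(data=data)
        ep, _ = reject_artifacts(ep, abs_threshold=100.0)
        assert not ep.reject_mask.any()


class TestAveraging:
    def test_average_of_identical_trials_equals_each(self, noiseless_recording):
        ep = extract_epochs(noiseless_recording, "cue", -700.0, 0.0)
        # pre-target segments of same-cue trials are identical (noiseless)
        avg = average_condition(ep, by=["cue"], go_only=False)
        key = ("directional",)
        sel = ep.trial_meta.cue == "directional"
        first = np.where(sel)[0][0]
        assert np.allclose(avg[key].values, ep.data[first], atol=1e-9)

    def test_noise_average_rms_shrinks_like_sqrt_n(self, rng):
        mont = compact_montage()
        n_tr, n_t = 64, 100
        data = rng.normal(0, 1, size=(n_tr, len(mont.channels), n_t))
        from gonogo_erp.preprocess import EpochSet
        meta = pd.DataFrame({"trial": range(n_tr),
                             "cue": "directional",
                             "target_type": "go", "correct": True})
        ep = EpochSet(data=data, fs=FS, time_ms=np.arange(n_t, dtype=float),
                      zero_event="target", montage=mont, trial_meta=meta)
        avg = average_condition(ep, by=["cue"])[("directional",)]
        rms = np.sqrt((avg.values**2).mean())
        assert rms == pytest.approx(1.0 / np.sqrt(n_tr), rel=0.3)

    def test_cells_contain_only_matching_trials(self, noiseless_recording):
        ep = extract_epochs(noiseless_recording, "target", -200.0, 500.0)
        avg = average_condition(ep, by=["cue", "target_dir"])
        meta = ep.trial_meta
        key = ("directional", "L")
        n = int(((meta.cue == "directional") & (meta.target_dir == "L")
                 & (meta.target_type == "go") & meta.correct).sum())
        assert avg[key].n_trials == n

    def test_requested_empty_cell_errors(self, noiseless_recording):
        ep = extract_epochs(noiseless_recording, "target", -200.0, 500.0)
        with pytest.raises(ValueError, match="empty condition cell"):
            average_condition(ep, by=["cue"], cells=[("sideways",)])


class TestBehaviour:
    def test_known_rts_give_exact_cell_means(self):
        meta = pd.DataFrame([
            dict(cue="directional", target_type="go", target_dir="L",
                 hand="L", rt_ms=rt, correct=True)
            for rt in (300.0, 400.0, 500.0)
        ] + [
            dict(cue="directional", target_type="go", target_dir="R",
                 hand="R", rt_ms=350.0, correct=True),
            dict(cue="directional", target_type="go", target_dir="R",
                 hand="none", rt_ms=np.nan, correct=False),
            dict(cue="directional", target_type="nogo", target_dir="none",
                 hand="none", rt_ms=np.nan, correct=True),
        ])
        m = behavioral_measures(meta, "s0", "sham")
        rt_l = m[(m.measure == "rt") & (m.hand == "L")].value.iloc[0]
        assert rt_l == pytest.approx(400.0)
        err = m[m.measure == "go_error_rate"].value.iloc[0]
        assert err == pytest.approx(1 / 5)
        fa = m[m.measure == "false_alarm_rate"].value.iloc[0]
        assert fa == pytest.approx(0.0)

    def test_linearity_mean_amplitude_commutes_with_averaging(
            self, noisy_recording):
        """Measuring the average equals averaging per-trial measures."""
        from gonogo_erp.components import mean_amplitude
        ep = extract_epochs(noisy_recording, "target", -300.0, 500.0)
        ep = baseline(ep, (-200.0, 0.0))
        avg = average_condition(ep, by=["cue"])
        key = ("directional",)
        erp = avg[key]
        pooled = mean_amplitude(erp, "Cz", (100.0, 300.0))
        meta = ep.trial_meta
        keep = ((meta.cue == "directional") & (meta.target_type == "go")
                & meta.correct).to_numpy()
        ci = ep.montage.index("Cz")
        mask = (ep.time_ms >= 100.0 - 1e-9) & (ep.time_ms <= 300.0 + 1e-9)
        per_trial = ep.data[keep][:, ci, :][:, mask].mean(axis=1)
        assert pooled == pytest.approx(per_trial.mean(), abs=1e-9)


def test_filtering_is_local_so_it_commutes_with_windowing():
    """Filtering the whole recording vs filtering a long surrounding
    segment yields the same interior samples (edge effects decay), which
    is what makes filter-then-epoch equivalent to epoching with context
    and filtering afterwards."""
    from gonogo_erp.simulate import one_over_f_noise
    fs = 128.0
    mont = compact_montage()
    rng = np.random.default_rng(3)
    n = int(1200 * fs)
    data = one_over_f_noise(rng, 2, n, fs, rms=10.0)
    data = np.vstack([data, np.zeros((len(mont.channels) - 2, n))])
    events = pd.DataFrame({"onset_ms": [1000.0], "code": ["FIX"]})
    rec = ContinuousRecording(data=data, fs=fs, montage=mont, events=events)
    whole = filter_recording(rec)
    lo, hi = int(50 * fs), int(1150 * fs)
    seg = rec.copy_with(data=rec.data[:, lo:hi], events=events)
    seg_f = filter_recording(seg)
    t0 = (hi - lo) // 2
    inner = slice(t0 - 128, t0 + 128)
    a = whole.data[0, lo:hi][inner]
    b = seg_f.data[0, inner]
    assert np.allclose(a, b, atol=0.03 * np.abs(a).max())
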