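"""Preprocessing chain: resample, filters, CAR, epoching, rejection, cleaning."""

import numpy as np
import pytest
from scipy import signal as sp_signal

from amyeeg.montage import channel_index
from amyeeg.preprocess import (
    EpochSet,
    PreprocessConfig,
    bandpass_and_notch,
    epoch,
    preprocess_recording,
    rereference_car,
    reject_bad_epochs,
    remove_ocular_emg,
    resample,
)
from amyeeg.recording import Recording


def _sine_recording(freq, fs=200.0, duration=20.0, amplitude=10.0):
    t = np.arange(int(duration * fs)) / fs
    data = np.tile(amplitude * np.sin(2 * np.pi * freq * t), (19, 1))
    return Recording("sine", fs, data)


def _peak_freq(x, fs):
    f, p = sp_signal.periodogram(x, fs=fs)
    return f[np.argmax(p)]


class TestResample:
    def test_sine_frequency_and_amplitude_preserved(self):
        rec = resample(_sine_recording(10.0, fs=200.0), 250.0)
        assert rec.fs == 250.0
        assert _peak_freq(rec.data[0], 250.0) == pytest.approx(10.0, abs=0.1)
        mid = rec.data[0][500:-500]  # skip filter edges
        assert np.max(np.abs(mid)) == pytest.approx(10.0, rel=0.01)

    def test_identity_when_already_at_target(self):
        rec = _sine_recording(10.0, fs=250.0)
        out = resample(rec, 250.0)
        assert np.allclose(out.data, rec.data, atol=1e-9)

    def test_sample_count(self):
        rec = Recording("r", 200.0, np.zeros((19, 36000)))
        assert resample(rec, 250.0).n_samples == 45000

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError, match="target_fs"):
            resample(_sine_recording(5.0), 300.0)


class TestBandpassNotch:
    def test_line_component_suppressed_passband_kept(self):
        fs, dur = 250.0, 20.0
        t = np.arange(int(dur * fs)) / fs
        x = 10 * np.sin(2 * np.pi * 10 * t) + 10 * np.sin(2 * np.pi * 60 * t)
        rec = Recording("r", fs, np.tile(x, (19, 1)))
        out = bandpass_and_notch(rec, low=1.0, high=100.0, line_freq=60.0)
        f, p_in = sp_signal.periodogram(rec.data[0], fs=fs)
        _, p_out = sp_signal.periodogram(out.data[0], fs=fs)
        at = lambda fr: slice(np.searchsorted(f, fr - 0.5), np.searchsorted(f, fr + 0.5))
        db = lambda a, b: 10 * np.log10(a / b)
        assert db(p_in[at(60)].sum(), p_out[at(60)].sum()) >= 20.0
        assert abs(db(p_in[at(10)].sum(), p_out[at(10)].sum())) <= 1.0

    def test_slow_drift_attenuated(self):
        fs, dur = 250.0, 60.0
        t = np.arange(int(dur * fs)) / fs
        rec = Recording("r", fs, np.tile(20 * np.sin(2 * np.pi * 0.3 * t), (19, 1)))
        out = bandpass_and_notch(rec)  # default 1-45.5 Hz
        atten = 10 * np.log10(np.var(rec.data[0]) / max(np.var(out.data[0]), 1e-30))
        assert atten >= 20.0

    def test_zero_in_zero_out_and_linearity(self):
        rec = Recording("r", 250.0, np.zeros((19, 5000)))
        assert np.allclose(bandpass_and_notch(rec).data, 0.0)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((19, 5000))
        a = bandpass_and_notch(Recording("r", 250.0, x)).data
        b = bandpass_and_notch(Recording("r", 250.0, 3.5 * x)).data
        assert np.allclose(3.5 * a, b, rtol=1e-9, atol=1e-9)

    def test_invalid_band_rejected(self):
        rec = Recording("r", 250.0, np.zeros((19, 1000)))
        with pytest.raises(ValueError, match="low"):
            bandpass_and_notch(rec, low=50.0, high=40.0)


class TestCommonAverage:
    def test_constant_offset_removed(self):
        rec = Recording("r", 250.0, np.full((19, 100), 50.0))
        assert np.allclose(rereference_car(rec).data, 0.0, atol=1e-9)

    def test_single_active_channel_arithmetic(self):
        data = np.zeros((19, 10))
        data[channel_index("Cz")] = 19.0
        out = rereference_car(Recording("r", 250.0, data))
        assert np.allclose(out.data[channel_index("Cz")], 18.0)
        assert np.allclose(out.data[channel_index("Fp1")], -1.0)

    def test_idempotent_and_zero_mean(self):
        rng = np.random.default_rng(1)
        rec = Recording("r", 250.0, rng.standard_normal((19, 500)))
        once = rereference_car(rec)
        twice = rereference_car(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)
        assert np.max(np.abs(once.data.mean(axis=0))) < 1e-9
        assert once.reference == "common-average"


class TestEpoching:
    def test_counts(self):
        rec = Recording("r", 250.0, np.zeros((19, 45000)))
        assert epoch(rec, 4.0, 0.0).n_epochs == 45
        assert epoch(rec, 4.0, 0.5).n_epochs == 89

    def test_too_short_recording_rejected(self):
        rec = Recording("r", 250.0, np.zeros((19, 750)))  # 3 s
        with pytest.raises(ValueError, match="shorter"):
            epoch(rec, 4.0)

    def test_non_integer_epoch_length_rejected(self):
        rec = Recording("r", 250.0, np.zeros((19, 5000)))
        with pytest.raises(ValueError, match="integer"):
            epoch(rec, 4.0001)


class TestRejection:
    def _epochs(self, rng, n=10, scale=5.0):
        rec = Recording("r", 250.0, scale * rng.standard_normal((19, n * 1000)))
        return epoch(rec, 4.0)

    def test_clean_epochs_all_kept(self, clean_recording, prep_no_ocular):
        es = epoch(clean_recording, 4.0)
        out = reject_bad_epochs(es, amp_thresh=100.0, var_mult=5.0)
        assert out.n_epochs == es.n_epochs

    def test_injected_transient_rejects_exactly_that_epoch(self):
        es = self._epochs(np.random.default_rng(2))
        es.epochs[3, channel_index("Fp1"), 100:150] += 500.0
        out = reject_bad_epochs(es, amp_thresh=100.0, var_mult=np.inf)
        assert out.n_epochs == es.n_epochs - 1
        assert out.kept[3] is False and sum(out.kept) == es.n_epochs - 1

    def test_infinite_thresholds_keep_everything(self):
        es = self._epochs(np.random.default_rng(3))
        out = reject_bad_epochs(es, amp_thresh=np.inf, var_mult=np.inf)
        assert np.array_equal(out.epochs, es.epochs)

    def test_all_rejected_raises_with_subject(self):
        es = self._epochs(np.random.default_rng(4), scale=500.0)
        with pytest.raises(RuntimeError, match="r"):
            reject_bad_epochs(es, amp_thresh=1.0, var_mult=np.inf)


class TestOcularRemoval:
    def _blinky_epochs(self, rng, n_epochs=10, fs=250.0, L=1000):
        from amyeeg.synth import _blink_template

        # low-frequency-dominated background, like real EEG (a white
        # background would itself trip the >20 Hz myogenic-component rule)
        sos = sp_signal.butter(4, 15.0, btype="lowpass", fs=fs, output="sos")
        clean = sp_signal.sosfiltfilt(sos, rng.standard_normal((n_epochs, 19, L)), axis=2)
        clean *= 5.0 / clean.std()
        blink = np.zeros((n_epochs, L))
        tpl = _blink_template(fs, 0.4)
        for e in range(n_epochs):
            start = 100 + 37 * e
            blink[e, start:start + tpl.size] = tpl
        epochs = clean.copy()
        for ch, w in (("Fp1", 150.0), ("Fp2", 150.0), ("F3", 60.0)):
            epochs[:, channel_index(ch), :] += w * blink
        return EpochSet("s", epochs, 4.0, fs), blink

    def test_regression_removes_frontal_blink_leakage(self):
        es, blink = self._blinky_epochs(np.random.default_rng(5))
        f3 = channel_index("F3")
        before = np.corrcoef(es.epochs[:, f3, :].ravel(), blink.ravel())[0, 1]
        out = remove_ocular_emg(es, mode="regression")
        after = np.corrcoef(out.epochs[:, f3, :].ravel(), blink.ravel())[0, 1]
        assert before > 0.6
        assert abs(after) < 0.2
        # least-squares projection can only shrink per-channel variance
        assert np.all(
            out.epochs.var(axis=(0, 2)) <= es.epochs.var(axis=(0, 2)) + 1e-12
        )

    def test_artifact_free_input_barely_changed(self):
        rng = np.random.default_rng(6)
        es = EpochSet("s", 5.0 * rng.standard_normal((10, 19, 1000)), 4.0, 250.0)
        out = remove_ocular_emg(es, mode="regression")
        rms_change = np.sqrt(((out.epochs - es.epochs) ** 2).mean(axis=(0, 2)))
        rms = np.sqrt((es.epochs ** 2).mean(axis=(0, 2)))
        assert np.all(rms_change / rms < 0.05)

    def test_zero_input_zero_output(self):
        es = EpochSet("s", np.zeros((4, 19, 1000)), 4.0, 250.0)
        out = remove_ocular_emg(es, mode="regression")
        assert np.allclose(out.epochs, 0.0)

    def test_ica_mode_needs_enough_epochs(self):
        es = EpochSet("s", np.random.default_rng(7).standard_normal((4, 19, 250)),
                      1.0, 250.0)
        with pytest.raises(ValueError, match="8"):
            remove_ocular_emg(es, mode="ica")

    def test_ica_mode_removes_blink_leakage(self):
        es, blink = self._blinky_epochs(np.random.default_rng(8))
        out = remove_ocular_emg(es, mode="ica", seed=0)
        f3 = channel_index("F3")
        after = np.corrcoef(out.epochs[:, f3, :].ravel(), blink.ravel())[0, 1]
        assert abs(after) < 0.3


def test_full_chain_preserves_clean_band_powers(clean_recording):
    """Preprocessing leaves the band structure of a clean recording intact.

    Filtering, rejection and ocular regression together move relative band
    powers by < 0.02 absolute.  Common-average referencing additionally
    redistributes a little power between channels sharing strong rhythms (it
    subtracts a mixture of all channels), so the full chain including CAR is
    held to 0.03.
    """
    from amyeeg.features import estimate_spectra, relative_band_power

    rp_raw = relative_band_power(estimate_spectra(epoch(clean_recording, 4.0)))

    filtered = bandpass_and_notch(clean_recording)
    es_nocar = remove_ocular_emg(
        reject_bad_epochs(epoch(filtered, 4.0), 100.0, 5.0), mode="regression"
    )
    rp_nocar = relative_band_power(estimate_spectra(es_nocar))
    assert np.max(np.abs(rp_raw - rp_nocar)) < 0.02

    es_full = preprocess_recording(clean_recording, PreprocessConfig())
    rp_full = relative_band_power(estimate_spectra(es_full))
    assert np.max(np.abs(rp_raw - rp_full)) < 0.03


def test_pipeline_order_is_logged(default_recording):
    es = preprocess_recording(default_recording, PreprocessConfig())
    joined = " | ".join(es.log)
    for stage in ("resample", "bandpass", "car", "epoch", "reject_bad_epochs",
                  "remove_ocular_emg"):
        assert stage in joined
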