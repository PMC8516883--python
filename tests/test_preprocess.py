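"""Preprocessing chain: mean removal, notch, bandpass, re-referencing,
segmentation and deterministic artifact rejection."""

import numpy as np
import pytest
from scipy import signal

from roipower import (Recording, bandpass_filter, notch_filter,
                      preprocess_recording, reject_artifact_epochs,
                      remove_mean, rereference_common_average,
                      segment_epochs)
from roipower.filters import fir_bandpass, iir_notch, zero_phase_fir


def _rec(data, fs=500.0):
    data = np.atleast_2d(np.asarray(data, float))
    return Recording(data=data, fs_hz=fs,
                     channel_labels=tuple(f"ch{i}" for i in range(data.shape[0])))


def _tone(freq, fs=500.0, dur=10.0):
    t = np.arange(int(dur * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


def _rms(x):
    return np.sqrt(np.mean(np.square(x)))


class TestRemoveMean:
    def test_constant_channel_becomes_zero(self):
        out = remove_mean(_rec(np.full(1000, 5.0)))
        assert np.allclose(out.data, 0.0, atol=1e-12)

    def test_zero_mean_channel_unchanged(self, rng):
        x = rng.standard_normal(1000)
        x -= x.mean()
        out = remove_mean(_rec(x))
        assert np.allclose(out.data[0], x, atol=1e-12)

    def test_offset_sinusoid_closed_form(self):
        x = _tone(10.0, dur=2.0)  # integer cycles → zero mean
        out = remove_mean(_rec(x + 3.0))
        assert np.allclose(out.data[0], x, atol=1e-9)


class TestNotch:
    def test_tone_at_notch_killed(self):
        out = notch_filter(_rec(_tone(50.0)), 50.0).data[0]
        # steady state: discard 2 s of filter transient at each edge
        assert _rms(out[1000:-1000]) / _rms(_tone(50.0)) <= 0.01

    def test_neighbour_tones_nearly_unity(self):
        b, a = iir_notch(50.0, 500.0)
        for f in (45.0, 55.0):
            w, h = signal.freqz(b, a, worN=[2 * np.pi * f / 500.0])
            net_db = 20 * np.log10(np.abs(h[0]) ** 2)  # forward-backward
            assert net_db >= -1.0

    def test_passband_tone_preserved(self):
        x = _tone(10.0)
        out = notch_filter(_rec(x)).data[0]
        assert abs(_rms(out) / _rms(x) - 1.0) < 0.01

    def test_zero_in_zero_out(self):
        out = notch_filter(_rec(np.zeros(1000)))
        assert np.allclose(out.data, 0.0)

    def test_rejects_notch_at_or_above_nyquist(self):
        with pytest.raises(ValueError):
            notch_filter(_rec(np.zeros(1000)), f0_hz=250.0)


class TestBandpass:
    @pytest.mark.parametrize("freq,min_att_db", [(0.2, 40.0), (87.5, 40.0)])
    def test_stopband_attenuation(self, freq, min_att_db):
        x = _tone(freq, dur=20.0)
        out = bandpass_filter(_rec(x, fs=500.0)).data[0]
        mid = slice(2500, -2500)
        att = -20 * np.log10(max(_rms(out[mid]) / _rms(x[mid]), 1e-15))
        assert att >= min_att_db

    @pytest.mark.parametrize("freq", [2.0, 20.0, 63.0])
    def test_passband_within_1db(self, freq):
        x = _tone(freq, dur=20.0)
        out = bandpass_filter(_rec(x)).data[0]
        mid = slice(2500, -2500)
        gain_db = 20 * np.log10(_rms(out[mid]) / _rms(x[mid]))
        assert abs(gain_db) <= 1.0

    def test_zero_phase_no_group_delay(self):
        x = _tone(20.0, dur=20.0)
        out = bandpass_filter(_rec(x)).data[0]
        mid = slice(2500, -2500)
        # projection onto the quadrature component measures phase shift
        quad = np.cos(2 * np.pi * 20.0 * np.arange(10000) / 500.0)
        phase = np.dot(out[mid], quad[mid]) / np.dot(x[mid], x[mid])
        assert abs(phase) < 1e-3

    def test_linearity_scaling_commutes(self, rng):
        x = rng.standard_normal(4000)
        a = bandpass_filter(_rec(3.7 * x)).data
        b = 3.7 * bandpass_filter(_rec(x)).data
        assert np.allclose(a, b, atol=1e-9 * np.abs(b).max())

    def test_rejects_invalid_edges(self):
        with pytest.raises(ValueError):
            bandpass_filter(_rec(np.zeros(1000)), lo_hz=70.0, hi_hz=1.0)
        with pytest.raises(ValueError):
            bandpass_filter(_rec(np.zeros(1000), fs=100.0), hi_hz=70.0)

    def test_fir_design_is_odd_length_hamming(self):
        taps = fir_bandpass(1.0, 70.0, 500.0)
        assert len(taps) % 2 == 1
        assert np.allclose(taps, taps[::-1])  # linear phase


class TestCommonAverage:
    def test_antisymmetric_pair_unchanged(self, rng):
        x = rng.standard_normal(100)
        rec = _rec(np.vstack([x, -x]))
        assert np.allclose(rereference_common_average(rec).data, rec.data)

    def test_identical_channels_become_zero(self, rng):
        x = rng.standard_normal(100)
        rec = _rec(np.vstack([x, x, x]))
        assert np.allclose(rereference_common_average(rec).data, 0.0)

    def test_column_means_zero(self, rng):
        rec = _rec(rng.standard_normal((3, 256)))
        out = rereference_common_average(rec)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-9

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            rereference_common_average(_rec(np.zeros(10)))


class TestSegmentation:
    def test_five_minute_recording_gives_60_epochs(self, rng):
        rec = _rec(rng.standard_normal((2, 300 * 500)))
        es = segment_epochs(rec, 5.0)
        assert es.epochs.shape == (60, 2, 2500)

    def test_short_recording_gives_no_epochs(self, rng):
        rec = _rec(rng.standard_normal((1, int(4.9 * 500))))
        assert segment_epochs(rec, 5.0).n_epochs == 0

    def test_trailing_partial_epoch_dropped(self, rng):
        rec = _rec(rng.standard_normal((1, 12 * 500)))
        es = segment_epochs(rec, 5.0)
        assert es.n_epochs == 2
        # provenance: epochs are exactly consecutive slices of the input
        assert np.array_equal(es.epochs[0, 0], rec.data[0, :2500])
        assert np.array_equal(es.epochs[1, 0], rec.data[0, 2500:5000])


class TestArtifactRejection:
    def _clean_epochs(self, rng, n_epochs=12):
        rec = _rec(rng.standard_normal((3, n_epochs * 2500)))
        return segment_epochs(rec, 5.0)

    def test_clean_epochs_all_kept(self, rng):
        es = self._clean_epochs(rng)
        out = reject_artifact_epochs(es, ptp_threshold_uv=150.0)
        assert out.n_epochs == es.n_epochs

    def test_injected_transient_epoch_dropped(self, rng):
        from roipower import inject_transient
        rec = _rec(rng.standard_normal((3, 12 * 2500)))
        rec = inject_transient(rec, time_s=17.0, amplitude_uv=500.0, channel=1)
        out = reject_artifact_epochs(segment_epochs(rec, 5.0))
        assert list(out.kept_indices) == [i for i in range(12) if i != 3]

    def test_infinite_thresholds_keep_everything(self, rng):
        es = self._clean_epochs(rng)
        out = reject_artifact_epochs(es, ptp_threshold_uv=np.inf,
                                     z_threshold=np.inf)
        assert np.array_equal(out.epochs, es.epochs)

    def test_all_rejected_warns_not_fails(self, rng):
        es = self._clean_epochs(rng, n_epochs=3)
        with pytest.warns(RuntimeWarning):
            out = reject_artifact_epochs(es, ptp_threshold_uv=0.0)
        assert out.n_epochs == 0


class TestFullChain:
    def test_epochs_derive_from_processed_signal(self, rng):
        rec = _rec(rng.standard_normal((3, 30 * 500)))
        es = preprocess_recording(rec)
        manual = rereference_common_average(
            bandpass_filter(notch_filter(remove_mean(rec))))
        seg = segment_epochs(manual, 5.0)
        for k, idx in enumerate(es.kept_indices):
            assert np.allclose(es.epochs[k], seg.epochs[idx])

    def test_artifact_hook_is_applied(self, rng):
        rec = _rec(rng.standard_normal((3, 10 * 500)))
        seen = []

        def hook(r):
            seen.append(True)
            return r.with_data(r.data * 0.5)

        es = preprocess_recording(rec, artifact_hook=hook)
        es_ref = preprocess_recording(rec)
        assert seen and np.allclose(es.epochs, 0.5 * es_ref.epochs, atol=1e-9)


class TestRecordingValidation:
    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            Recording(data=np.array([[np.nan, 1.0]]), fs_hz=500.0,
                      channel_labels=("a",))

    def test_rejects_duplicate_labels(self):
        with pytest.raises(ValueError):
            Recording(data=np.zeros((2, 10)), fs_hz=500.0,
                      channel_labels=("a", "a"))

    def test_zero_phase_fir_on_short_signal(self, rng):
        # padding must clip when the signal is shorter than the kernel
        taps = fir_bandpass(1.0, 70.0, 500.0)
        x = rng.standard_normal(300)
        assert zero_phase_fir(x, taps).shape == (300,)
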