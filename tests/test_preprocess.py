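"""Filtering, epoching, channel repair, rejection and referencing."""

import numpy as np
import pandas as pd
import pytest

from windeeg.exceptions import InvalidParameterError, QualityError
from windeeg.forward import standard_channel_positions
from windeeg.preprocess import (
    EpochSet,
    bandpass_filter,
    crop_analysis_window,
    detect_and_interpolate_bad_channels,
    extract_epochs,
    preprocess_recording,
    reject_artifact_epochs,
    remove_ocular_artifacts,
    rereference_average,
    spherical_spline_matrix,
)
from windeeg.synth import FS, Recording


def _tone_recording(freq, amplitude=1.0, duration_s=60.0, n_channels=2):
    t = np.arange(int(duration_s * FS)) / FS
    wave = amplitude * np.sin(2 * np.pi * freq * t)
    data = np.tile(wave, (n_channels, 1)).astype(np.float32)
    return Recording(
        data=data,
        fs=float(FS),
        channel_names=tuple(f"ch{i}" for i in range(n_channels)),
        events=pd.DataFrame(columns=["onset_sample", "kind", "session", "trial",
                                     "velocity", "score"]),
    )


def _mid_amplitude(x):
    mid = slice(x.shape[-1] // 4, 3 * x.shape[-1] // 4)
    return np.abs(x[..., mid]).max()


class TestBandpassFilter:
    def test_passband_tone_preserved(self):
        rec = _tone_recording(25.0)
        out = bandpass_filter(rec)
        assert _mid_amplitude(out.data) == pytest.approx(1.0, rel=0.05)

    def test_slow_drift_removed(self):
        rec = _tone_recording(0.05, amplitude=100.0, duration_s=120.0)
        out = bandpass_filter(rec)
        assert _mid_amplitude(out.data) < 10.0

    def test_stopband_attenuation_spec(self):
        """>= 20 dB down at 0.1 and 60 Hz, < 1 dB ripple inside [1, 40] Hz."""
        import scipy.signal

        from windeeg.preprocess import design_bandpass

        sos_hp, sos_lp = design_bandpass(FS)
        freqs = np.array([0.1, 1.0, 10.0, 25.0, 40.0, 60.0])
        gain = np.ones_like(freqs)
        for sos in (sos_hp, sos_lp):
            _, h = scipy.signal.sosfreqz(sos, worN=freqs, fs=FS)
            gain *= np.abs(h) ** 2  # zero-phase (two-pass) magnitude
        db = 20 * np.log10(gain)
        assert db[0] < -20 and db[-1] < -20
        assert np.all(db[1:5] > -1.0)

    def test_zero_input_zero_output(self):
        rec = _tone_recording(10.0, amplitude=0.0)
        out = bandpass_filter(rec)
        assert np.all(out.data == 0)

    def test_invalid_cutoffs_rejected(self):
        rec = _tone_recording(10.0)
        with pytest.raises(InvalidParameterError):
            bandpass_filter(rec, lp=300.0)
        with pytest.raises(InvalidParameterError):
            bandpass_filter(rec, hp=50.0, lp=45.0)


class TestExtractEpochs:
    def test_counts_alignment_and_metadata(self, tiny_recording):
        epochs = extract_epochs(tiny_recording)
        assert epochs.data.shape == (8, 64, 11 * 512)
        on = tiny_recording.events[tiny_recording.events["kind"] == "wind_on"]
        np.testing.assert_array_equal(
            epochs.metadata["onset_sample"].to_numpy(), on["onset_sample"].to_numpy()
        )
        np.testing.assert_array_equal(
            epochs.metadata["velocity"].to_numpy(), on["velocity"].to_numpy()
        )
        # t=0 sample equals the event sample
        k = int(on["onset_sample"].iloc[0])
        np.testing.assert_array_equal(
            epochs.data[0, :, 512], tiny_recording.data[:, k]
        )

    def test_marker_too_close_to_edge_skipped(self, tiny_recording):
        events = tiny_recording.events.copy()
        early = events.iloc[[0]].copy()
        early["onset_sample"] = 100  # < 1 s of history
        bad = Recording(
            data=tiny_recording.data,
            fs=tiny_recording.fs,
            channel_names=tiny_recording.channel_names,
            events=pd.concat([early, events], ignore_index=True),
        )
        epochs = extract_epochs(bad)
        assert epochs.n_epochs == 8  # the malformed marker is dropped


class TestBadChannels:
    def test_noisy_channel_flagged_and_only_it(self, tiny_recording):
        _, pos = standard_channel_positions()
        epochs = extract_epochs(tiny_recording)
        epochs.channel_positions = pos
        rng = np.random.default_rng(0)
        data = epochs.data.copy()
        # inject 100x-amplitude noise on channel 17
        data[:, 17, :] = 100.0 * epochs.data.std() * rng.standard_normal(
            (data.shape[0], data.shape[2])
        ).astype(np.float32)
        epochs.data = data
        # oracle: direct variance ranking identifies channel 17 as the outlier
        assert int(np.argmax(data.var(axis=(0, 2)))) == 17
        repaired = detect_and_interpolate_bad_channels(epochs)
        assert repaired.bad_channels == (epochs.channel_names[17],)
        assert repaired.data[:, 17, :].var() < data[:, 17, :].var() / 100

    def test_clean_data_unchanged(self, tiny_recording):
        _, pos = standard_channel_positions()
        epochs = extract_epochs(tiny_recording)
        epochs.channel_positions = pos
        out = detect_and_interpolate_bad_channels(epochs)
        assert out is epochs

    def test_spline_recovers_smooth_field(self):
        """A low-order spherical-harmonic field is recovered within 5%."""
        _, pos = standard_channel_positions()
        u = pos / np.linalg.norm(pos, axis=1, keepdims=True)
        x, y, z = u.T
        field = 1.3 * x + 0.7 * y - 0.9 * z + 0.6 * (x * y) + 0.4 * (z * z - 1 / 3)
        for missing in (5, 30, 55):
            good = np.setdiff1d(np.arange(64), [missing])
            interp = spherical_spline_matrix(pos[good], pos[[missing]])
            estimate = (interp @ field[good]).item()
            assert estimate == pytest.approx(field[missing], rel=0.05)

    def test_too_many_bad_channels_raise(self, tiny_recording):
        _, pos = standard_channel_positions()
        epochs = extract_epochs(tiny_recording)
        epochs.channel_positions = pos
        data = epochs.data.copy()
        rng = np.random.default_rng(1)
        scale = 1000.0 * epochs.data.std()
        for ch in range(20):
            data[:, ch, :] = scale * rng.standard_normal(
                (data.shape[0], data.shape[2])
            ).astype(np.float32)
        epochs.data = data
        with pytest.raises(QualityError):
            detect_and_interpolate_bad_channels(epochs)


class TestRejectEpochs:
    def test_clean_set_keeps_everything(self, tiny_recording):
        epochs = extract_epochs(tiny_recording)
        out = reject_artifact_epochs(epochs)
        assert int(out.metadata["rejected"].sum()) == 0

    def test_spiked_epoch_rejected_exactly(self, tiny_recording):
        epochs = extract_epochs(tiny_recording)
        epochs.data = epochs.data.copy()
        epochs.data[3, 10, 100] = 500.0
        epochs.data[3, 10, 101] = -500.0
        out = reject_artifact_epochs(epochs)
        assert out.metadata["rejected"].tolist() == [False] * 3 + [True] + [False] * 4

    def test_idempotent(self, tiny_recording):
        epochs = extract_epochs(tiny_recording)
        epochs.data = epochs.data.copy()
        epochs.data[0, 0, :2] = [400.0, -400.0]
        once = reject_artifact_epochs(epochs)
        twice = reject_artifact_epochs(once)
        assert once.metadata["rejected"].equals(twice.metadata["rejected"])

    def test_all_rejected_raises(self, tiny_recording):
        epochs = extract_epochs(tiny_recording)
        with pytest.raises(QualityError):
            reject_artifact_epochs(epochs, ptp_thresh_uv=0.0)


class TestOcularRegression:
    def _epochs(self, data):
        n_e, n_c, n_t = data.shape
        return EpochSet(
            data=data.astype(np.float32),
            fs=float(FS),
            channel_names=tuple(f"ch{i}" for i in range(n_c)),
            metadata=pd.DataFrame({"rejected": [False] * n_e}),
        )

    def test_known_contamination_removed(self):
        rng = np.random.default_rng(0)
        clean = rng.standard_normal((4, 8, 1024))
        eog = rng.standard_normal((4, 1024))
        b = np.linspace(0.5, 4.0, 8)
        contaminated = clean + b[None, :, None] * eog[:, None, :]
        out = remove_ocular_artifacts(self._epochs(contaminated), eog)
        err = np.abs(out.data - clean).mean() / np.abs(clean).mean()
        assert err < 0.01

    def test_orthogonal_reference_no_change(self):
        n = 1024
        t = np.arange(n)
        data = np.sin(2 * np.pi * 10 * t / n)[None, None, :] * np.ones((2, 3, 1))
        eog = np.cos(2 * np.pi * 10 * t / n)[None, :] * np.ones((2, 1))
        out = remove_ocular_artifacts(self._epochs(data), eog)
        np.testing.assert_allclose(out.data, data.astype(np.float32), atol=1e-6)

    def test_missing_reference_skips(self):
        rng = np.random.default_rng(0)
        epochs = self._epochs(rng.standard_normal((2, 3, 64)))
        out = remove_ocular_artifacts(epochs, None)
        assert out is epochs


class TestRereference:
    def test_channel_mean_zero_and_idempotent(self, tiny_recording):
        epochs = extract_epochs(tiny_recording)
        once = rereference_average(epochs)
        np.testing.assert_allclose(
            once.data.mean(axis=1), 0.0, atol=1e-4  # float32 accumulation
        )
        twice = rereference_average(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-5)

    def test_bipolar_pairs_invariant(self, tiny_recording):
        epochs = extract_epochs(tiny_recording)
        out = rereference_average(epochs)
        np.testing.assert_allclose(
            out.data[:, 3] - out.data[:, 7],
            epochs.data[:, 3] - epochs.data[:, 7],
            atol=1e-4,
        )


class TestCropAndChain:
    def test_window_lengths_and_alignment(self, tiny_recording):
        epochs = extract_epochs(tiny_recording)
        windows = crop_analysis_window(epochs)
        assert windows.baseline.shape[2] == 512
        assert windows.analysis.shape[2] == 4096
        # analysis starts exactly at t = 2 s
        i2 = int((2.0 - epochs.tmin) * epochs.fs)
        np.testing.assert_array_equal(
            windows.analysis[:, :, 0], epochs.data[:, :, i2]
        )

    def test_full_chain_preserves_metadata(self, tiny_recording):
        _, pos = standard_channel_positions()
        epochs, windows = preprocess_recording(
            tiny_recording, channel_positions=pos
        )
        assert epochs.n_epochs == 8
        assert list(windows.metadata["velocity"]) == list(
            epochs.metadata.loc[~epochs.metadata["rejected"], "velocity"]
        )
        np.testing.assert_allclose(
            windows.analysis.mean(axis=1), 0.0, atol=1e-4
        )
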