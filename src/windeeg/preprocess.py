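"""Continuous recording -> clean average-referenced analysis epochs.

Stage order is fixed and asserted by :func:`preprocess_recording`:

    band-pass filter -> epoch extraction -> bad-channel interpolation ->
    artifact-epoch rejection -> (optional ocular regression) ->
    average re-reference -> analysis-window crop

Epochs span -1 s .. +10 s around wind onset (5632 samples at 512 Hz); the
analysis window drops the first 2 s of wind (velocity ramp-up), the baseline
window is the 1 s of pre-wind rest used later for the noise covariance.
"""

from __future__ import annotations

import functools
import logging
import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.fft
import scipy.signal

from .exceptions import InvalidParameterError, QualityError
from .synth import Recording

logger = logging.getLogger(__name__)

EPOCH_TMIN = -1.0
EPOCH_TMAX = 10.0
ANALYSIS_TMIN = 2.0

# Perrin-style spherical spline constants
_SPLINE_ORDER_M = 4
_SPLINE_DEGREE = 7


@dataclass
class EpochSet:
    """Trials x channels x samples with per-trial metadata.

    ``metadata`` columns include session, trial, velocity, score, rejected;
    rejected trials stay in ``data`` but are excluded by :meth:`retained`.
    """

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    metadata: pd.DataFrame
    tmin: float = EPOCH_TMIN
    bad_channels: tuple[str, ...] = ()
    channel_positions: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[2]) / self.fs

    def retained(self) -> "EpochSet":
        keep = ~self.metadata["rejected"].to_numpy(bool)
        return replace(
            self,
            data=self.data[keep],
            metadata=self.metadata.loc[keep].reset_index(drop=True),
        )


class AnalysisWindows(NamedTuple):
    """Baseline ([-1, 0) s) and analysis ([2, 10) s) segments of an EpochSet."""

    baseline: np.ndarray  # (n_epochs, n_channels, 1 s)
    analysis: np.ndarray  # (n_epochs, n_channels, 8 s)
    metadata: pd.DataFrame
    fs: float


def design_bandpass(
    fs: float, hp: float = 0.5, lp: float = 45.0
) -> tuple[np.ndarray, np.ndarray]:
    """Second-order sections of the zero-phase band-pass (HP order 4, LP order 10)."""
    if lp >= fs / 2:
        raise InvalidParameterError(
            f"low-pass cutoff {lp} Hz must be below Nyquist ({fs / 2} Hz)"
        )
    if hp <= 0 or hp >= lp:
        raise InvalidParameterError(f"invalid band ({hp}, {lp}) Hz")
    sos_hp = scipy.signal.butter(4, hp, btype="highpass", fs=fs, output="sos")
    sos_lp = scipy.signal.butter(10, lp, btype="lowpass", fs=fs, output="sos")
    return sos_hp, sos_lp


@functools.lru_cache(maxsize=8)
def _bandpass_gain(n: int, fs: float, hp: float, lp: float) -> np.ndarray:
    """Two-pass (zero-phase) power gain of the Butterworth cascade on rfft bins."""
    sos_hp, sos_lp = design_bandpass(fs, hp, lp)
    freqs = scipy.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.ones_like(freqs)
    for sos in (sos_hp, sos_lp):
        _, h = scipy.signal.sosfreqz(sos, worN=freqs, fs=fs)
        gain *= np.abs(h) ** 2  # forward-backward => |H|^2, zero phase
    return gain


def bandpass_filter(recording: Recording, hp: float = 0.5, lp: float = 45.0) -> Recording:
    """Zero-phase band-pass of a recording.

    Applies the squared magnitude response of the designed Butterworth
    cascade (the response of a forward-backward pass) spectrally, which is
    exactly zero-phase and fast on half-hour recordings. The data are
    reflect-padded by 8 s at both ends to suppress wrap-around edge effects.
    """
    data = recording.data
    pad = int(8 * recording.fs)
    # pad right up to an FFT-friendly length
    n = scipy.fft.next_fast_len(data.shape[-1] + 2 * pad, real=True)
    padded = np.pad(
        data, [(0, 0), (pad, n - data.shape[-1] - pad)], mode="reflect"
    )
    gain = _bandpass_gain(n, recording.fs, hp, lp)
    spec = scipy.fft.rfft(padded, axis=-1)
    spec *= gain.astype(np.float32 if spec.dtype == np.complex64 else np.float64)
    filtered = scipy.fft.irfft(spec, n=n, axis=-1)[:, pad : pad + data.shape[-1]]
    return replace(recording, data=filtered.astype(recording.data.dtype))


def extract_epochs(recording: Recording) -> EpochSet:
    """One epoch (-1 .. +10 s) per wind-onset event, metadata joined."""
    fs = recording.fs
    n_pre = int(round(-EPOCH_TMIN * fs))
    n_post = int(round(EPOCH_TMAX * fs))
    onsets = recording.events[recording.events["kind"] == "wind_on"]

    rows, chunks = [], []
    for _, ev in onsets.iterrows():
        s = int(ev["onset_sample"])
        if s - n_pre < 0 or s + n_post > recording.n_samples:
            logger.warning("skipping wind_on at sample %d: epoch out of bounds", s)
            continue
        chunks.append(recording.data[:, s - n_pre : s + n_post])
        rows.append(
            dict(session=int(ev["session"]), trial=int(ev["trial"]),
                 velocity=float(ev["velocity"]), score=float(ev["score"]),
                 onset_sample=s, rejected=False)
        )
    if not chunks:
        raise InvalidParameterError("recording contains no usable wind_on events")
    return EpochSet(
        data=np.stack(chunks).astype(np.float32, copy=False),
        fs=fs,
        channel_names=recording.channel_names,
        metadata=pd.DataFrame(rows),
    )


def _spline_g(cosang: np.ndarray, m: int = _SPLINE_ORDER_M,
              n_terms: int = _SPLINE_DEGREE) -> np.ndarray:
    """Perrin surface-spline kernel g(cos angle), series truncated at n_terms."""
    x = np.clip(cosang, -1.0, 1.0)
    out = np.zeros_like(x, dtype=float)
    p_prev = np.ones_like(out)
    p_curr = x.astype(float)
    for n in range(1, n_terms + 1):
        out += (2 * n + 1) / (n**m * (n + 1) ** m) * p_curr
        p_next = ((2 * n + 1) * x * p_curr - n * p_prev) / (n + 1)
        p_prev, p_curr = p_curr, p_next
    return out / (4.0 * np.pi)


def spherical_spline_matrix(
    pos_from: np.ndarray, pos_to: np.ndarray, smooth: float = 1e-5
) -> np.ndarray:
    """Interpolation matrix mapping values at ``pos_from`` to ``pos_to``.

    Spherical-spline interpolation with spline order m=4 and the Legendre
    series truncated at degree 7; ``smooth`` is a small diagonal regulariser.
    """
    u_from = pos_from / np.linalg.norm(pos_from, axis=1, keepdims=True)
    u_to = pos_to / np.linalg.norm(pos_to, axis=1, keepdims=True)
    g_ff = _spline_g(u_from @ u_from.T) + smooth * np.eye(len(u_from))
    g_tf = _spline_g(u_to @ u_from.T)
    n = len(u_from)
    lhs = np.zeros((n + 1, n + 1))
    lhs[:n, :n] = g_ff
    lhs[:n, n] = 1.0
    lhs[n, :n] = 1.0
    sol = np.linalg.solve(lhs, np.vstack([np.eye(n), np.zeros((1, n))]))
    return g_tf @ sol[:n] + sol[n]


def detect_and_interpolate_bad_channels(
    epochs: EpochSet, z_thresh: float = 5.0
) -> EpochSet:
    """Flag channels with outlying robust variance and rebuild them by spline.

    A channel is bad when the robust z-score (median/MAD across channels) of
    its log variance exceeds ``z_thresh``. Flagged channels are replaced by
    spherical-spline interpolation from the remaining ones; more than 20%
    flagged raises a quality error.
    """
    variances = epochs.data.var(axis=(0, 2), dtype=np.float64)
    logv = np.log(np.maximum(variances, np.finfo(float).tiny))
    med = np.median(logv)
    mad = np.median(np.abs(logv - med))
    scale = 1.4826 * mad if mad > 0 else np.std(logv) or 1.0
    z = (logv - med) / scale
    bad = np.flatnonzero(np.abs(z) > z_thresh)

    if bad.size == 0:
        return epochs
    n_ch = epochs.data.shape[1]
    if bad.size > 0.2 * n_ch:
        raise QualityError(
            f"{bad.size}/{n_ch} channels flagged bad; data quality insufficient"
        )
    if n_ch - bad.size < 8:
        raise QualityError("fewer than 8 good channels remain")
    if epochs.channel_positions is None:
        raise InvalidParameterError(
            "channel positions required for spherical-spline interpolation"
        )

    good = np.setdiff1d(np.arange(n_ch), bad)
    interp = spherical_spline_matrix(
        epochs.channel_positions[good], epochs.channel_positions[bad]
    )
    data = epochs.data.copy()
    data[:, bad, :] = np.einsum(
        "bg,egt->ebt", interp, epochs.data[:, good, :].astype(np.float64)
    ).astype(epochs.data.dtype)
    bad_names = tuple(epochs.channel_names[i] for i in bad)
    logger.info("interpolated %d bad channel(s): %s", bad.size, ", ".join(bad_names))
    return replace(epochs, data=data, bad_channels=epochs.bad_channels + bad_names)


def reject_artifact_epochs(epochs: EpochSet, ptp_thresh_uv: float = 150.0) -> EpochSet:
    """Flag epochs whose peak-to-peak amplitude exceeds the threshold on any channel."""
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)
    bad = (ptp > ptp_thresh_uv).any(axis=1)
    meta = epochs.metadata.copy()
    meta["rejected"] = meta["rejected"].to_numpy(bool) | bad
    if meta["rejected"].all():
        raise QualityError("all epochs exceed the peak-to-peak threshold")
    n_new = int(bad.sum())
    if n_new:
        logger.info("rejected %d epoch(s) above %.0f uV peak-to-peak", n_new, ptp_thresh_uv)
    return replace(epochs, metadata=meta)


def remove_ocular_artifacts(
    epochs: EpochSet, eog_reference: np.ndarray | None
) -> EpochSet:
    """Optional regression of an EOG reference out of every channel.

    ``eog_reference`` is (n_epochs, n_samples); per channel a least-squares
    coefficient is fit over all epochs and the scaled reference subtracted.
    Missing reference skips the stage with a warning.
    """
    if eog_reference is None:
        logger.warning("no EOG reference available; ocular stage skipped")
        return epochs
    eog = np.asarray(eog_reference, float)
    if eog.shape != (epochs.data.shape[0], epochs.data.shape[2]):
        raise InvalidParameterError(
            f"EOG reference shape {eog.shape} does not match epochs"
        )
    e = eog.ravel()
    denom = e @ e
    if denom == 0:
        return epochs
    flat = epochs.data.astype(np.float64).transpose(1, 0, 2).reshape(
        epochs.data.shape[1], -1
    )
    beta = flat @ e / denom  # per-channel LS coefficient
    cleaned = flat - np.outer(beta, e)
    data = cleaned.reshape(
        epochs.data.shape[1], epochs.data.shape[0], epochs.data.shape[2]
    ).transpose(1, 0, 2).astype(epochs.data.dtype)
    return replace(epochs, data=data)


def rereference_average(epochs: EpochSet) -> EpochSet:
    """Subtract the instantaneous mean across channels (average reference)."""
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return replace(epochs, data=data)


def crop_analysis_window(epochs: EpochSet) -> AnalysisWindows:
    """Split epochs into baseline ([-1, 0) s) and analysis ([2, 10) s) segments."""
    fs = epochs.fs
    i0 = int(round((0.0 - epochs.tmin) * fs))
    ia = int(round((ANALYSIS_TMIN - epochs.tmin) * fs))
    ib = int(round((EPOCH_TMAX - epochs.tmin) * fs))
    if epochs.tmin > EPOCH_TMIN + 1e-9 or epochs.data.shape[2] < ib:
        raise InvalidParameterError("epochs must span -1 .. +10 s")
    return AnalysisWindows(
        baseline=epochs.data[:, :, :i0],
        analysis=epochs.data[:, :, ia:ib],
        metadata=epochs.metadata,
        fs=fs,
    )


def preprocess_recording(
    recording: Recording,
    channel_positions: np.ndarray | None = None,
    hp: float = 0.5,
    lp: float = 45.0,
    z_thresh: float = 5.0,
    ptp_thresh_uv: float = 150.0,
    eog_reference: np.ndarray | None = None,
    run_ocular: bool = False,
) -> tuple[EpochSet, AnalysisWindows]:
    """Run the fixed preprocessing chain and return retained epochs + windows."""
    filtered = bandpass_filter(recording, hp, lp)
    epochs = extract_epochs(filtered)
    if channel_positions is not None:
        epochs = replace(epochs, channel_positions=channel_positions)
    epochs = detect_and_interpolate_bad_channels(epochs, z_thresh)
    epochs = reject_artifact_epochs(epochs, ptp_thresh_uv)
    if run_ocular:
        epochs = remove_ocular_artifacts(epochs, eog_reference)
    epochs = rereference_average(epochs)
    retained = epochs.retained()
    windows = crop_analysis_window(retained)
    assert math.isclose(windows.baseline.shape[2], -EPOCH_TMIN * recording.fs)
    return epochs, windows
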