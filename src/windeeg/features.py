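"""Source epochs -> 24-dimensional log band-power feature vectors.

Per trial: Welch power spectral density at every source vertex (1 s Hann
windows, 50% overlap, 1 Hz bins), unweighted average over the vertices of
each of the 68 atlas regions, band averages over theta (4-7 Hz), alpha
(8-13 Hz), beta (14-30 Hz) and gamma (31-45 Hz) with inclusive integer-bin
membership, then the natural log of the six pleasantness ROIs' band powers
in a fixed column order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.fft
import scipy.signal

from .exceptions import InvalidParameterError, NumericalError
from .geometry import PLEASANTNESS_ROIS, AtlasLabels

#: Canonical EEG bands, inclusive frequency ranges in Hz.
BANDS: dict[str, tuple[int, int]] = {
    "theta": (4, 7),
    "alpha": (8, 13),
    "beta": (14, 30),
    "gamma": (31, 45),
}
BAND_NAMES = tuple(BANDS)

#: Fixed feature-column order: ROI-major (L/R interleaved), band-minor.
FEATURE_COLUMNS = tuple(
    f"{roi}_{band}" for roi in PLEASANTNESS_ROIS for band in BAND_NAMES
)

METADATA_COLUMNS = ("session", "trial", "velocity", "score")


def welch_psd(
    signal: np.ndarray,
    fs: float = 512.0,
    win: int = 512,
    overlap: int = 256,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD with a Hann window; density scaling, one-sided spectrum.

    The mean of modified periodograms over 50%-overlapping segments,
    vectorised over the leading axes of any-dimensional input (the last axis
    is time). With the defaults the frequency bins are spaced exactly 1 Hz
    apart. Matches ``scipy.signal.welch(..., detrend=False)`` to float
    precision while vectorising far better over many short epochs.
    """
    signal = np.asarray(signal)
    if signal.shape[-1] < win:
        raise InvalidParameterError(
            f"signal length {signal.shape[-1]} is shorter than the window ({win})"
        )
    if not 0 <= overlap < win:
        raise InvalidParameterError("overlap must lie in [0, win)")
    window = scipy.signal.get_window("hann", win).astype(signal.dtype, copy=False)
    step = win - overlap
    segments = np.lib.stride_tricks.sliding_window_view(signal, win, axis=-1)[
        ..., ::step, :
    ]
    spectra = scipy.fft.rfft(segments * window, axis=-1)
    psd = (spectra.real**2 + spectra.imag**2).mean(axis=-2)
    # one-sided density scaling: doubled except DC and Nyquist
    psd *= 2.0 / (fs * (window**2).sum())
    psd[..., 0] /= 2.0
    if win % 2 == 0:
        psd[..., -1] /= 2.0
    freqs = scipy.fft.rfftfreq(win, d=1.0 / fs)
    return freqs, psd


def aggregate_rois(
    vertex_powers: np.ndarray, atlas: AtlasLabels
) -> np.ndarray:
    """Unweighted mean power over member vertices for each of the 68 regions.

    ``vertex_powers`` has vertices on axis -2 and frequency bins on axis -1;
    the output replaces the vertex axis with a region axis of length 68.
    """
    vp = np.asarray(vertex_powers)
    if vp.shape[-2] != len(atlas.labels):
        raise InvalidParameterError(
            f"vertex axis has length {vp.shape[-2]}, atlas labels {len(atlas.labels)}"
        )
    counts = np.bincount(atlas.labels, minlength=atlas.n_regions)
    if np.any(counts == 0):
        empty = [atlas.region_names[i] for i in np.flatnonzero(counts == 0)]
        raise InvalidParameterError(f"empty atlas region(s): {', '.join(empty)}")
    # membership matrix (68, n_vertices) with rows summing to 1 => means
    member = np.zeros((atlas.n_regions, len(atlas.labels)))
    member[atlas.labels, np.arange(len(atlas.labels))] = 1.0
    member /= counts[:, None]
    return member.astype(vp.dtype, copy=False) @ vp


def band_powers(
    region_powers: np.ndarray, freqs: np.ndarray
) -> np.ndarray:
    """Average power per canonical band, inclusive integer-bin membership.

    ``region_powers``'s last axis must align with ``freqs``; returns an array
    with the frequency axis replaced by a band axis ordered as
    (theta, alpha, beta, gamma).
    """
    freqs = np.asarray(freqs)
    bands = []
    for name, (lo, hi) in BANDS.items():
        mask = (freqs >= lo) & (freqs <= hi)
        if not mask.any():
            raise InvalidParameterError(
                f"frequency bins do not cover the {name} band ({lo}-{hi} Hz)"
            )
        covered = np.unique(np.round(freqs[mask]).astype(int))
        if covered.min() > lo or covered.max() < hi:
            raise InvalidParameterError(
                f"frequency bins only partially cover the {name} band"
            )
        bands.append(region_powers[..., mask].mean(axis=-1))
    return np.stack(bands, axis=-1)


def build_feature_table(
    band_table: np.ndarray,
    atlas: AtlasLabels,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Log-transform the six ROIs' band powers into the fixed 24-column table.

    ``band_table`` is (n_trials, 68 regions, 4 bands); the result has the 24
    feature columns of :data:`FEATURE_COLUMNS` plus the per-trial metadata.
    """
    band_table = np.asarray(band_table)
    if band_table.ndim != 3 or band_table.shape[1] != atlas.n_regions:
        raise InvalidParameterError(
            "band table must be (trials, 68 regions, 4 bands); got "
            f"{band_table.shape}"
        )
    if len(metadata) != band_table.shape[0]:
        raise InvalidParameterError("metadata row count does not match trials")

    roi_ids = [atlas.region_id(roi) for roi in PLEASANTNESS_ROIS]
    roi_bands = band_table[:, roi_ids, :]  # (trials, 6, 4)
    if np.any(roi_bands <= 0):
        raise NumericalError(
            "non-positive band power encountered; upstream PSD is invalid"
        )
    features = np.log(roi_bands).reshape(band_table.shape[0], -1)
    table = pd.DataFrame(features, columns=list(FEATURE_COLUMNS))
    for col in METADATA_COLUMNS:
        if col in metadata.columns:
            table[col] = metadata[col].to_numpy()
    return table


def extract_features(
    source_epochs: np.ndarray,
    atlas: AtlasLabels,
    metadata: pd.DataFrame,
    fs: float = 512.0,
) -> pd.DataFrame:
    """Convenience chain: Welch -> ROI aggregation -> bands -> log table."""
    freqs, psd = welch_psd(source_epochs, fs=fs)
    region = aggregate_rois(psd, atlas)
    bands = band_powers(region, freqs)
    return build_feature_table(bands, atlas, metadata)
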