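"""Preprocessing for the microstate and spectral paths.

The microstate path band-passes (zero-phase Butterworth), re-references to
the common average, reduces the recording to samples at local maxima of the
global field power (GFP), and standardizes each retained topographic map to
zero mean / unit standard deviation across channels before clustering.

The spectral path uses its own, slightly different filter order and a
decimation to a lower rate; see :func:`decimate`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import EEGRecording


@dataclass
class GFPSeries:
    """Global field power curve with the retained peak sample indices."""

    values: np.ndarray
    peak_indices: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        if (self.values < 0).any():
            raise ValueError("GFP values must be nonnegative")
        if self.peak_indices.size and (np.diff(self.peak_indices) <= 0).any():
            raise ValueError("peak indices must be strictly increasing")


def bandpass_filter(rec: EEGRecording, low: float, high: float,
                    order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass.

    The filter is applied forward and backward (``sosfiltfilt``) so the
    topography at each instant is not shifted in time; the stated ``order``
    is the design order of the underlying one-pass filter.
    """
    nyq = rec.sampling_rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyq} Hz)"
        )
    if order < 1:
        raise ValueError("filter order must be >= 1")
    sos = signal.butter(order, [low, high], btype="bandpass",
                        fs=rec.sampling_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(data=filtered)


def average_reference(rec: EEGRecording) -> EEGRecording:
    """Subtract the instantaneous mean across channels from every sample."""
    if rec.n_channels < 2:
        raise ValueError("average reference requires at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy_with(data=data, reference="average")


def gfp(data: np.ndarray) -> np.ndarray:
    """Per-sample GFP: population standard deviation across channels.

    ``data`` is channels x samples; the divisor is the channel count C
    (population convention), so for an average-referenced sample
    ``GFP**2 = ||s||**2 / C``.
    """
    data = np.asarray(data, dtype=float)
    return data.std(axis=0, ddof=0)


def compute_gfp(rec: EEGRecording) -> GFPSeries:
    """GFP curve of a recording, with all strict local maxima as peaks."""
    values = gfp(rec.data)
    peaks, _ = signal.find_peaks(values)
    return GFPSeries(values=values, peak_indices=peaks)


def extract_gfp_peaks(series: GFPSeries, min_separation: float = 10.0,
                      sampling_rate: float = 256.0) -> GFPSeries:
    """Local maxima of the GFP curve at least ``min_separation`` ms apart.

    When two candidate peaks fall within the separation window the larger
    GFP value wins; an exact tie keeps the earlier index. Interior maxima
    only — the series endpoints are never peaks.
    """
    if min_separation < 0:
        raise ValueError("min_separation must be >= 0")
    if series.values.size == 0:
        raise ValueError("empty GFP series")
    distance = max(1, int(round(min_separation * sampling_rate / 1000.0)))
    # find_peaks ranks candidates by height, earlier index first on ties,
    # which implements the documented tie-break.
    peaks, _ = signal.find_peaks(series.values, distance=distance)
    return GFPSeries(values=series.values, peak_indices=peaks)


def standardize_samples(maps: np.ndarray) -> np.ndarray:
    """Z-score each topographic map across channels.

    ``maps`` is n_maps x n_channels; every row is shifted to zero mean and
    scaled to unit (population) standard deviation. Zero-variance rows are
    rejected because they carry no topography.
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    mean = maps.mean(axis=1, keepdims=True)
    sd = maps.std(axis=1, ddof=0, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        raise ValueError(
            f"zero-variance map(s) at row(s) {bad.tolist()}: cannot standardize"
        )
    return (maps - mean) / sd


def decimate(rec: EEGRecording, target_rate: float) -> EEGRecording:
    """Anti-alias filtered downsampling (spectral path).

    The decimation factor must be an integer ratio of the current rate.
    """
    factor = rec.sampling_rate / target_rate
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(
            f"target rate {target_rate} Hz is not an integer divisor of "
            f"{rec.sampling_rate} Hz"
        )
    factor = int(round(factor))
    if factor == 1:
        return rec.copy_with(data=rec.data.copy())
    data = signal.decimate(rec.data, factor, axis=1, zero_phase=True)
    return rec.copy_with(data=data, sampling_rate=target_rate)


def repair_artifacts(rec: EEGRecording, method: str = "none") -> EEGRecording:
    """Artifact-repair hook.

    Synthetic recordings are artifact-free, so the default (and only
    built-in) method is the identity. The hook exists so an ICA-based
    pipeline can be slotted in front of the microstate path without
    changing downstream code.
    """
    if method != "none":
        raise ValueError(f"unknown artifact repair method: {method!r}")
    return rec
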