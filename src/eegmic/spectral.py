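"""Delta/theta band-power ratio, normative z-transform, region averaging.

The delta (1-4 Hz) to theta (4-8 Hz) absolute-power ratio decreases with
encephalopathy severity. Per channel, the ratio is computed from a
Welch-averaged spectrum, log-transformed, and z-scored against a normative
reference (per-channel mean and SD of the log ratio in a healthy
population), with the z clipped to [-3, 3] as is conventional in
quantitative-EEG reporting. Channel-level values can be aggregated into
nine standard scalp regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.integrate import trapezoid

from .recording import EEGRecording

__all__ = [
    "DELTA_BAND", "THETA_BAND", "NINE_REGIONS", "BandPowerTable",
    "NormativeReference", "band_power", "delta_theta_ratio", "zscore_ratio",
    "regional_means", "reference_from_ratios", "synthetic_normative_reference",
]

DELTA_BAND = (1.0, 4.0)
THETA_BAND = (4.0, 8.0)
Z_CLIP = 3.0

#: Nine-region aggregation of the 19-channel montage. Note the composite
#: frontal/temporal regions average their electrodes directly, not the
#: sub-region means.
NINE_REGIONS: dict[str, list[str]] = {
    "left_frontal": ["Fp1", "F3", "F7"],
    "right_frontal": ["Fp2", "F4", "F8"],
    "frontal": ["Fp2", "F4", "F8", "Fz", "Fp1", "F3", "F7"],
    "central": ["C3", "Cz", "C4"],
    "left_temporal": ["T3", "T5"],
    "right_temporal": ["T4", "T6"],
    "temporal": ["T4", "T6", "T3", "T5"],
    "parietal": ["P3", "P4", "Pz"],
    "occipital": ["O1", "O2"],
}


@dataclass
class NormativeReference:
    """Per-channel normative mean/SD of the log delta/theta ratio."""

    table: pd.DataFrame   # columns: channel, mean_log_ratio, sd_log_ratio

    def __post_init__(self) -> None:
        required = {"channel", "mean_log_ratio", "sd_log_ratio"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"reference table lacks columns: {sorted(missing)}")
        if (self.table["sd_log_ratio"] <= 0).any():
            raise ValueError("reference SDs must be > 0")

    def lookup(self, channels: list[str]) -> tuple[np.ndarray, np.ndarray]:
        idx = self.table.set_index("channel")
        absent = [c for c in channels if c not in idx.index]
        if absent:
            raise ValueError(f"channels missing from normative reference: {absent}")
        sub = idx.loc[channels]
        return (sub["mean_log_ratio"].to_numpy(dtype=float),
                sub["sd_log_ratio"].to_numpy(dtype=float))

    @classmethod
    def read_csv(cls, path) -> "NormativeReference":
        return cls(pd.read_csv(path))

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class BandPowerTable:
    """Per-channel delta/theta powers, ratio, and clipped z-ratio."""

    channels: list[str]
    delta_power: np.ndarray
    theta_power: np.ndarray
    ratio: np.ndarray
    z_ratio: np.ndarray | None = None
    flagged_channels: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        data = {"channel": self.channels, "delta_power": self.delta_power,
                "theta_power": self.theta_power, "ratio": self.ratio}
        if self.z_ratio is not None:
            data["z_ratio"] = self.z_ratio
        return pd.DataFrame(data)


def band_power(rec: EEGRecording, band: tuple[float, float],
               window_seconds: float = 2.0) -> np.ndarray:
    """Absolute band power per channel from a Welch spectrum.

    Hann windows of ``window_seconds`` with 50% overlap; the power spectral
    density is integrated (trapezoid) over ``band``, so contiguous bands
    partition the total power exactly.
    """
    low, high = band
    nyq = rec.sampling_rate / 2.0
    if not (0 < low < high <= nyq):
        raise ValueError(f"band {band} outside (0, {nyq}] Hz")
    nperseg = int(round(window_seconds * rec.sampling_rate))
    if rec.n_samples < nperseg:
        raise ValueError(
            f"recording shorter than one {window_seconds} s Welch window")
    freqs, psd = signal.welch(rec.data, fs=rec.sampling_rate, window="hann",
                              nperseg=nperseg, noverlap=nperseg // 2, axis=1)
    mask = (freqs >= low) & (freqs <= high)
    if mask.sum() < 2:
        raise ValueError("band too narrow for the spectral resolution")
    return trapezoid(psd[:, mask], freqs[mask], axis=1)


def delta_theta_ratio(rec: EEGRecording,
                      window_seconds: float = 2.0) -> BandPowerTable:
    """Delta/theta absolute power ratio per channel.

    Channels with (numerically) zero theta power get a NaN ratio and are
    listed in ``flagged_channels``.
    """
    delta = band_power(rec, DELTA_BAND, window_seconds)
    theta = band_power(rec, THETA_BAND, window_seconds)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(theta > 0, delta / np.where(theta > 0, theta, 1.0),
                         np.nan)
    flagged = [rec.channel_names[i] for i in np.flatnonzero(theta <= 0)]
    return BandPowerTable(channels=list(rec.channel_names), delta_power=delta,
                          theta_power=theta, ratio=ratio,
                          flagged_channels=flagged)


def zscore_ratio(table: BandPowerTable,
                 ref: NormativeReference) -> BandPowerTable:
    """Z-transform log ratios against the normative reference, clip to +/-3."""
    mean, sd = ref.lookup(table.channels)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (np.log(table.ratio) - mean) / sd
    table.z_ratio = np.clip(z, -Z_CLIP, Z_CLIP)
    return table


def regional_means(values: dict[str, float] | pd.Series,
                   regions: dict[str, list[str]] | None = None) -> pd.Series:
    """Unweighted mean of a per-channel quantity over each named region."""
    regions = regions if regions is not None else NINE_REGIONS
    if isinstance(values, dict):
        values = pd.Series(values)
    out = {}
    for region, electrodes in regions.items():
        absent = [e for e in electrodes if e not in values.index]
        if absent:
            raise ValueError(f"region {region!r} needs missing electrodes {absent}")
        out[region] = float(values.loc[electrodes].mean())
    return pd.Series(out)


def reference_from_ratios(channels: list[str],
                          ratios: np.ndarray) -> NormativeReference:
    """Build a normative reference from raw ratios of reference subjects.

    ``ratios`` is n_subjects x n_channels of delta/theta ratios; the
    reference stores the mean and (sample) SD of the log ratio per channel.
    """
    ratios = np.atleast_2d(np.asarray(ratios, dtype=float))
    if ratios.shape[0] < 2:
        raise ValueError("need at least 2 reference subjects")
    logs = np.log(ratios)
    return NormativeReference(pd.DataFrame({
        "channel": channels,
        "mean_log_ratio": logs.mean(axis=0),
        "sd_log_ratio": logs.std(axis=0, ddof=1),
    }))


def synthetic_normative_reference(n_subjects: int = 100,
                                  duration: float = 60.0,
                                  seed: int = 0) -> NormativeReference:
    """Normative reference from simulated 'healthy' recordings.

    The proprietary normative databases behind commercial QEEG tools are
    not redistributable; this generator produces a self-consistent
    reference for the z-pipeline from the package's own synthetic EEG
    (band components at 2 and 6 Hz with subject-varying amplitudes).
    """
    from .synthetic import SyntheticSpec, simulate_label_sequence, synthesize_eeg

    rng = np.random.default_rng(seed)
    ratios = []
    channels = None
    for i in range(n_subjects):
        amp_d = rng.lognormal(0.0, 0.2)
        amp_t = rng.lognormal(0.0, 0.2)
        spec = SyntheticSpec(band_components=((2.0, amp_d), (6.0, amp_t)),
                             seed=int(rng.integers(2**31 - 1)))
        truth = simulate_label_sequence(spec, duration)
        rec = synthesize_eeg(truth, spec)
        table = delta_theta_ratio(rec)
        ratios.append(table.ratio)
        channels = table.channels
    return reference_from_ratios(channels, np.array(ratios))
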