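"""Core in-memory container for multichannel EEG.

An :class:`EEGRecording` holds a channels-by-samples matrix in microvolts
together with the sampling rate, ordered channel names and the reference
used during acquisition. All downstream stages (filtering, global field
power, microstate clustering, band power) operate on this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: The 19 scalp electrodes of the international 10-20 system, in the
#: conventional anterior-to-posterior, left-to-right order. Older temporal
#: names (T3/T4/T5/T6) are used; modern synonyms are normalized on read.
TEN_TWENTY_19 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
]

#: Modern (10-10 style) synonyms for the older temporal electrode names.
CHANNEL_SYNONYMS = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}


def normalize_channel_name(name: str) -> str:
    """Map a 10-20 channel label to its canonical form (e.g. ``T7`` -> ``T3``).

    Case is normalized against the canonical 19-channel list; unknown labels
    are returned stripped but otherwise untouched.
    """
    stripped = name.strip()
    canon = {c.upper(): c for c in TEN_TWENTY_19}
    upper = stripped.upper()
    upper = CHANNEL_SYNONYMS.get(upper, CHANNEL_SYNONYMS.get(stripped, upper))
    if isinstance(upper, str) and upper.upper() in canon:
        return canon[upper.upper()]
    return stripped


@dataclass
class EEGRecording:
    """Multichannel EEG as a channels x samples microvolt matrix.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    sampling_rate
        Sampling frequency in Hz; must be positive.
    channel_names
        Ordered, unique channel labels, one per data row.
    reference
        Acquisition reference label (e.g. ``"A1"``, ``"average"``).
    """

    data: np.ndarray
    sampling_rate: float
    channel_names: list[str] = field(default_factory=list)
    reference: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains NaN or infinite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def copy_with(self, **changes) -> "EEGRecording":
        """Return a copy with ``data``/metadata fields replaced."""
        return replace(self, **changes)
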