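"""Readers and writers: EDF recordings, cohort CSV, ground-truth JSON.

EDF (European Data Format) is the standard interchange format for clinical
EEG. Reading goes through MNE; writing uses a minimal EDF encoder (ASCII
header + 16-bit samples) sufficient for uniform-rate multichannel EEG,
since no installed library exposes an EDF writer.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import EEGRecording, normalize_channel_name, TEN_TWENTY_19
from .synthetic import GroundTruth

__all__ = ["read_edf", "write_edf", "write_ground_truth",
           "read_ground_truth", "write_cohort_csv", "read_cohort_csv"]

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    raw = text.encode("ascii")[:width]
    return raw + b" " * (width - len(raw))


def write_edf(rec: EEGRecording, path) -> None:
    """Write a recording as EDF with 1-second data records.

    The sampling rate must be an integer; the trailing partial second is
    zero-padded. Physical units are microvolts; amplitude resolution is
    the per-channel physical range over the 16-bit digital range.
    """
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_records = int(np.ceil(rec.n_samples / fs))
    data = np.zeros((rec.n_channels, n_records * fs))
    data[:, :rec.n_samples] = rec.data

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max - phys_min < 1e-9
    phys_min = np.where(flat, phys_min - 1.0, phys_min)
    phys_max = np.where(flat, phys_max + 1.0, phys_max)

    ns = rec.n_channels
    header = b"".join([
        _pad("0", 8), _pad("X X X X", 80), _pad("Startdate X X X X", 80),
        _pad("01.01.00", 8), _pad("00.00.00", 8),
        _pad(str(256 * (ns + 1)), 8), _pad("", 44),
        _pad(str(n_records), 8), _pad("1", 8), _pad(str(ns), 4),
    ])
    fields = [
        [_pad(f"EEG {name}", 16) for name in rec.channel_names],
        [_pad("", 80)] * ns,
        [_pad("uV", 8)] * ns,
        [_pad(f"{v:.6g}"[:8], 8) for v in phys_min],
        [_pad(f"{v:.6g}"[:8], 8) for v in phys_max],
        [_pad(str(_EDF_DIG_MIN), 8)] * ns,
        [_pad(str(_EDF_DIG_MAX), 8)] * ns,
        [_pad("", 80)] * ns,
        [_pad(str(fs), 8)] * ns,
        [_pad("", 32)] * ns,
    ]
    header += b"".join(b"".join(f) for f in fields)

    # use the physical min/max actually parsed back from the 8-char header
    # fields so that digitization is exactly invertible on read
    pmin = np.array([float(f"{v:.6g}"[:8]) for v in phys_min])
    pmax = np.array([float(f"{v:.6g}"[:8]) for v in phys_max])
    gain = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (pmax - pmin)
    digital = np.rint((data - pmin[:, None]) * gain[:, None] + _EDF_DIG_MIN)
    digital = np.clip(digital, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = digital[:, r * fs:(r + 1) * fs]
            fh.write(block.tobytes())


def _check_edf_size(path: Path) -> None:
    """Reject truncated EDF files instead of silently reading less data."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError(f"truncated EDF header in {path}")
        try:
            n_records = int(head[236:244].decode("ascii").strip())
            ns = int(head[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise ValueError(f"unreadable EDF header in {path}: {exc}") from exc
        sig_head = fh.read(256 * ns)
        if len(sig_head) < 256 * ns:
            raise ValueError(f"truncated EDF signal header in {path}")
        spr_field = sig_head[ns * 216:ns * 216 + ns * 8]
        samples_per_record = [int(spr_field[i * 8:(i + 1) * 8].decode().strip())
                              for i in range(ns)]
    expected = 256 * (ns + 1) + n_records * 2 * sum(samples_per_record)
    actual = path.stat().st_size
    if n_records >= 0 and actual < expected:
        raise ValueError(
            f"truncated EDF file {path}: {actual} bytes, header promises "
            f"{expected}")


def read_edf(path, normalize_names: bool = True) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (microvolts).

    Channel labels are normalized to canonical 10-20 names where a synonym
    is recognized (e.g. ``T7`` -> ``T3``); unknown labels are preserved.
    Raises on unreadable or truncated files.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_edf_size(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise ValueError(f"could not parse EDF file {path}: {exc}") from exc
    sfreqs = {raw.info["sfreq"]}
    if len(sfreqs) != 1:
        raise ValueError("mixed sampling rates are not supported")
    data = raw.get_data() * 1e6      # volts -> microvolts
    names = [n.removeprefix("EEG ").strip() for n in raw.ch_names]
    if normalize_names:
        names = [normalize_channel_name(n) for n in names]
    return EEGRecording(data=data, sampling_rate=float(raw.info["sfreq"]),
                        channel_names=names)


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Serialize planted ground truth (labels, segments, prototypes) as JSON."""
    payload = {
        "sampling_rate": truth.sampling_rate,
        "label_sequence": truth.label_sequence.tolist(),
        "segment_table": [list(s) for s in truth.segment_table],
        "prototypes": {
            "maps": truth.true_prototypes.maps.tolist(),
            "class_labels": truth.true_prototypes.class_labels,
        },
        "parameters": truth.true_parameters.as_dict(),
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Cohort table CSV: subject_id, group, MIS, twelve parameter columns."""
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "group", "mis"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV lacks columns: {sorted(missing)}")
    return df
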