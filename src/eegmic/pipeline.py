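"""End-to-end pipeline: preprocess -> cluster -> backfit -> parameters -> MIC.

The driver mirrors how a resting-state microstate study is analyzed:
per-group concatenated GFP-peak maps are clustered once (group-level
prototypes), the prototypes are ordered against canonical templates, every
subject's recording is backfitted and smoothed with the group prototypes,
per-subject parameters are extracted, and the biomarker indices and
classifier report are computed over the pooled cohort. All randomness
flows from the single configured seed and every output carries the config
hash, so re-runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biomarker import biomarker_table, classify_mic
from .microstates import (backfit, canonical_templates, modified_kmeans,
                          order_prototypes, segment_statistics,
                          smooth_segments)
from .preprocess import (average_reference, bandpass_filter, compute_gfp,
                         extract_gfp_peaks, standardize_samples)
from .recording import EEGRecording

__all__ = ["PipelineConfig", "SubjectInput", "run_pipeline",
           "subject_parameters"]


@dataclass
class SubjectInput:
    subject_id: str
    group: str                       # "H" or "L"
    recording: EEGRecording | None = None
    edf_path: str | None = None
    mis: int | None = None


@dataclass
class PipelineConfig:
    """Validated settings for the full microstate pipeline."""

    k_classes: int = 4
    n_restarts: int = 20
    filter_low: float = 1.0
    filter_high: float = 40.0
    filter_order: int = 4
    min_peak_separation_ms: float = 10.0
    smooth_min_duration_ms: float = 30.0
    test_fraction: float = 0.3
    n_splits: int = 100
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.k_classes < 2:
            raise ValueError("k_classes must be >= 2")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if not (0 < self.filter_low < self.filter_high):
            raise ValueError("invalid filter band")
        if self.filter_order < 1:
            raise ValueError("filter order must be >= 1")
        if self.min_peak_separation_ms < 0 or self.smooth_min_duration_ms < 0:
            raise ValueError("durations must be >= 0")
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must be in (0, 1)")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))

    def config_hash(self) -> str:
        """Fingerprint of the analysis settings (output location excluded)."""
        settings = asdict(self)
        settings.pop("out_dir")
        text = json.dumps(settings, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _preprocessed_peak_maps(rec: EEGRecording, cfg: PipelineConfig):
    """Filter, average-reference, and return standardized GFP-peak maps
    plus the full preprocessed recording."""
    rec = bandpass_filter(rec, cfg.filter_low, cfg.filter_high,
                          cfg.filter_order)
    rec = average_reference(rec)
    series = compute_gfp(rec)
    peaks = extract_gfp_peaks(series, cfg.min_peak_separation_ms,
                              rec.sampling_rate)
    maps = rec.data[:, peaks.peak_indices].T
    return standardize_samples(maps), rec


def subject_parameters(rec: EEGRecording, prototypes, cfg: PipelineConfig,
                       preprocessed: bool = False):
    """Backfit + smooth + parameters for one subject with given prototypes."""
    if not preprocessed:
        rec = bandpass_filter(rec, cfg.filter_low, cfg.filter_high,
                              cfg.filter_order)
        rec = average_reference(rec)
    seg = backfit(rec.data.T, prototypes)
    seg = smooth_segments(seg, rec.data.T, prototypes,
                          cfg.smooth_min_duration_ms, rec.sampling_rate)
    return segment_statistics(seg, rec.sampling_rate,
                              class_labels=prototypes.class_labels,
                              k_classes=prototypes.k_classes)


def run_pipeline(subjects: list[SubjectInput],
                 config: PipelineConfig) -> dict:
    """Run the full analysis over a cohort of recordings.

    Returns a bundle with the per-group prototypes, the per-subject
    parameter table, the biomarker table, the classifier report and a
    provenance record. When ``config.out_dir`` is set, the tables are also
    written as CSV/JSON.
    """
    if not subjects:
        raise ValueError("no subjects given")
    groups = sorted({s.group for s in subjects})

    recordings: dict[str, EEGRecording] = {}
    for s in subjects:
        if s.recording is not None:
            recordings[s.subject_id] = s.recording
        elif s.edf_path:
            from .io import read_edf
            recordings[s.subject_id] = read_edf(s.edf_path)
        else:
            raise ValueError(f"subject {s.subject_id}: no recording or EDF path")

    # group-level clustering on concatenated standardized GFP-peak maps
    templates = canonical_templates()
    prototypes_by_group = {}
    preproc: dict[str, EEGRecording] = {}
    rng = np.random.default_rng(config.seed)
    for group in groups:
        stacked = []
        for s in subjects:
            if s.group != group:
                continue
            maps, rec = _preprocessed_peak_maps(recordings[s.subject_id], config)
            preproc[s.subject_id] = rec
            stacked.append(maps)
        stacked = np.vstack(stacked)
        protos, _seg, _diag = modified_kmeans(
            stacked, k=config.k_classes, n_restarts=config.n_restarts,
            seed=rng)
        if protos.n_channels == templates.n_channels:
            protos, _score = order_prototypes(protos, templates)
        prototypes_by_group[group] = protos

    rows = []
    for s in subjects:
        params = subject_parameters(preproc[s.subject_id],
                                    prototypes_by_group[s.group], config,
                                    preprocessed=True)
        row = {"subject_id": s.subject_id, "group": s.group, "mis": s.mis}
        row.update(params.as_dict())
        rows.append(row)
    param_df = pd.DataFrame(rows)

    bio = biomarker_table(param_df)
    report = classify_mic(param_df, test_fraction=config.test_fraction,
                          n_splits=config.n_splits, seed=config.seed)

    provenance = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": json.loads(config.to_json()),
        "config_hash": config.config_hash(),
        "n_subjects": len(subjects),
        "groups": groups,
    }
    bundle = {
        "prototypes": prototypes_by_group,
        "parameters": param_df,
        "biomarkers": bio,
        "classifier": report,
        "provenance": provenance,
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        hash_comment = config.config_hash()
        param_out = param_df.copy()
        param_out["config_hash"] = hash_comment
        param_out.to_csv(out / "parameters.csv", index=False,
                         float_format="%.10g")
        bio_out = bio.table.copy()
        bio_out["config_hash"] = hash_comment
        bio_out.to_csv(out / "biomarkers.csv", index=False,
                       float_format="%.10g")
        (out / "classifier.json").write_text(json.dumps(
            {**report.as_dict(), "config_hash": hash_comment}, indent=1))
        (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return bundle
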