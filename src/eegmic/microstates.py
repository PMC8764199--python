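"""Polarity-invariant microstate clustering, backfitting and parameters.

EEG microstates are brief (~80-120 ms) periods during which the scalp
topography stays quasistable. The model is

    s_n = i_kn * m_k + a_n,    k = l_n,

where ``s_n`` is the topographic map at sample ``n``, ``m_k`` the unit-norm
prototype of class ``k``, ``i_kn`` the signed intensity (polarity carries no
class information) and ``a_n`` zero-mean noise. Clustering maximizes the
squared projection of each sample onto its prototype — the "modified
k-means" of the microstate literature — rather than Euclidean proximity,
which makes the fit invariant to map polarity.

Fit quality is summarized by the global explained variance

    GEV = sum_n CS_n^2 * GFP_n^2 / sum_n GFP_n^2,

the squared cosine similarity between each sample and its assigned
prototype, weighted by the sample's share of squared global field power.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.optimize import linear_sum_assignment

from .preprocess import gfp

__all__ = [
    "PrototypeSet", "Segmentation", "MicrostateParameters",
    "activation", "cosine_similarity", "assign_labels",
    "global_explained_variance", "modified_kmeans", "backfit",
    "smooth_segments", "segments_from_labels", "segment_statistics",
    "parameters_from_segments", "order_prototypes", "canonical_templates",
]

CLASS_NAMES = ("A", "B", "C", "D", "E", "F", "G", "H")


@dataclass
class PrototypeSet:
    """K unit-norm topographic prototype maps with class labels."""

    maps: np.ndarray                       # K x C, rows unit-norm
    class_labels: list[str] = field(default_factory=list)
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        norms = np.linalg.norm(self.maps, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("prototype maps must be unit-norm")
        if not self.class_labels:
            self.class_labels = list(CLASS_NAMES[: self.maps.shape[0]])
        if len(self.class_labels) != self.maps.shape[0]:
            raise ValueError("one class label per prototype map required")
        gram = self.maps @ self.maps.T
        off = gram[~np.eye(len(gram), dtype=bool)]
        if off.size and (off**2 >= 1.0 - 1e-12).any():
            raise ValueError("distinct prototypes must not be collinear")

    @property
    def k_classes(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


@dataclass
class Segmentation:
    """Per-sample microstate labelling of a recording.

    ``segments`` is a list of ``(class_index, start_sample, length)`` tuples
    tiling the sample axis.
    """

    labels: np.ndarray            # (N,) int class indices
    activations: np.ndarray       # (N,) signed intensity of assigned class
    similarities: np.ndarray      # (N,) cosine similarity to assigned map
    gev: float
    segments: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.activations = np.asarray(self.activations, dtype=float)
        self.similarities = np.asarray(self.similarities, dtype=float)
        if not self.segments:
            self.segments = segments_from_labels(self.labels)
        if not (0.0 - 1e-12 <= self.gev <= 1.0 + 1e-12):
            raise ValueError(f"GEV {self.gev} outside [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.labels.size


@dataclass
class MicrostateParameters:
    """Coverage (%), mean duration (ms) and occurrence (Hz) per class.

    ``duration`` entries are NaN for classes with no interior (untruncated)
    segment; such classes have occurrence 0 and are listed in
    ``degenerate_classes``. ``average_duration`` is the unweighted mean of
    the defined per-class durations.
    """

    class_labels: list[str]
    coverage: np.ndarray       # %, sums to ~100
    duration: np.ndarray       # ms, NaN when undefined
    occurrence: np.ndarray     # Hz
    average_duration: float    # ms
    gev: float = float("nan")
    mean_similarity: float = float("nan")
    degenerate_classes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for i, lab in enumerate(self.class_labels):
            out[f"coverage_{lab}"] = float(self.coverage[i])
            out[f"duration_{lab}"] = float(self.duration[i])
            out[f"occurrence_{lab}"] = float(self.occurrence[i])
        out["average_duration"] = float(self.average_duration)
        out["gev"] = float(self.gev)
        out["mean_similarity"] = float(self.mean_similarity)
        return out


# ---------------------------------------------------------------------------
# elementary quantities


def activation(sample: np.ndarray, prototype: np.ndarray) -> float:
    """Signed intensity of a prototype in a sample: the dot product."""
    sample = np.asarray(sample, dtype=float)
    prototype = np.asarray(prototype, dtype=float)
    if sample.shape != prototype.shape:
        raise ValueError("sample and prototype must have equal length")
    return float(sample @ prototype)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two maps; in [-1, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero-norm map")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def _label_samples(samples: np.ndarray, maps: np.ndarray):
    """Vectorized Eq-style labelling: argmax_k (s_n . m_k)^2.

    Ties go to the lowest class index (np.argmax convention). Returns
    (labels, activations-of-assigned-class, full activation matrix).
    """
    acts = samples @ maps.T                     # N x K
    labels = np.argmax(acts**2, axis=1)
    assigned = acts[np.arange(len(labels)), labels]
    return labels, assigned, acts


def assign_labels(samples: np.ndarray, prototypes: PrototypeSet) -> Segmentation:
    """Label every map by its most intense prototype (polarity-invariant)."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.size == 0:
        raise ValueError("empty sample set")
    if samples.shape[1] != prototypes.n_channels:
        raise ValueError("channel count mismatch between samples and prototypes")
    labels, assigned, _ = _label_samples(samples, prototypes.maps)
    norms = np.linalg.norm(samples, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cs = np.where(norms > 0, assigned / np.where(norms > 0, norms, 1.0), 0.0)
    gev_val = global_explained_variance(samples, prototypes, labels)
    return Segmentation(labels=labels, activations=assigned,
                        similarities=cs, gev=gev_val)


def global_explained_variance(samples: np.ndarray, prototypes: PrototypeSet,
                              labels: np.ndarray) -> float:
    """GEV of a labelling: squared-cosine weighted by squared-GFP share."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    labels = np.asarray(labels, dtype=int)
    gfp_sq = gfp(samples.T) ** 2
    total = gfp_sq.sum()
    if total == 0:
        raise ValueError("GEV undefined: all samples have zero GFP")
    acts = np.einsum("nc,nc->n", samples, prototypes.maps[labels])
    norms_sq = np.einsum("nc,nc->n", samples, samples)
    with np.errstate(invalid="ignore", divide="ignore"):
        cs_sq = np.where(norms_sq > 0, acts**2 / np.where(norms_sq > 0, norms_sq, 1.0), 0.0)
    return float(np.sum(cs_sq * gfp_sq) / total)


# ---------------------------------------------------------------------------
# modified k-means


def _dominant_eigenvector(class_samples: np.ndarray) -> np.ndarray:
    """Unit-norm dominant eigenvector of the within-class outer-product sum.

    This is the polarity-invariant fixed point of the squared-projection
    loss: it maximizes sum_n (s_n . m)^2 over unit-norm m.
    """
    cov = class_samples.T @ class_samples
    vals, vecs = np.linalg.eigh(cov)
    v = vecs[:, -1]
    return v / np.linalg.norm(v)


def modified_kmeans(samples: np.ndarray, k: int, n_restarts: int = 20,
                    max_iter: int = 1000, tol: float = 1e-6,
                    seed: int | np.random.Generator | None = None,
                    class_labels: list[str] | None = None,
                    ) -> tuple[PrototypeSet, Segmentation, dict]:
    """Polarity-invariant modified k-means over topographic maps.

    Alternates labelling (argmax squared intensity) with prototype updates
    (dominant eigenvector of each class's sample outer-product matrix)
    until the relative change of the loss

        E = sum_n ( ||s_n||^2 - (s_n . m_{l_n})^2 )

    drops below ``tol`` or ``max_iter`` is reached. Of ``n_restarts``
    random initializations the run with maximum GEV is returned. Empty
    classes are re-seeded from the currently worst-fit sample.

    Returns ``(prototypes, segmentation, diagnostics)``; diagnostics holds
    per-restart iteration counts, convergence flags and the loss trace of
    the winning run.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    n, c = samples.shape
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot fit {k} classes to {n} samples")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    norms_sq = np.einsum("nc,nc->n", samples, samples)
    total_norm_sq = norms_sq.sum()

    best = None
    diag: dict = {"restarts": []}
    for _ in range(n_restarts):
        idx = rng.choice(n, size=k, replace=False)
        maps = samples[idx].astype(float).copy()
        row_norms = np.linalg.norm(maps, axis=1)
        if (row_norms == 0).any():   # degenerate zero samples as seeds
            maps[row_norms == 0] = rng.standard_normal((int((row_norms == 0).sum()), c))
            row_norms = np.linalg.norm(maps, axis=1)
        maps /= row_norms[:, None]

        prev_e = np.inf
        trace = []
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            labels, assigned, _ = _label_samples(samples, maps)
            # re-seed empty classes from the worst-fit sample
            for ki in range(k):
                if not (labels == ki).any():
                    with np.errstate(invalid="ignore", divide="ignore"):
                        fit = np.where(norms_sq > 0, assigned**2 / norms_sq, 1.0)
                    worst = int(np.argmin(fit))
                    maps[ki] = samples[worst] / np.linalg.norm(samples[worst])
                    labels, assigned, _ = _label_samples(samples, maps)
            for ki in range(k):
                members = samples[labels == ki]
                if len(members):
                    maps[ki] = _dominant_eigenvector(members)
            labels, assigned, _ = _label_samples(samples, maps)
            e = float(total_norm_sq - np.sum(assigned**2))
            trace.append(e)
            if prev_e < np.inf and abs(prev_e - e) <= tol * max(e, 1e-300):
                converged = True
                break
            prev_e = e

        gev_val = global_explained_variance(
            samples, _raw_prototype_set(maps, class_labels), labels)
        diag["restarts"].append({"n_iter": n_iter, "converged": converged,
                                 "gev": gev_val, "final_loss": trace[-1]})
        if best is None or gev_val > best[0]:
            best = (gev_val, maps.copy(), trace)

    gev_val, maps, trace = best
    protos = _raw_prototype_set(maps, class_labels)
    seg = assign_labels(samples, protos)
    diag["loss_trace"] = trace
    diag["gev"] = seg.gev
    return protos, seg, diag


def _raw_prototype_set(maps: np.ndarray, class_labels: list[str] | None) -> PrototypeSet:
    labels = class_labels or list(CLASS_NAMES[: maps.shape[0]])
    return PrototypeSet(maps=maps, class_labels=list(labels))


# ---------------------------------------------------------------------------
# backfitting and temporal smoothing


def backfit(samples: np.ndarray, prototypes: PrototypeSet) -> Segmentation:
    """Label every sample of a recording by its most similar prototype.

    Identical contract to :func:`assign_labels`; the distinct name marks
    the stage where group-level prototypes are fitted back onto each
    individual recording (all samples, not only GFP peaks).
    """
    return assign_labels(samples, prototypes)


def segments_from_labels(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode a label sequence into (class, start, length)."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return [(int(labels[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def smooth_segments(seg: Segmentation, samples: np.ndarray,
                    prototypes: PrototypeSet, min_duration: float,
                    sampling_rate: float) -> Segmentation:
    """Small-segment rejection smoothing.

    Interior segments shorter than ``min_duration`` (ms) are iteratively
    dissolved: each of their samples is reassigned to whichever of the two
    flanking segments' classes has the larger squared intensity for that
    sample. Segments touching the recording edges are exempt (their true
    length is unknown) but remain flagged as truncated downstream.
    """
    if min_duration < 0:
        raise ValueError("min_duration must be >= 0")
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    n = samples.shape[0]
    min_samples = int(np.ceil(min_duration * sampling_rate / 1000.0))
    if min_samples > n:
        raise ValueError("min_duration exceeds the recording length")

    labels = seg.labels.copy()
    acts = samples @ prototypes.maps.T        # N x K, reused every pass
    for _ in range(n):                        # passes; always terminates earlier
        segments = segments_from_labels(labels)
        short = [i for i in range(1, len(segments) - 1)
                 if segments[i][2] < min_samples]
        if not short:
            break
        # dissolve the shortest offender first; one per pass keeps the
        # neighbour classes well-defined
        i = min(short, key=lambda j: (segments[j][2], j))
        cls, start, length = segments[i]
        left_cls = segments[i - 1][0]
        right_cls = segments[i + 1][0]
        sl = slice(start, start + length)
        take_left = acts[sl, left_cls] ** 2 >= acts[sl, right_cls] ** 2
        labels[sl] = np.where(take_left, left_cls, right_cls)

    assigned = acts[np.arange(n), labels]
    norms = np.linalg.norm(samples, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cs = np.where(norms > 0, assigned / np.where(norms > 0, norms, 1.0), 0.0)
    gev_val = global_explained_variance(samples, prototypes, labels)
    return Segmentation(labels=labels, activations=assigned,
                        similarities=cs, gev=gev_val)


# ---------------------------------------------------------------------------
# parameters


def parameters_from_segments(segments: list[tuple[int, int, int]],
                             n_samples: int, sampling_rate: float,
                             k_classes: int,
                             class_labels: list[str] | None = None,
                             ) -> MicrostateParameters:
    """Coverage/duration/occurrence from a segment table.

    Coverage counts every sample. Duration and occurrence use interior
    segments only: the first and last segments of the recording are
    truncated by the recording edges, so their lengths are biased low and
    they are excluded from those two statistics.
    """
    labels = class_labels or list(CLASS_NAMES[:k_classes])
    counts = np.zeros(k_classes)
    for cls, _start, length in segments:
        counts[cls] += length
    coverage = counts / max(n_samples, 1) * 100.0

    interior = segments[1:-1] if len(segments) > 2 else []
    dur_sum = np.zeros(k_classes)
    seg_count = np.zeros(k_classes)
    for cls, _start, length in interior:
        dur_sum[cls] += length
        seg_count[cls] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        duration = np.where(seg_count > 0,
                            dur_sum / np.maximum(seg_count, 1)
                            / sampling_rate * 1000.0,
                            np.nan)
    total_seconds = n_samples / sampling_rate
    occurrence = seg_count / total_seconds
    degenerate = [labels[i] for i in range(k_classes) if seg_count[i] == 0]
    defined = duration[~np.isnan(duration)]
    avg_dur = float(defined.mean()) if defined.size else float("nan")
    return MicrostateParameters(class_labels=list(labels), coverage=coverage,
                                duration=duration, occurrence=occurrence,
                                average_duration=avg_dur,
                                degenerate_classes=degenerate)


def segment_statistics(seg: Segmentation, sampling_rate: float,
                       class_labels: list[str] | None = None,
                       k_classes: int | None = None) -> MicrostateParameters:
    """Microstate parameters of a (smoothed) segmentation."""
    k = k_classes if k_classes is not None else int(seg.labels.max()) + 1
    params = parameters_from_segments(seg.segments, seg.n_samples,
                                      sampling_rate, k, class_labels)
    params.gev = seg.gev * 100.0
    sims = np.abs(seg.similarities)
    params.mean_similarity = float(sims.mean()) * 100.0
    return params


# ---------------------------------------------------------------------------
# canonical ordering


def canonical_templates() -> PrototypeSet:
    """Synthetic canonical A-D template maps on the 19-channel montage.

    Constructed from schematic 10-20 electrode positions to match the
    classical descriptions (A: right-frontal/left-posterior diagonal,
    B: mirrored diagonal, C: anterior-posterior, D: fronto-central focal);
    they are a synthetic stand-in, not empirical grand averages, and serve
    only to give recovered prototypes a reproducible A-D ordering.
    """
    text = resources.files("eegmic.data").joinpath(
        "synthetic_templates.json").read_text()
    payload = json.loads(text)
    return PrototypeSet(maps=np.array(payload["maps"], dtype=float),
                        class_labels=payload["class_labels"],
                        channel_names=payload["channel_names"])


def order_prototypes(prototypes: PrototypeSet,
                     templates: PrototypeSet | None = None,
                     ) -> tuple[PrototypeSet, float]:
    """Relabel prototypes by best one-to-one match to template maps.

    Solves the assignment problem maximizing the summed absolute cosine
    similarity (polarity-invariant) between prototype rows and template
    rows; returns the reordered set and the assignment score (sums to K
    for a perfect match).
    """
    templates = templates if templates is not None else canonical_templates()
    if prototypes.n_channels != templates.n_channels:
        raise ValueError("prototype/template channel count mismatch")
    p = prototypes.maps / np.linalg.norm(prototypes.maps, axis=1, keepdims=True)
    t = templates.maps / np.linalg.norm(templates.maps, axis=1, keepdims=True)
    score = np.abs(p @ t.T)                     # K x K_template
    rows, cols = linear_sum_assignment(-score)
    order = rows[np.argsort(cols)]
    new_maps = prototypes.maps[order]
    new_labels = [templates.class_labels[i] for i in sorted(cols)]
    total = float(score[rows, cols].sum())
    return PrototypeSet(maps=new_maps, class_labels=new_labels,
                        channel_names=prototypes.channel_names), total
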