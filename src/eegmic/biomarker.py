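"""MIC biomarker index and its classification performance.

The Malnutrition-Inflammation Cutoff (MIC) index condenses the microstate
parameters that move with malnutrition-inflammation severity into one
number per subject:

    AB_i  = [ Z(Occ_A + Occ_B) + Z(Cov_A + Cov_B) ] / 2
    C_i   = [ Z(Occ_C) + Z(Cov_C) + Z(Dur_C) ] / 3
    MIC_i = (AB_i - C_i) / 2

where Z is the z-transform against the mean and SD of the analyzed cohort
(both groups pooled). A positive MIC flags a high risk of
malnutrition-inflammation complex syndrome; the zero-cutoff rule and a
single-feature logistic regression with stratified train/test splits are
both reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import train_test_split

__all__ = [
    "BiomarkerTable", "ClassifierReport", "ab_index", "c_index", "mic_index",
    "biomarker_table", "classify_mic", "zero_cutoff_accuracy",
]


def _cohort_z(values: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Z-score against the pooled cohort (population SD by default)."""
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=ddof)
    if sd == 0:
        raise ValueError("zero cohort variance: z-score undefined")
    return (values - values.mean()) / sd


def _col(cohort: pd.DataFrame, name: str) -> np.ndarray:
    if name not in cohort.columns:
        raise ValueError(f"cohort table lacks column {name!r}")
    return cohort[name].to_numpy(dtype=float)


def ab_index(cohort: pd.DataFrame, ddof: int = 0) -> np.ndarray:
    """Per-subject AB index: mean of the two pooled-cohort z-scores."""
    if len(cohort) < 2:
        raise ValueError("need at least 2 subjects")
    occ = _col(cohort, "occurrence_A") + _col(cohort, "occurrence_B")
    cov = _col(cohort, "coverage_A") + _col(cohort, "coverage_B")
    return (_cohort_z(occ, ddof) + _cohort_z(cov, ddof)) / 2.0


def c_index(cohort: pd.DataFrame, ddof: int = 0) -> np.ndarray:
    """Per-subject C index: mean of the three C-class z-scores."""
    if len(cohort) < 2:
        raise ValueError("need at least 2 subjects")
    parts = [_cohort_z(_col(cohort, name), ddof)
             for name in ("occurrence_C", "coverage_C", "duration_C")]
    return (parts[0] + parts[1] + parts[2]) / 3.0


def mic_index(cohort: pd.DataFrame, ddof: int = 0) -> np.ndarray:
    """Per-subject MIC index, (AB - C) / 2; positive flags high risk."""
    return (ab_index(cohort, ddof) - c_index(cohort, ddof)) / 2.0


@dataclass
class BiomarkerTable:
    """Per-subject indices with the population statistics used for Z."""

    table: pd.DataFrame                   # subject_id, group, ab, c, mic, ...
    population_stats: dict[str, tuple[float, float]]

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def biomarker_table(cohort: pd.DataFrame, ddof: int = 0) -> BiomarkerTable:
    """Compute AB/C/MIC (and average duration) for a cohort table.

    The cohort DataFrame must carry the twelve ``coverage_/duration_/
    occurrence_{A..D}`` columns; ``subject_id``, ``group`` and ``mis`` are
    propagated when present.
    """
    ab = ab_index(cohort, ddof)
    ci = c_index(cohort, ddof)
    mic = (ab - ci) / 2.0
    dur_cols = [f"duration_{c}" for c in "ABCD"]
    avg_dur = cohort[dur_cols].mean(axis=1).to_numpy(dtype=float)

    out = pd.DataFrame({"ab_index": ab, "c_index": ci, "mic_index": mic,
                        "average_duration": avg_dur})
    for meta in ("subject_id", "group", "mis"):
        if meta in cohort.columns:
            out.insert(0, meta, cohort[meta].to_numpy())
    stats = {}
    for name in ("occurrence_A", "occurrence_B", "occurrence_C",
                 "coverage_A", "coverage_B", "coverage_C", "duration_C"):
        v = cohort[name].to_numpy(dtype=float)
        stats[name] = (float(v.mean()), float(v.std(ddof=ddof)))
    return BiomarkerTable(table=out, population_stats=stats)


@dataclass
class ClassifierReport:
    """Held-out performance of the single-feature MIC classifier."""

    accuracy_mean: float
    accuracy_sd: float
    sensitivity_mean: float
    specificity_mean: float
    auc_mean: float
    n_splits: int
    test_fraction: float
    seed: int
    zero_cutoff_accuracy: float
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    intercept: float = float("nan")
    slope: float = float("nan")
    per_split_accuracy: list[float] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "accuracy_mean", "accuracy_sd", "sensitivity_mean",
            "specificity_mean", "auc_mean", "n_splits", "test_fraction",
            "seed", "zero_cutoff_accuracy", "intercept", "slope")}
        d["roc_points"] = self.roc_points
        return d


def zero_cutoff_accuracy(mic: np.ndarray, is_high: np.ndarray) -> float:
    """Accuracy of the model-free rule: MIC > 0 means high risk."""
    mic = np.asarray(mic, dtype=float)
    is_high = np.asarray(is_high, dtype=bool)
    return float(np.mean((mic > 0) == is_high))


def classify_mic(cohort: pd.DataFrame, test_fraction: float = 0.3,
                 n_splits: int = 100, seed: int = 0) -> ClassifierReport:
    """Single-feature logistic regression on MIC with repeated splits.

    MIC indices are computed once on the pooled cohort, then a logistic
    model (L2-regularized, which also tames the infinite MLE under perfect
    separation) is fitted on stratified train portions and scored on the
    held-out portions across ``n_splits`` split seeds. The ROC is computed
    from the decision scores pooled over test folds; the zero-cutoff rule
    is evaluated on the full cohort independently of the fitted model.
    """
    if "group" not in cohort.columns:
        raise ValueError("cohort table must carry a 'group' column")
    mic = mic_index(cohort).reshape(-1, 1)
    y = (cohort["group"].to_numpy() == "H").astype(int)
    if y.all() or not y.any():
        raise ValueError("both groups must be present")

    accs, sens, spec, aucs = [], [], [], []
    pooled_scores, pooled_truth = [], []
    last_model = None
    for i in range(n_splits):
        x_tr, x_te, y_tr, y_te = train_test_split(
            mic, y, test_size=test_fraction, stratify=y,
            random_state=(seed + i) % (2**31 - 1))
        model = LogisticRegression()
        model.fit(x_tr, y_tr)
        pred = model.predict(x_te)
        accs.append(np.mean(pred == y_te))
        tp = np.sum((pred == 1) & (y_te == 1))
        tn = np.sum((pred == 0) & (y_te == 0))
        sens.append(tp / max(np.sum(y_te == 1), 1))
        spec.append(tn / max(np.sum(y_te == 0), 1))
        scores = model.decision_function(x_te)
        if len(np.unique(y_te)) == 2:
            aucs.append(roc_auc_score(y_te, scores))
        pooled_scores.append(scores)
        pooled_truth.append(y_te)
        last_model = model

    fpr, tpr, _ = roc_curve(np.concatenate(pooled_truth),
                            np.concatenate(pooled_scores))
    return ClassifierReport(
        accuracy_mean=float(np.mean(accs)), accuracy_sd=float(np.std(accs)),
        sensitivity_mean=float(np.mean(sens)),
        specificity_mean=float(np.mean(spec)),
        auc_mean=float(np.mean(aucs)) if aucs else float("nan"),
        n_splits=n_splits, test_fraction=test_fraction, seed=seed,
        zero_cutoff_accuracy=zero_cutoff_accuracy(mic.ravel(), y == 1),
        roc_points=[(float(a), float(b)) for a, b in zip(fpr, tpr)],
        intercept=float(last_model.intercept_[0]),
        slope=float(last_model.coef_[0][0]),
        per_split_accuracy=[float(a) for a in accs])
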