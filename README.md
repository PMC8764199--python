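# eegmic

EEG microstate analysis and quantitative-EEG biomarkers for
malnutrition-inflammation risk in end-stage renal disease (ESRD).

Dialysis patients frequently develop malnutrition-inflammation complex
syndrome (MICS), conventionally assessed with the Malnutrition-Inflammation
Score (MIS, 0–30; cutoff 5 separates low from high risk). Because
resting-state EEG changes with the cerebral complications of MICS, EEG
offers a non-invasive route to the same stratification. This package
implements, with full tests and a ground-truthed simulator, the analysis
chain that turns a 19-channel resting EEG into that stratification:

- **Microstates** — polarity-invariant modified k-means over
  topographic maps at global-field-power (GFP) peaks, labelling by
  `l_n = argmax_k (s_nᵀ m_k)²`, prototype update by dominant eigenvector,
  restart selection by global explained variance
  `GEV = Σ CS_n² GFP_n² / Σ GFP_n²`; backfitting, small-segment-rejection
  smoothing, and per-class coverage (%), duration (ms), occurrence (Hz).
- **Spectral** — per-channel delta (1–4 Hz) / theta (4–8 Hz)
  absolute-power ratio, z-scored against a normative reference and
  clipped to ±3, aggregated into nine scalp regions.
- **MIC index** — per subject,
  `AB = [Z(Occ_A+Occ_B) + Z(Cov_A+Cov_B)]/2`,
  `C = [Z(Occ_C)+Z(Cov_C)+Z(Dur_C)]/3`, `MIC = (AB − C)/2`, with Z taken
  against the pooled cohort; `MIC > 0` flags high risk, and a
  single-feature logistic regression with repeated stratified splits
  quantifies held-out performance.
- **Statistics** — permutation t-test (Welch), TANOVA on topographies
  (cosine distance, label permutation), Mann-Whitney U, Spearman ρ,
  Shapiro-Wilk.
- **Synthetic data** — semi-Markov microstate EEG with planted
  prototypes/segments and two-group MIS-labelled cohorts, so every stage
  has a recoverable target.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

```python
import numpy as np
from eegmic import (SyntheticSpec, simulate_label_sequence, synthesize_eeg,
                    modified_kmeans, backfit, smooth_segments,
                    segment_statistics)
from eegmic.preprocess import (average_reference, compute_gfp,
                               extract_gfp_peaks, standardize_samples)

spec = SyntheticSpec(seed=5)                      # 19 ch, 256 Hz, 4 classes
truth = simulate_label_sequence(spec, 600.0)      # planted segment table
rec = average_reference(synthesize_eeg(truth, spec))

peaks = extract_gfp_peaks(compute_gfp(rec), 10.0, rec.sampling_rate)
maps = standardize_samples(rec.data[:, peaks.peak_indices].T)
protos, seg, _ = modified_kmeans(maps, k=4, n_restarts=20, seed=1)
print(f"GEV at GFP peaks: {seg.gev:.3f}")

full = backfit(rec.data.T, protos)
full = smooth_segments(full, rec.data.T, protos, 30.0, rec.sampling_rate)
params = segment_statistics(full, rec.sampling_rate)
print(np.round(params.coverage, 2), np.round(params.duration, 1))
```

prints

```
GEV at GFP peaks: 0.910
[24.94 24.93 25.27 24.86] [105.9 105.5 105.2 105.3]
```

GEV ≈ 0.91 says the four recovered prototypes explain 91 % of the squared
GFP at the clustering input; the coverages (≈25 % each) and durations
(≈105 ms vs ≈101 ms planted, the ~4 % smoothing bias discussed in the
methods note) recover the generator's truth. The scripts in `examples/`
walk through each capability the same way — simulation, the full
microstate pipeline, spectral z-scores, the MIC biomarker, and the group
statistics — each printing the numbers it computes and what they mean.

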