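"""Recover microstates from synthetic EEG: cluster, backfit, smooth, measure.

Runs the full microstate path on one synthetic recording — band-pass,
average reference, GFP-peak reduction, per-map standardization, modified
k-means (20 restarts), backfitting, 30 ms small-segment smoothing — and
compares the recovered prototypes and parameters with the planted truth.
"""

import itertools

import numpy as np

from eegmic import (SyntheticSpec, backfit, modified_kmeans,
                    segment_statistics, simulate_label_sequence,
                    smooth_segments, synthesize_eeg)
from eegmic.preprocess import (average_reference, bandpass_filter,
                               compute_gfp, extract_gfp_peaks,
                               standardize_samples)

spec = SyntheticSpec(seed=7)
truth = simulate_label_sequence(spec, total_duration=120.0)
rec = synthesize_eeg(truth, spec)

rec = bandpass_filter(rec, 1.0, 40.0, order=4)
rec = average_reference(rec)
series = compute_gfp(rec)
peaks = extract_gfp_peaks(series, min_separation=10.0,
                          sampling_rate=rec.sampling_rate)
maps = standardize_samples(rec.data[:, peaks.peak_indices].T)
print(f"{maps.shape[0]} GFP-peak maps extracted from "
      f"{rec.n_samples} samples")

protos, seg, diag = modified_kmeans(maps, k=4, n_restarts=20, seed=1)
print(f"clustering GEV on peak maps: {seg.gev:.4f} "
      f"(fraction of squared GFP explained)")

sim = np.abs(protos.maps @ truth.true_prototypes.maps.T)
match = max(itertools.permutations(range(4)),
            key=lambda p: sum(sim[i, p[i]] for i in range(4)))
print("recovered-vs-planted |cosine| per class:",
      [f"{sim[i, match[i]]:.3f}" for i in range(4)])

full = backfit(rec.data.T, protos)
full = smooth_segments(full, rec.data.T, protos, min_duration=30.0,
                       sampling_rate=rec.sampling_rate)
params = segment_statistics(full, rec.sampling_rate)
print("recovered parameters (planted values in brackets):")
tp = truth.true_parameters
for i in range(4):
    j = match[i]
    print(f"  class {i}: coverage {params.coverage[i]:5.2f} "
          f"[{tp.coverage[j]:5.2f}] %   "
          f"duration {params.duration[i]:6.2f} [{tp.duration[j]:6.2f}] ms   "
          f"occurrence {params.occurrence[i]:4.2f} [{tp.occurrence[j]:4.2f}] Hz")
print("a |cosine| near 1 and parameter agreement within a few percent mean "
      "the planted microstate structure was recovered.")
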