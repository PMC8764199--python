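# Methods

`eegmic` implements a resting-state EEG microstate pipeline, a delta/theta
band-power z-ratio, and a composite biomarker (the MIC index) for
stratifying malnutrition-inflammation risk in end-stage renal disease
(ESRD) patients, together with a synthetic-data module that makes every
stage verifiable against planted ground truth.

## The microstate model

The scalp EEG topography at sample *n* is modelled as

    s_n = i_kn · m_k + a_n,   k = l_n,

with unit-norm prototype maps `m_k` (K = 4 classes, A–D), a signed
intensity `i_kn = s_nᵀ m_k`, and zero-mean noise `a_n`. Polarity carries
no class information, so labelling maximizes the squared intensity:
`l_n = argmax_k (s_nᵀ m_k)²` (ties broken by the lowest class index —
deterministic and documented).

**Modified k-means.** Clustering alternates this labelling with a
prototype update that sets `m_k` to the dominant eigenvector of
`Σ_{l_n=k} s_n s_nᵀ` — the polarity-invariant fixed point of the loss
`E = Σ_n (‖s_n‖² − (s_nᵀ m_{l_n})²)`. Iteration stops when the relative
change of E falls below 1e-6 or after 1000 iterations; non-convergence is
reported in diagnostics, not raised. Of 20 random restarts (prototypes
seeded from random samples), the run with maximal global explained
variance is kept. Empty classes are re-seeded from the currently
worst-fit sample. Both steps decrease E monotonically, which the test
suite asserts on the loss trace.

**GEV.** Fit quality is the global explained variance
`GEV = Σ_n CS_n² GFP_n² / Σ_n GFP_n²`, where `CS_n` is the cosine
similarity between the sample and its assigned prototype and `GFP_n` is
the global field power (population standard deviation across channels —
divisor C, a documented convention choice). On average-referenced maps
`‖s_n‖² = C·GFP_n²`, so GEV is exactly the normalized complement of E and
the alternating algorithm ascends it; the brute-force optimality tests
therefore operate in that space. On maps with a nonzero channel mean the
two objectives differ slightly.

**Pipeline order.** Recordings are band-passed 1–40 Hz with a 4th-order
Butterworth applied forward-backward (zero phase, so topography timing is
preserved; the stated order is the design order), average-referenced, and
reduced to local maxima of the GFP curve at least 10 ms apart (larger
peak wins a conflict; exact ties keep the earlier index). Peak maps are
standardized to zero mean / unit SD across channels before clustering, so
prototypes live in z-score space. Backfitting labels *every* sample of a
recording (not only GFP peaks) with the group-level prototypes in the
same average-referenced space; per-sample standardization would not
change labels because the similarity is scale-invariant once the channel
mean is removed.

**Temporal smoothing.** Small-segment rejection: interior segments
shorter than 30 ms (default; a free parameter in the config) are
iteratively dissolved, shortest first, each sample joining whichever
flanking segment's class has the larger squared intensity for it.
Recording-edge segments are exempt (their true length is unknown).

**Parameters.** Per class: coverage (% of samples), mean duration (ms),
and occurrence (segment onsets per second). The first and last segments
of a recording are truncated by the edges and are excluded from duration
and occurrence but counted in coverage; consequently
`coverage ≈ occurrence × duration / 10` holds within edge effects (~0.3
percentage points at 60 s, asserted within 2 points in the tests). A
class with no interior segment has undefined duration (NaN), occurrence
0, and is flagged degenerate.

**Canonical ordering.** Recovered prototypes are relabelled A–D by
maximum-weight one-to-one assignment of absolute cosine similarity
against template maps. The shipped templates
(`data/synthetic_templates.json`) are *synthetic*: they are constructed
from schematic 10-20 electrode positions to match the classical
descriptions of the four canonical topographies (two mirrored diagonals,
an anterior–posterior gradient, a fronto-central focal map). They define
a reproducible ordering only and are not empirical grand averages.

## Spectral path

The delta (1–4 Hz) / theta (4–8 Hz) absolute-power ratio decreases with
encephalopathy severity. The spectral path is kept separate from the
microstate path: it decimates to 128 Hz (anti-alias filtered) and uses a
5th-order 1–40 Hz Butterworth. Band power per channel is a Welch
periodogram (2 s Hann windows, 50 % overlap — a documented choice; only
an FFT-based estimate is prescribed by the field's tooling) integrated
over the band by the trapezoid rule, so contiguous bands partition total
power exactly. Ratios are log-transformed before z-scoring (ratios are
right-skewed) against a normative reference table of per-channel
mean/SD of the log ratio; z values are clipped to ±3 as is conventional
in quantitative-EEG reporting. Commercial normative databases are
proprietary, so the package defines the reference file format and ships a
generator that builds a self-consistent reference from simulated
recordings; this is a deliberate, documented deviation from clinical
practice, where a validated normative population would be used.
Channel values aggregate into nine standard regions by unweighted means
over electrodes (the composite frontal/temporal regions average their 7
and 4 electrodes directly, not the sub-region means).

## The MIC biomarker

Per subject i, with Z the z-transform against the mean and SD of the
pooled analyzed cohort (population SD, divisor n; switchable):

    AB_i  = [Z(Occ_A + Occ_B) + Z(Cov_A + Cov_B)] / 2
    C_i   = [Z(Occ_C) + Z(Cov_C) + Z(Dur_C)] / 3
    MIC_i = (AB_i − C_i) / 2

A positive MIC flags high malnutrition-inflammation risk (zero-cutoff
rule). "Population" means the cohort being analyzed — the index is
cohort-scoped by construction, so every report records the population
statistics used. Classification performance is evaluated two ways: the
model-free zero-cutoff rule, and a single-feature logistic regression
(L2-regularized, which also regularizes the otherwise-infinite MLE under
perfect separation) with stratified 70/30 train/test splits repeated over
100 split seeds (the split proportions are a documented choice). ROC/AUC
are computed from held-out decision scores; AUC of a score equals the
Mann-Whitney U statistic divided by n_H·n_L, an identity cross-checked in
the tests.

## Statistics

- **Permutation t-test**: Welch statistic (unequal variances, a
  documented choice), uniform label permutations, two-sided
  `p = (1 + #{|t*| ≥ |t|}) / (n_perm + 1)`; the floor `1/(n_perm+1)` is
  respected by construction. Default 5000 permutations.
- **TANOVA**: subject maps are unit-normalized and sign-aligned to the
  dominant eigenvector of their pooled outer-product sum (invariant to
  per-subject polarity and to group labels), the statistic is
  `1 − |cos|` between group-mean maps, and p comes from group-label
  permutations. Unit-norm maps rather than GFP-normalized maps are used
  (a flagged open choice in the field).
- **Mann-Whitney U**: `U1 = #{high > low} + ½·#{ties}`; p exact where
  feasible, otherwise normal approximation with tie correction (scipy).
- **Spearman's ρ** with average ranks; **Shapiro-Wilk** routes
  descriptive reporting (mean ± SD vs median/IQR). Constant inputs raise
  rather than returning NaN.
- No multiple-testing correction is applied by default (raw p-values are
  reported, matching the analysis style this package reproduces).

Type-I calibration of both permutation tests is asserted at α = 0.05
within [0.035, 0.065] over 1000 null replicates of 999 permutations.

## Synthetic data: what it emulates and what it does not

**Signal level.** A semi-Markov label sequence: segment classes i.i.d.
(no immediate self-transition — otherwise segments are ill-defined),
segment lengths gamma-distributed with shape 4 (CV = 0.5; the empirical
duration law of real EEG is not established, so this is a stand-in chosen
to avoid near-zero segments) and per-class means defaulting to 100 ms,
inside the 80–120 ms range of quasistable periods. Prototypes are random
orthonormal zero-mean maps by default (a shared set can be passed for
cohort simulations; real subjects share topographies). Within a segment
the intensity follows a raised-cosine bell on a pedestal of 0.35 of the
peak (transitions dip but field strength does not vanish), which places
GFP maxima in segment interiors — the premise of GFP-peak downsampling.
`noise_sd` is the per-channel noise-to-signal amplitude ratio (noise SD =
`noise_sd · intensity_mean / √C`); the default 0.2 leaves raw backfit
label recovery above 95 %. Optional band components add a shared-phase
sinusoid identical on all channels, which leaves the GFP and the
average-referenced signal untouched — spectral content can be injected
without disturbing the microstate path.

Not emulated: volume conduction, spatially correlated noise, artifacts
(blinks, ECG), non-stationarity. Passing recovery tests therefore shows
the algorithms are correct under the model's own assumptions, not that
they are robust to real-world contamination — which is why the artifact
repair stage is an explicit pass-through hook.

Known bias: smoothing dissolves genuine sub-30 ms segments (~3.5 % of a
gamma(4) population at 100 ms mean), inflating recovered duration and
deflating occurrence by ~4 % relative to planted truth. Recovery is
asserted within 5 % per class as the error averaged over 10 Monte-Carlo
seeds; single seeds can graze the bound.

**Cohort level.** Twelve parameters per subject drawn independently from
per-group normal distributions; defaults are the published group
statistics of a 23 + 23 ESRD cohort stratified at MIS 5 (occurrence was
published as median/IQR and is converted by mean = median,
SD = IQR/1.35). The integer MIS (0–30) derives from a latent severity
score computed from the subject's own parameters with signed loadings
(A/B coverage and occurrence up; all C parameters down; A and D duration
weakly down), mapped through
`MIS = round(clip(5.5 + 2.2·latent + ε, 0, 30))`, ε ~ N(0, 1.1); β and
the noise scale were calibrated once so the strong rank correlations at
n = 46 land near |ρ| ≈ 0.55–0.78. Because the group statistics are
conditional on the MIS cutoff, the drawn MIS is kept consistent with the
sampled stratum (clipped to ≤ 5 / > 5); group labels then follow the MIS
rule exactly. Independence of the twelve draws is a simplification — real
parameters are strongly correlated within subject — and adds
within-group MIC variance a real cohort would not have, which is why the
simulated classifier accuracy averages ~99.5 % rather than exactly 100 %.

## Numerical choices and degenerate inputs

- Single seed per simulation/config; all derived randomness flows from
  `numpy.random.default_rng` children of it. Identical seeds give
  byte-identical pipeline outputs (asserted).
- Zero-variance maps cannot be standardized, zero-norm maps have no
  cosine similarity, constant samples have no rank correlation or
  normality test: all raise `ValueError` with the offending input named.
- EDF is written with 1 s records, 16-bit samples, physical range set
  per channel from the data; round-trip error is bounded by the
  quantization step (asserted). Truncated files are rejected by a size
  check against the header's promise before parsing.
- Problem sizes in the test suite (600 s recordings for recovery, 50
  cohorts × 100 splits for the classifier, 1000 replicates for
  calibration) were chosen to keep Monte-Carlo error well inside the
  asserted tolerances.

## Known limitations

- K is fixed at 4; no map-count selection criterion is provided.
- No alternative clustering families (AAHC, PCA, HMM variants).
- The normative reference is synthetic unless the user supplies one; z
  values are only as meaningful as the supplied reference population.
- The MIC index is cohort-scoped: adding or removing a subject changes
  every index. It classifies risk strata; it does not estimate MIS
  severity.
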