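# Methods

This note documents the models, numerical choices, and validation design
behind `fcbands`, in the spirit of a statistical-software methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model of the synthetic cohort

The generator emulates the data structure of a two-group resting-state
study: `n_patients + n_controls` subjects, each a T×N matrix of regional
BOLD-like series at sampling interval TR. Defaults mirror a 19-patient /
20-control design with N = 90 regions and T = 170 retained volumes at
TR = 2 s (180 acquired minus 10 discarded for signal equilibration),
labels +1 for patients and −1 for controls.

Each region is a sum of independent white Gaussian noise (SD
`noise_sd`, default 1) and one band-limited latent component per planted
edge incident to the region. The latent of an edge is shared by its two
regions, synthesized by masking the Fourier coefficients of white noise
outside the edge's band and inverse-transforming (so its spectral
support exactly matches the ideal band-pass used downstream), and
standardized to unit variance. With in-band white-noise power fraction
`p` (the fraction of DFT degrees of freedom inside the band), the latent
weight `w` is chosen to hit a target in-band Pearson correlation `r`:

    r = w² / (w² + noise_sd² · p)   ⇒   w² = |r| · noise_sd² · p / (1 − |r|),

with the latent's sign flipped in the second region for negative
targets. Outside the planted band the latent carries no power, so the
coupling is invisible to the other bands — this is what makes band
specificity testable. When several planted edges share a region and a
band, their latents add and realized correlations fall slightly below
target; validation designs therefore plant region-disjoint edges.

What the generator does *not* emulate: hemodynamic response shape, 1/f
noise spectra, physiological (cardiac/respiratory) aliasing, scanner
drift, head-motion artifacts, spatial autocorrelation between regions,
and voxel-level imaging (a `expand_to_voxels` helper replicates regional
series into noisy pseudo-voxels solely to exercise ROI averaging).
Passing tests on this cohort therefore certify the *pipeline machinery*
— filtering, network construction, ranking, cross-validation,
calibration — not robustness to real-fMRI confounds.

Per-subject realized in-band correlations are estimated from the
band-filtered series. At T = 170 and TR = 2 s the slow-5 band holds only
~12 real degrees of freedom, so single-subject estimates are noisy and
slightly attenuated toward zero (the classical sample-correlation bias
at small effective n); group means over ≥ 20 subjects recover targets to
within ±0.1, which is what the tests assert.

## Conditioning

Order is fixed: linear detrend → nuisance regression (optional) → ideal
band-pass, and each step appends its name to the series' provenance
tuple. The band-pass is a rectangular filter on discrete Fourier
coefficients, matching the convention of the standard resting-state
preprocessing toolchains: a bin is kept iff `low ≤ f ≤ high`
(inclusive on both edges, so slow-5 and slow-4 share the 0.027 Hz bin
whenever T·TR puts a bin exactly there; at T = 170, TR = 2 s none falls
on the edge and the two bands tile the whole band exactly). The DC bin
is always removed when `low > 0`. Ideal filtering makes the operator
exactly idempotent and linear, properties the tests verify bin-by-bin.
A zero-phase Butterworth alternative (`bandpass_butterworth`, order 4)
exists for sensitivity analysis and is not the default. The shipped
slow-5 band is 0.01–0.027 Hz; whole-band is 0.01–0.073 Hz, consistent
with the oscillation taxonomy and with slow-4 starting at 0.027 Hz.

Filtering is applied to ROI-level series. For fixed ROI membership,
voxel averaging and linear filtering commute, so this is equivalent to
voxel-level filtering followed by averaging.

## Network construction

Pearson correlation over all region pairs; symmetric, unit diagonal,
entries clipped to [−1, 1] against rounding. Negative correlations are
retained as features — no thresholding or absolute value. Edge order is
the row-major strict upper triangle over 1-based atlas indices,
(1,2), (1,3), …, (1,N), (2,3), …, fixed so feature indices are
reproducible across runs; N = 90 gives 4005 edges. Normalization is the
elementwise Fisher r-to-z transform (default); per-feature z-scoring
across subjects is available as `feature_zscore` for sensitivity
analysis. Strict mode rejects zero-variance regions and |r| = 1
entries; lenient mode zeroes/clips with a logged count.

## Classification and ranking

The classifier is a linear C-SVC with C = 1 (scikit-learn's libsvm
wrapper). The RFE criterion is Guyon's: recursively eliminate the
feature with the smallest squared weight of the linear SVM refitted on
the surviving set. Because the criterion is defined on linear weights,
ranking refuses non-linear kernels; an RBF classifier
(gamma = 1/num_features, the libsvm default) is available for the
classification stage only, as a fidelity experiment.

Determinism: there is no randomness anywhere in ranking; weight ties
are broken by eliminating the larger feature index first. For large P a
chunked schedule (default: eliminate 10% of survivors per iteration
until 200 remain, then one at a time) keeps study-scale runs at seconds;
the final 200 eliminations are always one-by-one so the top of the
ranking is step-independent, and the step is recorded in the run
manifest.

LOOCV runs exactly K folds, one held-out subject each. The default
k-schedule is dense over 1..min(P, 200) then ~12 geometrically spaced
points to P, since the informative region of the accuracy curve is at
small k. The convergence point is the smallest k whose accuracy equals
the curve maximum and whose following `window` (default 10) schedule
points stay within `tolerance` (default 0) of that maximum; when fewer
than `window` points remain, the criterion degrades to "maximum reached
and held to the end" with a log message.

### Two evaluation modes, and why both exist

`paper_fidelity` ranks features once on the *full* dataset and then
cross-validates the nested subsets. The ranking has seen every test
subject, so small-k accuracies are optimistically biased — on pure-noise
data this mode reaches ~0.9 best-k "accuracy" (the acceptance suite
measures this). It is kept because it replicates the published
procedure and because the bias itself is worth demonstrating. `nested`
re-ranks within every training fold, so feature selection never sees
the held-out subject; it is the recommended default for drawing
conclusions from new data.

### Permutation control and chance level

The permutation control shuffles labels and re-runs either the fixed
selected subset (`fixed_subset`, the published check generalized from
one shuffle to many) or the full rank-then-score pipeline (`rerank`).
The default is 100 permutations; the empirical p uses the add-one rule
`(1 + #{perm ≥ observed}) / (1 + n_perm)`. Chance is defined as the
majority-class proportion (20/39 ≈ 0.513 for the study design), not 0.5,
because the design is unbalanced.

### A known, deliberate property: LOOCV at the null is below chance

On label-free data, leave-one-out with a 19/20 design is *pessimistically*
biased: removing the held-out subject always makes its class the
training minority, and a margin classifier on uninformative features
leans toward the training majority, so held-out predictions
anti-correlate with the true class. Measured on null cohorts, LOOCV
accuracy sits roughly 2–5 points below the 20/39 chance level, and
permuted-label accuracies show the same depression (the study-scale run
in `scripts/acceptance.py` reproduces permuted accuracies in the high
30s — the published single-shuffle values sit in the same range). This
is a property of leave-one-out under imbalance, not an implementation
defect; the acceptance test that asserts permuted accuracies lie within
3 SE of the majority-class chance level fails for exactly this reason
and is intentionally left failing as documentation. Consequences for
practice: the permutation null should be compared against the *permuted
distribution itself* (empirical p), never against a nominal chance
constant.

The nested-mode null check is asserted at a fixed subset size (k = 10)
rather than at the best k over the schedule, because taking the maximum
of many unbiased per-k estimates is itself optimistically biased and
would mix two effects the suite keeps separate.

## Group statistics

Per selected edge: group means and SDs on the Fisher-z features,
pooled-variance two-tailed Student's t with df = K − 2 (Welch available
by flag), stars `*` for p < 0.05 and `**` for p < 0.01, and direction
`increased`/`decreased` by the sign of (patient mean − control mean);
the t statistic is signed the same way, so positive t means increased
in patients. No multiple-testing correction is applied across selected
edges (matching the published presentation); p-values are nominal, and
the type-I rate of the test itself is calibrated in the acceptance
suite (5.1% at α = 0.05 over 2000 null features in the shipped run).
Region occurrence counts every incidence of a region among selected
edges, so counts sum to twice the number of edges.

## Problem sizes used in validation

The structural acceptance test and the acceptance script run the full
study scale (39 subjects, 90 regions, 4005 edges, three bands) once.
The replicate-based suites use the study's subject counts (19/20) and
T = 170 but reduced atlases — 20 regions (190 edges) for planted-effect
recovery and band specificity (25 replicates), 10 regions (45 edges)
for null calibration (50 replicates in the tests, 20 in the script) —
chosen so the Monte-Carlo suites stay at desk scale while preserving
the K ≪ P regime that makes the selection-bias phenomena visible.
Planted recovery uses couplings ±0.4 (about d ≈ 2–2.5 on the Fisher-z
features at slow-5's effective DOF), and success means both planted
edges rank in the matching band's top 10 while neither enters the other
band's top 10.

## Known limitations

- The generator's noise is white; real BOLD has autocorrelated noise,
  which inflates correlation variance beyond what these tests exercise.
- Ideal filtering assumes exact DFT-bin semantics; finite windows leak
  power in real data where signals are not periodic.
- The pipeline starts at regional time series; image-space
  preprocessing (slice timing, realignment, normalization, motion
  estimation) is out of scope.
- Graph-theoretic summaries (degree, clustering, small-worldness) and
  alternative edge definitions (partial correlation, wavelets, mutual
  information) are out of scope.
- Hyperparameters (C, RFE step) are fixed, not tuned; the package
  deliberately offers no grid search.
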