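# Methods

## Data model and bin conventions

A retrieval session is represented as percent time freezing per 30-s bin,
one row per animal, values in [0, 100]. Bin indices are 1-based
everywhere. Under the standard protocol the 6-min conditioned stimulus
(CS, the tone) occupies bins 13–24; under the shortened protocol the same
12-bin window occupies bins 7–18. Within the CS window, the first 5 bins
(2.5 min) are the phasic component of the freezing curve and the last
7 bins (3.5 min) the sustained component; the two windows differ between
protocols only by a constant offset of 6 bins.

Datasets are exchanged as wide CSV (`animal_id, sex, batch,
bin_1..bin_N`), comma-separated, UTF-8, header required; session and
protocol are supplied by the caller rather than stored per row. Values
outside [0, 100] and missing bins are hard validation errors, not clipped
or imputed: silent repair could mask tracking-software faults. Floats are
written at 17 significant digits and parsed with round-trip precision, so
write∘read is the identity. Adaptation-session data are representable but
no pipeline stage consumes them; phenotyping uses the retrieval sessions
(MR1/MR2) only.

## Log-linear curve features

Each animal's CS-window freezing is modelled by ordinary least squares as

    freezing_t = β₀ + β₁·ln(t),  t = 1..12 (1-based within-CS bin index)

with the natural log. ln(1) = 0 makes β₀ the modelled freezing at CS
onset, and β₁ a decay rate on the raw percent scale (near 0 for sustained
responders, strongly negative for phasic ones). Regressing on ln(elapsed
seconds) or using another log base would only rescale/shift (β₀, β₁)
jointly and cannot change clustering or classification results; the
bin-index form is fixed as the package convention. R² is 1 − SSres/SStot,
defined as 1 when SSres = 0 (including constant input, where the fit is
exact with slope 0). Fits require ≥ 3 finite values.

The third feature, the sustained mean, is the arithmetic mean of the
*raw* (not fitted) values over the sustained window. The feature vector
(β₀, β₁, sustained mean) feeds clustering unstandardized — mixture models
on the natural scale keep the component means interpretable — while
classifiers standardize internally (below).

## Gaussian-mixture phenotype assignment

K is fixed at 2: the model is a two-phenotype hypothesis, not a
model-order search. EM is run under each covariance structure in
{spherical, diagonal, tied, full} with k-means initialization, 10
restarts, tolerance 1e-6 on the log-likelihood, at most 500 iterations
and a positive-definiteness floor (reg_covar 1e-6); the structure with
the lowest BIC is retained. Degenerate fits trigger up to 5
re-initializations with a progressively raised floor before a fit-failure
error that resampling callers count and skip.

Components are named by the sustained-mean coordinate of their means: the
component lying higher on that axis is the sustained phenotype. Hard
labels are maximum-posterior; with K = 2 the assigned posterior is in
[0.5, 1]. The naming rule makes labels comparable across independent fits
without Hungarian matching and doubles as the alignment rule in all
resampling experiments; an explicit two-permutation alignment helper
exists for labelings of unknown orientation (ties keep identity).

## Bootstrap stability

B resamples (default 200) of size n are drawn with replacement; each is
re-clustered and every animal present keeps one inclusion tally per
resample and one match tally when its aligned label equals its original
one. The per-animal Jaccard index is match/inclusion; per-cluster medians
summarize stability. Duplicates within a resample count once — duplicated
feature rows are identical, so their labels cannot disagree within a
sample. Failed refits are excluded from all counts and tallied; a report
with > 10 % failures is flagged invalid. Resampling derives from the seed
through one child RNG stream per bootstrap index, so reports are exactly
reproducible and the counts auditable by brute-force recomputation (the
test suite does both).

## Classifiers and evaluation

Five algorithms: logistic regression (unregularized), LDA, SVM with
linear and RBF kernels (cost 1; RBF gamma by the scale heuristic
1/(n_features·var)), and a 500-tree random forest. Hyperparameters are
fixed at these conventional defaults; no tuning. Features are
standardized by training mean/sd stored inside the bundle, because the
margin-based and discriminant models are scale-sensitive and storing the
statistics preserves exact single-animal prediction.

The positive class is *sustained* everywhere, orienting sensitivity,
specificity and F1:

    accuracy = (TP+TN)/(TP+TN+FP+FN)   sensitivity = TP/(TP+FN)
    specificity = TN/(TN+FP)           F1 = TP/(TP+0.5·(FP+FN))

Zero denominators flag the metric undefined (NaN) rather than raising.
AUROC is the rank-based (Mann–Whitney) area with ties at 1/2. Cohen's
kappa uses marginal-product expected agreement; the degenerate case of
two identical constant labelings is defined as 1.

Monte Carlo cross-validation repeats stratified random 70:30 train/test
splits (default 1000 iterations) and averages per-iteration metrics.
Stratification is a deliberate choice: it prevents single-class test sets
at small n, at the cost of fixing class proportions across splits. Model
selection takes the highest mean accuracy, with ties broken by mean
sensitivity, then specificity, then a fixed algorithm order. The registry
of per-setting defaults is female/MR1 → logistic, female/MR2 → logistic,
male/MR1 → random forest, male/MR2 → linear SVM.

Prediction scores each row through the estimator individually, so the
output for an animal is bit-for-bit identical whether it is scored alone
or in any batch — the property that justifies phenotyping arbitrarily
small cohorts with a pre-trained model. Internal evaluation loops use a
batched path that is equal up to BLAS rounding.

Bundles persist as versioned JSON: metadata (sex, session, n, class
counts, seed), standardization vectors and archived training data as
plain arrays, and the fitted estimator as an opaque base64 payload.
Retraining unions the archived data with a new cohort (after checking
sex/session metadata) and records provenance.

## Synthetic cohorts

The generator emulates a two-phenotype mixture of freezing curves: per
animal, phenotype ~ Bernoulli(sustained fraction), then CS-window bins
clip(onset + decay·ln(t) + ε, 0, 100) with (onset, decay) drawn from
phenotype-specific normals and ε i.i.d. Gaussian bin noise (sd 6 %);
pre-CS bins come from a baseline distribution. Clipping preserves the
percent scale and mimics the floor effect of fully decayed phasic curves.
A fixed-counts mode and a constant batch-shift option exist for
exact-recovery and batch-effect experiments.

Default specs encode the study conditions: female cohorts of 168 with
sustained fraction 78/168, male cohorts of 224 with 88/224; male onsets
are lower and male phasic decay steeper (sustained onset 75 vs 65 %,
phasic decay −22 vs −26 %/ln-bin, baseline 15 vs 10 %). These constants
are versioned synthetic calibrations chosen to produce clearly separated
phenotypes with realistic freezing levels — the sustained/phasic gap in
late-tone freezing exceeds 20 percentage points — not estimates of any
real cohort's feature distributions. A reduced-separation variant (decay
−6 vs −13, noise sd 9 %) produces deliberately overlapping mixtures for
small-sample instability studies.

What the generator does **not** emulate: adaptation/conditioning
sessions, shock reactivity, temporal autocorrelation of noise within a
curve, inter-batch variance structure beyond a location shift, or the
right-skewed male sustained-freezing distribution in full detail. Tests
passing on synthetic cohorts therefore demonstrate correctness of the
algorithms and their small-sample behavior, not performance claims about
real freezing data.

## Subsampling robustness

Subsamples are drawn **without** replacement (unlike the bootstrap), per
size and iteration from independent seeded substreams. The clustering arm
refits the mixture on each subsample and scores agreement with the
full-cohort reference after sustained-mean alignment; the classification
arm scores the pre-trained bundle's predictions against the same
reference. Reference labels are the full-cohort clustering; on synthetic
data generator truth can substitute. The default grid is
{100, 75, 50, 40, 30, 20, 10, 5}; sizes below 4 are rejected for the
clustering arm (a 2-component mixture needs ≥ 4 points) and allowed down
to 1 when only the classification arm runs.

## Problem sizes and reproducibility

Every stage takes a single integer seed; resampling and cross-validation
derive per-iteration child streams from it, so all outputs are
byte-identical across reruns. The shipped test suite and the acceptance
script run the study-condition cohort sizes (168/224) with B = 200
bootstrap resamples; cross-validation uses 100–200 iterations and the
subsampling experiment 100–200 iterations per size, which puts Monte
Carlo standard errors well below the margins being tested while keeping a
full run in minutes on one CPU.

## Known limitations

- K = 2 is assumed, never tested against richer phenotype structure.
- The mixture weight is the component's prior probability, not the hard
  label fraction; under overlapping components the two can differ by
  several points.
- Cluster-label agreement uses the sustained-mean naming rule; pathological
  fits in which both component means invert on that axis relative to the
  data's true structure would be aligned wrongly (not observed under the
  shipped conditions).
- The classifier bundle's estimator payload is a Python pickle (inside the
  JSON envelope); bundles are portable across machines but tied to
  compatible scikit-learn versions.
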