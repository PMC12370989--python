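# phenofreeze

Sex-specific phenotyping of conditioned-freezing behavior in mice.

After auditory aversive conditioning with a prolonged (6-min) tone,
individual mice differ systematically in how their freezing evolves during
memory retrieval: *sustained* responders hold a high freezing plateau
through the late tone phase (a high-trait-anxiety endophenotype), while
*phasic* responders freeze strongly at tone onset and then decay.
`phenofreeze` implements the full statistical pipeline for resolving these
two phenotypes from per-animal freezing time series, for researchers in
behavioral neuroscience who score retrieval sessions in 30-s bins:

1. **Curve features** — each animal's freezing over the 12 tone bins is
   fitted with a log-linear model, freezing(t) = β₀ + β₁·ln(t); the
   intercept β₀ (onset freezing), slope β₁ (decay rate) and the mean
   freezing over the last 3.5 min of the tone (the sustained phase) form a
   3-D feature vector.
2. **Clustering** — a 2-component Gaussian mixture in that feature space,
   with covariance structure (spherical/diagonal/tied/full) selected by
   BIC, assigns each animal a sustained or phasic label; the component
   whose mean sits higher on the sustained-freezing axis is the sustained
   phenotype.
3. **Stability** — bootstrap resampling (B = 200 by default) re-clusters
   the cohort and reports each animal's Jaccard index: the fraction of
   resamples containing it in which it kept its original label.
4. **Classification** — logistic regression, LDA, linear/RBF SVMs and
   random forests learn the cluster labels; Monte Carlo cross-validation
   (repeated stratified 70:30 splits) averages accuracy, sensitivity,
   specificity, F1 and AUROC over iterations. Trained models persist as
   versioned JSON bundles that classify future animals one at a time —
   the per-animal prediction is bit-for-bit independent of batch
   composition.
5. **Robustness** — a subsampling experiment contrasts de-novo clustering
   accuracy with pre-trained classification accuracy across cohort sizes,
   demonstrating why a pre-trained classifier supports much smaller (even
   single-animal) cohorts.

A synthetic cohort generator emulating the two-phenotype mixture (with
sex-specific class balance and freezing levels) makes the whole pipeline
testable without animal data.

## Worked example

```python
import phenofreeze as pf

dataset, truth = pf.generate_cohort(pf.default_spec("female", n=120, seed=3))
features = pf.extract_features(dataset)
model, assignment = pf.fit_phenotype_gmm(features, seed=3)
print(features.head(3))
```

```
animal_id  intercept      slope  sustained_mean  r_squared
SIM-F0001  96.322492  -8.489758       77.683551   0.769243
SIM-F0002  75.399155  -0.192764       74.465852   0.001051
SIM-F0003  70.073545 -27.201528       10.914963   0.943400
```

The first two animals hold high late-tone freezing (sustained_mean ≈ 75-78
with shallow slopes) — sustained responders; the third decays steeply
(slope ≈ −27) to ~11 % — phasic.  On this cohort the mixture selects a
tied covariance structure, assigns 51 sustained / 69 phasic, and agrees
with the generator's hidden labels for 100 % of animals.

The robustness contrast (see `examples/05_sample_size_robustness.py`, run
on a deliberately overlapping cohort where clustering is harder):

```
 size  clustering_mean  classification_mean
  100            0.917                1.000
   50            0.835                1.000
   20            0.789                1.000
   10            0.824                1.000
    5            0.780                1.000
```

Re-clustering 5-animal subsamples agrees with the full-cohort phenotypes
only ~78 % of the time, while the pre-trained classifier stays at 100 % at
every size — the case for training once on a large pooled cohort and then
phenotyping small experiments with the stored model.

The scripts in `examples/` cover each capability: simulation, feature
extraction + clustering, bootstrap stability, classifier training/CV and
the sample-size experiment.  A thin CLI exposes the same stages
(`phenofreeze simulate|features|cluster|stability|train|cv|classify|subsample`);
all stages are seeded and byte-reproducible.

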