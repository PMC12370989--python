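"""Extract log-linear curve features and cluster animals into phenotypes.

Each animal's CS-window curve is summarized by three numbers — the
log-linear intercept (freezing at CS onset), slope (decay rate) and the
mean freezing over the last 3.5 min of the tone — and a 2-component
Gaussian mixture splits the cohort into sustained and phasic responders.
"""

import phenofreeze as pf

dataset, truth = pf.generate_cohort(pf.default_spec("female", n=120, seed=3))
features = pf.extract_features(dataset)
model, assignment = pf.fit_phenotype_gmm(features, seed=3)

print(features.head(3).to_string(index=False))
print(f"\ncovariance structure selected by BIC: {model.covariance_structure}")
print(f"assigned: {assignment['label'].value_counts().to_dict()}")
agree = (assignment.set_index("animal_id")["label"] == truth).mean()
print(f"agreement with generator truth: {agree:.1%}")
print(
    "-> sustained animals sit high on the sustained_mean axis with a flat "
    "slope; phasic animals decay steeply. The mixture recovers the hidden "
    "labels almost perfectly under the default separation."
)
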