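"""Quantify clustering stability with per-animal bootstrap Jaccard indices.

The cohort is resampled with replacement B times; each resample is
re-clustered and every animal's label is compared with its original one.
An animal's Jaccard index is the fraction of resamples containing it in
which it kept its original phenotype.
"""

import phenofreeze as pf

dataset, _ = pf.generate_cohort(pf.default_spec("female", n=120, seed=5))
features = pf.extract_features(dataset)
_, assignment = pf.fit_phenotype_gmm(features, seed=5)

report = pf.bootstrap_stability(features, assignment, B=100, seed=5)
print(report.per_animal.head(5).to_string(index=False))
print(f"\nB = {report.B}, failed refits = {report.failed_fits}")
for label, median in report.cluster_medians.items():
    print(f"median Jaccard, {label} cluster: {median:.3f}")
print(
    "-> medians near 1 mean animals almost never switch phenotype when the "
    "cohort is perturbed by resampling: the clustering is robust to "
    "sampling error at this cohort size."
)
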