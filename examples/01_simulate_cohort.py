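"""Generate a labeled synthetic cohort and write it as a wide CSV.

The generator draws each animal's phenotype (sustained vs. phasic) and a
freezing curve over 24 thirty-second bins: pre-CS baseline in bins 1-12,
then onset + decay * ln(t) within the 6-min CS window (bins 13-24), with
Gaussian bin noise clipped to the 0-100 percent scale.
"""

import phenofreeze as pf

spec = pf.default_spec("female", n=40, seed=7)
dataset, labels = pf.generate_cohort(spec)
pf.write_freezing_csv(dataset, "cohort_female_n40.csv")

counts = labels.value_counts().to_dict()
print(f"cohort: {dataset.n_animals} females, {dataset.n_bins} bins each")
print(f"true phenotypes: {counts}")
print(f"generating sustained fraction: {spec.sustained_proportion:.4f}")
print(
    "-> each row of cohort_female_n40.csv is one animal's percent-freezing "
    "trace; the sustained fraction is the Bernoulli rate used to draw the "
    "hidden phenotype labels."
)
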