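"""Bootstrap evaluation of clustering stability.

The clustering is refitted on B resamples drawn with replacement (each of
the original size n) and compared with the original phenotype assignment.
For each animal i the per-animal Jaccard index is

    jaccard_i = (# resamples where i kept its original label)
                / (# resamples containing i at least once)

with labels aligned to the original assignment through the sustained-mean
naming rule.  Per-cluster medians summarize overall stability.  Duplicates
within a resample count once — their feature rows are identical, so their
labels cannot disagree within a sample.

Resampling is reproducible and auditable: resample index lists derive from
the seed through one child RNG stream per bootstrap index and are stored on
the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import fit_phenotype_gmm
from .errors import (
    ConfigurationError,
    FitFailureError,
    InsufficientDataError,
    StabilityFailureError,
    UndefinedValueError,
    ValidationError,
)
from .synthetic import PHASIC, SUSTAINED

#: A report is considered invalid when more than this fraction of
#: bootstrap refits fail.
MAX_FAILED_FRACTION = 0.10


def jaccard_index(match_count: int, inclusion_count: int) -> float:
    """Per-animal Jaccard index: match_count / inclusion_count."""
    if not 0 <= match_count <= inclusion_count:
        raise ConfigurationError(
            f"need 0 <= match_count <= inclusion_count, got "
            f"({match_count}, {inclusion_count})"
        )
    if inclusion_count == 0:
        raise UndefinedValueError(
            "animal was never included in a bootstrap sample"
        )
    return match_count / inclusion_count


@dataclass
class StabilityReport:
    """Per-animal bootstrap agreement and per-cluster medians."""

    B: int
    per_animal: pd.DataFrame  # animal_id, original_label, inclusion_count,
                              # match_count, jaccard
    cluster_medians: dict[str, float]
    failed_fits: int
    seed: int
    resample_indices: list[np.ndarray] = field(default_factory=list, repr=False)

    @property
    def failed_fraction(self) -> float:
        return self.failed_fits / self.B

    def to_csv(self, path) -> None:
        self.per_animal.to_csv(path, index=False)


def bootstrap_stability(
    features: pd.DataFrame,
    original: pd.DataFrame,
    B: int = 200,
    seed: int = 0,
) -> StabilityReport:
    """Quantify clustering robustness by bootstrap resampling.

    Parameters
    ----------
    features:
        Feature table for all animals of the original fit.
    original:
        Assignment frame (``animal_id``, ``label``) from the full-cohort
        clustering.
    B:
        Number of bootstrap resamples (with replacement, size n).
    seed:
        Seeds both the resample draws and each refit.

    Failed refits (degenerate resamples) are excluded from all counts and
    tallied; the report raises if every fit fails and flags invalidity
    above a 10% failure fraction.
    """
    if B < 1:
        raise ConfigurationError(f"B must be >= 1, got {B}")
    if set(features["animal_id"]) != set(original["animal_id"]):
        raise ValidationError(
            "features and original assignment must cover the same animals"
        )
    n = len(features)
    original_labels = (
        original.set_index("animal_id")["label"].reindex(features["animal_id"])
    ).to_numpy()

    root = np.random.SeedSequence(seed)
    children = root.spawn(B)

    inclusion = np.zeros(n, dtype=int)
    match = np.zeros(n, dtype=int)
    failed = 0
    kept_indices: list[np.ndarray] = []
    for child in children:
        rng = np.random.default_rng(child)
        idx = rng.integers(0, n, size=n)
        fit_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        resample = features.iloc[idx].reset_index(drop=True)
        try:
            _, assignment = fit_phenotype_gmm(resample, seed=fit_seed)
        except (FitFailureError, InsufficientDataError):
            failed += 1
            continue
        kept_indices.append(idx)
        # The sustained-mean naming rule already aligns labels to the
        # original fit; per distinct animal, compare once per sample.
        boot_labels = assignment["label"].to_numpy()
        uniq = np.unique(idx)
        first_pos = np.searchsorted(np.sort(idx), uniq)
        order = np.argsort(idx, kind="stable")
        labels_for_uniq = boot_labels[order[first_pos]]
        inclusion[uniq] += 1
        match[uniq] += labels_for_uniq == original_labels[uniq]

    if failed == B:
        raise StabilityFailureError(f"all {B} bootstrap refits failed")

    with np.errstate(invalid="ignore"):
        jaccard = np.where(inclusion > 0, match / np.maximum(inclusion, 1), np.nan)
    per_animal = pd.DataFrame(
        {
            "animal_id": features["animal_id"].to_numpy(),
            "original_label": original_labels,
            "inclusion_count": inclusion,
            "match_count": match,
            "jaccard": jaccard,
        }
    )
    medians = {
        label: float(
            per_animal.loc[per_animal["original_label"] == label, "jaccard"].median()
        )
        for label in (SUSTAINED, PHASIC)
        if (per_animal["original_label"] == label).any()
    }
    return StabilityReport(
        B=B,
        per_animal=per_animal,
        cluster_medians=medians,
        failed_fits=failed,
        seed=seed,
        resample_indices=kept_indices,
    )
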