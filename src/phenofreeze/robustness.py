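"""Sample-size robustness: de-novo clustering vs. pre-trained classification.

The experiment that motivates shipping pre-trained classifiers: draw random
subsamples of decreasing size from a phenotyped cohort, and at each size
score two ways of labeling the subsample against the full-cohort reference
assignment —

  (a) *clustering arm*: fit a fresh 2-component mixture on the subsample
      alone (labels aligned through the sustained-mean naming rule);
  (b) *classification arm*: score the subsample with a pre-trained
      classifier bundle.

Because the classifier scores each animal independently, its accuracy curve
stays flat down to a single animal, whereas de-novo mixture fits degrade as
the subsample shrinks.  Subsampling is without replacement, in contrast to
the bootstrap used for stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classification import ClassifierBundle, predict
from .clustering import fit_phenotype_gmm
from .errors import (
    ConfigurationError,
    FitFailureError,
    InsufficientDataError,
)

#: Default subsample-size grid, largest to smallest.
DEFAULT_SIZES = (100, 75, 50, 40, 30, 20, 10, 5)

#: Smallest subsample on which a 2-component mixture can be refitted.
MIN_CLUSTER_SIZE = 4


@dataclass
class RobustnessCurve:
    """Per-size mean accuracy and standard error for both arms."""

    sizes: tuple[int, ...]
    table: pd.DataFrame  # size, clustering_mean, clustering_se,
                         # classification_mean, classification_se,
                         # clustering_failed
    iterations: int
    seed: int
    subsample_indices: dict[int, list[np.ndarray]] = field(
        default_factory=dict, repr=False
    )

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def subsample_experiment(
    features: pd.DataFrame,
    reference: pd.DataFrame,
    bundle: ClassifierBundle,
    sizes=DEFAULT_SIZES,
    iters: int = 1000,
    seed: int = 0,
    keep_indices: bool = False,
    clustering_arm: bool = True,
) -> RobustnessCurve:
    """Contrast clustering vs. classification accuracy across cohort sizes.

    Parameters
    ----------
    features:
        Full-cohort feature table.
    reference:
        Full-cohort assignment frame (``animal_id``, ``label``) treated as
        ground truth.
    bundle:
        Pre-trained classifier used for the classification arm.
    sizes:
        Subsample sizes; each must satisfy ``MIN_CLUSTER_SIZE <= size <= n``.
    iters:
        Subsamples drawn per size.
    keep_indices:
        Store the drawn index lists on the curve for auditing.
    clustering_arm:
        Run the de-novo clustering arm (default).  With ``False`` only the
        classification arm is scored, which permits sizes down to 1.

    Failed mixture refits are excluded from the clustering-arm average and
    counted per size.  Deterministic given the seed.
    """
    if iters < 1:
        raise ConfigurationError(f"iters must be >= 1, got {iters}")
    n = len(features)
    sizes = tuple(int(s) for s in sizes)
    min_size = MIN_CLUSTER_SIZE if clustering_arm else 1
    for s in sizes:
        if s > n:
            raise ConfigurationError(f"subsample size {s} exceeds cohort size {n}")
        if s < min_size:
            raise ConfigurationError(
                f"subsample size {s} below the minimum of {min_size}"
                + (" required by the clustering arm" if clustering_arm else "")
            )
    ref_labels = (
        reference.set_index("animal_id")["label"].reindex(features["animal_id"])
    ).to_numpy()
    if pd.isna(ref_labels).any():
        raise ConfigurationError("reference must cover every animal in features")

    rows = []
    indices: dict[int, list[np.ndarray]] = {}
    for si, size in enumerate(sizes):
        children = np.random.SeedSequence([seed, si]).spawn(iters)
        clus_acc: list[float] = []
        clas_acc: list[float] = []
        failed = 0
        drawn: list[np.ndarray] = []
        for child in children:
            rng = np.random.default_rng(child)
            idx = rng.choice(n, size=size, replace=False)
            if keep_indices:
                drawn.append(idx)
            sub = features.iloc[idx].reset_index(drop=True)
            truth = ref_labels[idx]

            if clustering_arm:
                fit_seed = int(
                    child.generate_state(1, dtype=np.uint32)[0] % (2**31)
                )
                try:
                    _, assignment = fit_phenotype_gmm(sub, seed=fit_seed)
                except (FitFailureError, InsufficientDataError):
                    failed += 1
                else:
                    clus_acc.append(
                        float(np.mean(assignment["label"].to_numpy() == truth))
                    )

            pred = predict(bundle, sub)
            clas_acc.append(float(np.mean(pred["label"].to_numpy() == truth)))

        def _mean_se(vals: list[float]) -> tuple[float, float]:
            if not vals:
                return float("nan"), float("nan")
            arr = np.asarray(vals)
            se = arr.std(ddof=1) / np.sqrt(len(arr)) if len(arr) > 1 else 0.0
            return float(arr.mean()), float(se)

        cm, cse = _mean_se(clus_acc)
        km, kse = _mean_se(clas_acc)
        rows.append(
            {
                "size": size,
                "clustering_mean": cm,
                "clustering_se": cse,
                "classification_mean": km,
                "classification_se": kse,
                "clustering_failed": failed,
            }
        )
        if keep_indices:
            indices[size] = drawn

    return RobustnessCurve(
        sizes=sizes,
        table=pd.DataFrame(rows),
        iterations=iters,
        seed=seed,
        subsample_indices=indices,
    )
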