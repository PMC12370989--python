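"""Two-component Gaussian-mixture phenotype assignment.

Animals are clustered in the 3-D feature space (intercept, slope,
sustained mean) with a K=2 Gaussian mixture.  Following the mclust-style
family search, EM is run under each covariance structure in {spherical,
diagonal, tied, full} and the structure with the best (lowest) BIC is
retained.  Components are named by the sustained-mean coordinate of their
means: the component whose mean sits higher on that axis is the
*sustained* phenotype.  This naming rule makes labels comparable across
independent fits, and doubles as the label-alignment rule in resampling
experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .errors import (
    AlignmentError,
    FitFailureError,
    InsufficientDataError,
    StateError,
)
from .features import FEATURE_COLUMNS, feature_matrix
from .synthetic import PHASIC, SUSTAINED

COVARIANCE_STRUCTURES = ("spherical", "diag", "tied", "full")
_SUSTAINED_AXIS = FEATURE_COLUMNS.index("sustained_mean")

#: EM settings (documented defaults): 10 k-means-seeded restarts,
#: log-likelihood tolerance 1e-6, at most 500 iterations, PD floor 1e-6.
N_INIT = 10
EM_TOL = 1e-6
EM_MAX_ITER = 500
REG_COVAR = 1e-6
MAX_REFIT_ATTEMPTS = 5

MODEL_FORMAT_VERSION = 1


def _full_covariances(gm: GaussianMixture) -> np.ndarray:
    """Expand sklearn's packed covariances to two full 3x3 matrices."""
    c = gm.covariances_
    d = gm.means_.shape[1]
    if gm.covariance_type == "full":
        return np.asarray(c)
    if gm.covariance_type == "tied":
        return np.stack([c, c])
    if gm.covariance_type == "diag":
        return np.stack([np.diag(row) for row in c])
    return np.stack([np.eye(d) * v for v in c])  # spherical


@dataclass
class GMMPhenotypeModel:
    """A fitted 2-component mixture with phenotype naming attached."""

    weights: np.ndarray           # (2,), positive, sums to 1
    means: np.ndarray             # (2, 3)
    covariances: np.ndarray       # (2, 3, 3) symmetric PD
    covariance_structure: str
    sustained_component: int      # index of the higher-sustained-mean component
    log_likelihood: float
    bic: float
    n_iterations: int
    seed: int
    _gm: GaussianMixture | None = None

    @property
    def component_labels(self) -> list[str]:
        return [
            SUSTAINED if k == self.sustained_component else PHASIC
            for k in range(2)
        ]

    def posterior(self, features: pd.DataFrame) -> np.ndarray:
        """(n, 2) responsibility matrix; rows sum to 1."""
        if self._gm is None:
            self._rebuild()
        return self._gm.predict_proba(feature_matrix(features))

    def _rebuild(self) -> None:
        """Reconstruct a scoring-capable sklearn mixture from stored arrays."""
        gm = GaussianMixture(n_components=2, covariance_type="full")
        gm.weights_ = self.weights
        gm.means_ = self.means
        gm.covariances_ = self.covariances
        gm.precisions_cholesky_ = np.stack(
            [np.linalg.cholesky(np.linalg.inv(S)).T for S in self.covariances]
        )
        gm.converged_ = True
        self._gm = gm

    def to_json(self, path) -> None:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "kind": "gmm_phenotype_model",
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "covariance_structure": self.covariance_structure,
            "sustained_component": self.sustained_component,
            "naming_rule": "sustained_mean_axis",
            "log_likelihood": self.log_likelihood,
            "bic": self.bic,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "GMMPhenotypeModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise StateError(
                f"unsupported model format version {payload.get('format_version')}"
            )
        return cls(
            weights=np.array(payload["weights"]),
            means=np.array(payload["means"]),
            covariances=np.array(payload["covariances"]),
            covariance_structure=payload["covariance_structure"],
            sustained_component=payload["sustained_component"],
            log_likelihood=payload["log_likelihood"],
            bic=payload["bic"],
            n_iterations=payload["n_iterations"],
            seed=payload["seed"],
        )


def _assignments_frame(ids, labels, posteriors) -> pd.DataFrame:
    return pd.DataFrame(
        {"animal_id": list(ids), "label": labels, "posterior": posteriors}
    )


def fit_phenotype_gmm(
    features: pd.DataFrame, seed: int = 0
) -> tuple[GMMPhenotypeModel, pd.DataFrame]:
    """Fit the 2-component mixture and hard-assign phenotypes.

    Runs EM under every covariance structure, keeps the best-BIC fit, and
    labels each animal by maximum posterior.  Deterministic for a given
    (features, seed).  Raises :class:`InsufficientDataError` for n < 4 and
    :class:`FitFailureError` if EM fails under every structure after the
    documented re-initialization attempts.
    """
    X = feature_matrix(features)
    if X.shape[0] < 4:
        raise InsufficientDataError(
            f"mixture fit needs >= 4 animals, got {X.shape[0]}"
        )

    best: GaussianMixture | None = None
    best_structure = None
    errors: list[str] = []
    for structure in COVARIANCE_STRUCTURES:
        gm = None
        for attempt in range(MAX_REFIT_ATTEMPTS):
            try:
                cand = GaussianMixture(
                    n_components=2,
                    covariance_type=structure,
                    n_init=N_INIT,
                    tol=EM_TOL,
                    max_iter=EM_MAX_ITER,
                    reg_covar=REG_COVAR * 10**attempt,
                    init_params="kmeans",
                    random_state=(seed + 1009 * attempt) % (2**31),
                ).fit(X)
            except Exception as exc:  # degenerate resample, singular cov
                errors.append(f"{structure}: {exc}")
                continue
            if cand.converged_ or cand.n_iter_ >= EM_MAX_ITER:
                gm = cand
                break
        if gm is None:
            continue
        if best is None or gm.bic(X) < best.bic(X):
            best, best_structure = gm, structure

    if best is None:
        raise FitFailureError(
            "EM failed under every covariance structure: " + "; ".join(errors)
        )

    covs = _full_covariances(best)
    sustained_component = int(np.argmax(best.means_[:, _SUSTAINED_AXIS]))
    model = GMMPhenotypeModel(
        weights=np.asarray(best.weights_),
        means=np.asarray(best.means_),
        covariances=covs,
        covariance_structure=best_structure,
        sustained_component=sustained_component,
        log_likelihood=float(best.score(X) * X.shape[0]),
        bic=float(best.bic(X)),
        n_iterations=int(best.n_iter_),
        seed=seed,
        _gm=best,
    )
    return model, assign(model, features)


def assign(model: GMMPhenotypeModel, features: pd.DataFrame) -> pd.DataFrame:
    """Maximum-posterior phenotype labels under a fitted mixture.

    Works for any number of animals, including a single one; the label of
    an animal never depends on which other animals are scored with it.
    """
    if model.weights is None:
        raise StateError("model is not fitted")
    resp = model.posterior(features)
    hard = np.argmax(resp, axis=1)
    names = model.component_labels
    labels = [names[k] for k in hard]
    posterior = resp[np.arange(len(hard)), hard]
    return _assignments_frame(features["animal_id"], labels, posterior)


def align_to_reference(
    labels: pd.DataFrame, reference: pd.DataFrame
) -> dict[str, str]:
    """Label mapping {new -> reference} maximizing agreement on the overlap.

    Both labelings normally use the sustained-mean naming rule, so the
    mapping is the identity; the swap is returned only when it strictly
    increases agreement (ties keep identity).
    """
    merged = labels.merge(
        reference, on="animal_id", suffixes=("_new", "_ref")
    )
    if merged.empty:
        raise AlignmentError("no overlapping animals between labelings")
    same = (merged["label_new"] == merged["label_ref"]).mean()
    identity = {SUSTAINED: SUSTAINED, PHASIC: PHASIC}
    swap = {SUSTAINED: PHASIC, PHASIC: SUSTAINED}
    swapped = (
        merged["label_new"].map(swap) == merged["label_ref"]
    ).mean()
    return swap if swapped > same else identity
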