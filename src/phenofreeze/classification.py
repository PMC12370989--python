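"""Supervised phenotype classifiers with Monte Carlo cross-validation.

Five binary classifiers assign sustained/phasic labels from the 3-D
freezing-curve features: logistic regression, linear discriminant
analysis, linear- and RBF-kernel support vector machines, and random
forests.  Hyperparameters mirror the defaults of the R packages commonly
used for these models (SVM cost 1, scale-based RBF gamma, 500 trees,
unregularized logistic/LDA); no tuning is performed.

Evaluation uses Monte Carlo cross-validation: repeated stratified random
70:30 train/test splits, with accuracy, sensitivity, specificity, F1 and
AUROC averaged over iterations.  The positive class is *sustained*
everywhere, which orients sensitivity/specificity/F1.

Trained models are persisted as :class:`ClassifierBundle`: a versioned
JSON envelope carrying the fitted estimator, the training-data
standardization vectors (so a single animal can be scored exactly as it
would be inside any batch), the archived training data (enabling
retraining with additional cohorts) and metadata (sex, session, n, class
counts, seed).
"""

from __future__ import annotations

import base64
import json
import pickle
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from .errors import (
    BundleFormatError,
    ConfigurationError,
    StateError,
    UndefinedValueError,
    ValidationError,
)
from .features import FEATURE_COLUMNS, feature_matrix
from .synthetic import SUSTAINED

ALGORITHMS = ("logistic", "lda", "svm_linear", "svm_rbf", "random_forest")

#: Best-performing algorithm per (sex, retrieval session), used as the
#: default when training a production bundle for a given setting.
MODEL_REGISTRY = {
    ("female", "MR1"): "logistic",
    ("female", "MR2"): "logistic",
    ("male", "MR1"): "random_forest",
    ("male", "MR2"): "svm_linear",
}

BUNDLE_FORMAT_VERSION = 1
POSITIVE_CLASS = SUSTAINED


# ---------------------------------------------------------------------------
# metrics

@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts with *sustained* as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ConfigurationError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(cls, predicted, truth) -> "ConfusionCounts":
        p = np.asarray(predicted) == POSITIVE_CLASS
        t = np.asarray(truth) == POSITIVE_CLASS
        return cls(
            tp=int(np.sum(p & t)),
            fp=int(np.sum(p & ~t)),
            tn=int(np.sum(~p & ~t)),
            fn=int(np.sum(~p & t)),
        )


@dataclass(frozen=True)
class Metrics:
    """Accuracy, sensitivity, specificity and F1; undefined entries are NaN
    and listed in ``undefined``."""

    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    undefined: tuple[str, ...] = ()


def compute_metrics(c: ConfusionCounts) -> Metrics:
    """Evaluate the four standard confusion-matrix metrics.

        accuracy    = (TP + TN) / (TP + TN + FP + FN)
        sensitivity = TP / (TP + FN)
        specificity = TN / (TN + FP)
        F1          = TP / (TP + 0.5 * (FP + FN))

    A metric whose denominator is zero is flagged undefined (NaN), not an
    error.
    """
    if c.total < 1:
        raise ConfigurationError("confusion counts must total >= 1")
    undefined: list[str] = []

    accuracy = (c.tp + c.tn) / c.total
    if c.tp + c.fn == 0:
        sensitivity = float("nan")
        undefined.append("sensitivity")
    else:
        sensitivity = c.tp / (c.tp + c.fn)
    if c.tn + c.fp == 0:
        specificity = float("nan")
        undefined.append("specificity")
    else:
        specificity = c.tn / (c.tn + c.fp)
    if c.tp + 0.5 * (c.fp + c.fn) == 0:
        f1 = float("nan")
        undefined.append("f1")
    else:
        f1 = c.tp / (c.tp + 0.5 * (c.fp + c.fn))
    return Metrics(accuracy, sensitivity, specificity, f1, tuple(undefined))


def auroc(scores, truth) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve.

    ``scores`` are per-animal sustained scores; ties contribute 1/2.
    """
    t = np.asarray(truth)
    y = (t == POSITIVE_CLASS).astype(int)
    if y.min() == y.max():
        raise UndefinedValueError("AUROC needs both classes in the truth labels")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def cohens_kappa(a, b) -> float:
    """Cohen's kappa between two complete labelings of the same animals.

    kappa = (p_o - p_e) / (1 - p_e) with marginal-product expected
    agreement.  When both labelings are constant and identical, p_e = 1
    and kappa is defined as 1 (perfect, degenerate agreement).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.size == 0:
        raise ValidationError("labelings must be nonempty and equal-length")
    n = a.size
    p_o = float(np.mean(a == b))
    cats = np.union1d(a, b)
    p_e = float(
        sum((np.mean(a == c)) * (np.mean(b == c)) for c in cats)
    )
    if p_e >= 1.0 - 1e-15:
        # both labelings constant; identical -> 1, different is unreachable
        # here because p_e would then be 0
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


# ---------------------------------------------------------------------------
# training / prediction

def _make_estimator(algorithm: str, seed: int):
    if algorithm == "logistic":
        return LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
    if algorithm == "lda":
        return LinearDiscriminantAnalysis()
    if algorithm == "svm_linear":
        return SVC(kernel="linear", C=1.0)
    if algorithm == "svm_rbf":
        return SVC(kernel="rbf", C=1.0, gamma="scale")
    if algorithm == "random_forest":
        return RandomForestClassifier(n_estimators=500, random_state=seed % (2**31))
    raise ConfigurationError(
        f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}"
    )


@dataclass
class ClassifierBundle:
    """A trained classifier plus everything needed to reuse and retrain it."""

    algorithm: str
    estimator: object
    scaler_mean: np.ndarray   # (3,) training means
    scaler_sd: np.ndarray     # (3,) training sds (floored at tiny eps)
    training_features: pd.DataFrame
    training_labels: pd.Series   # indexed like training_features rows
    metadata: dict

    def _check_fitted(self) -> None:
        if self.estimator is None:
            raise StateError("bundle has no fitted estimator")

    def transform(self, features: pd.DataFrame) -> np.ndarray:
        X = feature_matrix(features)
        return (X - self.scaler_mean) / self.scaler_sd


def _labels_series(labels) -> pd.Series:
    if isinstance(labels, pd.DataFrame):
        return labels.set_index("animal_id")["label"]
    return pd.Series(labels)


def train(
    features: pd.DataFrame,
    labels,
    algorithm: str,
    seed: int = 0,
    sex: str | None = None,
    session: str | None = None,
) -> ClassifierBundle:
    """Fit one classifier on a labeled feature table.

    Features are standardized by their training mean/sd, which are stored
    in the bundle so later predictions (including single-animal ones) use
    identical preprocessing.  Deterministic given the seed.
    """
    lab = _labels_series(labels)
    if isinstance(labels, pd.DataFrame):
        y = lab.reindex(features["animal_id"]).to_numpy()
    else:
        y = np.asarray(lab)
    if len(y) != len(features):
        raise ValidationError("labels must cover every animal in features")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError(
            f"training needs both classes; got only {classes.tolist()}"
        )
    if counts.min() < 2:
        raise ValidationError("training needs >= 2 animals per class")

    X = feature_matrix(features)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    Xs = (X - mean) / sd

    est = _make_estimator(algorithm, seed)
    est.fit(Xs, y)
    meta = {
        "sex": sex,
        "session": session,
        "algorithm": algorithm,
        "training_n": int(len(y)),
        "class_counts": {str(c): int(k) for c, k in zip(classes, counts)},
        "seed": int(seed),
        "positive_class": POSITIVE_CLASS,
        "format_version": BUNDLE_FORMAT_VERSION,
    }
    return ClassifierBundle(
        algorithm=algorithm,
        estimator=est,
        scaler_mean=mean,
        scaler_sd=sd,
        training_features=features.reset_index(drop=True),
        training_labels=pd.Series(y, name="label"),
        metadata=meta,
    )


def _score_rows(est, Xs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = est.predict(Xs)
    pos_idx = list(est.classes_).index(POSITIVE_CLASS)
    if hasattr(est, "predict_proba"):
        score = est.predict_proba(Xs)[:, pos_idx]
    else:
        raw = est.decision_function(Xs)
        score = raw if pos_idx == 1 else -raw
    return labels, score


def predict(bundle: ClassifierBundle, features: pd.DataFrame) -> pd.DataFrame:
    """Per-animal label and sustained score.

    The prediction for an animal is bit-for-bit identical whether it is
    scored alone or inside any batch: preprocessing uses the bundle's
    stored training statistics and each row is scored through the
    estimator individually, so no batched linear-algebra path can change
    the result with batch composition.
    """
    bundle._check_fitted()
    if len(features) == 0:
        return pd.DataFrame(columns=["animal_id", "label", "score"])
    Xs = bundle.transform(features)
    est = bundle.estimator
    labels = []
    scores = np.empty(len(Xs))
    for i in range(len(Xs)):
        lab, sc = _score_rows(est, Xs[i : i + 1])
        labels.append(lab[0])
        scores[i] = sc[0]
    return pd.DataFrame(
        {"animal_id": features["animal_id"].to_numpy(),
         "label": labels,
         "score": scores}
    )


def _predict_batch(bundle: ClassifierBundle, features: pd.DataFrame) -> pd.DataFrame:
    """Batched scoring for internal evaluation loops (no cross-batch
    contract; numerically equal to :func:`predict` up to BLAS rounding)."""
    bundle._check_fitted()
    if len(features) == 0:
        return pd.DataFrame(columns=["animal_id", "label", "score"])
    labels, scores = _score_rows(bundle.estimator, bundle.transform(features))
    return pd.DataFrame(
        {"animal_id": features["animal_id"].to_numpy(),
         "label": labels,
         "score": scores}
    )


# ---------------------------------------------------------------------------
# Monte Carlo cross-validation

@dataclass
class MetricSummary:
    """Per-iteration and averaged MC-CV metrics for one algorithm."""

    algorithm: str
    iterations: int
    train_fraction: float
    per_iteration: pd.DataFrame  # accuracy, sensitivity, specificity, f1, auroc
    mean: dict[str, float]
    sd: dict[str, float]
    excluded_iterations: int = 0

    @property
    def mean_accuracy(self) -> float:
        return self.mean["accuracy"]


def _stratified_split(y: np.ndarray, train_frac: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random split keeping >= 1 animal of each class on each side."""
    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        n_train = int(round(train_frac * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def monte_carlo_cv(
    features: pd.DataFrame,
    labels,
    algorithm: str,
    iters: int = 1000,
    train_frac: float = 0.7,
    seed: int = 0,
) -> MetricSummary:
    """Monte Carlo cross-validation of one algorithm.

    Each iteration draws a stratified random 70:30 (by default) split,
    trains on the larger part and computes the confusion-matrix metrics
    and AUROC on the held-out part; the summary averages over iterations.
    Deterministic given the seed.
    """
    if iters < 1:
        raise ConfigurationError(f"iters must be >= 1, got {iters}")
    if not 0.0 < train_frac < 1.0:
        raise ConfigurationError("train_frac must lie strictly between 0 and 1")
    lab = _labels_series(labels)
    if isinstance(labels, pd.DataFrame):
        y = lab.reindex(features["animal_id"]).to_numpy()
    else:
        y = np.asarray(lab)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValidationError("MC-CV needs >= 2 animals in each class")

    root = np.random.SeedSequence(seed)
    children = root.spawn(iters)
    rows = []
    excluded = 0
    for child in children:
        rng = np.random.default_rng(child)
        tr, te = _stratified_split(y, train_frac, rng)
        if len(np.unique(y[te])) < 2:
            excluded += 1  # unreachable with stratification; kept defensive
            continue
        fit_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        bundle = train(
            features.iloc[tr].reset_index(drop=True), y[tr], algorithm, seed=fit_seed
        )
        pred = _predict_batch(bundle, features.iloc[te].reset_index(drop=True))
        m = compute_metrics(ConfusionCounts.from_labels(pred["label"], y[te]))
        rows.append(
            {
                "accuracy": m.accuracy,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "f1": m.f1,
                "auroc": auroc(pred["score"], y[te]),
            }
        )
    per_iter = pd.DataFrame(rows)
    mean = {k: float(np.nanmean(per_iter[k])) for k in per_iter.columns}
    sd = {k: float(np.nanstd(per_iter[k], ddof=1)) if len(per_iter) > 1 else 0.0
          for k in per_iter.columns}
    return MetricSummary(
        algorithm=algorithm,
        iterations=iters,
        train_fraction=train_frac,
        per_iteration=per_iter,
        mean=mean,
        sd=sd,
        excluded_iterations=excluded,
    )


def select_best(summaries: list[MetricSummary]) -> str:
    """Pick the algorithm with the best MC-CV performance.

    Highest mean accuracy wins; ties break by mean sensitivity, then mean
    specificity, then the fixed order of :data:`ALGORITHMS`.
    """
    if not summaries:
        raise ConfigurationError("select_best needs at least one summary")
    def key(s: MetricSummary):
        order = ALGORITHMS.index(s.algorithm) if s.algorithm in ALGORITHMS else 99
        return (
            -s.mean.get("accuracy", float("-inf")),
            -s.mean.get("sensitivity", float("-inf")),
            -s.mean.get("specificity", float("-inf")),
            order,
        )
    return min(summaries, key=key).algorithm


# ---------------------------------------------------------------------------
# persistence and retraining

def save_bundle(bundle: ClassifierBundle, path) -> None:
    """Serialize a bundle to versioned JSON.

    Standardization vectors, metadata and the archived training data are
    stored as plain JSON; the fitted estimator is an opaque base64-encoded
    payload.  ``load_bundle(save_bundle(b))`` predicts identically to
    ``b``.
    """
    bundle._check_fitted()
    payload = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "kind": "classifier_bundle",
        "algorithm": bundle.algorithm,
        "metadata": bundle.metadata,
        "scaler_mean": bundle.scaler_mean.tolist(),
        "scaler_sd": bundle.scaler_sd.tolist(),
        "training_features": {
            c: bundle.training_features[c].tolist()
            for c in ["animal_id", *FEATURE_COLUMNS]
        },
        "training_labels": bundle.training_labels.tolist(),
        "estimator_pickle_b64": base64.b64encode(
            pickle.dumps(bundle.estimator)
        ).decode("ascii"),
    }
    Path(path).write_text(json.dumps(payload))


def load_bundle(path) -> ClassifierBundle:
    """Load a bundle saved by :func:`save_bundle`; checks the format version."""
    try:
        payload = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise BundleFormatError(f"{path}: corrupt bundle file ({exc})") from exc
    if not isinstance(payload, dict) or payload.get("kind") != "classifier_bundle":
        raise BundleFormatError(f"{path}: not a classifier bundle")
    if payload.get("format_version") != BUNDLE_FORMAT_VERSION:
        raise BundleFormatError(
            f"{path}: unsupported bundle format version "
            f"{payload.get('format_version')!r}"
        )
    try:
        estimator = pickle.loads(
            base64.b64decode(payload["estimator_pickle_b64"])
        )
        tf = pd.DataFrame(payload["training_features"])
        return ClassifierBundle(
            algorithm=payload["algorithm"],
            estimator=estimator,
            scaler_mean=np.array(payload["scaler_mean"]),
            scaler_sd=np.array(payload["scaler_sd"]),
            training_features=tf,
            training_labels=pd.Series(payload["training_labels"], name="label"),
            metadata=payload["metadata"],
        )
    except (KeyError, ValueError, pickle.UnpicklingError) as exc:
        raise BundleFormatError(f"{path}: corrupt bundle file ({exc})") from exc


def retrain_with(
    bundle: ClassifierBundle,
    features: pd.DataFrame,
    labels,
    seed: int | None = None,
    sex: str | None = None,
    session: str | None = None,
) -> ClassifierBundle:
    """Retrain on the union of the bundle's archived data and new data.

    When the new cohort's ``sex``/``session`` are given they must match
    the bundle's metadata.  The returned bundle records provenance
    (previous n, added n).  With an empty addition this reproduces a
    bundle equivalent to the original.
    """
    bundle._check_fitted()
    if sex is not None or session is not None:
        check_retrain_metadata(
            bundle,
            sex if sex is not None else bundle.metadata.get("sex"),
            session if session is not None else bundle.metadata.get("session"),
        )
    new_lab = _labels_series(labels)
    if isinstance(labels, pd.DataFrame):
        y_new = new_lab.reindex(features["animal_id"]).to_numpy()
    else:
        y_new = np.asarray(new_lab)
    if len(y_new) != len(features):
        raise ValidationError("labels must cover every animal in features")

    all_features = pd.concat(
        [bundle.training_features[["animal_id", *FEATURE_COLUMNS]],
         features[["animal_id", *FEATURE_COLUMNS]]],
        ignore_index=True,
    )
    all_y = np.concatenate([bundle.training_labels.to_numpy(), y_new])
    new_bundle = train(
        all_features,
        all_y,
        bundle.algorithm,
        seed=bundle.metadata.get("seed", 0) if seed is None else seed,
        sex=bundle.metadata.get("sex"),
        session=bundle.metadata.get("session"),
    )
    new_bundle.metadata["retrained_from_n"] = bundle.metadata.get("training_n")
    new_bundle.metadata["added_n"] = int(len(features))
    return new_bundle


def check_retrain_metadata(bundle: ClassifierBundle, sex: str, session: str) -> None:
    """Raise unless the new cohort's sex/session match the bundle's."""
    b_sex = bundle.metadata.get("sex")
    b_session = bundle.metadata.get("session")
    if (b_sex is not None and sex != b_sex) or (
        b_session is not None and session != b_session
    ):
        raise ConfigurationError(
            f"retraining data ({sex}, {session}) does not match bundle "
            f"metadata ({b_sex}, {b_session})"
        )
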