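"""Log-linear freezing-curve features.

Each animal's freezing during CS presentation is modelled as

    freezing_t = beta0 + beta1 * ln(t),     t = 1..12 (1-based CS bin index)

by ordinary least squares with the natural log.  ln(1) = 0 makes the
intercept beta0 the modelled freezing at CS onset; the slope beta1 is the
decay rate of freezing on the raw percent scale (near 0 for sustained
responders, strongly negative for phasic ones).  The third feature is the
arithmetic mean of the *raw* freezing values over the sustained window (the
last 3.5 min of CS presentation) — the dominant phenotype marker.

Feature tables are plain DataFrames with columns
``animal_id, intercept, slope, sustained_mean, r_squared`` and are consumed
unstandardized by the clustering stage; classifiers standardize internally.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import CSWindow, FreezingDataset
from .errors import InsufficientDataError, ValidationError

FEATURE_COLUMNS = ["intercept", "slope", "sustained_mean"]


def fit_log_linear(cs_values) -> tuple[float, float, float]:
    """OLS fit of freezing on ln(bin index) over the CS window.

    Returns ``(intercept, slope, r_squared)``.  R^2 is defined as 1 when
    the residual sum of squares is 0 — including the constant-input case,
    where the fit reproduces the data exactly with slope 0.
    """
    y = np.asarray(cs_values, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise InsufficientDataError(
            f"log-linear fit needs >= 3 bins, got {y.size}"
        )
    if not np.all(np.isfinite(y)):
        raise ValidationError("non-finite freezing value in CS window")
    x = np.log(np.arange(1, y.size + 1, dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_res <= 1e-12 * max(ss_tot, 1.0):
        r2 = 1.0
    elif ss_tot == 0.0:
        r2 = 1.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(intercept), float(slope), float(min(max(r2, 0.0), 1.0))


def sustained_mean(bins, window: CSWindow) -> float:
    """Mean raw freezing over the sustained window (last 3.5 min of CS)."""
    b = np.asarray(bins, dtype=float)
    if b.ndim != 1:
        raise ValidationError("bins must be a 1-D per-animal vector")
    if b.size < window.max_bin:
        raise IndexError(
            f"bins length {b.size} cannot index sustained bins up to "
            f"{window.max_bin}"
        )
    return float(np.mean(b[[i - 1 for i in window.sustained_bins]]))


def extract_features(
    dataset: FreezingDataset, window: CSWindow | None = None
) -> pd.DataFrame:
    """Per-animal 3-D feature table (plus fit quality), order preserved.

    Intercept and slope come from :func:`fit_log_linear` on the CS-window
    values; ``sustained_mean`` from the raw bins.  Errors in a per-animal
    fit are re-raised tagged with the animal_id.
    """
    if window is None:
        window = dataset.cs_window()
    rows = []
    cs = dataset.bins[:, [b - 1 for b in window.cs_bins]]
    for i, animal_id in enumerate(dataset.animal_ids):
        try:
            intercept, slope, r2 = fit_log_linear(cs[i])
            sm = sustained_mean(dataset.bins[i], window)
        except Exception as exc:
            raise type(exc)(f"animal_id {animal_id!r}: {exc}") from exc
        rows.append(
            {
                "animal_id": animal_id,
                "intercept": intercept,
                "slope": slope,
                "sustained_mean": sm,
                "r_squared": r2,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["animal_id", "intercept", "slope", "sustained_mean", "r_squared"],
    )


def feature_matrix(features: pd.DataFrame) -> np.ndarray:
    """The (n, 3) numeric matrix [intercept, slope, sustained_mean]."""
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise ValidationError(f"feature table missing columns {missing}")
    X = features[FEATURE_COLUMNS].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValidationError("non-finite value in feature table")
    return X
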