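"""Freezing-data schema, CS-window conventions and CSV I/O.

A retrieval session is scored as percent time freezing per 30-s bin.  Under
the standard protocol the 6-min tone (CS, conditioned stimulus) occupies
bins 13-24; a shortened protocol moves the same 12-bin window to bins 7-18.
Within the CS window the first 5 bins (2.5 min) are the *phasic* component
of the freezing curve and the last 7 bins (3.5 min) the *sustained*
component.  All bin indices are 1-based throughout the package.

Datasets are exchanged as wide CSV: one row per animal with columns
``animal_id, sex, batch, bin_1 .. bin_N``; session and protocol are supplied
by the caller (they are study-design facts, not per-row measurements).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError, ValidationError

SEXES = ("female", "male")
SESSIONS = ("adaptation", "MR1", "MR2")
PROTOCOLS = ("standard", "shortened")

#: Number of CS bins under a 6-min tone analysed in 30-s bins.
CS_N_BINS = 12
#: First 2.5 min of the CS window (5 bins): the phasic component.
PHASIC_N_BINS = 5
#: Last 3.5 min of the CS window (7 bins): the sustained component.
SUSTAINED_N_BINS = 7

_CS_START = {"standard": 13, "shortened": 7}


@dataclass(frozen=True)
class CSWindow:
    """1-based bin indices of the CS presentation and its two components."""

    cs_bins: tuple[int, ...]
    phasic_bins: tuple[int, ...]
    sustained_bins: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.phasic_bins + self.sustained_bins != self.cs_bins:
            raise ConfigurationError(
                "phasic and sustained bins must partition the CS window in order"
            )
        if len(self.cs_bins) != CS_N_BINS:
            raise ConfigurationError(
                f"CS window must span {CS_N_BINS} bins, got {len(self.cs_bins)}"
            )

    @property
    def max_bin(self) -> int:
        return self.cs_bins[-1]


def cs_window_for(protocol: str) -> CSWindow:
    """Return the CS window for a protocol variant.

    ``standard``: CS bins 13-24 (phasic 13-17, sustained 18-24).
    ``shortened``: CS bins 7-18 (phasic 7-11, sustained 12-18) — the same
    window shifted earlier by 6 bins.
    """
    if protocol not in PROTOCOLS:
        raise ConfigurationError(
            f"unknown protocol {protocol!r}; expected one of {PROTOCOLS}"
        )
    start = _CS_START[protocol]
    cs = tuple(range(start, start + CS_N_BINS))
    return CSWindow(
        cs_bins=cs,
        phasic_bins=cs[:PHASIC_N_BINS],
        sustained_bins=cs[PHASIC_N_BINS:],
    )


@dataclass
class FreezingDataset:
    """Per-animal freezing time series for one session of one protocol.

    Parameters
    ----------
    animals:
        DataFrame with columns ``animal_id`` (unique strings), ``sex``
        (``female``/``male``) and ``batch``; row order is preserved by
        every operation.
    bins:
        Array of shape ``(n_animals, n_bins)`` of percent freezing per
        30-s bin, each value in [0, 100].
    session, protocol:
        Shared by all animals in the dataset.
    """

    animals: pd.DataFrame
    bins: np.ndarray
    session: str
    protocol: str = "standard"

    def __post_init__(self) -> None:
        self.animals = self.animals.reset_index(drop=True)
        self.bins = np.asarray(self.bins, dtype=float)
        if self.bins.ndim == 1:
            self.bins = self.bins.reshape(0, 0) if self.bins.size == 0 else self.bins
        problems = validate(self)
        if problems:
            raise ValidationError("; ".join(problems))

    @property
    def n_animals(self) -> int:
        return len(self.animals)

    @property
    def n_bins(self) -> int:
        return self.bins.shape[1] if self.bins.ndim == 2 else 0

    @property
    def animal_ids(self) -> list[str]:
        return self.animals["animal_id"].tolist()

    def cs_window(self) -> CSWindow:
        return cs_window_for(self.protocol)

    def cs_values(self) -> np.ndarray:
        """Freezing values restricted to the CS window, shape (n, 12)."""
        w = self.cs_window()
        cols = [b - 1 for b in w.cs_bins]
        return self.bins[:, cols]

    def subset(self, indices) -> "FreezingDataset":
        indices = list(indices)
        return replace(
            self,
            animals=self.animals.iloc[indices].reset_index(drop=True),
            bins=self.bins[indices],
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, FreezingDataset):
            return NotImplemented
        return (
            self.session == other.session
            and self.protocol == other.protocol
            and self.animals.equals(other.animals)
            and self.bins.shape == other.bins.shape
            and np.array_equal(self.bins, other.bins)
        )


def validate(dataset: FreezingDataset) -> list[str]:
    """Check all dataset invariants; return one message per violation.

    An empty list means the dataset is valid.  Messages name the animal,
    the field and the rule so they can be surfaced directly to users.
    """
    problems: list[str] = []
    ani = dataset.animals
    expected_cols = {"animal_id", "sex", "batch"}
    missing = expected_cols - set(ani.columns)
    if missing:
        return [f"animals table missing columns: {sorted(missing)}"]

    if dataset.session not in SESSIONS:
        problems.append(
            f"session {dataset.session!r} not one of {SESSIONS}"
        )
    if dataset.protocol not in PROTOCOLS:
        problems.append(
            f"protocol {dataset.protocol!r} not one of {PROTOCOLS}"
        )
        return problems

    dup = ani["animal_id"][ani["animal_id"].duplicated()].unique()
    for a in dup:
        problems.append(f"animal_id {a!r}: animal_id must be unique")
    bad_sex = ani.loc[~ani["sex"].isin(SEXES), "animal_id"]
    for a in bad_sex:
        problems.append(f"animal_id {a!r}: sex must be one of {SEXES}")

    n = len(ani)
    if dataset.bins.shape[0] != n:
        problems.append(
            f"bins has {dataset.bins.shape[0]} rows for {n} animals"
        )
        return problems

    min_bins = cs_window_for(dataset.protocol).max_bin
    if n and dataset.n_bins < min_bins:
        problems.append(
            f"bins length {dataset.n_bins} shorter than CS window "
            f"(needs >= {min_bins} for protocol {dataset.protocol!r})"
        )
    if n and dataset.bins.size:
        finite = np.isfinite(dataset.bins)
        in_range = finite & (dataset.bins >= 0) & (dataset.bins <= 100)
        bad = np.argwhere(~in_range)
        for i, j in bad[:50]:  # cap message volume on badly broken files
            problems.append(
                f"animal_id {ani['animal_id'].iloc[i]!r}: bin_{j + 1} value "
                f"{dataset.bins[i, j]!r} outside [0, 100]"
            )
    return problems


def _bin_columns(columns) -> list[str]:
    cols = [c for c in columns if c.startswith("bin_")]
    try:
        order = sorted(cols, key=lambda c: int(c.split("_", 1)[1]))
    except ValueError as exc:
        raise SchemaError(f"malformed bin column name: {exc}") from exc
    if order != [f"bin_{i}" for i in range(1, len(order) + 1)]:
        raise SchemaError(
            "bin columns must be contiguous bin_1..bin_N; got "
            + ", ".join(order)
        )
    return order


def read_freezing_csv(path, protocol: str, session: str) -> FreezingDataset:
    """Read a wide freezing CSV into a validated :class:`FreezingDataset`.

    The file must carry a header row with ``animal_id, sex, batch`` and
    contiguous ``bin_1..bin_N`` columns.  Row order is preserved.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        dtype={"animal_id": str, "sex": str, "batch": str},
        float_precision="round_trip",
    )
    required = ["animal_id", "sex", "batch"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    bin_cols = _bin_columns(df.columns)
    if not bin_cols and len(df):
        raise SchemaError(f"{path}: no bin_* columns found")
    bins = df[bin_cols].to_numpy(dtype=float) if bin_cols else np.empty((len(df), 0))
    try:
        return FreezingDataset(
            animals=df[required].copy(),
            bins=bins if len(df) else np.empty((0, len(bin_cols))),
            session=session,
            protocol=protocol,
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_freezing_csv(dataset: FreezingDataset, path) -> None:
    """Write the wide CSV dialect read by :func:`read_freezing_csv`.

    ``read_freezing_csv(write_freezing_csv(d)) == d`` for all valid
    datasets (full float precision is preserved).
    """
    path = Path(path)
    out = dataset.animals.copy()
    for j in range(dataset.n_bins):
        out[f"bin_{j + 1}"] = dataset.bins[:, j]
    out.to_csv(path, index=False, float_format="%.17g")
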