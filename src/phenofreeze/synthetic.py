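"""Synthetic cohorts of sustained and phasic freezers.

The generator emulates the two-phenotype structure of conditioned-freezing
data from prolonged (6-min) tone retrieval: *sustained* responders hold a
high freezing plateau through the late CS phase, *phasic* responders start
high and decay roughly log-linearly within the tone.  Each animal's CS-window
curve is drawn from

    freezing(t) = clip(onset + decay * ln(t) + noise_t, 0, 100),   t = 1..12

with per-animal ``onset`` and ``decay`` drawn from phenotype-specific normal
distributions, i.i.d. Gaussian bin noise, and pre-CS bins drawn from a
baseline distribution.  Values are clipped to the percent scale, which also
mimics the floor effect visible in decayed phasic curves.

The default specs reproduce the study conditions qualitatively: the female
cohort is 168 animals with sustained fraction 78/168, the male cohort 224
animals with sustained fraction 88/224, males freeze less and their phasic
decay is steeper.  The parameter constants are versioned synthetic
calibrations chosen to produce clearly separated phenotypes — they are not
estimates of any real cohort's feature distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data_model import CS_N_BINS, FreezingDataset, cs_window_for
from .errors import ConfigurationError

#: Phenotype labels, also used as class labels downstream.
SUSTAINED = "sustained"
PHASIC = "phasic"


@dataclass(frozen=True)
class PhenotypeParams:
    """Generating parameters of one phenotype's freezing curves (percent)."""

    onset_mean: float
    onset_sd: float
    decay_mean: float
    decay_sd: float

    def check(self, tag: str) -> None:
        if self.onset_sd < 0 or self.decay_sd < 0:
            raise ConfigurationError(f"{tag}: standard deviations must be >= 0")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Full recipe for one synthetic cohort.

    ``sustained_proportion`` is the Bernoulli probability that an animal is
    a sustained responder; ``fixed_counts=True`` instead assigns exactly
    ``round(n * sustained_proportion)`` sustained animals (for
    exact-recovery tests).  ``batch_shift`` adds a constant to every bin
    before clipping, emulating a batch-level location shift.
    """

    n: int
    sex: str
    sustained_proportion: float
    protocol: str = "standard"
    sustained: PhenotypeParams = PhenotypeParams(75.0, 8.0, -3.0, 2.0)
    phasic: PhenotypeParams = PhenotypeParams(70.0, 10.0, -22.0, 4.0)
    baseline_mean: float = 15.0
    baseline_sd: float = 8.0
    bin_noise_sd: float = 6.0
    batch_shift: float = 0.0
    batch: str = "SIM"
    seed: int = 0
    fixed_counts: bool = False

    def check(self) -> None:
        if self.n < 0:
            raise ConfigurationError("n must be >= 0")
        if not 0.0 <= self.sustained_proportion <= 1.0:
            raise ConfigurationError("sustained_proportion must lie in [0, 1]")
        if self.baseline_sd < 0 or self.bin_noise_sd < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        self.sustained.check("sustained")
        self.phasic.check("phasic")
        cs_window_for(self.protocol)  # raises on unknown protocol


def default_spec(sex: str, **overrides) -> SyntheticCohortSpec:
    """Study-condition cohort spec for one sex.

    Female: n=168, sustained fraction 78/168; male: n=224, sustained
    fraction 88/224, with lower freezing onset and steeper phasic decay
    than females.  Keyword overrides are applied on top (e.g. ``n=40``).
    """
    if sex == "female":
        spec = SyntheticCohortSpec(
            n=168,
            sex="female",
            sustained_proportion=78 / 168,
            sustained=PhenotypeParams(75.0, 8.0, -3.0, 2.0),
            phasic=PhenotypeParams(70.0, 10.0, -22.0, 4.0),
            baseline_mean=15.0,
            baseline_sd=8.0,
        )
    elif sex == "male":
        spec = SyntheticCohortSpec(
            n=224,
            sex="male",
            sustained_proportion=88 / 224,
            sustained=PhenotypeParams(65.0, 9.0, -4.0, 2.0),
            phasic=PhenotypeParams(58.0, 10.0, -26.0, 4.0),
            baseline_mean=10.0,
            baseline_sd=6.0,
        )
    else:
        raise ConfigurationError(f"unknown sex {sex!r}; expected 'female' or 'male'")
    return replace(spec, **overrides) if overrides else spec


def reduced_separation_spec(sex: str, **overrides) -> SyntheticCohortSpec:
    """A deliberately overlapping mixture for small-sample instability studies.

    The phasic decay is pulled towards the sustained one and noise is
    inflated, so a 2-component mixture fitted on a handful of animals can
    no longer recover the full-cohort partition reliably.
    """
    base = default_spec(sex)
    spec = replace(
        base,
        sustained=replace(base.sustained, decay_mean=-6.0, decay_sd=4.0),
        phasic=replace(base.phasic, decay_mean=-13.0, decay_sd=5.0,
                       onset_mean=base.sustained.onset_mean - 6.0),
        bin_noise_sd=9.0,
    )
    return replace(spec, **overrides) if overrides else spec


def generate_cohort(spec: SyntheticCohortSpec) -> tuple[FreezingDataset, pd.Series]:
    """Draw one labeled cohort from a spec.

    Returns the dataset (an MR1-session :class:`FreezingDataset` under the
    spec's protocol) and a Series of true phenotype labels indexed by
    animal_id.  The same spec (including seed) always produces the same
    cohort, byte for byte.
    """
    spec.check()
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    window = cs_window_for(spec.protocol)
    n_bins = window.max_bin  # session ends with the CS under both protocols

    if spec.fixed_counts:
        n_sus = int(round(n * spec.sustained_proportion))
        is_sustained = np.zeros(n, dtype=bool)
        is_sustained[:n_sus] = True
        rng.shuffle(is_sustained)
    else:
        is_sustained = rng.random(n) < spec.sustained_proportion

    bins = np.empty((n, n_bins))
    # Pre-CS bins: baseline freezing, no phenotype structure.
    pre_cols = [b for b in range(1, n_bins + 1) if b not in window.cs_bins]
    bins[:, [b - 1 for b in pre_cols]] = rng.normal(
        spec.baseline_mean, spec.baseline_sd, size=(n, len(pre_cols))
    )

    t = np.arange(1, CS_N_BINS + 1)
    log_t = np.log(t)
    onset = np.where(
        is_sustained,
        rng.normal(spec.sustained.onset_mean, spec.sustained.onset_sd, n),
        rng.normal(spec.phasic.onset_mean, spec.phasic.onset_sd, n),
    )
    decay = np.where(
        is_sustained,
        rng.normal(spec.sustained.decay_mean, spec.sustained.decay_sd, n),
        rng.normal(spec.phasic.decay_mean, spec.phasic.decay_sd, n),
    )
    curves = onset[:, None] + decay[:, None] * log_t[None, :]
    curves += rng.normal(0.0, spec.bin_noise_sd, size=(n, CS_N_BINS))
    bins[:, [b - 1 for b in window.cs_bins]] = curves

    bins = np.clip(bins + spec.batch_shift, 0.0, 100.0)

    ids = [f"{spec.batch}-{spec.sex[0].upper()}{i + 1:04d}" for i in range(n)]
    animals = pd.DataFrame(
        {"animal_id": ids, "sex": spec.sex, "batch": spec.batch}
        if n
        else {"animal_id": pd.Series(dtype=str),
              "sex": pd.Series(dtype=str),
              "batch": pd.Series(dtype=str)}
    )
    dataset = FreezingDataset(
        animals=animals,
        bins=bins,
        session="MR1",
        protocol=spec.protocol,
    )
    labels = pd.Series(
        np.where(is_sustained, SUSTAINED, PHASIC), index=ids, name="label", dtype=object
    )
    return dataset, labels
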