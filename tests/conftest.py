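import numpy as np
import pandas as pd
import pytest

import phenofreeze as pf


def blob_features(rng, mu, n, sd=1.0, prefix="A"):
    """Gaussian blob in (intercept, slope, sustained_mean) space."""
    X = rng.normal(mu, sd, size=(n, 3))
    X[:, 2] = np.clip(X[:, 2], 0, 100)
    return pd.DataFrame(
        {
            "animal_id": [f"{prefix}{i:04d}" for i in range(n)],
            "intercept": X[:, 0],
            "slope": X[:, 1],
            "sustained_mean": X[:, 2],
            "r_squared": 0.9,
        }
    )


@pytest.fixture(scope="session")
def separable_features():
    """Two well-separated blobs with ground-truth labels.

    The (60, -2, 60) blob is the sustained one under the naming rule.
    """
    rng = np.random.default_rng(42)
    sus = blob_features(rng, (60.0, -2.0, 60.0), 100, sd=1.0, prefix="S")
    pha = blob_features(rng, (40.0, -25.0, 10.0), 100, sd=1.0, prefix="P")
    feats = pd.concat([sus, pha], ignore_index=True)
    truth = pd.Series(
        [pf.SUSTAINED] * 100 + [pf.PHASIC] * 100,
        index=feats["animal_id"],
        name="label",
    )
    return feats, truth


@pytest.fixture(scope="session")
def female_cohort():
    """Default study-condition female cohort with generator truth."""
    spec = pf.default_spec("female", seed=11)
    dataset, labels = pf.generate_cohort(spec)
    feats = pf.extract_features(dataset)
    return dataset, labels, feats


@pytest.fixture(scope="session")
def small_fixture_bundle(separable_features):
    """Logistic bundle trained on a 60-animal separable subset."""
    feats, truth = separable_features
    sub = pd.concat([feats.iloc[:30], feats.iloc[100:130]], ignore_index=True)
    y = truth.loc[sub["animal_id"]].to_numpy()
    bundle = pf.train(sub, y, "logistic", seed=5, sex="female", session="MR1")
    return sub, y, bundle
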