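import numpy as np
import pytest

from immunotexture import generate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """3 classes x 12 images, enough for five stratified folds."""
    return generate_dataset(n_per_class=12, seed=7, size=256)


@pytest.fixture(scope="session")
def blob_dataset():
    """Well-separated 3-class Gaussian blobs in 30-D with stratified folds."""
    import pandas as pd

    from immunotexture import FEATURE_NAMES, LabeledDataset, assign_folds

    rng = np.random.default_rng(0)
    centers = {"normal": 0.0, "cirrhosis": 6.0, "cancer": 12.0}
    v = np.ones(30) / np.sqrt(30)  # single latent class axis
    rows, labels = [], []
    for label, mu in centers.items():
        t = mu + rng.normal(0, 1.0, 30)
        rows.append(t[:, None] * v[None, :] + 0.5 * rng.normal(0, 1, (30, 30)))
        labels += [label] * 30
    features = pd.DataFrame(np.vstack(rows), columns=list(FEATURE_NAMES))
    labels = np.asarray(labels)
    return LabeledDataset(features=features, labels=labels, fold_id=assign_folds(labels, seed=0))
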