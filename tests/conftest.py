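import numpy as np
import pandas as pd
import pytest

from cryclass import synthcry
from cryclass.features import FeatureMatrix


@pytest.fixture(scope="session")
def separable_config():
    return synthcry.preset("separable")


@pytest.fixture(scope="session")
def small_dataset(separable_config):
    """10 clips/class at test scale, with clip-level features."""
    from cryclass.features import extract_feature_matrix

    clips, manifest = synthcry.generate_dataset(separable_config, 10, seed=11)
    fm = extract_feature_matrix([(c.clip, c.sex) for c in clips])
    return clips, manifest, fm


def make_blobs_matrix(n_per_class=40, separation=4.0, n_features=4, seed=0, classes=("a", "b", "c")):
    """Gaussian blobs wrapped as a FeatureMatrix with known-family column names."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for k, c in enumerate(classes):
        center = np.zeros(n_features)
        center[k % n_features] = separation
        rows.append(rng.normal(center, 1.0, size=(n_per_class, n_features)))
        labels += [c] * n_per_class
    X = pd.DataFrame(np.vstack(rows), columns=[f"mfcc_{i+1}" for i in range(n_features)])
    return FeatureMatrix(X, pd.Series(labels))


@pytest.fixture
def blobs():
    return make_blobs_matrix
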