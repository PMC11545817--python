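import numpy as np
import pytest

from isonut import default_study_config, generate, merge_classes

#: Three-class design: Mediterranean origins pooled against Chile and Georgia.
THREE_CLASS_MERGE = {"CHL": "CHL", "ESP": "ESP+ITA", "ITA": "ESP+ITA", "GEO": "GEO"}


@pytest.fixture(scope="session")
def study_dataset():
    """One 207-sample draw from the published study design."""
    return generate(default_study_config(), seed=7)


@pytest.fixture(scope="session")
def merged_dataset(study_dataset):
    return merge_classes(study_dataset, THREE_CLASS_MERGE)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def separable_toy(n_per_class=15, spread=0.01, seed=0):
    """Three well-separated Gaussian blobs in 8-marker space."""
    from isonut import IsotopeDataset, MARKER_NAMES

    rng = np.random.default_rng(seed)
    base = np.linspace(0.0, 7.0, len(MARKER_NAMES))
    centroids = {  # non-colinear, mutually distant
        "A": base + 10.0 * np.eye(len(MARKER_NAMES))[0],
        "B": base + 10.0 * np.eye(len(MARKER_NAMES))[3],
        "C": base - 10.0 * np.eye(len(MARKER_NAMES))[6],
    }
    ids, origins, years, rows = [], [], [], []
    for lab, mu in centroids.items():
        for i in range(n_per_class):
            ids.append(f"{lab}{i}")
            origins.append(lab)
            years.append(2020 + i % 2)
            rows.append(mu + spread * rng.standard_normal(len(mu)))
    return IsotopeDataset(
        np.array(ids, dtype=object),
        np.array(origins, dtype=object),
        np.array(years, dtype=int),
        np.vstack(rows),
    )
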