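import numpy as np
import pytest

from nanovote.forcecurve import ProbeSpec
from nanovote.synthdata import AcquisitionSpec


@pytest.fixture(scope="session")
def probe() -> ProbeSpec:
    return ProbeSpec()


@pytest.fixture(scope="session")
def acq() -> AcquisitionSpec:
    return AcquisitionSpec()


@pytest.fixture(scope="session")
def quiet_acq() -> AcquisitionSpec:
    return AcquisitionSpec(noise_sigma=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_blob_records(n_per_class: int, seed: int, n_features: int = 6,
                      informative: tuple[int, ...] = (0, 1, 2)):
    """Well-separated 3-class Gaussian blobs shaped like a pixel table.

    Class signal lives only in the ``informative`` feature columns; the
    rest are pure noise.  Returns a DataFrame with the six canonical
    feature names (plus X7, X8, ... beyond six) and a Category column.
    """
    import pandas as pd

    from nanovote.mapbuild import FEATURES

    rng = np.random.default_rng(seed)
    names = list(FEATURES)[:n_features] + [
        f"X{i}" for i in range(7, n_features + 1)
    ]
    centers = np.zeros((3, n_features))
    for k in range(3):
        for j in informative:
            centers[k, j] = [(-1.0), 0.0, 1.0][(k + j) % 3] * 2.0
    X = np.vstack(
        [rng.normal(centers[k], 0.4, size=(n_per_class, n_features)) for k in range(3)]
    )
    y = np.repeat(["M0", "M1", "M2"], n_per_class)
    frame = pd.DataFrame(X, columns=names[:n_features])
    frame["Category"] = y
    return frame.sample(frac=1.0, random_state=seed).reset_index(drop=True)
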