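import warnings

import numpy as np
import pytest

from pepstack.encoders import EncoderSpec, FeatureMatrix
from pepstack.peptide_io import LabeledDataset, PeptideSequence

# keep CI output readable: the sklearn/lightgbm interop warnings carry no
# information for ndarray-based pipelines
warnings.filterwarnings("ignore", message="X does not have valid feature names")

#: the two published example peptides, one per class
POSITIVE_EXAMPLE = "RPFERDISNVPFS"
NEGATIVE_EXAMPLE = "SHLVEALYLVAGERG"


@pytest.fixture
def example_dataset() -> LabeledDataset:
    return LabeledDataset(
        [
            PeptideSequence("pos1", POSITIVE_EXAMPLE),
            PeptideSequence("neg1", NEGATIVE_EXAMPLE),
        ],
        np.array([1, 0]),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def blob_matrix(rng) -> tuple[FeatureMatrix, np.ndarray]:
    """Two well-separated Gaussian blobs, imbalanced 20:60, 5 features."""
    n_min, n_maj, d = 20, 60, 5
    X = np.vstack([
        rng.normal(0.0, 0.3, size=(n_min, d)),
        rng.normal(2.0, 0.3, size=(n_maj, d)),
    ])
    y = np.array([1] * n_min + [0] * n_maj)
    m = FeatureMatrix(
        [f"r{i}" for i in range(n_min + n_maj)],
        [f"f{j}" for j in range(d)],
        X,
    )
    return m, y


@pytest.fixture
def aac_spec() -> EncoderSpec:
    return EncoderSpec("AAC")
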