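import numpy as np
import pytest

from ajivekit.blocks import MultiOmicsCollection, OmicsBlock
from ajivekit.preprocess import center_features
from ajivekit.simulate import SyntheticConfig, generate_blocks


@pytest.fixture(scope="session")
def small_config():
    """Desk-size three-block scenario used across integration tests."""
    return SyntheticConfig(
        n_samples=60,
        block_dims=(200, 120, 60),
        joint_rank=2,
        individual_ranks=(2, 2, 2),
        block_scales=(10.0, 1.0, 0.1),
        snr=(5.0, 5.0, 5.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_collection(small_config):
    collection, truth = generate_blocks(small_config)
    centered = [center_features(b) for b in collection.blocks]
    return (
        MultiOmicsCollection(
            blocks=centered, covariates=collection.covariates, outcome=collection.outcome
        ),
        truth,
    )


def make_block(values, name="b", assay_kind="expression_log", feature_ids=None, sample_ids=None):
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    return OmicsBlock(
        values=values,
        feature_ids=feature_ids or [f"f{i + 1}" for i in range(p)],
        sample_ids=sample_ids or [f"s{j + 1}" for j in range(n)],
        name=name,
        assay_kind=assay_kind,
    )
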