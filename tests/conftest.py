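"""Shared fixtures: seeded RNGs and phantom datasets at test scale.

The full 31-subject preprocessed phantom dataset is session-scoped because
the end-to-end and ablation acceptance tests both consume it and generating
it costs a few seconds.
"""

import numpy as np
import pytest

import voxtrans as vt


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_spec():
    return vt.PhantomSpec(seed=0)


@pytest.fixture(scope="session")
def phantom_dataset(phantom_spec):
    """31 raw phantom pairs: 26 train + 5 test (outlier tail)."""
    return vt.generate_dataset(phantom_spec, 31)


@pytest.fixture(scope="session")
def preprocessed_dataset(phantom_spec, phantom_dataset):
    return vt.preprocess_dataset(phantom_dataset, phantom_spec.shape)


@pytest.fixture(scope="session")
def train_test_split(preprocessed_dataset):
    return vt.split_train_test(preprocessed_dataset, n_test=5)


@pytest.fixture(scope="session")
def test_layout(phantom_spec):
    side = phantom_spec.shape[2]
    return vt.default_layout(phantom_spec.shape, (side, side, side))


def patch_pairs(samples, layout, index):
    """Extract patch ``index`` of every sample as a new paired dataset."""
    from voxtrans.preprocess import PairedSample

    return [PairedSample(subject_id=s.subject_id,
                         mr=vt.extract_patch(s.mr, layout, index),
                         ct=vt.extract_patch(s.ct, layout, index))
            for s in samples]


@pytest.fixture
def tiny_pairs(rng):
    """Four 8^3 paired patches in [-1, 1] for fast GAN bookkeeping tests."""
    from voxtrans.preprocess import PairedSample
    from voxtrans.volume_io import Volume

    pairs = []
    for i in range(4):
        mr = np.clip(rng.normal(0, 0.4, (8, 8, 8)), -1, 1)
        ct = np.clip(-0.5 * mr + 0.2, -1, 1)
        pairs.append(PairedSample(subject_id=f"tiny-{i}",
                                  mr=Volume(data=mr), ct=Volume(data=ct)))
    return pairs
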