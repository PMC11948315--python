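"""Shared fixtures: small synthetic datasets and trainers.

Everything is generated at test time from fixed seeds; no stored data.
"""

from __future__ import annotations

import numpy as np
import pytest

from afcs.synthetic import (
    BlobDataset,
    SyntheticDatasetSpec,
    make_blob_dataset,
    make_tiny_cnn,
)


@pytest.fixture(scope="session")
def small_blob_dataset() -> BlobDataset:
    """A quick 3-class, 16-px blob set with a clear signal."""
    return make_blob_dataset(
        SyntheticDatasetSpec(
            n_classes=3, n_per_class=12, image_size=16,
            signal_strength=140.0, noise_sd=20.0, seed=11,
        )
    )


@pytest.fixture
def small_cnn(small_blob_dataset):
    """A fresh tiny CNN on the small blob set (cheap epochs)."""
    return make_tiny_cnn(
        n_classes=3, seed=11, dataset=small_blob_dataset, fractions=(0.7, 0.15, 0.15)
    )


@pytest.fixture
def probe_batch():
    """A deterministic image batch for input-output map comparisons."""
    rng = np.random.default_rng(5)
    return rng.integers(0, 256, size=(4, 16, 16, 3)).astype(float)
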