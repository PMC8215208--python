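import numpy as np
import pytest

from ocutax.synthetic import (
    SynthConfig,
    default_counts,
    generate_arrays,
    labels_to_matrices,
)
from ocutax.taxonomy import bundled_taxonomy


@pytest.fixture(scope="session")
def anterior():
    return bundled_taxonomy("anterior")


@pytest.fixture(scope="session")
def retinal():
    return bundled_taxonomy("retinal")


@pytest.fixture(scope="session")
def desk():
    return bundled_taxonomy("desk")


@pytest.fixture(scope="session")
def tiny_dataset(desk):
    """Small 32-px balanced dataset for fast training-path tests."""
    cfg = SynthConfig(
        taxonomy=desk,
        image_size=32,
        n_per_class={c: 16 for c in desk.class_order[2]},
        composite_fraction=0.0,
        noise_sd=0.01,
        seed=7,
    )
    X, records = generate_arrays(cfg)
    labels = labels_to_matrices([r.label for r in records], desk)
    return cfg, X, records, labels
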