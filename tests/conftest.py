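import numpy as np
import pytest

from taxonet import (
    SyntheticSpec,
    generate_dataset,
    make_shaped_taxonomy,
    make_synthetic_taxonomy,
)

#: The published rank shape of the iNaturalist 2019 hierarchy
#: (Kingdom..Species).
INAT_LEVEL_SIZES = [3, 4, 9, 34, 57, 72, 1010]
INAT_LEVEL_NAMES = [
    "kingdom", "phylum", "class", "order", "family", "genus", "species",
]


@pytest.fixture(scope="session")
def inat_tree():
    return make_shaped_taxonomy(INAT_LEVEL_SIZES, INAT_LEVEL_NAMES)


@pytest.fixture(scope="session")
def branch22_tree():
    return make_synthetic_taxonomy(SyntheticSpec(branching=(2, 2)))


def noiseless_spec(seed=1, samples_per_leaf=10):
    """Fully deterministic study conditions: full-frame subject, no
    noise, no blur — every render of a leaf is identical, so a
    nearest-centroid oracle on raw pixels is exact."""
    return SyntheticSpec(
        branching=(2, 2),
        samples_per_leaf=samples_per_leaf,
        image_size=32,
        noise_sigma=0.0,
        blur_prob=0.0,
        subject_scale_range=(1.0, 1.0),
        seed=seed,
    )


@pytest.fixture(scope="session")
def noiseless_dataset(tmp_path_factory):
    """branching (2,2), 40 images, 32 train / 8 test."""
    out = tmp_path_factory.mktemp("noiseless")
    manifest = generate_dataset(noiseless_spec(), train_fraction=0.8, out_dir=out)
    return manifest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
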