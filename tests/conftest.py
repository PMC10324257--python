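"""Shared fixtures: a small noiseless synthetic dataset and a fitted model.

The dataset regime used throughout the training-level tests: 30 images per
class at 128 px, noise 0, well-separated lesion parameters, split 2:1 into
20 train + 10 test per class.  Session-scoped so the expensive pieces run
once.
"""

from __future__ import annotations

import numpy as np
import pytest

from ocusiam import SiameseKNN, TrainConfig
from ocusiam.synthetic import LesionParams, SyntheticSpec, generate_dataset


def desk_spec(seed: int = 11, noise: float = 0.0, n_per_class: int = 30) -> SyntheticSpec:
    return SyntheticSpec(
        size=128,
        n_per_class=n_per_class,
        noise_level=noise,
        seed=seed,
        lesions=LesionParams(
            spot_count=3, spot_radius=(4.0, 7.0), spot_intensity=(0.8, 0.95),
            arc_thickness=4.0,
        ),
    )


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("synthetic")
    generate_dataset(desk_spec(), out)
    return out


@pytest.fixture(scope="session")
def desk_model(dataset_dir):
    model = SiameseKNN.from_manifest(
        dataset_dir / "manifest.csv",
        images_root=dataset_dir,
        train_fraction=2 / 3,
        split_seed=0,
        **SiameseKNN.desk_profile(0),
    )
    model.train = TrainConfig(learning_rate=1e-3, batch_size=50, epochs=4, seed=0)
    return model


@pytest.fixture(scope="session")
def fitted(desk_model):
    return desk_model.fit(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
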