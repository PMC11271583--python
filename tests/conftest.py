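import numpy as np
import pandas as pd
import pytest

from fmrinorm import ActivationDataset, VolumeImage
from fmrinorm.simulate import SiteSpec, default_mask, make_truth_model, sample_covariates


def flat_mask(n_voxels: int) -> VolumeImage:
    """All-true mask over an (n_voxels, 1, 1) grid: V voxels, trivial geometry."""
    return VolumeImage(np.ones((n_voxels, 1, 1), dtype=bool), np.eye(4))


def dataset_from_matrix(Y: np.ndarray, contrast: str = "faces>shapes") -> ActivationDataset:
    Y = np.atleast_2d(Y)
    ids = [f"s{i:04d}" for i in range(Y.shape[0])]
    return ActivationDataset(Y, flat_mask(Y.shape[1]), ids, contrast)


@pytest.fixture(scope="session")
def small_mask() -> VolumeImage:
    return default_mask(shape=(8, 8, 8))


@pytest.fixture(scope="session")
def two_sites() -> list[SiteSpec]:
    return [
        SiteSpec("alpha", 150, (20.0, 60.0), 0.5, 0.8, True, 176, 150.0, 3,
                 "match_faces", "NimStim"),
        SiteSpec("bravo", 150, (25.0, 75.0), 0.6, 2.0, False, 195, 280.0, 4,
                 "match_expression", "Ekman"),
    ]


@pytest.fixture(scope="session")
def small_reference(small_mask, two_sites):
    """Two-site cohort with truth model and activation on the small mask."""
    from fmrinorm.simulate import generate_activation

    cov = sample_covariates(two_sites, seed=7)
    truth = make_truth_model(two_sites, small_mask, seed=7)
    data = generate_activation(cov, truth, seed=7)
    return cov, truth, data
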