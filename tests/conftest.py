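import numpy as np
import pytest

from plantrecon.cloud_io import PointCloud
from plantrecon.synthetic_fixtures import PlantParams, generate_plant_cloud


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_plant():
    """A quick ~1,000-point plant cloud used across registration tests."""
    return generate_plant_cloud(PlantParams(sampling_density=6e3, leaf_count=5, seed=7))


@pytest.fixture
def random_cloud(rng):
    return PointCloud(rng.uniform(-1, 1, size=(400, 3)))


def brute_force_nn(query: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """O(N*M) exhaustive nearest-neighbor distances (the independent oracle)."""
    diff = query[:, None, :] - reference[None, :, :]
    d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    return d.min(axis=1)


def brute_force_prf(recon: np.ndarray, gt: np.ndarray, d: float):
    """Exhaustive precision/recall/F1 on raw coordinate arrays."""
    p = 100.0 * np.count_nonzero(brute_force_nn(recon, gt) < d) / len(recon)
    r = 100.0 * np.count_nonzero(brute_force_nn(gt, recon) < d) / len(gt)
    f = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    return p, r, f
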