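import numpy as np
import pytest

from dcban.datasets import make_linear_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def rank3_noiseless():
    """Noiseless rank-3 voxel-to-feature mapping for recovery tests."""
    return make_linear_dataset(
        n_samples=200, n_voxels=50, n_features=30, rank=3, noise_sd=0.0, seed=42
    )


def principal_angle_deg(A: np.ndarray, B: np.ndarray) -> float:
    """Largest principal angle (degrees) between the column spans of A and B."""
    Qa, _ = np.linalg.qr(A)
    Qb, _ = np.linalg.qr(B)
    s = np.linalg.svd(Qa.T @ Qb, compute_uv=False)
    return float(np.degrees(np.arccos(np.clip(s.min(), -1.0, 1.0))))
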