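"""Seeded synthetic data with the statistical structure the decoder assumes.

The decoding model is a noisy linear voxel-to-feature map: responses
``X`` (samples x voxels) relate to stimulus features ``Y`` through a
low-rank coefficient matrix ``B_true`` plus i.i.d. Gaussian noise.  The
generators here produce such datasets with controllable rank and noise
level, low-rank matrices with a prescribed singular spectrum, and
token-embedding condition tensors of shape (77, 768) with controllable
reliability — everything needed to exercise the decoder and the
conditioning schedule without any neuroimaging download.

All generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SyntheticDataset",
    "ConditionSet",
    "make_linear_dataset",
    "make_lowrank_matrix",
    "make_condition_set",
    "CONDITION_SHAPE",
]

#: token x embedding shape of a text-conditioning tensor
CONDITION_SHAPE = (77, 768)


@dataclass
class SyntheticDataset:
    """A voxel-response / target-feature pair with known ground truth.

    Attributes
    ----------
    X : ndarray of shape (n_samples, n_voxels)
        Simulated per-stimulus response amplitudes (beta estimates).
    Y : ndarray of shape (n_samples, n_features)
        Target stimulus features, ``X @ B_true`` plus Gaussian noise.
    B_true : ndarray of shape (n_voxels, n_features)
        Ground-truth coefficient matrix of exact rank ``rank``.
    noise_sd : float
        Standard deviation of the additive noise actually applied.
    seed : int
    """

    X: np.ndarray
    Y: np.ndarray
    B_true: np.ndarray
    noise_sd: float
    seed: int
    snr: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y must have the same number of rows")


@dataclass
class ConditionSet:
    """A batch of (77, 768) condition tensors with per-tensor reliability.

    Each tensor is ``reliability[i] * signal + (1 - reliability[i]) * noise_i``
    with a shared signal tensor and independent noise tensors, so reliability
    1 gives identical tensors and reliability 0 gives independent ones.
    """

    tensors: np.ndarray
    reliability: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if self.tensors.ndim != 3 or self.tensors.shape[1:] != CONDITION_SHAPE:
            raise ValueError(
                f"condition tensors must have shape (n, {CONDITION_SHAPE[0]}, "
                f"{CONDITION_SHAPE[1]}), got {self.tensors.shape}"
            )
        rel = np.asarray(self.reliability, dtype=float)
        if rel.min() < 0.0 or rel.max() > 1.0:
            raise ValueError("reliability values must lie in [0, 1]")


def _check_counts(**counts: int) -> None:
    for name, value in counts.items():
        if int(value) != value or value < 1:
            raise ValueError(f"{name} must be a positive integer, got {value!r}")


def make_lowrank_matrix(
    rows: int, cols: int, rank: int, decay: float = 0.5, seed: int = 0
) -> np.ndarray:
    """Random matrix with singular values ``decay**j`` for j < rank, 0 beyond.

    Orthonormal factors are drawn from seeded Gaussian matrices via QR, so
    the singular spectrum is exact (up to float rounding) while the singular
    vectors are random.
    """
    _check_counts(rows=rows, cols=cols, rank=rank)
    if rank > min(rows, cols):
        raise ValueError(f"rank {rank} exceeds min(rows, cols) = {min(rows, cols)}")
    if decay <= 0:
        raise ValueError(f"decay must be positive, got {decay}")
    rng = np.random.default_rng(seed)
    u, _ = np.linalg.qr(rng.standard_normal((rows, rank)))
    v, _ = np.linalg.qr(rng.standard_normal((cols, rank)))
    s = decay ** np.arange(rank)
    return (u * s) @ v.T


def make_linear_dataset(
    n_samples: int,
    n_voxels: int,
    n_features: int,
    rank: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    snr: float | None = None,
) -> SyntheticDataset:
    """Generate ``Y = X @ B_true + noise`` with ``B_true`` of exact rank.

    ``X`` has i.i.d. standard-normal entries; ``B_true`` is a product of two
    standard-normal factors through a rank-``rank`` bottleneck, which keeps
    its condition number moderate.  Noise is i.i.d. Gaussian.  If ``snr`` is
    given it overrides ``noise_sd``: the noise standard deviation is set so
    that the mean signal variance over feature columns is ``snr`` times the
    noise variance.
    """
    _check_counts(
        n_samples=n_samples, n_voxels=n_voxels, n_features=n_features, rank=rank
    )
    if rank > min(n_voxels, n_features):
        raise ValueError(
            f"rank {rank} exceeds min(n_voxels, n_features) = "
            f"{min(n_voxels, n_features)}"
        )
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be nonnegative, got {noise_sd}")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_samples, n_voxels))
    B_true = rng.standard_normal((n_voxels, rank)) @ rng.standard_normal(
        (rank, n_features)
    )
    signal = X @ B_true
    if snr is not None:
        if snr <= 0:
            raise ValueError(f"snr must be positive, got {snr}")
        noise_sd = float(np.sqrt(signal.var(axis=0).mean() / snr))
    Y = signal + noise_sd * rng.standard_normal(signal.shape)
    return SyntheticDataset(
        X=X, Y=Y, B_true=B_true, noise_sd=float(noise_sd), seed=seed, snr=snr
    )


def make_condition_set(
    n: int, reliability: np.ndarray | float, seed: int = 0
) -> ConditionSet:
    """Generate ``n`` condition tensors mixing a shared signal with noise."""
    _check_counts(n=n)
    rel = np.broadcast_to(np.asarray(reliability, dtype=float), (n,)).copy()
    if rel.min() < 0.0 or rel.max() > 1.0:
        raise ValueError("reliability values must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    signal = rng.standard_normal(CONDITION_SHAPE)
    noise = rng.standard_normal((n,) + CONDITION_SHAPE)
    tensors = rel[:, None, None] * signal + (1.0 - rel[:, None, None]) * noise
    return ConditionSet(tensors=tensors, reliability=rel, seed=seed)
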