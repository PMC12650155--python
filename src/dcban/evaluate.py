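"""Reconstruction quality metrics.

Pixelwise Pearson correlation, the structural similarity index (SSIM,
luminance x contrast x structure over local Gaussian windows), cosine
similarity-matrix identification accuracies, and a plain feature
correlation score.  Perceptual feature extraction is the caller's
responsibility: identification operates on whatever feature vectors are
supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import pearsonr

__all__ = [
    "ImagePair",
    "SimilarityReport",
    "pixcorr",
    "ssim",
    "identification",
    "feature_correlation",
]


@dataclass
class ImagePair:
    """Reference / reconstruction pair with a shared dynamic range."""

    reference: np.ndarray
    reconstruction: np.ndarray
    dynamic_range: float = 255.0

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        self.reconstruction = np.asarray(self.reconstruction, dtype=float)
        if self.reference.shape != self.reconstruction.shape:
            raise ValueError(
                f"image shapes differ: {self.reference.shape} vs "
                f"{self.reconstruction.shape}"
            )
        if self.dynamic_range <= 0:
            raise ValueError("dynamic_range must be positive")


@dataclass
class SimilarityReport:
    """Cosine-similarity matrix with diagonal and pairwise accuracies."""

    S: np.ndarray
    diagonal_accuracy: float
    pairwise_accuracy: float


def pixcorr(pair: ImagePair) -> float:
    """Pearson correlation over flattened pixels."""
    x = pair.reference.ravel()
    y = pair.reconstruction.ravel()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pixel correlation is undefined for a constant image")
    return float(pearsonr(x, y).statistic)


def ssim(pair: ImagePair, window: int = 11, sigma: float = 1.5) -> float:
    """Mean structural similarity over sliding Gaussian windows.

    Local means, variances and covariance are computed with a Gaussian
    window (truncated at ``window`` taps) and combined as

        ssim = (2 mx my + C1)(2 cov + C2) / ((mx^2 + my^2 + C1)(vx + vy + C2))

    with the standard stabilizers C1 = (0.01 R)^2, C2 = (0.03 R)^2 for
    dynamic range R.  Equals 1 exactly iff the images are identical.
    """
    x, y = pair.reference, pair.reconstruction
    if window > min(x.shape):
        raise ValueError(
            f"window {window} exceeds the smallest image dimension {min(x.shape)}"
        )
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    R = pair.dynamic_range
    C1, C2 = (0.01 * R) ** 2, (0.03 * R) ** 2
    radius = (window - 1) // 2
    truncate = radius / sigma

    def smooth(a):
        return gaussian_filter(a, sigma=sigma, truncate=truncate, mode="reflect")

    mx, my = smooth(x), smooth(y)
    vx = smooth(x * x) - mx * mx
    vy = smooth(y * y) - my * my
    cov = smooth(x * y) - mx * my
    num = (2 * mx * my + C1) * (2 * cov + C2)
    den = (mx * mx + my * my + C1) * (vx + vy + C2)
    # crop to windows fully inside the image, as the reference protocol does
    ssim_map = (num / den)[radius:-radius or None, radius:-radius or None]
    return float(ssim_map.mean())


def identification(
    features_recon: np.ndarray, features_true: np.ndarray
) -> SimilarityReport:
    """Identification accuracies from the cosine-similarity matrix.

    ``S[i, j]`` is the cosine similarity between true-image features i and
    reconstruction features j.  A reconstruction is identified when its
    diagonal entry is the strict row maximum; pairwise accuracy is the
    fraction of ordered pairs (i, j != i) with S[i, i] > S[i, j]
    (two-way identification averaged over alternatives).
    """
    A = np.atleast_2d(np.asarray(features_true, dtype=float))
    B = np.atleast_2d(np.asarray(features_recon, dtype=float))
    if A.shape != B.shape:
        raise ValueError("feature arrays must have identical shapes")
    if A.shape[0] < 2:
        raise ValueError("identification needs at least two items")
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("zero-norm feature rows are not allowed")
    S = (A / na[:, None]) @ (B / nb[:, None]).T
    n = S.shape[0]
    diag = np.diag(S)
    off_max = np.max(np.where(np.eye(n, dtype=bool), -np.inf, S), axis=1)
    diagonal_accuracy = float(np.mean(diag > off_max))
    wins = (diag[:, None] > S) & ~np.eye(n, dtype=bool)
    pairwise_accuracy = float(wins.sum() / (n * (n - 1)))
    return SimilarityReport(
        S=S,
        diagonal_accuracy=diagonal_accuracy,
        pairwise_accuracy=pairwise_accuracy,
    )


def feature_correlation(extracted: np.ndarray, original: np.ndarray) -> float:
    """Pearson correlation between two equal-length feature vectors."""
    x = np.asarray(extracted, dtype=float).ravel()
    y = np.asarray(original, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("feature vectors must have equal length")
    if x.size < 2:
        raise ValueError("need at least two entries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for a constant vector")
    return float(pearsonr(x, y).statistic)
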