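"""Nested low-rank feature extraction from voxel responses.

A stack of linear layers (a voxel-to-component input adapter, width-3
one-channel convolutions along the component axis, and a final fully
connected layer) is trained so that every layer output ``T_i`` matches the
PCA-reduced targets while a per-layer low-rank penalty keeps the leading
singular structure of each ``T_i`` sharp.  The loss is

    L_rank  = -b1 * sum_i (f_i' T_i g_i)^2
              + b2 * sum_i |f_i|^2 |g_i|^2
              + b3 * sum_{i<i'} <f_i, f_i'> <g_i, g_i'>
    L_total = L_rank + eps * L_MSE,   L_MSE = (1/L) sum_i mean((T_i - Y)^2)

where (f_i, g_i) is the leading singular pair of ``T_i``, held fixed within
each optimization step (no gradient flows through the factorization).
Parameters are updated with a hand-written full-batch Adam.

Because the default activation is the identity, the trained network is a
single linear map ``Xlowrank`` (voxels x d).  Its column norms are the
strongly correlated singular values ``lambda`` and its normalized columns
the basis ``V``; the induced sample-space basis is ``u_j = X v_j / |X v_j|``.
These three objects feed the singular-space ridge solver downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

__all__ = [
    "DeepSVDConfig",
    "LayerState",
    "LowRankBasis",
    "DeepSVD",
    "pca_reduce",
    "leading_singular_pair",
    "rank_loss",
    "mse_and_total_loss",
    "train_deepsvd",
    "extract_basis",
    "classic_svd_basis",
]

# full SVD below this dimension, power iteration above
_POWER_ITERATION_DIM = 512


@dataclass
class DeepSVDConfig:
    """Hyperparameters of the nested low-rank network.

    ``n_layers`` counts the trained layers after the input adapter:
    ``n_layers - 1`` width-3 convolutions plus one fully connected layer.
    ``beta1/beta2/beta3`` weight the matching, magnitude and orthogonality
    terms of the low-rank penalty.  ``eps_weight`` balances the penalty
    against the data-fit term; the string ``"auto"`` selects
    ``2 * n_layers * n_samples * d`` so the data-fit quadratic dominates the
    (concave) matching term regardless of data scale.
    """

    n_layers: int = 57
    beta1: float = 1.0
    beta2: float = -1.0
    beta3: float = 1.0
    eps_weight: float | str = 1.0
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 42
    activation_mode: str = "linear"
    epochs: int = 200
    loss_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.n_layers < 2:
            raise ValueError("n_layers must be >= 2 (one nested layer + final FC)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.activation_mode not in ("linear", "relu"):
            raise ValueError(f"unknown activation_mode {self.activation_mode!r}")


@dataclass
class LayerState:
    """One layer's output matrix and its current leading singular pair."""

    T: np.ndarray
    f: np.ndarray
    g: np.ndarray


@dataclass
class LowRankBasis:
    """Column-norm factorization of the learned voxel-to-component map.

    ``lambdas[j]`` is the Euclidean norm of column j of ``Xlowrank``; ``V``
    holds the unit-normalized columns (zero columns stay zero); ``U`` is the
    induced sample-space basis over the training responses.  ``sigma_min`` /
    ``sigma_max`` are the extremes of ``lambdas`` over nonzero entries.
    """

    Xlowrank: np.ndarray
    lambdas: np.ndarray
    V: np.ndarray
    U: np.ndarray | None = None
    sigma_min: float = 0.0
    sigma_max: float = 0.0


def pca_reduce(Y: np.ndarray, n_components: int) -> tuple[np.ndarray, PCA]:
    """Project ``Y`` onto its top principal axes (column means removed).

    Returns the scores and the fitted :class:`sklearn.decomposition.PCA`
    (holding axes, means and explained-variance ratios) for reuse at test
    time.
    """
    Y = np.asarray(Y, dtype=float)
    if n_components < 1 or n_components > min(Y.shape):
        raise ValueError(
            f"n_components must be in [1, {min(Y.shape)}], got {n_components}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Y)
    return scores, pca


def _power_iteration(T: np.ndarray, n_iter: int = 100, tol: float = 1e-8):
    rng = np.random.default_rng(0)
    g = rng.standard_normal(T.shape[1])
    g /= np.linalg.norm(g)
    sigma = 0.0
    for _ in range(n_iter):
        f = T @ g
        nf = np.linalg.norm(f)
        if nf == 0:
            break
        f /= nf
        g_new = T.T @ f
        sigma_new = np.linalg.norm(g_new)
        g = g_new / sigma_new
        if abs(sigma_new - sigma) < tol * max(sigma_new, 1.0):
            sigma = sigma_new
            break
        sigma = sigma_new
    return f, g, float(sigma)


def leading_singular_pair(T: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Leading singular triple of ``T`` with a fixed sign convention.

    The first nonzero entry of the left vector ``f`` is made positive (the
    right vector flips with it) so repeated runs agree bit for bit.  Uses a
    full SVD for small matrices and 100-step power iteration above
    ``512`` in the smaller dimension.
    """
    T = np.asarray(T, dtype=float)
    if not np.any(T):
        raise ValueError("leading singular pair of an all-zero matrix is undefined")
    if min(T.shape) <= _POWER_ITERATION_DIM:
        U, s, Vt = np.linalg.svd(T, full_matrices=False)
        f, g, sigma = U[:, 0], Vt[0], float(s[0])
    else:
        f, g, sigma = _power_iteration(T)
    nz = np.flatnonzero(f)
    if nz.size and f[nz[0]] < 0:
        f, g = -f, -g
    return f, g, sigma


def rank_loss(
    layers: list[LayerState], beta1: float, beta2: float, beta3: float
) -> float:
    """Low-rank penalty over the per-layer singular pairs."""
    match = 0.0
    mag = 0.0
    for st in layers:
        match += float(st.f @ st.T @ st.g) ** 2
        mag += float(st.f @ st.f) * float(st.g @ st.g)
    cross = 0.0
    for i in range(len(layers)):
        for j in range(i + 1, len(layers)):
            if layers[i].f.shape != layers[j].f.shape or (
                layers[i].g.shape != layers[j].g.shape
            ):
                raise ValueError("layer singular-vector shapes differ across layers")
            cross += float(layers[i].f @ layers[j].f) * float(
                layers[i].g @ layers[j].g
            )
    return -beta1 * match + beta2 * mag + beta3 * cross


def mse_and_total_loss(
    T_list: list[np.ndarray],
    Y_pca: np.ndarray,
    rank_loss_value: float,
    eps_weight: float,
) -> tuple[float, float]:
    """Per-element data-fit error averaged over layers, and the total loss."""
    for T in T_list:
        if T.shape != Y_pca.shape:
            raise ValueError(
                f"layer output shape {T.shape} does not match targets {Y_pca.shape}"
            )
    mse = float(np.mean([np.mean((T - Y_pca) ** 2) for T in T_list]))
    return mse, rank_loss_value + eps_weight * mse


def extract_basis(Xlowrank: np.ndarray, X: np.ndarray | None = None) -> LowRankBasis:
    """Column norms, normalized columns and (optionally) the induced U.

    ``lambda_j`` is the norm of column j; ``V`` columns are unit vectors
    (zero columns map to zero columns with ``lambda_j = 0``).  When the
    training responses ``X`` are supplied, ``u_j = X v_j / |X v_j|``.
    """
    Xlowrank = np.asarray(Xlowrank, dtype=float)
    if not np.all(np.isfinite(Xlowrank)):
        raise ValueError("Xlowrank contains non-finite entries")
    lambdas = np.linalg.norm(Xlowrank, axis=0)
    if np.all(lambdas == 0):
        raise ValueError("degenerate basis: every column of Xlowrank is zero")
    nz = lambdas > 0
    V = np.zeros_like(Xlowrank)
    V[:, nz] = Xlowrank[:, nz] / lambdas[nz]
    U = None
    if X is not None:
        XV = np.asarray(X, dtype=float) @ V
        norms = np.linalg.norm(XV, axis=0)
        U = np.zeros_like(XV)
        pos = norms > 0
        U[:, pos] = XV[:, pos] / norms[pos]
    return LowRankBasis(
        Xlowrank=Xlowrank,
        lambdas=lambdas,
        V=V,
        U=U,
        sigma_min=float(lambdas[nz].min()),
        sigma_max=float(lambdas[nz].max()),
    )


def classic_svd_basis(X: np.ndarray, rtol: float = 1e-12) -> LowRankBasis:
    """Basis from the exact SVD of ``X`` in the same container.

    With ``X = U S V'``, the column-scaled matrix ``V S`` has column norms
    equal to the singular values and normalized columns equal to ``V``, and
    the induced sample basis reproduces ``U`` exactly — the bridge between
    the learned basis and reference fractional ridge regression.
    Singular values below ``rtol`` times the largest are dropped.
    """
    X = np.asarray(X, dtype=float)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    keep = s > rtol * s[0]
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    return LowRankBasis(
        Xlowrank=Vt.T * s,
        lambdas=s.copy(),
        V=Vt.T.copy(),
        U=U.copy(),
        sigma_min=float(s.min()),
        sigma_max=float(s.max()),
    )


def _conv_matrix(kernel: np.ndarray, d: int) -> np.ndarray:
    """Width-3 zero-padded convolution along the component axis as a d x d map."""
    return (
        kernel[0] * np.eye(d, k=1) + kernel[1] * np.eye(d) + kernel[2] * np.eye(d, k=-1)
    )


def _forward(X, params, activation):
    """Layer outputs T_0..T_L; conv layers optionally pass through ReLU."""
    W0, kernels, Wf = params
    d = W0.shape[1]
    Ts = [X @ W0]
    masks = []
    for k in kernels:
        A = Ts[-1] @ _conv_matrix(k, d)
        if activation == "relu":
            mask = A > 0
            masks.append(mask)
            A = A * mask
        Ts.append(A)
    Ts.append(Ts[-1] @ Wf)
    return Ts, masks


def _end_to_end_map(X, params, activation, masks):
    """The voxels -> d linear map realized by the network.

    Linear mode composes the layer matrices exactly; ReLU mode returns the
    training-set-averaged Jacobian (experimental).
    """
    W0, kernels, Wf = params
    d = W0.shape[1]
    if activation == "linear":
        M = W0.copy()
        for k in kernels:
            M = M @ _conv_matrix(k, d)
        return M @ Wf
    # averaged Jacobian: masks are per-sample diagonal gates after each conv
    n = masks[0].shape[0]
    acc = np.zeros((W0.shape[0], d))
    convs = [_conv_matrix(k, d) for k in kernels]
    for s in range(n):
        J = W0.copy()
        for C, mask in zip(convs, masks):
            J = (J @ C) * mask[s]
        acc += J @ Wf
    return acc / n


def train_deepsvd(
    X: np.ndarray, Y_pca: np.ndarray, config: DeepSVDConfig
) -> tuple[LowRankBasis, np.ndarray]:
    """Train the nested network with Adam and extract the low-rank basis.

    Returns the basis (with the induced sample-space ``U``) and the
    per-epoch total-loss trace.  Training stops at the epoch budget or when
    the total loss falls below ``config.loss_threshold``.
    """
    X = np.asarray(X, dtype=float)
    Y_pca = np.asarray(Y_pca, dtype=float)
    if X.shape[0] != Y_pca.shape[0]:
        raise ValueError("X and Y_pca must have the same number of rows")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("degenerate input: X has zero variance in every voxel")
    n, n_vox = X.shape
    d = Y_pca.shape[1]
    L = config.n_layers
    eps = config.eps_weight
    if eps == "auto":
        eps = 2.0 * L * n * d
    eps = float(eps)
    if config.beta2 > 0:
        warnings.warn(
            "beta2 > 0 rewards large singular-vector magnitudes; the default "
            "is -1 (penalty term sign conflict)",
            stacklevel=2,
        )

    rng = np.random.default_rng(config.seed)
    W0 = rng.standard_normal((n_vox, d)) * np.sqrt(2.0 / (n_vox + d))
    kernels = [
        np.array([0.0, 1.0, 0.0]) + 0.01 * rng.standard_normal(3)
        for _ in range(L - 1)
    ]
    Wf = np.eye(d) + 0.01 * rng.standard_normal((d, d))
    params = [W0, *kernels, Wf]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]

    trace = []
    for epoch in range(config.epochs):
        Ts, masks = _forward(X, (W0, kernels, Wf), config.activation_mode)
        loss_layers = [
            LayerState(T, *leading_singular_pair(T)[:2]) for T in Ts[1:]
        ]
        lr_val = rank_loss(loss_layers, config.beta1, config.beta2, config.beta3)
        _, total = mse_and_total_loss([st.T for st in loss_layers], Y_pca, lr_val, eps)
        if not np.isfinite(total):
            raise RuntimeError(f"non-finite training loss at epoch {epoch}")
        trace.append(total)

        # per-layer direct gradients (singular pairs frozen within the step)
        grads_T = []
        for st in loss_layers:
            s1 = float(st.f @ st.T @ st.g)
            G = -config.beta1 * 2.0 * s1 * np.outer(st.f, st.g)
            G += eps * 2.0 * (st.T - Y_pca) / (L * st.T.size)
            grads_T.append(G)
        # backpropagate through the chain; D[i] is the gradient w.r.t. the
        # post-activation output Ts[i+1], masks gate conv pre-activations
        convs = [_conv_matrix(k, d) for k in kernels]
        relu = config.activation_mode == "relu"

        def _gate(G, conv_index):
            return G * masks[conv_index] if relu else G

        D = [None] * L
        D[-1] = grads_T[-1]
        for i in range(L - 2, -1, -1):
            if i + 1 == L - 1:  # downstream layer is the final FC
                down = D[i + 1] @ Wf.T
            else:  # downstream layer is conv i+2 (masks index i+1)
                down = _gate(D[i + 1], i + 1) @ convs[i + 1].T
            D[i] = grads_T[i] + down
        grad_T0 = _gate(D[0], 0) @ convs[0].T
        grads = [X.T @ grad_T0]
        for i in range(L - 1):
            dM = Ts[i].T @ _gate(D[i], i)
            grads.append(
                np.array(
                    [np.trace(dM, offset=1), np.trace(dM), np.trace(dM, offset=-1)]
                )
            )
        grads.append(Ts[L - 1].T @ D[-1])

        t = epoch + 1
        for p, g_, mi, vi in zip(params, grads, m, v):
            mi *= config.adam_beta1
            mi += (1 - config.adam_beta1) * g_
            vi *= config.adam_beta2
            vi += (1 - config.adam_beta2) * g_**2
            mhat = mi / (1 - config.adam_beta1**t)
            vhat = vi / (1 - config.adam_beta2**t)
            p -= config.learning_rate * mhat / (np.sqrt(vhat) + config.adam_eps)

        if config.loss_threshold is not None and total <= config.loss_threshold:
            break

    _, masks = _forward(X, (W0, kernels, Wf), config.activation_mode)
    Xlowrank = _end_to_end_map(X, (W0, kernels, Wf), config.activation_mode, masks)
    basis = extract_basis(Xlowrank, X=X)
    return basis, np.asarray(trace)


class DeepSVD(BaseEstimator, TransformerMixin):
    """Nested low-rank extractor with a scikit-learn estimator surface.

    ``fit(X, Y_pca)`` trains the network and exposes the learned basis as
    fitted attributes; ``transform(X)`` projects responses onto the induced
    component space ``X V``.

    Parameters mirror :class:`DeepSVDConfig`; see that class for meanings.

    Attributes
    ----------
    basis_ : LowRankBasis
    lambdas_, V_, U_, Xlowrank_ : ndarray views of the basis
    loss_trace_ : ndarray, per-epoch total loss
    """

    def __init__(
        self,
        n_layers: int = 57,
        beta1: float = 1.0,
        beta2: float = -1.0,
        beta3: float = 1.0,
        eps_weight: float | str = 1.0,
        learning_rate: float = 1e-3,
        epochs: int = 200,
        seed: int = 42,
        activation_mode: str = "linear",
        loss_threshold: float | None = None,
    ):
        self.n_layers = n_layers
        self.beta1 = beta1
        self.beta2 = beta2
        self.beta3 = beta3
        self.eps_weight = eps_weight
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.seed = seed
        self.activation_mode = activation_mode
        self.loss_threshold = loss_threshold

    def _config(self) -> DeepSVDConfig:
        return DeepSVDConfig(
            n_layers=self.n_layers,
            beta1=self.beta1,
            beta2=self.beta2,
            beta3=self.beta3,
            eps_weight=self.eps_weight,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            seed=self.seed,
            activation_mode=self.activation_mode,
            loss_threshold=self.loss_threshold,
        )

    def fit(self, X: np.ndarray, Y_pca: np.ndarray) -> "DeepSVD":
        basis, trace = train_deepsvd(X, Y_pca, self._config())
        self.basis_ = basis
        self.loss_trace_ = trace
        self.lambdas_ = basis.lambdas
        self.V_ = basis.V
        self.U_ = basis.U
        self.Xlowrank_ = basis.Xlowrank
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "basis_"):
            raise RuntimeError("DeepSVD instance is not fitted yet")
        return np.asarray(X, dtype=float) @ self.basis_.V
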