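"""Bayesian-adaptive fractional ridge regression in singular-value space.

Ridge regression is reparameterized by the *fraction* delta = target ratio
between the norm of the regularized coefficients and the norm of the OLS
solution, instead of by the penalty alpha directly.  After rotating the
problem into the singular-value space of the (learned or exact) basis,
shrinkage acts componentwise:

    Y~        = U' Y                  (projection onto the sample basis)
    b_ols     = Y~ / lambda           (componentwise OLS solve)
    b_rr      = lambda^2 / (lambda^2 + alpha) * b_ols
    beta      = V b_rr                (back to voxel space)

The achieved fraction gamma(alpha) = |b_rr|_F / |b_ols|_F is monotonically
decreasing in alpha; the alpha matching a requested delta is found by
linear interpolation on an (alpha, gamma) curve.  The alpha search grid is
log-spaced from the basis spectrum and refined by Bayesian optimization
(Gaussian-process surrogate + Expected Improvement) around the
validation-error minimizer; the fraction itself is selected by k-fold
cross-validation over a fixed delta grid (automated regularization score
optimization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import linalg
from scipy.stats import norm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold

from .deepsvd import DeepSVD, LowRankBasis, classic_svd_basis, pca_reduce

__all__ = [
    "FractionGrid",
    "AlphaGrid",
    "GPState",
    "BayesOptState",
    "AlphaFractionCurve",
    "RidgeSolution",
    "transform_to_singular_space",
    "init_alpha_grid",
    "gamma_curve",
    "alpha_for_fraction",
    "apply_fraction",
    "gp_posterior",
    "expected_improvement",
    "redistribute_grid",
    "bago_optimize",
    "bago_run",
    "arso_select",
    "predict",
    "BayesAdaptiveFractionalRidge",
]

_ALPHA_FLOOR = 1e-10


# --------------------------------------------------------------------------
# containers


@dataclass
class FractionGrid:
    """Ordered grid of target coefficient-norm fractions delta in [0, 1]."""

    delta_min: float = 0.0
    delta_max: float = 1.0
    step: float = 0.05
    k_folds: int = 5
    values: np.ndarray = field(default=None)
    cv_mse: np.ndarray | None = None
    delta_best: float | None = None

    def __post_init__(self) -> None:
        if self.values is None:
            n = int(round((self.delta_max - self.delta_min) / self.step))
            self.values = np.linspace(self.delta_min, self.delta_max, n + 1)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.values) <= 0):
            raise ValueError("fraction grid values must be strictly increasing")
        if self.values[0] < 0 or self.values[-1] > 1:
            raise ValueError("fraction grid values must lie in [0, 1]")


@dataclass
class AlphaGrid:
    """Ordered positive grid of ridge penalties alpha."""

    values: np.ndarray
    small_bias: float = 1e-2
    big_bias: float = 1e-3
    log_step: float = 0.2

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("alpha grid is empty")
        if np.any(self.values <= 0):
            raise ValueError("alpha grid values must be positive")
        if np.any(np.diff(self.values) <= 0):
            raise ValueError("alpha grid values must be strictly increasing")

    @property
    def n_points(self) -> int:
        return self.values.size


@dataclass
class GPState:
    """Training pairs and hyperparameters of the Gaussian-process surrogate."""

    train_alphas: np.ndarray = field(default_factory=lambda: np.empty(0))
    train_errors: np.ndarray = field(default_factory=lambda: np.empty(0))
    amplitude: float = 1.0
    length_scale: float = 1.0
    noise: float = 1e-6

    def __post_init__(self) -> None:
        self.train_alphas = np.asarray(self.train_alphas, dtype=float)
        self.train_errors = np.asarray(self.train_errors, dtype=float)
        if self.amplitude <= 0 or self.length_scale <= 0:
            raise ValueError("kernel hyperparameters must be positive")
        if self.noise < 0:
            raise ValueError("observation noise must be nonnegative")


@dataclass
class BayesOptState:
    """History of an adaptive grid-refinement run."""

    alpha_best: float
    radius: float = 1.75
    focus: float = 3.0
    n_iter: int = 20
    grids: list = field(default_factory=list)
    evaluated_alphas: np.ndarray = field(default_factory=lambda: np.empty(0))
    evaluated_errors: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class AlphaFractionCurve:
    """Ordered (alpha, gamma) pairs; gamma is non-increasing in alpha."""

    alphas: np.ndarray
    gammas: np.ndarray

    def __post_init__(self) -> None:
        self.alphas = np.asarray(self.alphas, dtype=float)
        self.gammas = np.asarray(self.gammas, dtype=float)
        if self.alphas.size != self.gammas.size:
            raise ValueError("alphas and gammas must have equal length")


@dataclass
class RidgeSolution:
    """Singular-space and voxel-space coefficients of one fractional solve."""

    Y_tilde: np.ndarray
    beta_ols: np.ndarray
    beta_rr: np.ndarray
    beta: np.ndarray
    lambdas: np.ndarray
    alpha_delta: float
    delta: float | None = None
    metadata: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# singular-space solve


def transform_to_singular_space(
    basis: LowRankBasis, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Project targets onto the sample basis and solve OLS componentwise.

    Components with lambda = 0 carry no signal and are dropped (with a
    warning); the returned arrays have one row per retained component.
    """
    if basis.U is None:
        raise ValueError("basis has no induced sample-space U; fit it with X")
    Y = np.asarray(Y, dtype=float)
    if basis.U.shape[0] != Y.shape[0]:
        raise ValueError("basis U and Y disagree on the number of samples")
    keep = basis.lambdas > 0
    if not np.any(keep):
        raise ValueError("degenerate basis: all singular values are zero")
    if not np.all(keep):
        warnings.warn(
            f"dropping {np.count_nonzero(~keep)} zero-singular-value components",
            stacklevel=2,
        )
    U = basis.U[:, keep]
    lam = basis.lambdas[keep]
    Y_tilde = U.T @ Y
    beta_ols = Y_tilde / lam[:, None]
    return Y_tilde, beta_ols


def apply_fraction(
    beta_ols: np.ndarray,
    lambdas: np.ndarray,
    alpha_delta: float,
    basis: LowRankBasis,
    delta: float | None = None,
) -> RidgeSolution:
    """Shrink the OLS solution componentwise and map back to voxel space."""
    if alpha_delta < 0:
        raise ValueError(f"alpha_delta must be nonnegative, got {alpha_delta}")
    lam = np.asarray(lambdas, dtype=float)
    shrink = lam**2 / (lam**2 + alpha_delta)
    beta_rr = shrink[:, None] * beta_ols
    keep = basis.lambdas > 0
    V = basis.V[:, keep]
    beta = V @ beta_rr
    return RidgeSolution(
        Y_tilde=beta_ols * lam[:, None],
        beta_ols=beta_ols,
        beta_rr=beta_rr,
        beta=beta,
        lambdas=lam,
        alpha_delta=float(alpha_delta),
        delta=delta,
    )


def predict(X_test: np.ndarray, solution: RidgeSolution) -> np.ndarray:
    """Decode features for new responses: ``X_test @ beta``."""
    X_test = np.asarray(X_test, dtype=float)
    if X_test.shape[1] != solution.beta.shape[0]:
        raise ValueError(
            f"X_test has {X_test.shape[1]} voxels but beta expects "
            f"{solution.beta.shape[0]}"
        )
    return X_test @ solution.beta


# --------------------------------------------------------------------------
# alpha grid and fraction curve


def init_alpha_grid(
    sigma_min: float,
    sigma_max: float,
    small_bias: float = 1e-2,
    big_bias: float = 1e-3,
    log_step: float = 0.2,
) -> AlphaGrid:
    """Log-spaced alpha grid from the spectrum extremes.

    Spans log10(small_bias * sigma_min^2) .. log10(big_bias * sigma_max^2)
    with the given step.  When the nominal upper endpoint falls at or below
    the lower one (the default biases do this), the endpoints are
    swapped and a warning is issued.
    """
    if sigma_min <= 0 or sigma_max <= 0:
        raise ValueError("singular values must be positive")
    if sigma_min > sigma_max:
        raise ValueError("sigma_min must not exceed sigma_max")
    if small_bias <= 0 or big_bias <= 0 or log_step <= 0:
        raise ValueError("biases and log_step must be positive")
    lo = np.log10(small_bias * sigma_min**2)
    hi = np.log10(big_bias * sigma_max**2)
    if hi <= lo:
        if hi < lo:
            warnings.warn(
                "alpha-grid endpoints inverted by the bias settings; "
                "ordering them ascending",
                stacklevel=2,
            )
            lo, hi = hi, lo
        else:
            return AlphaGrid(
                values=np.array([10.0**lo]),
                small_bias=small_bias,
                big_bias=big_bias,
                log_step=log_step,
            )
    n = int(np.floor((hi - lo) / log_step + 1e-9))
    exponents = lo + log_step * np.arange(n + 1)
    return AlphaGrid(
        values=10.0**exponents,
        small_bias=small_bias,
        big_bias=big_bias,
        log_step=log_step,
    )


def _gamma_values(lambdas: np.ndarray, beta_ols: np.ndarray, alphas: np.ndarray):
    lam2 = lambdas**2
    norm_ols = np.linalg.norm(beta_ols)
    row_norms2 = np.sum(beta_ols**2, axis=1)
    shrink = lam2[None, :] / (lam2[None, :] + np.asarray(alphas)[:, None])
    return np.sqrt((shrink**2 @ row_norms2)) / norm_ols


def gamma_curve(
    lambdas: np.ndarray, beta_ols: np.ndarray, grid: AlphaGrid
) -> AlphaFractionCurve:
    """Achieved coefficient-norm fraction gamma(alpha) over a grid."""
    lam = np.asarray(lambdas, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("gamma curve requires strictly positive singular values")
    beta_ols = np.atleast_2d(np.asarray(beta_ols, dtype=float))
    if not np.any(beta_ols):
        raise ValueError("undefined fraction: the OLS solution is zero")
    alphas = np.sort(grid.values)
    gammas = _gamma_values(lam, beta_ols, alphas)
    return AlphaFractionCurve(alphas=alphas, gammas=gammas)


def alpha_for_fraction(curve: AlphaFractionCurve, delta: float) -> float:
    """Invert the fraction curve by the bracketing linear interpolation.

    gamma is decreasing in alpha, so the bracket is gamma[j+1] <= delta <=
    gamma[j]; a delta outside the achieved range clamps to the nearest
    endpoint alpha with a warning.
    """
    if curve.alphas.size < 2:
        raise ValueError("fraction curve needs at least two (alpha, gamma) pairs")
    if not 0.0 <= delta <= 1.0:
        raise ValueError(f"delta must be in [0, 1], got {delta}")
    a, g = curve.alphas, curve.gammas
    if delta >= g[0]:
        if delta > g[0]:
            warnings.warn(
                f"target fraction {delta} above achieved range; clamping to "
                f"alpha={a[0]:.4g}",
                stacklevel=2,
            )
        return float(a[0])
    if delta <= g[-1]:
        if delta < g[-1]:
            warnings.warn(
                f"target fraction {delta} below achieved range; clamping to "
                f"alpha={a[-1]:.4g}",
                stacklevel=2,
            )
        return float(a[-1])
    j = int(np.searchsorted(-g, -delta) - 1)  # g[j] >= delta >= g[j+1]
    if g[j + 1] == g[j]:
        return float(a[j])
    return float(a[j] + (delta - g[j]) * (a[j + 1] - a[j]) / (g[j + 1] - g[j]))


def _bracketing_curve(
    lambdas: np.ndarray,
    beta_ols: np.ndarray,
    grid: AlphaGrid,
    gamma_low: float = 0.005,
    gamma_high: float = 0.999,
    max_extend: int = 200,
) -> AlphaFractionCurve:
    """Fraction curve on a grid extended until it brackets [~0, ~1].

    The default bias settings can place the whole grid in the
    weak-shrinkage regime; the fraction-to-alpha inversion presumes a
    bracketing interval exists, so the grid is extended geometrically (one
    log-step at a time) at both ends until gamma passes gamma_high at the
    small-alpha end and gamma_low at the large-alpha end.
    """
    lam = np.asarray(lambdas, dtype=float)
    step = 10.0**grid.log_step
    alphas = list(np.sort(grid.values))
    for _ in range(max_extend):
        if _gamma_values(lam, beta_ols, np.array([alphas[0]]))[0] >= gamma_high:
            break
        alphas.insert(0, alphas[0] / step)
    for _ in range(max_extend):
        if _gamma_values(lam, beta_ols, np.array([alphas[-1]]))[0] <= gamma_low:
            break
        alphas.append(alphas[-1] * step)
    return gamma_curve(lam, beta_ols, AlphaGrid(values=np.array(alphas)))


# --------------------------------------------------------------------------
# Gaussian-process surrogate and Expected Improvement


def _gp_solve(state: GPState):
    A = state.train_alphas
    K = state.amplitude * np.exp(
        -((A[:, None] - A[None, :]) ** 2) / (2.0 * state.length_scale**2)
    )
    K = K + state.noise * np.eye(A.size)
    jitter = 0.0
    for _ in range(8):
        try:
            cho = linalg.cho_factor(K + jitter * np.eye(A.size), lower=True)
            return cho
        except linalg.LinAlgError:
            jitter = 1e-12 if jitter == 0.0 else jitter * 100.0
    raise linalg.LinAlgError("GP Gram matrix is not positive definite after jitter")


def gp_posterior(state: GPState, alpha_query: float) -> tuple[float, float]:
    """Posterior mean and standard deviation at one query penalty.

    With an empty training set the prior (0, sqrt(amplitude)) is returned.
    """
    if state.train_alphas.size == 0:
        return 0.0, float(np.sqrt(state.amplitude))
    cho = _gp_solve(state)
    r = state.amplitude * np.exp(
        -((alpha_query - state.train_alphas) ** 2) / (2.0 * state.length_scale**2)
    )
    w = linalg.cho_solve(cho, state.train_errors)
    mean = float(r @ w)
    var = state.amplitude - float(r @ linalg.cho_solve(cho, r))
    return mean, float(np.sqrt(max(var, 0.0)))


def expected_improvement(
    state: GPState, best_mean: float, alpha_query: float
) -> float:
    """EI acquisition relative to the incumbent *predicted* best mean."""
    mean, sd = gp_posterior(state, alpha_query)
    gap = best_mean - mean
    if sd == 0.0:
        return max(0.0, gap)
    z = gap / sd
    return float(max(0.0, gap * norm.cdf(z) + sd * norm.pdf(z)))


def redistribute_grid(
    alpha_best: float, radius: float = 1.75, focus: float = 3.0, n: int = 26
) -> AlphaGrid:
    """Re-place n grid points tanh-concentrated around the current best.

    Points below the positivity floor are clamped to 1e-10 and duplicates
    removed, so the returned grid can be shorter than n.
    """
    if radius <= 0 or focus <= 0:
        raise ValueError("radius and focus must be positive")
    if n < 2:
        raise ValueError("grid needs at least two points")
    N = n - 1
    k = np.arange(n)
    values = alpha_best + radius * np.tanh(focus * (2 * k - N) / N)
    values = np.unique(np.maximum(values, _ALPHA_FLOOR))
    return AlphaGrid(values=values)


# --------------------------------------------------------------------------
# adaptive grid refinement (BAGO)


def bago_optimize(
    objective: Callable[[float], float],
    sigma_min: float,
    sigma_max: float,
    n_iter: int = 20,
    radius: float = 1.75,
    focus: float = 3.0,
    small_bias: float = 1e-2,
    big_bias: float = 1e-3,
    log_step: float = 0.2,
    amplitude: float = 1.0,
    length_scale: float = 1.0,
    noise: float = 1e-6,
) -> tuple[AlphaGrid, float, BayesOptState]:
    """Refine the alpha grid around the validation-error minimizer.

    The initial log-spaced grid is swept once; each of the ``n_iter``
    iterations fits the Gaussian-process surrogate on the (z-scored)
    error history, scores Expected Improvement on the current grid,
    evaluates the best candidate, moves the incumbent when its predicted
    mean improves, and redistributes the grid around the incumbent.
    """
    grid = init_alpha_grid(sigma_min, sigma_max, small_bias, big_bias, log_step)
    # the default biases can collapse the initial sweep to a handful of
    # points; keep enough resolution for the tanh redistribution to refine
    n_points = max(grid.n_points, 21)
    cache: dict[float, float] = {}

    def _eval(a: float) -> float:
        a = float(a)
        if a not in cache:
            cache[a] = float(objective(a))
        return cache[a]

    for a in grid.values:
        _eval(a)
    evaluated = np.array(sorted(cache))
    errors = np.array([cache[a] for a in evaluated])
    alpha_best = float(evaluated[np.argmin(errors)])
    state = BayesOptState(
        alpha_best=alpha_best, radius=radius, focus=focus, n_iter=n_iter
    )
    state.grids.append(grid)

    for _ in range(n_iter):
        evaluated = np.array(sorted(cache))
        errors = np.array([cache[a] for a in evaluated])
        sd = errors.std()
        z_errors = (errors - errors.mean()) / sd if sd > 0 else errors * 0.0
        gp = GPState(
            train_alphas=evaluated,
            train_errors=z_errors,
            amplitude=amplitude,
            length_scale=length_scale,
            noise=noise,
        )
        means = np.array([gp_posterior(gp, a)[0] for a in evaluated])
        alpha_best = float(evaluated[np.argmin(means)])
        best_mean = float(means.min())
        ei = np.array(
            [expected_improvement(gp, best_mean, a) for a in grid.values]
        )
        alpha_cur = float(grid.values[int(np.argmax(ei))])
        _eval(alpha_cur)
        mean_cur, _ = gp_posterior(gp, alpha_cur)
        if mean_cur < best_mean:
            alpha_best = alpha_cur
        grid = redistribute_grid(alpha_best, radius, focus, n_points)
        state.grids.append(grid)

    state.alpha_best = alpha_best
    evaluated = np.array(sorted(cache))
    state.evaluated_alphas = evaluated
    state.evaluated_errors = np.array([cache[a] for a in evaluated])
    return grid, alpha_best, state


def _holdout_split(n: int, frac: float, seed: int):
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(frac * n)))
    return perm[n_val:], perm[:n_val]


def _split_basis(basis: LowRankBasis, X_rows: np.ndarray, refit_classic: bool):
    """Basis restricted to a row subset of the training data.

    Classic mode recomputes the exact SVD of the subset; learned-basis mode
    keeps (V, lambda) and renormalizes the induced U on the subset rows.
    """
    if refit_classic:
        return classic_svd_basis(X_rows)
    XV = X_rows @ basis.V
    norms = np.linalg.norm(XV, axis=0)
    U = np.zeros_like(XV)
    pos = norms > 0
    U[:, pos] = XV[:, pos] / norms[pos]
    return LowRankBasis(
        Xlowrank=basis.Xlowrank,
        lambdas=basis.lambdas,
        V=basis.V,
        U=U,
        sigma_min=basis.sigma_min,
        sigma_max=basis.sigma_max,
    )


def _validation_mse_fn(basis, X, Y, holdout_frac, seed, refit_classic):
    """Build alpha -> held-out MSE for the surrogate objective."""
    tr, va = _holdout_split(X.shape[0], holdout_frac, seed)
    fold_basis = _split_basis(basis, X[tr], refit_classic)
    _, beta_ols = transform_to_singular_space(fold_basis, Y[tr])
    lam = fold_basis.lambdas[fold_basis.lambdas > 0]
    V = fold_basis.V[:, fold_basis.lambdas > 0]
    P_val = X[va] @ V
    Y_val = Y[va]

    def mse(alpha: float) -> float:
        shrink = lam**2 / (lam**2 + alpha)
        resid = P_val @ (shrink[:, None] * beta_ols) - Y_val
        return float(np.mean(resid**2))

    return mse


def bago_run(
    basis: LowRankBasis,
    X: np.ndarray,
    Y: np.ndarray,
    n_iter: int = 20,
    radius: float = 1.75,
    focus: float = 3.0,
    small_bias: float = 1e-2,
    big_bias: float = 1e-3,
    log_step: float = 0.2,
    holdout_frac: float = 0.2,
    seed: int = 42,
    refit_classic: bool = False,
) -> tuple[AlphaGrid, float, BayesOptState]:
    """Adaptive alpha-grid refinement driven by a seeded 80/20 holdout."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    objective = _validation_mse_fn(basis, X, Y, holdout_frac, seed, refit_classic)
    return bago_optimize(
        objective,
        basis.sigma_min,
        basis.sigma_max,
        n_iter=n_iter,
        radius=radius,
        focus=focus,
        small_bias=small_bias,
        big_bias=big_bias,
        log_step=log_step,
    )


# --------------------------------------------------------------------------
# fraction selection (ARSO)


def arso_select(
    basis: LowRankBasis,
    X: np.ndarray,
    Y: np.ndarray,
    fraction_grid: FractionGrid,
    alpha_grid: AlphaGrid,
    seed: int = 42,
    refit_classic: bool = False,
) -> FractionGrid:
    """k-fold cross-validated selection of the target fraction delta.

    Per fold, the fraction curve is rebuilt on the training-fold basis and
    each candidate delta is solved and scored on the held-out fold; the
    returned grid carries the per-delta mean CV error and the winner
    (ties broken toward larger delta, i.e. less regularization).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if fraction_grid.k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if X.shape[0] < 2 * fraction_grid.k_folds:
        raise ValueError("too few samples for the requested number of folds")
    deltas = fraction_grid.values
    kf = KFold(n_splits=fraction_grid.k_folds, shuffle=True, random_state=seed)
    fold_mse = np.zeros((fraction_grid.k_folds, deltas.size))
    for f, (tr, va) in enumerate(kf.split(X)):
        fold_basis = _split_basis(basis, X[tr], refit_classic)
        _, beta_ols = transform_to_singular_space(fold_basis, Y[tr])
        keep = fold_basis.lambdas > 0
        lam = fold_basis.lambdas[keep]
        curve = _bracketing_curve(lam, beta_ols, alpha_grid)
        P_val = X[va] @ fold_basis.V[:, keep]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for j, delta in enumerate(deltas):
                a = alpha_for_fraction(curve, float(delta))
                shrink = lam**2 / (lam**2 + a)
                resid = P_val @ (shrink[:, None] * beta_ols) - Y[va]
                fold_mse[f, j] = np.mean(resid**2)
    cv_mse = fold_mse.mean(axis=0)
    # argmin with ties toward larger delta
    best_j = deltas.size - 1 - int(np.argmin(cv_mse[::-1]))
    return FractionGrid(
        delta_min=fraction_grid.delta_min,
        delta_max=fraction_grid.delta_max,
        step=fraction_grid.step,
        k_folds=fraction_grid.k_folds,
        values=deltas,
        cv_mse=cv_mse,
        delta_best=float(deltas[best_j]),
    )


# --------------------------------------------------------------------------
# estimator


class BayesAdaptiveFractionalRidge(BaseEstimator, RegressorMixin):
    """Fractional ridge decoder with adaptive penalty-grid refinement.

    ``fit(X, Y)`` builds the singular basis (exact SVD of ``X`` or the
    nested low-rank network), refines the penalty grid by Bayesian
    optimization, selects the coefficient-norm fraction by k-fold CV and
    solves for the voxel-space coefficients; ``predict(X)`` decodes
    features as ``X @ coef_``.

    Parameters
    ----------
    basis_mode : {"classic", "deepsvd"}
        Source of the singular basis: exact SVD of the responses, or the
        trained nested low-rank network.
    delta : float or None
        Fixed target fraction; ``None`` selects it by cross-validation.
    alpha : float or None
        Fixed ridge penalty; when set, the fraction machinery is bypassed.
    n_folds, bayes_iters, radius, focus, small_bias, big_bias, log_step :
        Cross-validation and grid-refinement controls.
    deepsvd_params : dict or None
        Overrides forwarded to :class:`~dcban.deepsvd.DeepSVD`.
    pca_components : int or None
        Target dimensionality for the network's reduced targets; default is
        the smallest count explaining 99% variance, capped at 512.

    Attributes
    ----------
    coef_ : ndarray (voxels x features)
    solution_ : RidgeSolution
    basis_ : LowRankBasis
    delta_best_, alpha_delta_ : float
    alpha_grid_ : AlphaGrid, the refined grid
    bayes_state_ : BayesOptState
    fraction_grid_ : FractionGrid with CV errors (when delta was selected)
    """

    def __init__(
        self,
        basis_mode: str = "classic",
        delta: float | None = None,
        alpha: float | None = None,
        n_folds: int = 5,
        bayes_iters: int = 20,
        radius: float = 1.75,
        focus: float = 3.0,
        small_bias: float = 1e-2,
        big_bias: float = 1e-3,
        log_step: float = 0.2,
        holdout_frac: float = 0.2,
        deepsvd_params: dict | None = None,
        pca_components: int | None = None,
        seed: int = 42,
    ):
        self.basis_mode = basis_mode
        self.delta = delta
        self.alpha = alpha
        self.n_folds = n_folds
        self.bayes_iters = bayes_iters
        self.radius = radius
        self.focus = focus
        self.small_bias = small_bias
        self.big_bias = big_bias
        self.log_step = log_step
        self.holdout_frac = holdout_frac
        self.deepsvd_params = deepsvd_params
        self.pca_components = pca_components
        self.seed = seed

    def _build_basis(self, X, Y):
        if self.basis_mode == "classic":
            return classic_svd_basis(X)
        if self.basis_mode == "deepsvd":
            d = self.pca_components or _default_pca_dim(Y)
            Y_pca, pca = pca_reduce(Y, d)
            params = dict(self.deepsvd_params or {})
            params.setdefault("seed", self.seed)
            net = DeepSVD(**params)
            net.fit(X, Y_pca)
            self.deepsvd_ = net
            self.pca_ = pca
            return net.basis_
        raise ValueError(f"unknown basis_mode {self.basis_mode!r}")

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "BayesAdaptiveFractionalRidge":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must have the same number of samples")
        refit = self.basis_mode == "classic"
        basis = self._build_basis(X, Y)
        self.basis_ = basis
        _, beta_ols = transform_to_singular_space(basis, Y)
        lam = basis.lambdas[basis.lambdas > 0]

        if self.alpha is not None:
            if self.alpha < 0:
                raise ValueError("alpha must be nonnegative")
            self.alpha_delta_ = float(self.alpha)
            self.delta_best_ = None
            self.alpha_grid_ = None
            self.bayes_state_ = None
        else:
            grid, alpha_best, state = bago_run(
                basis,
                X,
                Y,
                n_iter=self.bayes_iters,
                radius=self.radius,
                focus=self.focus,
                small_bias=self.small_bias,
                big_bias=self.big_bias,
                log_step=self.log_step,
                holdout_frac=self.holdout_frac,
                seed=self.seed,
                refit_classic=refit,
            )
            self.alpha_grid_ = grid
            self.bayes_state_ = state
            # the fraction curve needs global coverage: merge the refined
            # grid with the initial log sweep, then extend until bracketing
            merged = AlphaGrid(
                values=np.unique(
                    np.concatenate([grid.values, state.grids[0].values])
                ),
                log_step=self.log_step,
            )
            if self.delta is None:
                fg = arso_select(
                    basis,
                    X,
                    Y,
                    FractionGrid(k_folds=self.n_folds),
                    merged,
                    seed=self.seed,
                    refit_classic=refit,
                )
                self.fraction_grid_ = fg
                self.delta_best_ = fg.delta_best
            else:
                if not 0.0 <= self.delta <= 1.0:
                    raise ValueError("delta must be in [0, 1]")
                self.delta_best_ = float(self.delta)
            curve = _bracketing_curve(lam, beta_ols, merged)
            self.curve_ = curve
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self.alpha_delta_ = (
                    0.0
                    if self.delta_best_ == 1.0
                    else alpha_for_fraction(curve, self.delta_best_)
                )

        solution = apply_fraction(
            beta_ols, lam, self.alpha_delta_, basis, delta=self.delta_best_
        )
        solution.metadata.update(
            basis_mode=self.basis_mode,
            delta_best=self.delta_best_,
            alpha_delta=self.alpha_delta_,
            seed=self.seed,
        )
        self.solution_ = solution
        self.coef_ = solution.beta
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "solution_"):
            raise RuntimeError("estimator is not fitted yet")
        return predict(np.asarray(X, dtype=float), self.solution_)


def _default_pca_dim(Y: np.ndarray, var_target: float = 0.99, cap: int = 512) -> int:
    """Smallest component count explaining 99% variance, capped at 512."""
    _, pca = pca_reduce(Y, min(Y.shape))
    ratios = np.cumsum(pca.explained_variance_ratio_)
    d = int(np.searchsorted(ratios, var_target) + 1)
    return min(d, cap, min(Y.shape))
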