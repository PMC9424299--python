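"""Ridge-regression mapping from lesion masks or disconnection matrices to
dynamic-PC scores.

The design matrix (subjects x voxels, binary; or subjects x region-pairs,
percent disconnection) is reduced by PCA to the components explaining at
least 97% of variance, globally z-scored, and regressed on the (z-scored)
score with ridge

    beta = (X^T X + lambda I)^{-1} X^T y      (no intercept)

lambda is selected on a 200-step logarithmic grid over [1e-5, 1e5] by
leave-one-out cross-validation (LOOCV); accuracy is the coefficient of
determination R^2 = 1 - SS_res/SS_tot computed on the held-out predictions
(it can be negative for models worse than the mean).  Model significance
comes from a permutation test that reruns the entire LOOCV + lambda
optimization on shuffled scores; per-predictor significance marks weights
outside the central 95% of their own permutation null.  LOOCV predictions
and the lambda path are evaluated with the exact closed-form leave-one-out
identity (residual_i / (1 - h_ii)), which is algebraically identical to
refitting each fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .core_io import logger

DEFAULT_LAMBDA_GRID = np.logspace(-5, 5, 200)


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------


@dataclass
class LesionDesign:
    """Pre-reduction binary lesion design with its voxel bookkeeping."""

    X: np.ndarray  # (n_subjects, n_columns) binary
    column_voxels: np.ndarray  # flat voxel index of each column
    grid_shape: tuple[int, int, int]
    affine: np.ndarray | None = None


def lesion_design(
    masks: list[np.ndarray], affines: list[np.ndarray] | None = None
) -> LesionDesign:
    """Subjects x voxels binary matrix over voxels lesioned in >= 1 subject.

    All masks must share grid shape (and affine, when given).
    """
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError("lesion masks must share one grid shape")
    affine = None
    if affines is not None:
        affine = np.asarray(affines[0])
        for a in affines[1:]:
            if not np.allclose(a, affine, atol=1e-6):
                raise ValueError("lesion masks must share one affine")
    flat = np.stack([np.asarray(m, dtype=bool).ravel() for m in masks])
    cols = np.flatnonzero(flat.any(axis=0))
    return LesionDesign(
        X=flat[:, cols].astype(float),
        column_voxels=cols,
        grid_shape=masks[0].shape,
        affine=affine,
    )


def disconnection_design(matrices: list[np.ndarray]) -> np.ndarray:
    """Subjects x region-pairs design from symmetric disconnection matrices.

    Pair order is the fixed row-major upper triangle (i < j), shared with
    the rank-1 window features.
    """
    n = matrices[0].shape[0]
    iu = np.triu_indices(n, k=1)
    rows = []
    for m in matrices:
        m = np.asarray(m, dtype=float)
        if m.shape != (n, n):
            raise ValueError("disconnection matrices must share the region set")
        if not np.allclose(m, m.T, atol=1e-8):
            raise ValueError("disconnection matrix must be symmetric")
        rows.append(m[iu])
    return np.stack(rows)


def devectorize_pairs(vec: np.ndarray, n_regions: int) -> np.ndarray:
    """Inverse of the pair vectorization (symmetric matrix, zero diagonal)."""
    out = np.zeros((n_regions, n_regions))
    iu = np.triu_indices(n_regions, k=1)
    out[iu] = vec
    return out + out.T


# ---------------------------------------------------------------------------
# PCA reduction
# ---------------------------------------------------------------------------


@dataclass
class ReducedDesign:
    X: np.ndarray  # (n_subjects, n_components), globally z-scored
    loadings: np.ndarray  # (n_columns, n_components)
    col_mean: np.ndarray  # column means removed before projection
    kept_variance: float
    z_mean: float
    z_std: float


def reduce_pca(X: np.ndarray, var_frac: float = 0.97) -> ReducedDesign:
    """Project onto the minimal leading PCs reaching ``var_frac`` cumulative
    variance, then z-score the reduced matrix with a SINGLE global mean/sd
    over all its entries."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need >= 3 subjects")
    col_mean = X.mean(axis=0)
    Xc = X - col_mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 0:
        raise ValueError("design matrix has no variance")
    cum = np.cumsum(var) / total
    n_comp = int(np.searchsorted(cum, var_frac - 1e-12) + 1)
    n_comp = min(n_comp, (var > 1e-12 * var[0]).sum())
    V = Vt[:n_comp].T
    Xr = Xc @ V
    z_mean = float(Xr.mean())
    z_std = float(Xr.std())
    if z_std == 0:
        raise ValueError("reduced design is constant")
    return ReducedDesign(
        X=(Xr - z_mean) / z_std,
        loadings=V,
        col_mean=col_mean,
        kept_variance=float(cum[n_comp - 1]),
        z_mean=z_mean,
        z_std=z_std,
    )


# ---------------------------------------------------------------------------
# Ridge core
# ---------------------------------------------------------------------------


def ridge_solve(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """beta = (X^T X + lambda I)^{-1} X^T y, no intercept."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    p = X.shape[1]
    A = X.T @ X + lam * np.eye(p)
    if lam == 0 and np.linalg.matrix_rank(X.T @ X) < p:
        raise np.linalg.LinAlgError(
            "X^T X is singular at lambda=0; use lambda > 0"
        )
    return np.linalg.solve(A, X.T @ y)


def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    """R^2 = 1 - SS_res / SS_tot about the mean of y; may be negative."""
    y = np.asarray(y, dtype=float)
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def _loocv_path(U: np.ndarray, s: np.ndarray, y: np.ndarray, grid: np.ndarray):
    """Exact LOOCV SSE and held-out predictions over the lambda grid.

    With X = U diag(s) V^T, the ridge hat diagonal is
    h_ii = sum_j U_ij^2 s_j^2/(s_j^2 + lambda) and the leave-one-out
    residual is (y_i - yhat_i)/(1 - h_ii).
    """
    Uty = U.T @ y
    U2 = U**2
    sse = np.empty(grid.size)
    preds = np.empty((grid.size, y.size))
    for g, lam in enumerate(grid):
        shrink = s**2 / (s**2 + lam)
        fitted = U @ (shrink * Uty)
        h = U2 @ shrink
        denom = np.clip(1.0 - h, 1e-12, None)
        e_loo = (y - fitted) / denom
        preds[g] = y - e_loo
        sse[g] = float((e_loo**2).sum())
    return sse, preds


def ridge_loocv(
    X: np.ndarray, y: np.ndarray, lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID
) -> tuple[float, np.ndarray, float]:
    """Select lambda minimizing the LOOCV squared error; return
    (lambda_opt, held-out predictions at lambda_opt, R^2)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 5:
        raise ValueError("need >= 5 subjects for LOOCV")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    sse, preds = _loocv_path(U, s, y, np.asarray(lambda_grid))
    g = int(np.argmin(sse))
    yhat = preds[g]
    return float(lambda_grid[g]), yhat, r_squared(y, yhat)


def _fold_svds(X: np.ndarray):
    """Per-fold economy SVDs of X with row i removed (X fixed, y varies)."""
    n = X.shape[0]
    out = []
    for i in range(n):
        Xi = np.delete(X, i, axis=0)
        U, s, Vt = np.linalg.svd(Xi, full_matrices=False)
        out.append((np.delete(np.arange(n), i), U, s, Vt))
    return out


def _fold_average_beta(fold_svds, y: np.ndarray, lam: float) -> np.ndarray:
    """Average over LOOCV folds of the per-fold ridge solution at lam."""
    acc = None
    for rows, U, s, Vt in fold_svds:
        b = Vt.T @ (s / (s**2 + lam) * (U.T @ y[rows]))
        acc = b if acc is None else acc + b
    return acc / len(fold_svds)


# ---------------------------------------------------------------------------
# Full fit with permutation inference
# ---------------------------------------------------------------------------


@dataclass
class RidgeFit:
    lambda_grid: np.ndarray
    lambda_opt: float
    beta_reduced: np.ndarray  # fold-averaged weights in reduced space
    beta_full: np.ndarray  # back-projected to voxels / pairs
    yhat: np.ndarray  # LOOCV held-out predictions
    r2: float
    p_model: float = np.nan
    significant: np.ndarray | None = None  # bool per original predictor
    null_r2: np.ndarray = field(default_factory=lambda: np.empty(0))


def backproject(beta_reduced: np.ndarray, loadings: np.ndarray) -> np.ndarray:
    """Map reduced-space weights back to the original predictors:
    beta_full = V beta_reduced."""
    return loadings @ beta_reduced


def ridge_map(
    X_orig: np.ndarray,
    y: np.ndarray,
    var_frac: float = 0.97,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    tail: float = 0.025,
) -> tuple[RidgeFit, ReducedDesign]:
    """End-to-end map: PCA reduction, LOOCV ridge, permutation inference.

    ``y`` is z-scored internally.  Each permutation shuffles y and reruns
    the full LOOCV + lambda optimization; the model p-value is the add-one
    exceedance probability of the permuted R^2 over the observed one.  The
    per-predictor null is each back-projected weight's own distribution
    over permutations; observed weights outside its central
    1 - 2*``tail`` span are significant.
    """
    rng = np.random.default_rng(seed)
    if n_perm < 100:
        logger.warning("n_perm=%d < 100: coarse p-value resolution", n_perm)
    y = np.asarray(y, dtype=float)
    y_sd = y.std()
    if y_sd == 0:
        raise ValueError("score vector is constant")
    yz = (y - y.mean()) / y_sd
    red = reduce_pca(X_orig, var_frac=var_frac)
    X = red.X
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    folds = _fold_svds(X)
    grid = np.asarray(lambda_grid)

    def fit(yv: np.ndarray):
        sse, preds = _loocv_path(U, s, yv, grid)
        g = int(np.argmin(sse))
        lam = float(grid[g])
        beta = _fold_average_beta(folds, yv, lam)
        return lam, preds[g], r_squared(yv, preds[g]), beta

    lam_opt, yhat, r2, beta_red = fit(yz)
    beta_full = backproject(beta_red, red.loadings)

    null_r2 = np.empty(n_perm)
    null_w = np.empty((n_perm, beta_full.size))
    for b in range(n_perm):
        yp = rng.permutation(yz)
        _, _, r2_p, beta_p = fit(yp)
        null_r2[b] = r2_p
        null_w[b] = backproject(beta_p, red.loadings)
    p_model = (1 + int((null_r2 >= r2).sum())) / (1 + n_perm)
    lo = np.quantile(null_w, tail, axis=0)
    hi = np.quantile(null_w, 1 - tail, axis=0)
    significant = (beta_full < lo) | (beta_full > hi)

    fitres = RidgeFit(
        lambda_grid=grid,
        lambda_opt=lam_opt,
        beta_reduced=beta_red,
        beta_full=beta_full,
        yhat=yhat,
        r2=r2,
        p_model=p_model,
        significant=significant,
        null_r2=null_r2,
    )
    return fitres, red


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def weights_to_volume(
    weights: np.ndarray, column_voxels: np.ndarray, grid_shape: tuple[int, int, int]
) -> np.ndarray:
    vol = np.zeros(int(np.prod(grid_shape)))
    vol[column_voxels] = weights
    return vol.reshape(grid_shape)


def render_weight_map(
    volume: np.ndarray, sigma: float = 1.0, display_threshold: float = 0.05
) -> np.ndarray:
    """Display map: Gaussian smoothing (variance 1 voxel^2 -> sigma 1),
    scaling into [-1, 1] by the max |weight|, and zeroing of weights with
    |w| <= ``display_threshold``.  Boundary mode: nearest-edge replication."""
    sm = gaussian_filter(np.asarray(volume, dtype=float), sigma=sigma, mode="nearest")
    peak = np.abs(sm).max()
    if peak > 0:
        sm = sm / peak
    sm[np.abs(sm) <= display_threshold] = 0.0
    return sm
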