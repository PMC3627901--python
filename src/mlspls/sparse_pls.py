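"""Sparse PLS and sparse PLS-DA with L1-induced variable selection.

The engine maximises, dimension by dimension, the covariance between paired
score vectors xi_h = X_{h-1} u_h and omega_h = Z_{h-1} v_h over unit-norm
loading vectors (u_h, v_h), subject to L1 penalties that zero all but a
requested number of loading weights (``keepX`` / ``keepZ``).  Each dimension
is solved by alternating soft-thresholded power iterations on the
cross-product matrix M = X'Z, initialised from the leading singular pair of
M; with all variables kept the iteration converges to the leading singular
vectors themselves, which is the dense-PLS solution.

Two deflation modes are provided.  In mode A ("canonical"), each block is
deflated by its own score (X <- X - xi c', Z <- Z - omega d'), modelling a
bidirectional relationship; this is the integration setting.  In regression
mode the response block is deflated by the predictor score (Z <- Z - xi e'),
which keeps the PLS regression coefficients well-defined and is the
convention used for the discriminant variant, where Z is the one-hot group
membership matrix Y.

Class prediction uses the standard PLS regression coefficients
B = W (C'W)^{-1} Q' applied to test rows standardized with the training
statistics; the predicted class is the argmax over the G columns of the
prediction mapped back to the dummy-variable scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .design_io import OmicsMatrix, _unique_in_order

logger = logging.getLogger("mlspls")

__all__ = [
    "StandardizationStats",
    "SPLSModel",
    "SPLSDAModel",
    "standardize",
    "dummy_matrix",
    "fit_spls",
    "fit_splsda",
    "predict_classes",
    "selected_features",
]

_TOL = 1e-6
_MAX_ITER = 500


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

@dataclass
class StandardizationStats:
    """Column means/SDs of a training block, for reuse on held-out rows.

    ``kept`` flags columns with nonzero variance; zero-variance columns are
    dropped from the standardized block (their list is logged).  SDs use the
    N-1 denominator.
    """

    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray  # boolean mask over the original columns
    n_original: int

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != self.n_original:
            raise ValueError(
                f"expected {self.n_original} columns, got {x.shape[1]}"
            )
        return (x[:, self.kept] - self.mean[self.kept]) / self.sd[self.kept]


def standardize(
    x: np.ndarray | OmicsMatrix, ddof: int = 1
) -> tuple[np.ndarray, StandardizationStats]:
    """Center and scale columns to mean 0, SD 1 (N-1 denominator).

    Zero-variance columns are dropped (logged); an all-constant matrix is an
    error.  Returns the standardized matrix over kept columns and the stats
    needed to apply the same transform to held-out rows.
    """
    values = x.values if isinstance(x, OmicsMatrix) else np.asarray(x, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 rows to standardize")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=ddof)
    kept = sd > 0
    if not kept.any():
        raise ValueError("all columns have zero variance")
    if not kept.all():
        dropped = np.flatnonzero(~kept)
        logger.info(
            "standardize: dropped %d zero-variance column(s): %s",
            dropped.size,
            dropped[:10].tolist(),
        )
    stats = StandardizationStats(
        mean=mean, sd=sd, kept=kept, n_original=values.shape[1]
    )
    return stats.transform(values), stats


def dummy_matrix(groups: Sequence[str]) -> pd.DataFrame:
    """One-hot N x G indicator of group membership.

    Column order is first-appearance order of the levels; at least two levels
    are required.
    """
    groups = [str(g) for g in groups]
    levels = _unique_in_order(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 group levels for a dummy matrix")
    pos = {g: j for j, g in enumerate(levels)}
    y = np.zeros((len(groups), len(levels)))
    for i, g in enumerate(groups):
        y[i, pos[g]] = 1.0
    return pd.DataFrame(y, columns=levels)


# ---------------------------------------------------------------------------
# the per-dimension sparse iteration
# ---------------------------------------------------------------------------

def _keep_threshold(a: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold ``a`` so at most ``keep`` entries stay nonzero.

    The threshold is the largest |entry| outside the kept set, i.e. the
    (keep+1)-th largest magnitude; ties at the boundary go to the earliest
    feature index (stable sort) and are logged.  An exact tie leaves the kept
    boundary entry at weight zero, so nnz may fall below ``keep`` only on
    ties.
    """
    p = a.size
    if keep >= p:
        return a.copy()
    order = np.argsort(-np.abs(a), kind="stable")
    lam = np.abs(a[order[keep]])
    boundary_ties = np.abs(np.abs(a) - lam) < 1e-300
    if boundary_ties.sum() > 1:
        logger.info(
            "keepX/keepZ boundary tie among features %s; earliest index kept",
            np.flatnonzero(boundary_ties)[:10].tolist(),
        )
    out = np.zeros_like(a)
    kept = order[:keep]
    out[kept] = np.sign(a[kept]) * np.maximum(np.abs(a[kept]) - lam, 0.0)
    if not np.any(out):
        # every kept entry is tied with the threshold (e.g. duplicated
        # columns): keep the first-index winners at their raw weights
        out[kept] = a[kept]
    return out


def _fit_dimension(
    xh: np.ndarray,
    zh: np.ndarray,
    keepx: int,
    keepz: int,
    tol: float = _TOL,
    max_iter: int = _MAX_ITER,
) -> tuple[np.ndarray, np.ndarray, bool, int]:
    """One sparse PLS dimension on the current deflated blocks.

    Alternating updates on M = X'Z, initialised from M's leading singular
    pair; returns unit-norm (u, v), a convergence flag and the iteration
    count.  The sign is fixed so the largest-|entry| coordinate of u is
    positive (v flips jointly, leaving cov(xi, omega) unchanged).
    """
    m = xh.T @ zh
    # economy SVD of the thin side for the initial singular pair
    if m.shape[0] >= m.shape[1]:
        left, sing, right_t = np.linalg.svd(m, full_matrices=False)
    else:
        right, sing, left_t = np.linalg.svd(m.T, full_matrices=False)
        left, right_t = left_t.T, right.T
    u = left[:, 0]
    v = right_t[0, :]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        u_old = u
        a = m @ v
        u = _keep_threshold(a, keepx)
        norm_u = np.linalg.norm(u)
        if norm_u == 0:
            raise ValueError(
                "all loading weights thresholded to zero; the requested keep "
                "is incompatible with a boundary tie"
            )
        u = u / norm_u
        b = m.T @ u
        v = _keep_threshold(b, keepz)
        norm_v = np.linalg.norm(v)
        if norm_v == 0:
            raise ValueError("all Z-loading weights thresholded to zero")
        v = v / norm_v
        if np.max(np.abs(u - u_old)) < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "sparse PLS dimension did not converge after %d iterations", max_iter
        )
    top = int(np.argmax(np.abs(u)))
    if u[top] < 0:
        u, v = -u, -v
    return u, v, converged, it


# ---------------------------------------------------------------------------
# fitted models
# ---------------------------------------------------------------------------

@dataclass
class SPLSModel:
    """Fitted sparse PLS: per-dimension loadings, scores and deflation state."""

    n_components: int
    keepX: list[int]
    keepZ: list[int]
    mode: str  # "canonical" (mode A) or "regression"
    x_loadings: np.ndarray  # p_kept x H, unit-norm columns (u_h)
    z_loadings: np.ndarray  # q_kept x H (v_h)
    x_scores: np.ndarray  # N x H (xi_h)
    z_scores: np.ndarray  # N x H (omega_h)
    x_regression: np.ndarray  # p_kept x H local regression coefficients (c_h)
    z_regression: np.ndarray  # q_kept x H (d_h mode A / e_h regression mode)
    x_residual: np.ndarray
    z_residual: np.ndarray
    x_stats: StandardizationStats
    z_stats: StandardizationStats
    converged: list[bool]
    feature_names: list[str]
    z_feature_names: list[str]
    sample_ids: list[str] | None = None
    fitted: bool = True

    def score_covariances(self, ddof: int = 1) -> np.ndarray:
        n = self.x_scores.shape[0]
        return np.einsum("nh,nh->h", self.x_scores, self.z_scores) / (n - ddof)


@dataclass
class SPLSDAModel(SPLSModel):
    """Sparse PLS-DA: the Z block is the standardized dummy matrix Y."""

    group_levels: list[str] = field(default_factory=list)
    y_dummy: np.ndarray | None = None  # N x G one-hot, training order

    @property
    def beta(self) -> np.ndarray:
        """Prediction coefficients on the standardized scale (p_kept x G)."""
        return self.beta_components(self.n_components)

    def beta_components(self, h: int) -> np.ndarray:
        """B_h = W_h (C_h' W_h)^{-1} Q_h' using the first h dimensions."""
        if not 1 <= h <= self.n_components:
            raise ValueError(f"h must be in 1..{self.n_components}")
        w = self.x_loadings[:, :h]
        c = self.x_regression[:, :h]
        q = self.z_regression[:, :h]
        return w @ np.linalg.solve(c.T @ w, q.T)


def _resolve_keep(keep, h: int, p: int, name: str) -> list[int]:
    if keep is None:
        keep = p
    if np.isscalar(keep):
        keep = [int(keep)] * h
    keep = [int(k) for k in keep]
    if len(keep) > h:
        raise ValueError(f"{name} has {len(keep)} entries but H={h}")
    if len(keep) < h:
        raise ValueError(f"{name} has {len(keep)} entries but H={h}")
    for k in keep:
        if not 1 <= k <= p:
            raise ValueError(f"{name} values must be in 1..{p}, got {k}")
    return keep


def _as_values(x) -> tuple[np.ndarray, list[str] | None, list[str] | None]:
    if isinstance(x, OmicsMatrix):
        return x.values, x.feature_names, x.sample_ids
    x = np.asarray(x, dtype=float)
    return x, None, None


def _engine(
    x_std: np.ndarray,
    z_std: np.ndarray,
    h: int,
    keepx: list[int],
    keepz: list[int],
    mode: str,
    tol: float,
    max_iter: int,
):
    n, p = x_std.shape
    q = z_std.shape[1]
    u_mat = np.zeros((p, h))
    v_mat = np.zeros((q, h))
    xi = np.zeros((n, h))
    om = np.zeros((n, h))
    c_mat = np.zeros((p, h))
    d_mat = np.zeros((q, h))
    conv: list[bool] = []
    xh, zh = x_std.copy(), z_std.copy()
    for i in range(h):
        u, v, ok, _ = _fit_dimension(xh, zh, keepx[i], keepz[i], tol, max_iter)
        s = xh @ u
        w = zh @ v
        ss = float(s @ s)
        c = xh.T @ s / ss
        xh = xh - np.outer(s, c)
        if mode == "canonical":
            ww = float(w @ w)
            d = zh.T @ w / ww
            zh = zh - np.outer(w, d)
        else:  # regression: deflate Z by the X score
            d = zh.T @ s / ss
            zh = zh - np.outer(s, d)
        u_mat[:, i], v_mat[:, i] = u, v
        xi[:, i], om[:, i] = s, w
        c_mat[:, i], d_mat[:, i] = c, d
        conv.append(ok)
    return u_mat, v_mat, xi, om, c_mat, d_mat, xh, zh, conv


def fit_spls(
    x,
    z,
    n_components: int = 2,
    keepX=None,
    keepZ=None,
    mode: str = "canonical",
    tol: float = _TOL,
    max_iter: int = _MAX_ITER,
) -> SPLSModel:
    """Two-block sparse PLS (mode A by default) on row-aligned matrices.

    Both blocks are column standardized internally (already-standardized
    input is unchanged).  ``keepX`` / ``keepZ`` give the number of variables
    allowed a nonzero loading on each dimension (scalar = same on all
    dimensions; default = all).
    """
    xv, x_names, ids = _as_values(x)
    zv, z_names, _ = _as_values(z)
    if xv.shape[0] != zv.shape[0]:
        raise ValueError(
            f"blocks have different numbers of rows: {xv.shape[0]} vs {zv.shape[0]}"
        )
    if mode not in ("canonical", "regression"):
        raise ValueError(f"unknown mode {mode!r}")
    x_std, x_stats = standardize(xv)
    z_std, z_stats = standardize(zv)
    n, p = x_std.shape
    q = z_std.shape[1]
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components must be in 1..min(N-1, p) = {min(n - 1, p)}"
        )
    keepx = _resolve_keep(keepX, n_components, p, "keepX")
    keepz = _resolve_keep(keepZ, n_components, q, "keepZ")
    u, v, xi, om, c, d, e_res, f_res, conv = _engine(
        x_std, z_std, n_components, keepx, keepz, mode, tol, max_iter
    )
    if x_names is None:
        x_names = [f"x{j}" for j in range(len(x_stats.kept))]
    if z_names is None:
        z_names = [f"z{j}" for j in range(len(z_stats.kept))]
    return SPLSModel(
        n_components=n_components,
        keepX=keepx,
        keepZ=keepz,
        mode=mode,
        x_loadings=u,
        z_loadings=v,
        x_scores=xi,
        z_scores=om,
        x_regression=c,
        z_regression=d,
        x_residual=e_res,
        z_residual=f_res,
        x_stats=x_stats,
        z_stats=z_stats,
        converged=conv,
        feature_names=[n_ for n_, k in zip(x_names, x_stats.kept) if k],
        z_feature_names=[n_ for n_, k in zip(z_names, z_stats.kept) if k],
        sample_ids=ids,
    )


def fit_splsda(
    xw,
    groups: Sequence[str],
    n_components: int | None = None,
    keepX=None,
    y_deflation: str = "regression",
    tol: float = _TOL,
    max_iter: int = _MAX_ITER,
) -> SPLSDAModel:
    """Sparse PLS-DA of group labels on a (within) matrix.

    The response block is the one-hot dummy matrix of the groups, centered
    and scaled like any column and never penalized.  ``n_components``
    defaults to G - 1.  ``y_deflation`` chooses how the Y block is deflated
    ("regression": by the X score, the discriminant convention that keeps the
    prediction coefficients well-defined; "modeA": by its own score).
    """
    xv, x_names, ids = _as_values(xw)
    groups = [str(g) for g in groups]
    if len(groups) != xv.shape[0]:
        raise ValueError(
            f"{len(groups)} group labels for {xv.shape[0]} samples"
        )
    y = dummy_matrix(groups)
    levels = list(y.columns)
    if n_components is None:
        n_components = len(levels) - 1
    mode = {"regression": "regression", "modeA": "canonical"}.get(y_deflation)
    if mode is None:
        raise ValueError(f"unknown y_deflation {y_deflation!r}")
    x_std, x_stats = standardize(xv)
    y_std, y_stats = standardize(y.to_numpy())
    n, p = x_std.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components must be in 1..min(N-1, p) = {min(n - 1, p)}"
        )
    keepx = _resolve_keep(keepX, n_components, p, "keepX")
    keepz = [y_std.shape[1]] * n_components  # Y never penalized
    u, v, xi, om, c, d, e_res, f_res, conv = _engine(
        x_std, y_std, n_components, keepx, keepz, mode, tol, max_iter
    )
    if x_names is None:
        x_names = [f"x{j}" for j in range(len(x_stats.kept))]
    return SPLSDAModel(
        n_components=n_components,
        keepX=keepx,
        keepZ=keepz,
        mode=mode,
        x_loadings=u,
        z_loadings=v,
        x_scores=xi,
        z_scores=om,
        x_regression=c,
        z_regression=d,
        x_residual=e_res,
        z_residual=f_res,
        x_stats=x_stats,
        z_stats=y_stats,
        converged=conv,
        feature_names=[n_ for n_, k in zip(x_names, x_stats.kept) if k],
        z_feature_names=levels,
        sample_ids=ids,
        group_levels=levels,
        y_dummy=y.to_numpy(),
    )


def predict_classes(
    model: SPLSDAModel,
    x_test,
    n_components: int | None = None,
) -> tuple[list[str], np.ndarray]:
    """Predict group labels for new rows: Y_hat = X_std B, argmax per row.

    ``x_test`` is standardized with the model's training statistics.  The
    caller supplies within-deviation rows when the model was trained on a
    within matrix.  The returned score matrix is mapped back to the
    dummy-variable (0/1) scale so its columns are comparable; ties go to the
    first group level.
    """
    if not isinstance(model, SPLSDAModel):
        raise TypeError("predict_classes needs a fitted SPLSDAModel")
    if n_components is None:
        n_components = model.n_components
    stats = model.x_stats
    mean_k = stats.mean[stats.kept]
    sd_k = stats.sd[stats.kept]
    if isinstance(x_test, OmicsMatrix):
        pos = {f: j for j, f in enumerate(x_test.feature_names)}
        missing = [f for f in model.feature_names if f not in pos]
        if missing:
            raise ValueError(
                f"test matrix is missing {len(missing)} model feature(s): "
                f"{missing[:5]}"
            )
        xv = x_test.values[:, [pos[f] for f in model.feature_names]]
        x_std = (xv - mean_k) / sd_k
    else:
        xv = np.asarray(x_test, dtype=float)
        if xv.ndim == 1:
            xv = xv[None, :]
        if xv.shape[1] == stats.n_original:
            x_std = stats.transform(xv)
        elif xv.shape[1] == stats.n_kept:
            x_std = (xv - mean_k) / sd_k
        else:
            raise ValueError(
                f"test matrix has {xv.shape[1]} features; model expects "
                f"{stats.n_original} (or {stats.n_kept} retained)"
            )
    beta = model.beta_components(n_components)
    yhat_std = x_std @ beta
    # back to the 0/1 dummy scale (column-wise monotone, but aligns columns
    # when group sizes are unequal)
    sd = model.z_stats.sd[model.z_stats.kept]
    mean = model.z_stats.mean[model.z_stats.kept]
    yhat = yhat_std * sd + mean
    labels = [model.group_levels[j] for j in np.argmax(yhat, axis=1)]
    return labels, yhat


def selected_features(model: SPLSModel) -> dict:
    """Per-dimension nonzero-loading features ordered by |weight| descending.

    Returns ``{"per_dimension": [list per h], "union": ordered union}``.
    """
    if not getattr(model, "fitted", False):
        raise ValueError("model is not fitted")
    per_dim: list[list[str]] = []
    for h_idx in range(model.n_components):
        u = model.x_loadings[:, h_idx]
        nz = np.flatnonzero(u)
        order = nz[np.argsort(-np.abs(u[nz]), kind="stable")]
        per_dim.append([model.feature_names[j] for j in order])
    union: dict[str, None] = {}
    for lst in per_dim:
        for f in lst:
            union.setdefault(f, None)
    return {"per_dimension": per_dim, "union": list(union)}
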