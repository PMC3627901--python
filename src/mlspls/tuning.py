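"""Parameter tuning for multilevel sparse PLS(-DA).

Two complementary criteria choose how many variables get a nonzero loading
on each dimension:

* criterion 1 — cross-validation whose folds are whole subjects
  (leave-one-subject-out by default, stratified k-fold over subjects for
  larger cohorts), so the repeated-measures structure is never split between
  training and test.  The held-out subject's within-deviation rows are
  computed from its own samples only, which is well-defined because the
  within deviation is subject-local.  Training standardization statistics
  are applied to the held-out rows.

* criterion 2 — an in-sample score computed on the whole data set,
  dimension per dimension on the deflated matrices: cor(Y, Xu) * var(Xu) for
  the discriminant analysis, cov(Xu, Zv) for the two-block integration.  A
  sudden drop of the per-dimension maximum (below a configurable fraction of
  the previous dimension's maximum) marks how many dimensions to retain.

Both criteria are applied sequentially: dimension h is tuned with dimensions
1..h-1 frozen at their chosen sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design_io import OmicsMatrix, RepeatedMeasuresDesign, align_design
from .multilevel import within_matrix
from .sparse_pls import (
    _MAX_ITER,
    _TOL,
    _engine,
    _fit_dimension,
    dummy_matrix,
    fit_splsda,
    predict_classes,
    standardize,
)

__all__ = [
    "CVResult",
    "Criterion2Result",
    "loso_cv",
    "subject_cv_error",
    "tune_criterion2_da",
    "tune_criterion2_integration",
    "choose_n_dimensions",
]


@dataclass
class CVResult:
    """Subject-structured CV over a grid of selection sizes."""

    table: pd.DataFrame  # columns: dimension, keep, error
    per_subject: pd.DataFrame  # columns: dimension, keep, subject, error
    chosen: dict[int, int]  # dimension (1-based) -> chosen keep
    grid: list[int]
    n_folds: int


@dataclass
class Criterion2Result:
    """In-sample criterion over a grid of selection sizes.

    ``maxima`` holds the per-dimension criterion maximum (cor*var or cov) at
    the chosen size; ``cor_at_chosen`` the corresponding score correlations,
    which are scale-free across dimensions and therefore drive the
    sudden-drop rule for ``n_dimensions``.
    """

    table: pd.DataFrame  # long format, per (dimension, keep[, keepz]) values
    chosen: dict[int, int | tuple[int, int]]
    maxima: list[float]
    cor_at_chosen: list[float]
    n_dimensions: int  # retained under the sudden-drop rule
    grid: list


def _subject_folds(
    design: RepeatedMeasuresDesign, n_folds: int | None, seed: int | None
) -> list[list[str]]:
    """Folds of whole subjects: singletons (LOSO) or k groups of subjects."""
    subjects = list(design.subject_levels)
    if n_folds is None or n_folds >= len(subjects):
        return [[s] for s in subjects]
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    order = np.arange(len(subjects))
    if seed is not None:
        np.random.default_rng(seed).shuffle(order)
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    for i, j in enumerate(order):
        folds[i % n_folds].append(subjects[j])
    return folds


def _fold_error(
    x: OmicsMatrix,
    design: RepeatedMeasuresDesign,
    test_subjects: list[str],
    keepX: list[int],
    n_components: int,
    multilevel: bool,
    two_factor: bool,
) -> np.ndarray:
    """Misclassification of the held-out subjects at 1..n_components comps."""
    is_test = np.array([s in test_subjects for s in design.subject])
    train_idx = np.flatnonzero(~is_test)
    test_idx = np.flatnonzero(is_test)
    d_train = design.subset(train_idx)
    d_test = design.subset(test_idx)
    missing = set(design.condition_levels) - set(d_train.condition)
    if missing:
        raise ValueError(
            f"condition(s) {sorted(missing)} absent from a training fold; "
            "use a coarser grid of folds (k-fold over subjects)"
        )
    x_train = x.subset_rows(train_idx)
    x_test = x.subset_rows(test_idx)
    if multilevel:
        x_train = within_matrix(x_train, d_train, two_factor=two_factor)
        # test rows: the held-out subjects' own within deviations
        x_test = OmicsMatrix(
            x_test.values
            - _per_subject_means(x_test.values, d_test.subject),
            x_test.sample_ids,
            x_test.feature_names,
        )
    model = fit_splsda(x_train, d_train.condition, n_components, keepX=keepX)
    errors = np.empty(n_components)
    truth = np.asarray(d_test.condition)
    for h in range(1, n_components + 1):
        pred, _ = predict_classes(model, x_test, n_components=h)
        errors[h - 1] = float(np.mean(np.asarray(pred) != truth))
    return errors


def _per_subject_means(values: np.ndarray, subjects: list[str]) -> np.ndarray:
    out = np.empty_like(values)
    subj = np.asarray(subjects)
    for s in np.unique(subj):
        rows = subj == s
        out[rows] = values[rows].mean(axis=0)
    return out


def subject_cv_error(
    x: OmicsMatrix,
    design: RepeatedMeasuresDesign,
    keep: int,
    n_components: int = 3,
    multilevel: bool = True,
    two_factor: bool = False,
    n_folds: int | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Mean subject-held-out error at 1..n_components components, fixed keep.

    Fits one model per fold (keep variables on every dimension) and reads the
    error at each component count from truncated predictions; this is the
    protocol behind the classical-vs-multilevel error benchmark.
    """
    design = align_design(x, design)
    folds = _subject_folds(design, n_folds, seed)
    errs = np.zeros(n_components)
    for fold in folds:
        errs += _fold_error(
            x, design, fold, [keep] * n_components, n_components,
            multilevel, two_factor,
        )
    return errs / len(folds)


def loso_cv(
    x: OmicsMatrix,
    design: RepeatedMeasuresDesign,
    n_components: int,
    keep_grid: list[int],
    multilevel: bool = True,
    two_factor: bool | None = None,
    n_folds: int | None = None,
    seed: int | None = None,
) -> CVResult:
    """Criterion 1: subject-structured CV over a grid of selection sizes.

    Dimensions are tuned sequentially: for each dimension h, every grid value
    is tried with dimensions 1..h-1 frozen at their already-chosen sizes, and
    the value with the lowest mean held-out error is chosen (ties go to the
    smallest size, the most parsimonious model).
    """
    design = align_design(x, design)
    if two_factor is None:
        two_factor = design.two_factor
    p = x.n_features
    grid = sorted(int(k) for k in keep_grid)
    if any(not 1 <= k <= p for k in grid):
        raise ValueError(f"grid values must be in 1..{p}")
    folds = _subject_folds(design, n_folds, seed)
    rows = []
    subj_rows = []
    chosen: dict[int, int] = {}
    kept_so_far: list[int] = []
    for h in range(1, n_components + 1):
        best_keep, best_err = None, np.inf
        for k in grid:
            keepx = kept_so_far + [k]
            fold_errs = []
            for fold in folds:
                e = _fold_error(
                    x, design, fold, keepx, h, multilevel, two_factor
                )[-1]
                fold_errs.append(e)
                subj_rows.append(
                    {
                        "dimension": h,
                        "keep": k,
                        "subject": "+".join(fold),
                        "error": e,
                    }
                )
            mean_err = float(np.mean(fold_errs))
            rows.append({"dimension": h, "keep": k, "error": mean_err})
            if mean_err < best_err - 1e-12:
                best_keep, best_err = k, mean_err
        chosen[h] = int(best_keep)
        kept_so_far.append(int(best_keep))
    return CVResult(
        table=pd.DataFrame(rows),
        per_subject=pd.DataFrame(subj_rows),
        chosen=chosen,
        grid=grid,
        n_folds=len(folds),
    )


def choose_n_dimensions(maxima: list[float], drop_threshold: float = 0.8) -> int:
    """Retain dimensions up to (not including) the first sudden drop.

    A dimension whose criterion maximum falls below ``drop_threshold`` times
    the previous dimension's maximum ends the model there.
    """
    if not maxima:
        return 0
    n = 1
    for h in range(1, len(maxima)):
        if maxima[h] < drop_threshold * maxima[h - 1]:
            break
        n += 1
    return n


def tune_criterion2_da(
    xw,
    groups,
    n_components: int,
    keep_grid: list[int],
    drop_threshold: float = 0.8,
) -> Criterion2Result:
    """Criterion 2 for the discriminant analysis: cor(Y, Xu) * var(Xu).

    Computed on the whole data set, dimension per dimension on the current
    deflated matrices; the chosen size maximizes the cor*var product (the
    plain correlation is reported alongside).  The number of dimensions to
    retain follows the sudden-drop rule on the per-dimension maxima.
    """
    xv = xw.values if isinstance(xw, OmicsMatrix) else np.asarray(xw, float)
    x_std, _ = standardize(xv)
    y_std, _ = standardize(dummy_matrix(groups).to_numpy())
    n, p = x_std.shape
    grid = sorted(int(k) for k in keep_grid)
    if any(not 1 <= k <= p for k in grid):
        raise ValueError(f"grid values must be in 1..{p}")
    rows = []
    chosen: dict[int, int] = {}
    maxima: list[float] = []
    cor_at_chosen: list[float] = []
    xh, yh = x_std, y_std
    for h in range(1, n_components + 1):
        best_keep, best_val, best_cor = None, -np.inf, 0.0
        for k in grid:
            u, v, _, _ = _fit_dimension(xh, yh, k, yh.shape[1])
            xi, om = xh @ u, yh @ v
            cor = _safe_cor(xi, om)
            var = float(xi @ xi) / (n - 1)
            val = cor * var
            rows.append(
                {"dimension": h, "keep": k, "cor": cor, "var": var,
                 "criterion": val}
            )
            if val > best_val + 1e-12:
                best_keep, best_val, best_cor = k, val, cor
        chosen[h] = int(best_keep)
        maxima.append(float(best_val))
        cor_at_chosen.append(float(best_cor))
        # refit at the chosen size and deflate for the next dimension
        u, v, xi, om, c, d, xh, yh, _ = _engine(
            xh, yh, 1, [chosen[h]], [yh.shape[1]], "regression", _TOL, _MAX_ITER
        )
    return Criterion2Result(
        table=pd.DataFrame(rows),
        chosen=chosen,
        maxima=maxima,
        cor_at_chosen=cor_at_chosen,
        n_dimensions=choose_n_dimensions(cor_at_chosen, drop_threshold),
        grid=grid,
    )


def tune_criterion2_integration(
    xw,
    zw,
    n_components: int,
    keepx_grid: list[int],
    keepz_grid: list[int] | None = None,
    drop_threshold: float = 0.8,
) -> Criterion2Result:
    """Criterion 2 for the two-block integration: cov(Xu, Zv).

    Grid search per dimension over (keepX, keepZ) pairs on the current
    mode-A-deflated matrices (``keepz_grid=None`` keeps every Z variable, the
    setting used when the second block is small).
    """
    xv = xw.values if isinstance(xw, OmicsMatrix) else np.asarray(xw, float)
    zv = zw.values if isinstance(zw, OmicsMatrix) else np.asarray(zw, float)
    if xv.shape[0] != zv.shape[0]:
        raise ValueError("blocks have different numbers of rows")
    x_std, _ = standardize(xv)
    z_std, _ = standardize(zv)
    n, p = x_std.shape
    q = z_std.shape[1]
    kx_grid = sorted(int(k) for k in keepx_grid)
    kz_grid = [q] if keepz_grid is None else sorted(int(k) for k in keepz_grid)
    if any(not 1 <= k <= p for k in kx_grid):
        raise ValueError(f"keepX grid values must be in 1..{p}")
    if any(not 1 <= k <= q for k in kz_grid):
        raise ValueError(f"keepZ grid values must be in 1..{q}")
    rows = []
    chosen: dict[int, tuple[int, int]] = {}
    maxima: list[float] = []
    cor_at_chosen: list[float] = []
    xh, zh = x_std, z_std
    for h in range(1, n_components + 1):
        best, best_val, best_cor = None, -np.inf, 0.0
        for kx in kx_grid:
            for kz in kz_grid:
                u, v, _, _ = _fit_dimension(xh, zh, kx, kz)
                xi, om = xh @ u, zh @ v
                cov = float(xi @ om) / (n - 1)
                cor = _safe_cor(xi, om)
                rows.append(
                    {"dimension": h, "keepx": kx, "keepz": kz,
                     "cor": cor, "criterion": cov}
                )
                if cov > best_val + 1e-12:
                    best, best_val, best_cor = (kx, kz), cov, cor
        chosen[h] = best
        maxima.append(float(best_val))
        cor_at_chosen.append(float(best_cor))
        u, v, xi, om, c, d, xh, zh, _ = _engine(
            xh, zh, 1, [best[0]], [best[1]], "canonical", _TOL, _MAX_ITER
        )
    return Criterion2Result(
        table=pd.DataFrame(rows),
        chosen=chosen,
        maxima=maxima,
        cor_at_chosen=cor_at_chosen,
        n_dimensions=choose_n_dimensions(cor_at_chosen, drop_threshold),
        grid=[kx_grid, kz_grid],
    )


def _safe_cor(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])
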