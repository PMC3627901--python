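"""Split-up variation: decompose repeated measures into offset, between- and
within-subject parts.

For a cross-over design where each of n subjects is measured under several
conditions, every observation x_sjk (subject s, condition j, feature k) splits
exactly into

    x_sjk = x..k  +  (x_s.k - x..k)  +  (x_sjk - x_s.k)
            offset   between-subject    within-subject

so that X = X_offset + X_b + X_w with ||X||^2 = ||X_offset||^2 + ||X_b||^2 +
||X_w||^2.  The within matrix X_w carries the condition effect net of
subject-level variation and is the input to the sparse PLS(-DA) steps.  With a
second within-subject factor (time), the within part is further decomposed and
the two random subject-by-factor interaction matrices are removed, leaving
X_w* = X_condition + X_time + X_condition:time + X_residual.

All means are arithmetic means over available samples, so unbalanced designs
(unequal numbers of conditions per subject) are handled by per-cell counts.
No distributional assumptions or mixed-model fitting are involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design_io import OmicsMatrix, RepeatedMeasuresDesign, align_design

__all__ = [
    "OneFactorDecomposition",
    "TwoFactorDecomposition",
    "split_one_factor",
    "split_two_factor",
    "variation_summary",
    "within_matrix",
]


def _group_means(x: np.ndarray, labels: list[str]) -> np.ndarray:
    """Rows replaced by the mean of their label group (arithmetic, per cell)."""
    codes, _ = pd.factorize(np.asarray(labels))
    n_groups = codes.max() + 1
    sums = np.zeros((n_groups, x.shape[1]))
    np.add.at(sums, codes, x)
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    means = sums / counts[:, None]
    return means[codes]


@dataclass
class OneFactorDecomposition:
    """X = offset + between + within, with the sum-of-squares split."""

    offset: np.ndarray
    between: np.ndarray
    within: np.ndarray
    ss_offset: float = field(init=False)
    ss_between: float = field(init=False)
    ss_within: float = field(init=False)

    def __post_init__(self) -> None:
        self.ss_offset = float(np.sum(self.offset**2))
        self.ss_between = float(np.sum(self.between**2))
        self.ss_within = float(np.sum(self.within**2))

    @property
    def ss_total(self) -> float:
        return self.ss_offset + self.ss_between + self.ss_within

    @property
    def parts(self) -> dict[str, np.ndarray]:
        return {
            "offset": self.offset,
            "between": self.between,
            "within": self.within,
        }


@dataclass
class TwoFactorDecomposition:
    """Two-factor split: within = within_star + subject:condition + subject:time.

    ``within_star`` retains the condition, time, interaction and residual
    effects; the two random subject-by-factor interaction matrices are removed
    from it.  The four fixed-effect matrices are exported individually for
    inspection (``condition_effect`` etc.); ``within_star`` itself is computed
    by subtraction so the reconstruction identity holds exactly even when the
    design is unbalanced.
    """

    offset: np.ndarray
    between: np.ndarray
    within: np.ndarray
    within_star: np.ndarray
    subject_by_condition: np.ndarray
    subject_by_time: np.ndarray
    condition_effect: np.ndarray
    time_effect: np.ndarray
    interaction_effect: np.ndarray
    residual_effect: np.ndarray
    ss_offset: float = field(init=False)
    ss_between: float = field(init=False)
    ss_within: float = field(init=False)
    ss_within_star: float = field(init=False)
    ss_subject_by_condition: float = field(init=False)
    ss_subject_by_time: float = field(init=False)

    def __post_init__(self) -> None:
        self.ss_offset = float(np.sum(self.offset**2))
        self.ss_between = float(np.sum(self.between**2))
        self.ss_within = float(np.sum(self.within**2))
        self.ss_within_star = float(np.sum(self.within_star**2))
        self.ss_subject_by_condition = float(np.sum(self.subject_by_condition**2))
        self.ss_subject_by_time = float(np.sum(self.subject_by_time**2))

    @property
    def ss_total(self) -> float:
        return self.ss_offset + self.ss_between + self.ss_within

    @property
    def parts(self) -> dict[str, np.ndarray]:
        return {
            "offset": self.offset,
            "between": self.between,
            "within": self.within,
            "within_star": self.within_star,
            "subject_by_condition": self.subject_by_condition,
            "subject_by_time": self.subject_by_time,
        }


def _check_rows(x: OmicsMatrix, design: RepeatedMeasuresDesign) -> RepeatedMeasuresDesign:
    design = align_design(x, design)
    if len(design) != x.n_samples:
        raise ValueError(
            f"design has {len(design)} rows but matrix has {x.n_samples}"
        )
    return design


def split_one_factor(
    x: OmicsMatrix, design: RepeatedMeasuresDesign
) -> OneFactorDecomposition:
    """One-factor split-up: offset, between-subject and within-subject matrices.

    The grand mean is taken over all N rows and each subject's mean over its
    own G_s rows, so the within rows of every subject sum to the zero vector
    and each subject's within block depends on that subject's samples only.
    """
    design = _check_rows(x, design)
    v = x.values
    grand = v.mean(axis=0, keepdims=True)
    offset = np.broadcast_to(grand, v.shape).copy()
    subj_mean = _group_means(v, design.subject)
    between = subj_mean - grand
    within = v - subj_mean
    return OneFactorDecomposition(offset=offset, between=between, within=within)


def split_two_factor(
    x: OmicsMatrix, design: RepeatedMeasuresDesign
) -> TwoFactorDecomposition:
    """Two-factor split-up with condition and time within-subject factors.

    All margins (condition, time, condition:time cell, subject:condition,
    subject:time) are arithmetic means over the samples available in that
    margin; a margin with zero samples is impossible for margins indexed by
    observed rows, but empty (subject, condition) or (subject, time) cells in
    a sparse design simply do not occur as rows and need no imputation.
    """
    if not design.two_factor:
        raise ValueError("design has no time factor; use split_one_factor")
    design = _check_rows(x, design)
    v = x.values
    grand = v.mean(axis=0, keepdims=True)
    offset = np.broadcast_to(grand, v.shape).copy()
    subj = _group_means(v, design.subject)
    between = subj - grand
    within = v - subj

    cond = _group_means(v, design.condition)
    time = _group_means(v, design.time)  # type: ignore[arg-type]
    cond_time = _group_means(
        v, [f"{c}\x1f{t}" for c, t in zip(design.condition, design.time)]  # type: ignore[arg-type]
    )
    subj_cond = _group_means(
        v, [f"{s}\x1f{c}" for s, c in zip(design.subject, design.condition)]
    )
    subj_time = _group_means(
        v, [f"{s}\x1f{t}" for s, t in zip(design.subject, design.time)]  # type: ignore[arg-type]
    )

    subject_by_condition = subj_cond - cond - subj + grand
    subject_by_time = subj_time - time - subj + grand
    within_star = within - subject_by_condition - subject_by_time

    condition_effect = cond - grand
    time_effect = time - grand
    interaction_effect = cond_time - cond - time + grand
    residual_effect = (
        within_star - condition_effect - time_effect - interaction_effect
    )
    return TwoFactorDecomposition(
        offset=offset,
        between=between,
        within=within,
        within_star=within_star,
        subject_by_condition=subject_by_condition,
        subject_by_time=subject_by_time,
        condition_effect=condition_effect,
        time_effect=time_effect,
        interaction_effect=interaction_effect,
        residual_effect=residual_effect,
    )


def within_matrix(
    x: OmicsMatrix, design: RepeatedMeasuresDesign, two_factor: bool | None = None
) -> OmicsMatrix:
    """Convenience: the within (one-factor) or within* (two-factor) matrix.

    This is the matrix the sparse PLS(-DA) steps operate on.
    """
    if two_factor is None:
        two_factor = design.two_factor
    if two_factor:
        w = split_two_factor(x, design).within_star
    else:
        w = split_one_factor(x, design).within
    return OmicsMatrix(w, x.sample_ids, x.feature_names)


def variation_summary(
    decomp: OneFactorDecomposition | TwoFactorDecomposition,
) -> pd.DataFrame:
    """Sums of squares and fractions of ||X||^2 per variation source.

    The last row reports the relative residual of the additive sum-of-squares
    identity (zero up to floating point for the one-factor split).
    """
    total = decomp.ss_total
    rows = [
        ("offset", decomp.ss_offset),
        ("between_subject", decomp.ss_between),
        ("within_subject", decomp.ss_within),
    ]
    if isinstance(decomp, TwoFactorDecomposition):
        rows += [
            ("within_star", decomp.ss_within_star),
            ("subject_by_condition", decomp.ss_subject_by_condition),
            ("subject_by_time", decomp.ss_subject_by_time),
        ]
    df = pd.DataFrame(rows, columns=["source", "sum_of_squares"])
    df["fraction_of_total"] = df["sum_of_squares"] / total if total > 0 else 0.0
    reconstructed = decomp.offset + decomp.between + decomp.within
    # identity residual measured on the actual matrices, not the stored SS
    x_norm2 = float(np.sum(reconstructed**2))
    ss_resid = abs(x_norm2 - total) / total if total > 0 else 0.0
    df.attrs["identity_residual"] = ss_resid
    return df
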