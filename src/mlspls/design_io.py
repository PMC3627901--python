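"""Input/output for expression matrices and repeated-measures design tables.

Data are carried as an :class:`OmicsMatrix` (N samples x p features, dense)
together with a :class:`RepeatedMeasuresDesign` mapping each sample to a
subject, a condition (e.g. an in-vitro stimulation), and optionally a time
point.  Samples-in-rows is the canonical orientation throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mlspls")

__all__ = [
    "OmicsMatrix",
    "RepeatedMeasuresDesign",
    "read_expression_matrix",
    "read_design",
    "align_matched",
    "write_selection_report",
]


@dataclass
class OmicsMatrix:
    """Dense numeric matrix of N samples x p features with row/column names."""

    values: np.ndarray
    sample_ids: list[str]
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        n, p = self.values.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"matrix has {n} rows but {len(self.sample_ids)} sample IDs"
            )
        if p != len(self.feature_names):
            raise ValueError(
                f"matrix has {p} columns but {len(self.feature_names)} feature names"
            )
        if n < 2:
            raise ValueError("need at least 2 samples")
        if p < 1:
            raise ValueError("need at least 1 feature")
        if len(set(self.sample_ids)) != n:
            dups = _duplicates(self.sample_ids)
            raise ValueError(f"duplicate sample IDs: {dups}")
        if len(set(self.feature_names)) != p:
            dups = _duplicates(self.feature_names)
            raise ValueError(f"duplicate feature names: {dups}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                "non-finite value at sample "
                f"{self.sample_ids[i]!r}, feature {self.feature_names[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_names
        )

    def write(self, path: str | Path, delimiter: str = "\t") -> None:
        df = self.to_frame()
        df.index.name = "sample"
        # %.17g keeps the text representation exactly round-trippable
        df.to_csv(path, sep=delimiter, float_format="%.17g")

    def subset_rows(self, idx: Sequence[int]) -> "OmicsMatrix":
        idx = list(idx)
        return OmicsMatrix(
            self.values[idx],
            [self.sample_ids[i] for i in idx],
            self.feature_names,
        )


def _duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for it in items:
        if it in seen and it not in out:
            out.append(it)
        seen.add(it)
    return out


def _unique_in_order(labels: Sequence[str]) -> list[str]:
    """Levels in first-appearance order (the package-wide level convention)."""
    seen: dict[str, None] = {}
    for lab in labels:
        seen.setdefault(lab, None)
    return list(seen)


@dataclass
class RepeatedMeasuresDesign:
    """Per-sample subject / condition (/ time) labels for a cross-over design.

    ``condition`` is the factor of interest (G levels); ``time`` is an optional
    second within-subject factor (T levels).  Factor levels are ordered by
    first appearance.  Validation of the repeated-measures invariants (every
    subject observed at least twice, at most one sample per within-subject
    cell) lives in :meth:`validate`; construction itself is unchecked so that
    degenerate designs can still be built for diagnostics.
    """

    subject: list[str]
    condition: list[str]
    time: list[str] | None = None
    sample_ids: list[str] | None = None
    subject_levels: list[str] = field(init=False)
    condition_levels: list[str] = field(init=False)
    time_levels: list[str] | None = field(init=False)

    def __post_init__(self) -> None:
        self.subject = [str(s) for s in self.subject]
        self.condition = [str(c) for c in self.condition]
        if self.time is not None:
            self.time = [str(t) for t in self.time]
            if len(self.time) != len(self.subject):
                raise ValueError("time and subject lengths differ")
        if len(self.condition) != len(self.subject):
            raise ValueError("condition and subject lengths differ")
        if self.sample_ids is not None:
            self.sample_ids = [str(s) for s in self.sample_ids]
            if len(self.sample_ids) != len(self.subject):
                raise ValueError("sample_ids and subject lengths differ")
        self.subject_levels = _unique_in_order(self.subject)
        self.condition_levels = _unique_in_order(self.condition)
        self.time_levels = (
            _unique_in_order(self.time) if self.time is not None else None
        )

    def __len__(self) -> int:
        return len(self.subject)

    @property
    def n_samples(self) -> int:
        return len(self.subject)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_levels)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_levels)

    @property
    def two_factor(self) -> bool:
        return self.time is not None

    def samples_per_subject(self) -> dict[str, int]:
        counts: dict[str, int] = {s: 0 for s in self.subject_levels}
        for s in self.subject:
            counts[s] += 1
        return counts

    def subject_indices(self) -> dict[str, np.ndarray]:
        """Row indices of each subject, in subject-level order."""
        idx: dict[str, list[int]] = {s: [] for s in self.subject_levels}
        for i, s in enumerate(self.subject):
            idx[s].append(i)
        return {s: np.asarray(v, dtype=int) for s, v in idx.items()}

    def validate(self) -> "RepeatedMeasuresDesign":
        for s, c in self.samples_per_subject().items():
            if c < 2:
                raise ValueError(
                    f"subject {s!r} has {c} sample(s); every subject needs >= 2 "
                    "(a single sample carries no within-subject information)"
                )
        if self.time is None:
            cells = list(zip(self.subject, self.condition))
            label = "(subject, condition)"
        else:
            cells = list(zip(self.subject, self.condition, self.time))
            label = "(subject, condition, time)"
        dup = _duplicates([repr(c) for c in cells])
        if dup:
            raise ValueError(
                f"more than one sample per {label} cell: {dup[0]}; "
                "at most one observation per within-subject cell is assumed"
            )
        return self

    def subset(self, idx: Sequence[int]) -> "RepeatedMeasuresDesign":
        idx = list(idx)
        return RepeatedMeasuresDesign(
            subject=[self.subject[i] for i in idx],
            condition=[self.condition[i] for i in idx],
            time=[self.time[i] for i in idx] if self.time is not None else None,
            sample_ids=(
                [self.sample_ids[i] for i in idx]
                if self.sample_ids is not None
                else None
            ),
        )

    def to_frame(self) -> pd.DataFrame:
        data = {
            "sample": self.sample_ids
            if self.sample_ids is not None
            else [f"s{i}" for i in range(len(self))],
            "subject": self.subject,
            "condition": self.condition,
        }
        if self.time is not None:
            data["time"] = self.time
        return pd.DataFrame(data)

    def write(self, path: str | Path, delimiter: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=delimiter, index=False)


def _infer_delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


def read_expression_matrix(
    path: str | Path,
    delimiter: str | None = None,
    transpose: bool = False,
) -> OmicsMatrix:
    """Read a samples x features numeric matrix from TSV/CSV.

    First row is a header of feature names, first column holds sample IDs.
    ``transpose=True`` accepts features-in-rows files and flips them into the
    canonical orientation.  Missing or non-numeric cells are rejected, naming
    the offending cell.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if transpose:
        df = df.T
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        raw = df[col].to_numpy()
        try:
            # numpy's strtod parses exactly, so text written at %.17g
            # precision round-trips bit for bit
            col_values = raw.astype(np.float64)
        except (TypeError, ValueError):
            col_values = None
        if col_values is None or np.isnan(col_values).any():
            for i, cell in enumerate(raw):
                try:
                    ok = not np.isnan(float(cell))
                except (TypeError, ValueError):
                    ok = False
                if not ok:
                    raise ValueError(
                        f"non-numeric or missing cell at sample "
                        f"{df.index[i]!r}, feature {col!r}: {cell!r}"
                    )
            raise ValueError(f"could not parse column {col!r}")
        values[:, j] = col_values
    return OmicsMatrix(values, list(df.index), list(df.columns))


def read_design(path: str | Path, delimiter: str | None = None) -> RepeatedMeasuresDesign:
    """Read a design table with columns sample, subject, condition[, time]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"sample", "subject", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design table is missing columns: {sorted(missing)}")
    design = RepeatedMeasuresDesign(
        subject=list(df["subject"]),
        condition=list(df["condition"]),
        time=list(df["time"]) if "time" in df.columns else None,
        sample_ids=list(df["sample"]),
    )
    if len(set(design.sample_ids)) != len(design.sample_ids):  # type: ignore[arg-type]
        raise ValueError(
            f"duplicate sample IDs in design: {_duplicates(design.sample_ids)}"
        )
    return design.validate()


def align_design(x: OmicsMatrix, design: RepeatedMeasuresDesign) -> RepeatedMeasuresDesign:
    """Reorder a design (by sample ID when available) to match matrix rows."""
    if len(design) != x.n_samples:
        if design.sample_ids is None:
            raise ValueError(
                f"design has {len(design)} rows but matrix has {x.n_samples}"
            )
    if design.sample_ids is None:
        return design
    pos = {s: i for i, s in enumerate(design.sample_ids)}
    missing = [s for s in x.sample_ids if s not in pos]
    if missing:
        raise ValueError(f"samples absent from design: {missing[:5]}")
    return design.subset([pos[s] for s in x.sample_ids])


def align_matched(
    x: OmicsMatrix, z: OmicsMatrix, design: RepeatedMeasuresDesign
) -> tuple[OmicsMatrix, OmicsMatrix, RepeatedMeasuresDesign]:
    """Row-align two matched assays and the design on common sample IDs.

    Samples absent from either matrix are dropped (count logged); row order
    follows the first matrix.  Mirrors the situation where a few samples fail
    QC on one platform only.
    """
    in_z = set(z.sample_ids)
    common = [s for s in x.sample_ids if s in in_z]
    if not common:
        raise ValueError("matrices share no sample IDs")
    dropped = (x.n_samples - len(common)) + (z.n_samples - len(common))
    if dropped:
        logger.info("align_matched: dropped %d unmatched sample(s)", dropped)
    design = align_design(x, design)
    x_pos = {s: i for i, s in enumerate(x.sample_ids)}
    z_pos = {s: i for i, s in enumerate(z.sample_ids)}
    xi = [x_pos[s] for s in common]
    zi = [z_pos[s] for s in common]
    return x.subset_rows(xi), z.subset_rows(zi), design.subset(xi)


def write_selection_report(
    model,
    path: str | Path,
    scores_path: str | Path | None = None,
) -> None:
    """Write loadings (dimension, feature, weight, rank by |weight|) and scores.

    The companion scores TSV defaults to ``<path stem>.scores.tsv``.
    """
    path = Path(path)
    if scores_path is None:
        scores_path = path.with_suffix(".scores.tsv")
    if not getattr(model, "fitted", False):
        raise ValueError("model is not fitted")
    rows = []
    for h in range(model.n_components):
        u = model.x_loadings[:, h]
        nz = np.flatnonzero(u)
        order = nz[np.argsort(-np.abs(u[nz]), kind="stable")]
        for rank, j in enumerate(order, start=1):
            rows.append(
                {
                    "dimension": h + 1,
                    "feature_name": model.feature_names[j],
                    "loading_weight": u[j],
                    "rank": rank,
                }
            )
    pd.DataFrame(
        rows, columns=["dimension", "feature_name", "loading_weight", "rank"]
    ).to_csv(path, sep="\t", index=False)

    scores = pd.DataFrame(
        model.x_scores,
        columns=[f"dim{h + 1}" for h in range(model.n_components)],
    )
    scores.insert(
        0,
        "sample",
        model.sample_ids
        if model.sample_ids is not None
        else [f"s{i}" for i in range(model.x_scores.shape[0])],
    )
    scores.to_csv(scores_path, sep="\t", index=False)
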