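"""Simulated repeated-measures benchmark with correlated gene clusters.

Data are drawn from a one-way random-effects model per gene,

    X_sjk = mu_jk + pi_sk + eps_sjk,

for subject s, condition (stimulation) j and gene k: mu_jk is the fixed
condition effect of gene k's cluster, pi_sk ~ N(0, sigma_pi^2) the random
subject effect and eps_sjk ~ N(0, sigma_eps^2) the residual.  Genes come in
clusters; within a cluster both random terms share an intra-cluster
correlation rho (compound-symmetric covariance), and genes in different
clusters are independent.  The default configuration has 12 subjects x 4
stimulations (labelled LIPO5, GAG+, GAG-, NS after an HIV vaccine trial's
in-vitro stimulations) and 10 clusters of 100 genes, six of which carry a
condition effect — those 600 genes are the ground-truth discriminative set.

The benchmark compares sparse PLS-DA fitted on the raw matrix ("classical")
against the same model fitted on the within-subject matrix ("multilevel"),
scoring (a) recovery of the truth genes at a prespecified selection size and
(b) leave-one-subject-out classification error across a grid of selection
sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design_io import OmicsMatrix, RepeatedMeasuresDesign
from .multilevel import within_matrix
from .sparse_pls import fit_splsda, selected_features
from .tuning import subject_cv_error

__all__ = [
    "SimulationSpec",
    "BenchmarkResult",
    "simulate_dataset",
    "selection_accuracy",
    "run_benchmark_table1",
    "run_benchmark_table2",
]

# default cluster mean profiles over the 4 conditions; the first six carry a
# condition effect (the ground-truth discriminative clusters), the last four
# are flat noise profiles
DEFAULT_CLUSTER_MEANS: tuple[tuple[float, float, float, float], ...] = (
    (4.0, 4.0, 0.0, 0.0),      # (LIPO5, GAG+) vs (GAG-, NS)
    (3.0, 3.0, 0.0, 0.0),
    (5.0, 2.0, 0.2, 0.2),      # LIPO5 vs GAG+
    (5.0, 2.0, 0.0, 0.0),
    (1.0, 1.0, 5.0, 2.0),      # GAG- vs NS
    (0.0, 0.0, 5.0, 2.0),
    (0.0, 0.0, 0.0, 0.0),      # flat (no condition effect)
    (0.0, 0.0, 0.0, 0.0),
    (0.5, 0.5, 0.5, 0.5),
    (0.5, 0.5, 0.5, 0.5),
)


@dataclass
class SimulationSpec:
    """Parameters of the clustered random-effects generator."""

    n_subjects: int = 12
    conditions: tuple[str, ...] = ("LIPO5", "GAG+", "GAG-", "NS")
    n_clusters: int = 10
    genes_per_cluster: int = 100
    cluster_means: tuple[tuple[float, ...], ...] = DEFAULT_CLUSTER_MEANS
    sigma_pi: float = 2.0
    sigma_eps: float = 0.5
    rho: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(
                f"rho must be in [0, 1) for a positive-definite covariance; "
                f"got {self.rho}"
            )
        if len(self.cluster_means) != self.n_clusters:
            raise ValueError(
                f"{len(self.cluster_means)} cluster mean vectors for "
                f"{self.n_clusters} clusters"
            )
        for mu in self.cluster_means:
            if len(mu) != len(self.conditions):
                raise ValueError(
                    f"cluster mean {mu} has {len(mu)} entries for "
                    f"{len(self.conditions)} conditions"
                )

    @property
    def n_genes(self) -> int:
        return self.n_clusters * self.genes_per_cluster

    @property
    def n_samples(self) -> int:
        return self.n_subjects * len(self.conditions)

    def truth_mask(self) -> np.ndarray:
        """True for genes in clusters with a non-constant mean profile."""
        mask = np.zeros(self.n_genes, dtype=bool)
        for c, mu in enumerate(self.cluster_means):
            if len(set(mu)) > 1:
                a = c * self.genes_per_cluster
                mask[a : a + self.genes_per_cluster] = True
        return mask


def _compound_symmetric_chol(m: int, sigma: float, rho: float) -> np.ndarray:
    if sigma == 0:
        return np.zeros((m, m))
    cov = np.full((m, m), rho * sigma**2)
    np.fill_diagonal(cov, sigma**2)
    return np.linalg.cholesky(cov)


def simulate_dataset(
    spec: SimulationSpec,
) -> tuple[OmicsMatrix, RepeatedMeasuresDesign, np.ndarray]:
    """Draw one dataset: (matrix, design, truth mask), deterministic in seed.

    One subject-effect vector is drawn per (subject, cluster) and one
    residual vector per (subject, condition, cluster), each from a
    multivariate normal with compound-symmetric covariance (Cholesky draw).
    Rows are ordered subject-major, conditions in spec order within subject.
    """
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_subjects, len(spec.conditions)
    m = spec.genes_per_cluster
    big_n = spec.n_samples
    l_pi = _compound_symmetric_chol(m, spec.sigma_pi, spec.rho)
    l_eps = _compound_symmetric_chol(m, spec.sigma_eps, spec.rho)

    x = np.empty((big_n, spec.n_genes))
    cond_idx = np.tile(np.arange(g), n)  # row -> condition index
    for c, mu in enumerate(spec.cluster_means):
        cols = slice(c * m, (c + 1) * m)
        pi = rng.standard_normal((n, m)) @ l_pi.T if spec.sigma_pi > 0 else np.zeros((n, m))
        eps = rng.standard_normal((big_n, m)) @ l_eps.T if spec.sigma_eps > 0 else np.zeros((big_n, m))
        mu_rows = np.asarray(mu, dtype=float)[cond_idx][:, None]
        x[:, cols] = mu_rows + np.repeat(pi, g, axis=0) + eps

    subjects = [f"S{s + 1:02d}" for s in range(n) for _ in range(g)]
    conditions = [spec.conditions[j] for _ in range(n) for j in range(g)]
    sample_ids = [f"{s}_{c}" for s, c in zip(subjects, conditions)]
    width = len(str(spec.n_genes))
    feature_names = [f"gene_{k + 1:0{width}d}" for k in range(spec.n_genes)]
    matrix = OmicsMatrix(x, sample_ids, feature_names)
    design = RepeatedMeasuresDesign(
        subject=subjects, condition=conditions, sample_ids=sample_ids
    ).validate()
    return matrix, design, spec.truth_mask()


def selection_accuracy(
    selected_per_dimension: list[list[str]],
    truth_mask: np.ndarray,
    feature_names: list[str],
) -> dict:
    """Score a selection against the ground-truth discriminative genes.

    Per dimension: the percentage of that dimension's selected genes that are
    truth genes (precision).  Overall: the percentage of truth genes present
    in the union of all dimensions' selections (recall of the truth set);
    the overall figure is the headline benchmark metric.
    """
    truth = {f for f, t in zip(feature_names, truth_mask) if t}
    per_dim = []
    union: set[str] = set()
    for sel in selected_per_dimension:
        union.update(sel)
        per_dim.append(
            100.0 * sum(f in truth for f in sel) / len(sel) if sel else 0.0
        )
    overall = 100.0 * len(union & truth) / len(truth) if truth else 0.0
    return {
        "per_dimension_precision": per_dim,
        "overall_recall": overall,
        "union_size": len(union),
    }


@dataclass
class BenchmarkResult:
    """Averaged benchmark output plus per-run detail and Monte-Carlo SEs."""

    table: pd.DataFrame
    stderr: pd.DataFrame
    per_run: list[pd.DataFrame]
    n_runs: int
    seeds: list[int]
    extras: dict = field(default_factory=dict)


def _replace_seed(spec: SimulationSpec, seed: int) -> SimulationSpec:
    from dataclasses import replace

    return replace(spec, seed=seed)


def run_benchmark_table1(
    spec: SimulationSpec,
    n_runs: int = 20,
    keep_per_dim: int = 200,
    n_components: int = 3,
) -> BenchmarkResult:
    """Truth-gene recovery at a prespecified selection size, both methods.

    Per run: simulate, fit sparse PLS-DA on the raw matrix (classical) and on
    the within matrix (multilevel) with ``keep_per_dim`` genes per dimension,
    and score the selections against the 600 truth genes.  Rows of the
    returned table are methods; columns are per-dimension precision plus the
    overall truth-recall ("all") averaged over runs.
    """
    seeds = [spec.seed + i for i in range(n_runs)]
    per_run = []
    for seed in seeds:
        x, design, truth = simulate_dataset(_replace_seed(spec, seed))
        xw = within_matrix(x, design)
        rows = {}
        for method, mat in (("classical", x), ("multilevel", xw)):
            model = fit_splsda(
                mat, design.condition, n_components,
                keepX=[keep_per_dim] * n_components,
            )
            sel = selected_features(model)["per_dimension"]
            acc = selection_accuracy(sel, truth, x.feature_names)
            rows[method] = acc["per_dimension_precision"] + [
                acc["overall_recall"]
            ]
        cols = [f"component_{h + 1}" for h in range(n_components)] + ["all"]
        per_run.append(pd.DataFrame(rows, index=cols).T)
    stacked = np.stack([df.to_numpy() for df in per_run])
    mean = pd.DataFrame(
        stacked.mean(axis=0), index=per_run[0].index, columns=per_run[0].columns
    )
    se = pd.DataFrame(
        stacked.std(axis=0, ddof=1) / np.sqrt(n_runs),
        index=per_run[0].index,
        columns=per_run[0].columns,
    )
    ordering = float(
        np.mean([df.loc["multilevel", "all"] > df.loc["classical", "all"]
                 for df in per_run])
    )
    return BenchmarkResult(
        table=mean, stderr=se, per_run=per_run, n_runs=n_runs, seeds=seeds,
        extras={"multilevel_beats_classical_fraction": ordering},
    )


def run_benchmark_table2(
    spec: SimulationSpec,
    n_runs: int = 20,
    keep_grid: tuple[int, ...] = tuple(range(25, 326, 25)),
    n_components: int = 3,
    methods: tuple[str, ...] = ("classical", "multilevel"),
) -> BenchmarkResult:
    """Leave-one-subject-out error across selection sizes, both methods.

    Per run and per grid value, each method fits one model per held-out
    subject (``keep`` genes on each of ``n_components`` dimensions) and the
    error is read at 1..n_components components from truncated predictions.
    The returned table is indexed by grid value with (method, components)
    columns, averaged over runs.
    """
    seeds = [spec.seed + i for i in range(n_runs)]
    columns = pd.MultiIndex.from_product(
        [methods, range(1, n_components + 1)], names=["method", "components"]
    )
    per_run = []
    for seed in seeds:
        x, design, _ = simulate_dataset(_replace_seed(spec, seed))
        df = pd.DataFrame(index=list(keep_grid), columns=columns, dtype=float)
        df.index.name = "n_genes"
        for keep in keep_grid:
            for method in methods:
                errs = subject_cv_error(
                    x, design, keep, n_components,
                    multilevel=(method == "multilevel"),
                )
                for h in range(1, n_components + 1):
                    df.loc[keep, (method, h)] = errs[h - 1]
        per_run.append(df)
    stacked = np.stack([df.to_numpy() for df in per_run])
    mean = pd.DataFrame(
        stacked.mean(axis=0), index=per_run[0].index, columns=columns
    )
    se = pd.DataFrame(
        stacked.std(axis=0, ddof=1) / np.sqrt(n_runs),
        index=per_run[0].index,
        columns=columns,
    )
    return BenchmarkResult(
        table=mean, stderr=se, per_run=per_run, n_runs=n_runs, seeds=seeds
    )
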