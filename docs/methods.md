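# Methods

## Problem setting

Repeated-measures (cross-over) omics experiments measure the same subjects
under several conditions — here, PBMC samples stimulated in vitro with
different peptide pools — so that every sample carries two superimposed
signals: a subject-specific baseline (between-subject variation) and the
condition effect of interest (within-subject variation). When between-subject
variation dominates, as it typically does for expression data, multivariate
models fitted on the raw matrix spend their leading directions on subject
differences rather than condition differences. The package separates the two
sources first and then applies sparse latent-variable models to the
within-subject part only.

## Split-up variation

For subject `s`, condition `j` and feature `k`, the observation decomposes
exactly as

    x_sjk = x..k + (x_s.k − x..k) + (x_sjk − x_s.k)
            offset  between-subject   within-subject

with `x..k` the grand mean and `x_s.k` the mean over subject `s`'s samples.
In matrix form `X = X_offset + X_b + X_w`, and because the three parts are
mutually orthogonal (each subject's within rows sum to zero; between rows sum
to zero over subjects), `‖X‖² = ‖X_offset‖² + ‖X_b‖² + ‖X_w‖²` holds exactly,
also for unbalanced designs (subjects with different numbers of conditions):
all means are arithmetic means over available samples. The decomposition is
purely algebraic — no mixed model is fitted, no distributional assumption is
used, and no variance components are estimated.

Two useful consequences:

* `variation_summary` reads off the share of each variation source from the
  sum-of-squares identity.
* the within block of a subject depends only on that subject's rows
  (locality), which is what makes subject-held-out cross-validation
  well-defined: a held-out subject's within rows can be computed from its own
  samples alone.

With a second within-subject factor (time), the within part is further split
into condition, time, condition:time and residual effects plus two *random*
interaction matrices (subject:condition, subject:time). The multivariate step
then uses `X_w* = X_w − X_subject:condition − X_subject:time`, which retains
the fixed effects and drops the subject-level interactions. `X_w*` is
computed by that subtraction (rather than by summing the four effect
matrices) so the reconstruction identity holds exactly even when the design
is unbalanced; the four effect matrices are still exported individually. In a
fully balanced design all component matrices are pairwise orthogonal and
`X_w*` is invariant to adding an arbitrary constant per subject.

## Sparse PLS engine

One engine drives both analyses. Given row-aligned blocks `X (N×p)` and
`Z (N×q)`, both column-standardized (mean 0, sd 1 with the N−1 denominator;
zero-variance columns are dropped and logged), each dimension `h` solves

    max cov(X_{h−1} u, Z_{h−1} v)   s.t.  ‖u‖ = ‖v‖ = 1,

with L1 penalties that keep at most `keepX[h]` / `keepZ[h]` nonzero loading
weights. The solver alternates soft-thresholded power iterations on
`M = X'Z`, initialized from M's leading singular pair; the threshold is set
each iteration to the (keep+1)-th largest |entry|, so exactly the requested
number of weights survives (ties at the boundary go to the earliest feature
index and are logged; an exact tie, e.g. duplicated columns, falls back to
hard thresholding so the kept set stays nonempty). Convergence is declared
when `max|u − u_prev| < 1e-6`, with a cap of 500 iterations (a warning and a
flag on non-convergence). With everything kept, the fixed point is the
leading singular pair of `M` — this dense limit is enforced in the tests
against an SVD oracle, and the whole engine is cross-checked against an
independent reference implementation (mixOmics) on a frozen fixture.

Sign convention: each `u_h` is flipped (jointly with `v_h`, leaving the
covariance unchanged) so its largest-magnitude coordinate is positive,
making outputs reproducible across platforms.

Deflation:

* **mode A (canonical)** — both blocks deflated by their own score:
  `X_h = X_{h−1} − ξ_h c_h'`, `Z_h = Z_{h−1} − ω_h d_h'` with
  `c_h = X_{h−1}'ξ_h / ξ_h'ξ_h` (and analogously `d_h`). This is the
  bidirectional two-assay integration setting (`fit_spls`).
* **regression mode on the response** — for the discriminant analysis
  (`fit_splsda`) the response block is the one-hot group matrix `Y (N×G)`,
  centered and scaled like any column and never penalized; `Y` is deflated
  by the X score (`Y_h = Y_{h−1} − ξ_h e_h'`), the convention that keeps
  regression coefficients well-defined. Mode A on Y is available via
  `y_deflation="modeA"`.

X-score orthogonality (`ξ_h ⊥ ξ_{h'}`) follows from the X deflation and is
asserted in the tests.

Class prediction uses the standard PLS coefficient construction
`B_h = W_h (C_h' W_h)^{-1} Q_h'` from the first `h` dimensions (`W` the
loading weights, `C` the X local-regression coefficients, `Q` the Y ones).
Test rows are standardized with the *training* statistics, `Ŷ = X_std B` is
mapped back to the 0/1 dummy scale (so columns stay comparable under
unequal group sizes), and the predicted class is the column argmax, ties to
the first level. The default number of dimensions for the discriminant
analysis is `G − 1`.

## Tuning

Two criteria choose the per-dimension selection size, both applied
sequentially (dimension `h` tuned with dimensions `1..h−1` frozen):

* **Criterion 1 — subject-structured CV** (`loso_cv`): folds are whole
  subjects (leave-one-subject-out by default; a subject-stratified k-fold is
  available for larger cohorts, in line with using LOO only below ~15
  subjects). Per fold, the training within matrix is rebuilt from training
  subjects only, the held-out subject's within rows come from its own
  samples, training standardization statistics are applied to the test rows
  (refitting them per fold and never on test data avoids leakage — the
  choice is ours; the alternative of standardizing once on all data leaks
  mildly), and the error is the fraction of the held-out subject's condition
  labels misclassified. Ties in mean error go to the smallest size
  (parsimony). In the two-factor case the held-out rows are the subject's
  own within deviations; the subject-by-factor interaction terms cannot be
  estimated from a single subject and remain in the test rows as noise.
* **Criterion 2 — in-sample score** (`tune_criterion2_da`,
  `tune_criterion2_integration`): on the current deflated matrices,
  `cor(ξ, ω_Y)·var(ξ)` for the discriminant analysis (the plain correlation
  is reported alongside, since either may be quoted) or `cov(ξ, ω)` for the
  integration. The number of dimensions to retain follows a sudden-drop
  rule applied to the score correlations at the chosen sizes (correlations
  are scale-free across dimensions, unlike `var(ξ)`, which decreases
  structurally under deflation): stop before the first dimension whose value
  falls below a fraction (default 0.8) of the previous dimension's — an
  explicit version of the usual by-eye rule (e.g. correlations 0.94, 0.96,
  0.95 followed by 0.62 retain three dimensions).

## Simulator and benchmark

The generator emulates a one-way random-effects model with clustered,
correlated genes:

    X_sjk = mu_jk + pi_sk + eps_sjk,
    pi ~ N(0, sigma_pi²), eps ~ N(0, sigma_eps²),

12 subjects × 4 stimulations (LIPO5, GAG+, GAG−, NS), 10 clusters of 100
genes. Within a cluster, both random terms have compound-symmetric
correlation `rho` across genes (one multivariate-normal draw per
(subject, cluster) for `pi`, one per (subject, condition, cluster) for
`eps`, via the covariance Cholesky factor); clusters are independent.
Defaults: `sigma_pi = 2`, `sigma_eps = 0.5`, `rho = 0.8` (with 0.7 as the
usual alternative correlation setting), cluster mean profiles

    (4,4,0,0) (3,3,0,0)  — separate (LIPO5, GAG+) from (GAG−, NS)
    (5,2,0.2,0.2) (5,2,0,0) — separate LIPO5 from GAG+
    (1,1,5,2) (0,0,5,2)  — separate GAG− from NS
    (0,0,0,0) ×2, (0.5,0.5,0.5,0.5) ×2 — flat noise clusters

so exactly 600 genes (6 clusters) are truly discriminative. The generator is
bitwise deterministic given its seed.

The benchmark compares **classical** (raw matrix) against **multilevel**
(within matrix) sparse PLS-DA two ways: truth-gene recovery with 200 genes
selected on each of 3 dimensions (per-dimension precision plus the headline
overall recall of the 600 truth genes in the selection union), and
leave-one-subject-out error across a grid of selection sizes at 1–3
components (one fit per fold; errors at fewer components read from truncated
predictions). Defaults average 20 replicate runs with per-run seeds
`seed + i`; with 20 runs the benchmark's own Monte-Carlo standard errors are
~1–3 percentage points for recovery and ~0.01–0.02 for errors.

What the simulation does *not* emulate: heavy-tailed or count-like
expression noise, gene-specific variances, unbalanced or missing samples,
and any two-factor structure (the two-factor code path is exercised by
property tests instead). Passing benchmarks therefore demonstrate the
variance-separation mechanism, not robustness to real-data artefacts.

Observed behaviour at these defaults: the multilevel analysis separates the
six discriminative clusters essentially perfectly (each dimension selects one
whole cluster pair, recovery ≈ 100%, held-out error ≈ 0 at 3 components,
exactly 0.5 at 1 component since one direction resolves only half the
conditions), while the classical analysis loses whole noise-cluster blocks to
the subject variation (recovery ≈ 90%, error ≈ 0.25–0.30). The ordering
multilevel > classical holds in essentially every run.

## Numerical choices and limitations

* SDs use the N−1 denominator throughout; covariances `ξ'ω/(N−1)`.
* Zero-variance columns are dropped at standardization, with the training
  mask reapplied at prediction; an all-constant block is an error.
* Degenerate inputs rejected with named locations: non-numeric/missing
  cells, duplicate IDs, subjects with a single sample, duplicate
  (subject, condition[, time]) cells, disjoint sample sets in the two-block
  alignment.
* `rho` must lie in [0, 1) so the compound-symmetric covariance is positive
  definite.
* The engine fits one local optimum per dimension; with strong sparsity the
  alternating iteration is not guaranteed to find the global maximizer
  (standard for this family). The SVD initialization makes it deterministic.
* Level order everywhere is first appearance in the input; all outputs state
  it explicitly.
* The CLI (`mlspls simulate|decompose|splsda|spls|tune|benchmark`) is a thin
  shell over the library; all computation lives in the importable modules.
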