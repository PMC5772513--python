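# Methods

## Object-symmetry decomposition

A configuration of k landmarks (k_p bilateral pairs, k_m midline points) in
d dimensions is compared with its *reflect-relabeled* copy: coordinates
negated on the reflection axis and paired rows swapped. The dataset is
doubled with these copies and superimposed jointly by generalized Procrustes
analysis (GPA): center, scale to unit centroid size, iteratively rotate each
configuration to the running consensus (proper rotations via SVD with
determinant correction), re-estimate the consensus until its change falls
below `tol = 1e-10` (at most `max_iter = 100` iterations), then re-rotate
everything once to the final consensus. The consensus is initialized from
the arithmetic mean of centered, scaled configurations so results do not
depend on specimen order.

The GPA frame is then made canonical in three steps. (1) The doubled-sample
consensus C satisfies T(C) = C·Q₀ for a rotation Q₀ (T = reflect-relabel);
U = Q₀ᵀR (R the coordinate reflection) is an orthogonal symmetric
involution, and the rotation built from its eigenvectors maps the sample
into a frame where the symmetry plane coincides with a coordinate plane.
(2) The consensus is replaced by its exactly symmetrized version and all
configurations re-aligned to it. (3) Because the +1 eigenspace of U is
degenerate, the frame is still free up to in-plane rotations, to which the
CR statistic is *not* invariant (zeroing block diagonals breaks rotation
equivariance); the in-plane coordinates are therefore rotated onto the
principal axes of the consensus with deterministic sign conventions. After
this, the symmetric component is invariant under reflect-relabel, and all
downstream statistics are reproducible to ~1e-12 regardless of input order.

Per specimen and replicate, `symmetric = (aligned original + aligned
reflected copy)/2` and `asymmetric = (aligned original − aligned reflected
copy)/2`, so `symmetric + asymmetric` reconstructs the aligned configuration
*exactly* (the ½ convention is ours; it makes the identity testable at
machine precision). Directional asymmetry (DA) is the specimen mean of the
asymmetric components; FA deviations are asymmetric − DA. DA removal can be
disabled (`remove_da=False`), but FA theory expects it and it is the
default. No projection beyond Procrustes residuals from the consensus is
applied (tangent-space projection is a negligible correction at facial
shape scales and is isolated here as a deliberate non-step).

### Procrustes ANOVA

Sums of squares are taken over the doubled dataset. With r replicates,
per-specimen replicate means s_i, a_i, grand mean s̄ and DA mean ā:

| effect            | SS                              | df                  |
|-------------------|---------------------------------|---------------------|
| individual        | 2r Σᵢ ‖sᵢ − s̄‖²               | (n−1)·s_sym         |
| side (DA)         | 2rn ‖ā‖²                       | s_asym              |
| individual × side | 2r Σᵢ ‖aᵢ − ā‖²                | (n−1)·s_asym        |
| error (r ≥ 2)     | 2 Σᵢₜ ‖sᵢₜ−sᵢ‖²+‖aᵢₜ−aᵢ‖²      | n(r−1)(s_sym+s_asym)|

These add exactly to the total squared deviation of all 2nr aligned
configurations around the consensus. The subspace dimensions are counted as
free coordinates minus structure-preserving similarity transforms:
`s_sym = 3k_p + 2k_m − 4`, `s_asym = 3k_p + k_m − 3` for d = 3 (both
`2k_p + k_m − 2` for d = 2); they sum to the full shape-space dimension of
the doubled configuration and are exposed on the ANOVA table for audit.
The error row exists only when replicates exist; with a single digitization
its absence is explicit, never a silent zero.

## CR modularity test

For disjoint variable sets A, B of covariance S:
`CR = ‖S_AB‖_F / √(‖S*_AA‖_F · ‖S*_BB‖_F)`, the starred blocks having their
diagonals zeroed *before* summation (subtracting diagonal sums afterwards
loses ~4 digits to cancellation when variances dominate — measured while
validating against an elementwise oracle). Multi-module CR is the
unweighted mean of pairwise CRs; a flag exposes the pairwise table. The
permutation test reassigns *landmarks* (their d coordinate variables move
jointly) to modules, preserving module sizes, and reports
`p = (1 + #{CR_perm ≤ CR_obs})/(n_perm + 1)` with ties counting toward
rejection — the add-one convention gives the attainable floor
`1/(n_perm+1)` (0.001 at the default 999 permutations). The observed value
is evaluated through the same canonical-order arithmetic as the
permutations so that a permutation reproducing the observed partition ties
*exactly*. Group subsamples reuse the shared joint superimposition of the
total dataset (one consistent shape space); `resuperimpose_groups`
re-aligns each subsample instead. Covariances are centered within the
analyzed (sub)sample.

Calibration (seeded Monte-Carlo, re-run by `scripts/acceptance.py`): mean
null CR ≈ 1.04 over 500 i.i.d. datasets (n = 200 × 30 variables); type-I
error at α = 0.05 within [0.03, 0.07] over 200 null datasets; power ≈ 1.0
over 100 replicates of the default modular scenario (ρ_within = 0.6,
ρ_between = 0.1, n = 200).

## Covariance-matrix similarity

Matrix correlation is the Pearson correlation over lower-triangle elements
(diagonal included by default; both modes are emitted, as conventions
differ). Significance comes from jointly permuting the d×d landmark blocks
of one matrix's rows and columns, `p = (1 + #{r_perm ≥ r_obs})/(n_perm+1)`,
default 10,000 iterations.

A structural caveat drives one design choice. The symmetric component lies
in the +1 eigenspace of the reflect-relabel operator and FA in the −1
eigenspace; the two covariance matrices are supported on orthogonal,
complementary subspaces, so their full-space Frobenius inner product is
*identically zero* and the full-space matrix correlation is bounded far
below 1 no matter how similar the underlying structures are (measured
≈ 0.10 at n = 500 under exactly proportional generation; moderate positive
values in real data arise from heterogeneous diagonals). Superimposition
adds a second distortion: similarity-transform-like covariance directions
are absorbed differently in the two subspaces. Proportionality of
individual and FA structure is therefore assessed on their common
parameterization — the paired-landmark one-side sub-block — where
Σ_FA = c·Σ_ind is exactly identifiable; with c = 0.5 and n = 500 the
recovered correlation is ≈ 0.97 with the permutation p at its floor. The
pipeline still reports the conventional full-space correlations alongside.

## Integration metrics

For a module covariance sub-block (extracted from the full-shape
covariance; no per-module re-superimposition, flag available) with p
variables and eigenvalues λᵢ: TVC = Σλᵢ, λ̄ = TVC/p,
`Var(λ) = Σ(λᵢ−λ̄)²/p` (population divisor, zero eigenvalues included),
`Evstv = Var(λ)/TVC²`, `Evstvnv = Var(λ)/(λ̄²(p−1))`. Evstvnv is the
standard relative eigenvalue variance: 0 when all eigenvalues are equal,
1 iff rank one, and scale-invariant — as is Evstv, whose numerator and
denominator are both quadratic in scale (only Var(λ) itself scales, as c²).
Per-module FA magnitude is the trace of the module's FA covariance
sub-block. Published per-module reference values for a 34-landmark facial
dataset are frozen in `validation.EVSTV_REFERENCE_TABLE`; all 12 module
rows are consistent with Evstv = Var(λ)/TVC² within printed rounding radii,
which pins down the scaling this package implements.

Module-level regressions are ordinary least squares with an F-test
(df 1, n−2) and a pointwise mean-response confidence band (default
α = 0.01) used to flag modules whose variation exceeds what their
integration predicts. Note that for the asymmetric component the FA
magnitude equals the module's TVC, so the FA-on-integration regression is
the mirror of the integration-on-variance regression there — a definitional
identity, not a finding.

## Morphospaces

PCA is the eigendecomposition of the component covariance; loading signs
are fixed by the largest-magnitude entry. Group ellipses are *coverage*
ellipses: the 2-D score covariance scaled by the χ²₂ quantile at the stated
coverage (0.90 by default), so the 90% ellipse is expected to contain 90%
of a bivariate-normal score cloud (verified by simulation). Group
mean-shapes take the place of rendered morphings, which are out of scope.

## Synthetic data generator

The generator emulates a bilateral landmark study on a perfectly symmetric
template (the curated 34-landmark, 3-D face at mm scale, or a random
template for other sizes). Deviations are drawn in *free* parameterizations
— symmetric: d coordinates per pair plus in-plane midline coordinates;
antisymmetric: d per pair plus the off-plane midline coordinate — and
expanded by exact mirroring, so ground-truth decomposition is exact before
GPA and any GPA-induced distortion is measured, not confounded. The
among-individual covariance comes from a latent factor model (one global
factor plus one factor per module): within-module correlation ρ_w,
between-module ρ_b, marginal SD σ_ind; positive semi-definite for all
0 ≤ ρ_b ≤ ρ_w ≤ 1. FA structure options: `proportional` (same modular
structure, variance scaled by (σ_fa/σ_ind)²), `independent` (random
Wishart-style structure unrelated to the individual one), `isotropic`.
DA is a fixed random antisymmetric direction of stated magnitude; group
effects are fixed random symmetric-type mean shifts; digitization error is
i.i.d. Gaussian per replicate. All draws flow from one seeded generator
(same seed → bit-identical dataset).

Defaults mirror a single-digitization facial study: n = 500, 34 landmarks,
d = 3, ρ_w = 0.6, ρ_b = 0.1, σ_ind = 1.0 mm, DA 0.4 mm, σ_fa = 0.35 mm
(facial FA is roughly an order of magnitude smaller than among-individual
variation), no error replicates. What the generator does **not** emulate:
landmark-specific variance profiles, allometry, non-Gaussian tails,
spatially correlated digitization error, and admixture structure beyond
mean shifts — so passing tests demonstrate correctness of the statistics
under the stated model, not robustness to those real-data features.

## Problem sizes and numerics

Validation experiments use: 500 datasets (null CR mean), 200 datasets × 199
permutations (type-I error), 100 replicates × 999 permutations through the
full pipeline (power), n = 500 for covariance recovery, 200 Wishart pairs
for matrix-permutation calibration — sizes at which the binomial noise of
the estimated rates is well inside the asserted bands while the whole suite
runs in well under a minute each. GPA uses batched 3×3 SVDs; CR
permutations reindex a precomputed squared covariance. Degenerate inputs
(zero centroid size, zero within-module covariation, constant matrices,
zero-variance regressors, sub-3 specimen groups) raise descriptive errors
or warnings rather than propagating NaNs.
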