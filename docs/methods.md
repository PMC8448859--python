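# Methods

`pdsubtype` implements a multi-view patient-subtyping analysis for
cross-sectional Parkinson's disease cohorts: per-view Gaussian similarity
kernels, bi-stochastic similarity fusion with learned convex view weights,
silhouette-tuned agglomerative clustering, subsampling stability with
optimal label matching, and a subtype-characterisation statistics battery.
This note records the model, the defaults that matter, and the design
choices made where the design was genuinely open.

## Cohort preparation

A cohort is a patient-by-variable table whose columns are assigned to a
motor view (MDS-UPDRS II total, MDS-UPDRS III on-medication total,
Schwab & England ADL), a non-motor view (MDS-UPDRS I total, MoCA, RBD
questionnaire), an optional biomarker view (CSF amyloid-beta, CSF/plasma
alpha-synuclein, CSF tau/p-tau), covariates, and categorical descriptors.
Cleaning order is fixed: complete-case filtering on the clustering views,
then mean imputation of explicitly listed columns only (the protocol
imputes medication dose, never clinical scores, and never silently), then
per-view z-scoring.  The z-score convention defaults to the sample
standard deviation (`ddof=1`, configurable); the choice is immaterial
downstream because kernel bandwidths are scaled by the median pairwise
distance, so a constant factor on the z-scores cancels exactly.
Missing-value tokens accepted in delimited input are the empty string,
"NA" and "NaN", case-insensitively; any other unparseable numeric cell
also becomes missing.

## Kernels

For a z-scored view matrix X the patient similarity is the Gaussian kernel
K_ij = exp(−d_ij² / 2σ²) with d_ij the Euclidean distance and
σ = s · median(off-diagonal pairwise distances).  The bandwidth scale s is
the per-view hyperparameter tuned by the search (log-uniform in
[0.25, 4]); s = 1 is the classical median heuristic.  A view whose rows
are all identical has no usable scale and is rejected.

## Bi-stochastication

A similarity matrix is bi-stochasticated (all row and column sums one,
entries non-negative) before clustering, so every patient contributes the
same total similarity mass and dense blocks indicate candidate clusters
rather than high-variance rows.  Two Bregman projections are provided:

- **Frobenius**: the Euclidean projection onto the Birkhoff polytope,
  computed by Dykstra's alternating projections between the affine
  row/column-sum constraint (which has a closed form for symmetric input)
  and the non-negative orthant.  This is the default for the standalone
  `bistochastize` operation and is verified against a generic
  constrained-QP solve in the tests.
- **KL (Sinkhorn–Knopp)**: symmetric diagonal scaling.  Multiplicative,
  hence structure-sharpening — small between-cluster similarities are
  suppressed relative to within-cluster ones — and scale-free.

Convergence is declared when the maximum row/column-sum deviation falls
below 1e-8 (default), with a hard iteration cap (6000) that raises a
convergence error carrying the residual; kernels built from very small
bandwidths are nearly decomposable and are the usual culprits, and the
hyperparameter search records such trials as failed rather than aborting.

## Fusion and view weights

`mbbs_fuse` learns one weight per view on the probability simplex and a
fused bi-stochastic matrix:

1. each view kernel is bi-stochasticated individually (B_v), putting
   views on a common scale;
2. a consensus S₀ = bistochastize(mean_v K_v) is built from the uniform
   combination of the raw kernels;
3. the weights solve w = argmin ‖Σ_v w_v B_v − S₀‖²_F on the simplex,
   computed exactly by active-set enumeration over the simplex faces
   (ties break to the maximum-entropy uniform vector);
4. the fused matrix is bistochastize(Σ_v w_v K_v) at the learned weights.

The weight fit compares cluster *contrast* only: diagonals are dropped
(self-similarity carries no grouping information), the mean off-diagonal
level is removed (all bi-stochastic matrices share the flat component, so
it cannot discriminate views), and each atom is normalised to unit
Frobenius norm (otherwise amplitude rather than structure buys weight —
a noise view at a tiny bandwidth yields a sparse high-contrast atom, at a
huge bandwidth a flat one, and both would otherwise spuriously dominate).

Two designs were rejected after analysis. Fitting raw kernels against the
bi-stochastic target is dominated by kernel norms: the lower-norm kernel
is always "closer" to the Birkhoff polytope, and in simulation the
pure-noise view received the larger weight in 20 of 20 seeded runs.  A
self-consistent alternation (rebuild S at the current w, refit w, repeat)
has the single-view corners of the simplex as global attractors — a fused
matrix built mostly from one view is in turn perfectly fit by that view
alone — and collapses whenever one view suffices for the clustering.  The
fixed uniform-prior consensus avoids both failure modes and yields
interior weights that grade each view by how much of the shared cluster
structure it carries; with an informative and a pure-noise view the
informative view received the larger weight in 20 of 20 seeded runs, and
with two informative views plus a noise view the noise view received the
smallest weight in 10 of 10.  KL is the fusion default (sharpening helps
the downstream clustering); Frobenius is available.  The recorded
objective trace is the consensus fit before and after the weight step and
is non-increasing by construction.

## Distance, clustering and model selection

The fused similarity is converted to a dissimilarity D = 1 − K*/max
off-diagonal(K*).  The rescaling matters: a bi-stochastic matrix has
entries averaging 1/N, so the literal complement compresses all distances
toward one; dividing by the maximum off-diagonal entry restores dynamic
range.  The literal complement is available as `rescale="none"`.
Clustering is agglomerative on the precomputed distances; average linkage
is the default (valid for arbitrary dissimilarities — Ward is excluded
because it presumes Euclidean geometry), with complete and single
available.  Model selection maximises the mean silhouette index over a
seeded random search: per trial, each view's bandwidth scale is drawn
log-uniformly in [0.25, 4] and the cluster count uniformly from
k ∈ {2,…,6}; 100 trials by default.  Exact ties in the search objective
are broken by the silhouette — relevant when an external agreement
objective (see below) saturates at its maximum.

## Stability

Patient-based: the cohort is subsampled 10 times with 10% of patients
removed, the full search (100 tunes) is re-run from scratch per subset —
hyperparameters are deliberately not frozen at the reference optimum —
and subset clusters are matched to the reference labels by the Hungarian
algorithm on the cluster-overlap contingency table; agreement is matched
overlap over shared patients, and per-subset confusion tables record
which reference subtypes absorb the errors.  Subset draws are without
replacement; disjointness across subsets is not enforced.

View-based: a third kernel (by default the five-variable biomarker panel)
is added and the search re-run for 50 rounds optimising the unadjusted
Rand index between the three-view clustering and the reference labels;
the adjusted Rand index is reported alongside, clearly labelled.  The
Rand index here is the plain pair-concordance fraction; both it and the
Hungarian matching are verified against exhaustive enumeration oracles.

## Statistics battery

Per continuous variable: Levene's test (mean-centred, α = 0.05;
median-centring available) screens variance homogeneity, and Shapiro–Wilk
on pooled within-group residuals (α = 0.05) stands in for visual QQ
inspection so the branch is deterministic and testable.  Unequal
variances → linear group-means model with HC3 heteroscedasticity-
consistent ("White") covariance and a robust Wald F, post-hoc Welch
pairwise t-tests BH-adjusted; equal variances and normal residuals →
one-way ANOVA with Tukey HSD post-hoc; equal variances, non-normal →
Kruskal–Wallis with pairwise Wilcoxon rank-sum BH-adjusted.  Post-hoc
batteries run when the omnibus p < 0.05.  Categorical variables get
Fisher's exact test; r×c tables beyond 2×2 use the exact conditional
(Freeman–Halton) generalisation by full enumeration when the table space
is below 200,000 tables, otherwise a seeded Monte-Carlo approximation
with 10⁵ margin-preserving samples (Patefield sampling, add-one p-value).
ANCOVA (ordinary least squares with group indicators plus age and disease
duration, partial F for the group term) is computed for the
ANOVA-eligible variables named by the caller — eligibility is explicit
configuration, not inferred.  The panel-wide FDR is Benjamini–Hochberg
over exactly the panel's nominal p-values, separate from the protein
screen's own BH correction.

The protein screen drops proteins with any missing value, then proteins
with standard deviation strictly below 0.3 (sample SD), runs one-way
ANOVA per remaining protein, BH-corrects across proteins, and reports
Tukey HSD post-hoc pairs per hit (FDR p < 0.05).

## Synthetic cohort generator

The generator emulates the structure of the study data so every stage is
testable without access to the real cohort: 103 patients (configurable),
three subtypes at proportions 60/20/23 assigned by largest-remainder
apportionment (printed subtype sizes are exactly reproducible), per-view
Gaussian features around per-subtype centroids taken from the published
per-subtype means and SDs, and a `separation` factor multiplying centroid
differences around the prevalence-weighted grand mean (1 = study scale,
0 = null cohort, 5 = the well-separated validation condition used in the
recovery tests).  Scores are snapped to instrument granularity (integer
rating-scale totals with their valid ranges, MoCA in [0, 30],
Schwab & England in multiples of 5), missingness is injected MCAR into
the clustering columns only (the real missingness mechanism is unknown),
the biomarker view always shares one centroid across subtypes, item-level
tremor (11) and PIGD (5) blocks are generated per medication state for
the phenotype logic, and the protein block carries 251 analysable
proteins plus 20 low-variance and 19 incomplete ones to exercise the
screen's filters, with 10 proteins shifted by 1 SD in the severe subtype
(nine up, one down).  Within-subtype feature noise is independent by
default; the real data's within-subtype correlation is unreported, and
this is the main respect in which the generator is easier *and* harder
than real data — easier because features are exchangeable, harder because
no correlated block reinforces the subtype signal.  Passing recovery
tests on this generator therefore demonstrates the pipeline's mechanics,
not field performance on BioFIND-like data.

At study-scale separation the three-subtype structure is genuinely
marginal under independent noise: the silhouette often prefers the
two-cluster mild-versus-rest split.  The well-separated condition exists
precisely to test recovery where the answer is unambiguous.

## Numerical choices

Bi-stochastic residual tolerance 1e-8; fusion weight ties broken to
uniform at 1e-12; Sinkhorn warm-starts its scaling vector when the same
matrix family is rebalanced repeatedly; ANOVA p-values with zero
between-group variance (F ≤ 0 up to roundoff) are clamped to 1; the
distance matrix is symmetrised and negative dust clipped at 0; fcluster
may merge ties and return fewer than k clusters, in which case the
reported k is the realised cluster count.

## Problem sizes

Default analyses run at the study's own sizes: N ≈ 100 patients, 100
search trials, 10 stability subsets × 100 tunes, 50 sensitivity rounds,
~250 proteins.  Dense N×N linear algebra is exact throughout; nothing is
approximated at this scale.

## Known limitations

- The exact objective of the original multi-matrix bi-stochastication
  method is not published in the main text it accompanies; the consensus
  formulation here is this package's own documented choice, isolated in
  `mbbs_fuse` so it can be swapped.
- Weights are a measure of contrast alignment with the uniform consensus,
  not likelihood-based; no uncertainty is attached to them.
- The statistics battery is cross-sectional; no mixed models, survival or
  longitudinal testing.
- LEDD is consumed as a precomputed column; medication-log conversion is
  out of scope, as are genotype-based risk scores.
- The RBD questionnaire positivity cutoff defaults to 5 and is exposed as
  configuration; the source protocol does not print its cutoff.
- TD/PIGD thresholds (1.15 / 0.90) and the 11/5 item sets follow the
  standard MDS-UPDRS phenotype convention.
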