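# pdsubtype

Multi-view similarity fusion and subtype discovery for cross-sectional
Parkinson's disease cohorts.

Parkinson's disease is clinically heterogeneous: patients at comparable
disease stages differ widely in motor severity, tremor versus gait
phenotype, cognition, sleep behaviour and mood.  Data-driven subtyping
asks whether a cohort decomposes into reproducible patient groups when
motor and non-motor assessments are considered jointly rather than
concatenated.  `pdsubtype` is a library for that analysis, aimed at
biostatisticians and clinical researchers working with cohort tables of
MDS-UPDRS scores, cognitive and sleep questionnaires, and optional
CSF/plasma biomarker and proteomic panels.

## Method

For each clinical view v (motor, non-motor, optionally biomarker) a
patient-similarity kernel is built from the z-scored features,

    K⁽ᵛ⁾_ij = exp( −‖x_i − x_j‖² / 2σ_v² ),   σ_v = s_v · median_ij ‖x_i − x_j‖,

and the views are fused into a single bi-stochastic similarity matrix
K\* (all row and column sums equal one) with learned convex weights
w ∈ Δ: each kernel is bi-stochasticated individually (Sinkhorn–Knopp or
Dykstra/Birkhoff projection), the weights solve the simplex-constrained
least-squares alignment of the per-view bi-stochastic kernels with the
uniform-combination consensus, and K\* = bistochastize(Σ_v w_v K⁽ᵛ⁾).
The weight on a view measures how much of the shared cluster structure
that view carries.

Patients are clustered by agglomerative hierarchical clustering (average
linkage) on D = 1 − K\*/max(K\*_offdiag), with the per-view bandwidth
scales s_v and the cluster number k tuned jointly by maximising the mean
silhouette index s(i) = (b_i − a_i)/max(a_i, b_i) over a seeded random
search.  Robustness is quantified by (i) repeated 10% patient deletion
with full re-tuning and Kuhn–Munkres (Hungarian) matching of subset
clusters to the reference, and (ii) adding a further data view and
re-optimising the Rand index against the reference clustering.  Subtypes
are characterised by an automatic test-selection battery (Levene +
normality screening → ANOVA / HC3-robust ANOVA / Kruskal–Wallis; Fisher's
exact for categoricals; ANCOVA adjusting age and disease duration;
panel-wide Benjamini–Hochberg FDR) plus a proteomics screen, and by
derived motor phenotypes (tremor/PIGD score ratio, TD/PIGD/indeterminate
classes, medication-state shifters, RBD positivity).

A seeded synthetic-cohort generator with known subtype structure
(103 patients, subtypes of 60/20/23, published per-subtype score
distributions, an uninformative biomarker panel, and a protein matrix
with subtype-III-shifted proteins) makes every stage testable without
access to the real repository.  See `docs/methods.md` for assumptions,
defaults and design rationale.

## Worked example

```python
from pdsubtype import (adjusted_rand_index, biofind_like_preset,
                       generate_cohort, joint_search)

cohort, truth = generate_cohort(
    biofind_like_preset(separation=2.0, seed=1, with_proteins=False))
result = joint_search(cohort, k_range=(2, 3, 4, 5, 6), n_trials=100, seed=1)

weights = {n: round(float(w), 3)
           for n, w in zip(result.best_fusion.view_names, result.best_fusion.weights)}
ari = adjusted_rand_index(truth.labels.to_numpy(), result.best.labels)
print(f"best cluster count: {result.best.k}")
print(f"silhouette: {result.best.silhouette:.3f}")
print(f"view weights: {weights}")
print(f"adjusted Rand index vs ground truth: {ari:.3f}")
```

prints

```
best cluster count: 3
silhouette: 0.363
view weights: {'motor': 0.816, 'non-motor': 0.184}
adjusted Rand index vs ground truth: 1.000
```

The search selects three subtypes; the motor view receives the dominant
fusion weight, meaning motor symptoms drive the fused patient similarity;
and an adjusted Rand index of 1.0 means the recovered labels match the
generator's ground truth exactly.  The scripts in `examples/` walk
through each capability (simulation, fusion/clustering, stability,
characterisation, motor phenotypes); a thin CLI (`pdsubtype simulate`,
`cluster`, `stability`, `sensitivity`, `characterize`) wraps the same
functions for shell use.

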