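# sglmri

Sparse group LASSO logistic regression for diagnosing a clinical
condition from atlas-grouped fMRI contrast features — with nested
cross-validated model selection, probabilistic discriminative scores,
and stability analysis of the selected brain areas.

## The problem

Classifying patients versus controls from task fMRI contrast maps is a
d ≫ n problem: tens of subjects, tens of thousands of voxels.  Penalized
logistic regression handles this and, unlike margin classifiers, yields
a probability for every diagnosis.  Plain L1 (LASSO) sparsity selects
isolated voxels, which is fragile when the precise location of
disease-related activity shifts between subjects.  Grouping voxels by
atlas brain area and penalizing the group norms selects whole areas
instead, which is both more robust to that spatial variability and more
interpretable anatomically.

The model, for features x ∈ ℝᵈ and label y ∈ {−1, +1}:

    P(y | x; w) = 1 / (1 + exp(−y xᵀw))

with weights minimizing

    J(w) = −(1/n) Σᵢ log P(yᵢ|xᵢ; w) + λ_S ‖w‖₁ + λ_G Σ_g ‖w_g‖₂

where groups g are atlas areas.  λ_G = 0 gives the standard LASSO
(sLASSO), λ_S = 0 the group LASSO (gLASSO), both positive the sparse
group LASSO (sgLASSO).  The solver is a from-scratch monotone FISTA
with the closed-form proximal operator of the combined penalty
(soft-threshold, then group shrinkage), so selected supports contain
exact zeros.  Penalties are chosen by nested stratified 10-fold
cross-validation maximizing the held-out mean log likelihood, and
selection stability is summarized over all cross-validated models.

Who this is for: researchers running MVPA-style group classification on
contrast maps (or any grouped, standardized feature matrix) who want
sparse, area-level, probabilistically calibrated classifiers with
honest nested-CV evaluation — plus a synthetic-data generator with
ground truth for validating the whole pipeline.

## Worked example

Generate a synthetic cohort (40 subjects, 864 voxels in 24 pseudo-atlas
areas, 3 areas truly active), clean it, and fit a group LASSO:

```python
from sglmri import (SyntheticSpec, generate, preprocess_pipeline,
                    SparseGroupLogit, PenaltyConfig)

spec = SyntheticSpec(seed=7)          # 12x12x6 grid, 24 areas, 20/class
ds = generate(spec)
fm, groups, report = preprocess_pipeline(ds.features)
model = SparseGroupLogit.from_feature_matrix(fm, groups)
res = model.fit(PenaltyConfig(lambda_s=0.0, lambda_g=0.25))
print(res.summary())
```

```
Sparse Group LASSO Logistic Regression Results
======================================================
Algorithm:            gLASSO
No. observations:     40
No. features:         864
No. groups:           24
lambda_S:             0
lambda_G:             0.25
Objective J(w):       0.42631273
Neg. mean loglik:     0.2430622
Selected features:    180
Selected groups:      5
Iterations:           91
Converged:            True
======================================================
```

The fit selects 5 of 24 areas; the ground-truth active areas 1–3 are
among them (`res.group_support` → groups 1, 2, 3, 8, 23 in 1-based area
labels).  Whole areas enter or leave together — that is the group
penalty working.  `res.predict_proba(x)` returns P(patient | x), and
`res.linear_score(x)` the log odds xᵀw.

Nested cross-validation and stability, at demo scale:

```python
from sglmri import lambda_grid, nested_cv, summarize, frequent_set

rep = nested_cv(fm.values, fm.labels, groups, lambda_grid("gLASSO", "demo"),
                n_repeats=5, k=10, seed=1)
print(rep.summary)                       # mean +/- SD over repeats
summ = summarize(rep.weight_matrix(), groups)
print(frequent_set(summ, 0.8, level="area"))   # areas selected in >80% of models
```

Cohort statistics from printed group summaries (31 controls vs 31
patients; semantic verbal-fluency successful trials, 29.19 ± 1.51 vs
27.81 ± 3.12):

```python
from sglmri import t_test_from_summary
from sglmri.cohort import STUDY_COHORT

ctrl, pat = STUDY_COHORT["semantic_successful_trials"]
t, df, p = t_test_from_summary(ctrl, pat, "pooled")
print(f"t={t:.3f}, df={df:.0f}, p={p:.4f}")
# t=2.217, df=60, p=0.0304
```

A command-line interface mirrors the stages
(`sglmri synth | preprocess | evaluate | stability | cohort | run`);
`sglmri run` executes the whole demo pipeline into an artifact
directory with full provenance (config hash, seeds, per-stage logs).

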