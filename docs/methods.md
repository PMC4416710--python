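# Methods

## The model

`sglmri` fits a penalized logistic regression to case/control contrast
features.  A subject is described by a feature vector *x* ∈ ℝᵈ of
voxel-wise Z-scores and a label *y* ∈ {−1, +1} (−1 control, +1 patient).
The model is

P(y | x; w) = 1 / (1 + exp(−y xᵀw)),

so the log odds log(P(+1|x)/P(−1|x)) equal xᵀw exactly.  The weights
minimize the penalized negative mean log-likelihood

J(w) = f(w) + λ_S‖w‖₁ + λ_G Σ_g ‖w_g‖₂,
f(w) = −(1/n) Σᵢ log P(yᵢ | xᵢ; w),

where the groups *g* partition the voxels into atlas brain areas.  The
three penalty regimes are the standard LASSO (λ_G = 0, voxel-wise
sparsity), the group LASSO (λ_S = 0, area-wise sparsity), and the sparse
group LASSO (both positive).  The scientific motivation for the group
penalty is robustness: disease-related activation differences occupy
contiguous brain areas, but their precise voxel location shifts between
subjects, so a classifier built on isolated voxels is fragile while one
built on whole areas is not.

Deliberate modeling choices:

- **No intercept by default**, matching the bare logistic form above;
  with class-balanced cohorts and voxel-wise standardized features an
  intercept is nearly redundant.  An unpenalized intercept is available
  behind a flag.
- **No group-size weighting.**  Each group enters the penalty with unit
  weight, not the √|g| factor common elsewhere in the group-LASSO
  literature; the objective is implemented exactly as written.
- **Tie rule.**  xᵀw = 0 classifies as −1 (healthy) — the conservative
  diagnosis for the boundary case the discriminant rule leaves open.

## The solver

Accelerated proximal gradient (FISTA) with:

- closed-form proximal operator of the combined penalty: element-wise
  soft-thresholding at t·λ_S followed by per-group shrinkage by
  max(1 − t·λ_G/‖u_g‖₂, 0), which produces exact zeros;
- step size 1/L with L = ‖X‖₂²/(4n) (the true Lipschitz bound of ∇f),
  plus a backtracking halving loop as a safety net for ill-scaled input;
- a monotone safeguard: if the accelerated step increases the objective,
  a plain proximal step from the best iterate is taken instead and the
  momentum is restarted, so the recorded objective trace is non-increasing
  by construction;
- convergence when the relative objective change or the relative weight
  change drops below `tol` (default 1e−8); non-convergence returns a
  result flagged `converged=False` rather than raising.

Support is reported at `zero_tol = 1e−8` on standardized features —
below solver tolerance, so numerical dust never counts as a selected
voxel.  Regularization paths are fitted warm-started from the strongest
penalty (where the exact-zero solution is known analytically: w = 0 is
optimal once λ_S ≥ ‖∇f(0)‖_∞ or λ_G ≥ max_g ‖∇f(0)_g‖₂) toward the
weakest.

The solver is verified against independent oracles in the test suite: a
generic L-BFGS-B minimization of the same objectives (with the L1 term
made smooth by a positive/negative split and the group norms by
ε-smoothing with continuation, accurate to ~1e−9), the KKT subgradient
conditions, and, for the pure-L1 special case, scikit-learn's liblinear
L1 logistic regression.

## Preprocessing

Starting from per-subject Z-score contrast volumes and an integer atlas:

1. **Assembly** — volumes are vectorized; only voxels with a nonzero
   atlas label become columns.  Voxel bookkeeping (atlas label, 0-based
   volume coordinate, task tag) survives every later filter, so any
   weight maps back to a volume coordinate.
2. **Outlier filter** — any column containing an entry with |Z| > 5 is
   dropped for all subjects.  Dropping the whole voxel (rather than the
   single entry) keeps the matrix rectangular; the removal is reported.
3. **Zero columns** — columns zero for every subject are dropped.
4. **Normalization** — each column is standardized to mean 0, SD 1 using
   the sample SD (n−1).  The default `"pooled"` mode uses all subjects,
   replicating the original design in which the full matrix is normalized
   before cross-validation; because that leaks test-set statistics, a
   `"train-only"` mode computes the statistics on a designated training
   subset and applies them to all rows.  Results should be labeled with
   the mode used.
5. **Groups** — one group per distinct (task, area) pair among surviving
   columns.  Concatenating two task matrices offsets the second task's
   group ids, so the same anatomical area measured in two tasks forms two
   groups (105 areas per task → 210 groups).

## Nested cross-validation

Penalties are selected by the mean log likelihood
μ_logL = (1/n) Σ log P(yᵢ|xᵢ; w), a probabilistic criterion that rewards
calibrated confidence rather than just correct signs.  The scheme:

1. Stratified 10-fold outer split (controls and patients dealt
   separately; per-class fold sizes differ by ≤ 1).
2. For each outer fold: a stratified 10-fold inner split of the outer
   training set; every grid penalty is fitted on each inner training set
   (warm-started along the grid) and scored on the inner test folds.
3. μ_logL per grid point is computed by pooling all inner-test subjects
   (equivalent to the defining formula over the union, and robust to
   unequal fold sizes; fold-averaging would weight subjects unevenly).
4. The penalty maximizing μ_logL is selected — ties broken toward the
   sparser model (larger λ_S, then larger λ_G) and flagged; grid points
   that fail to converge on any inner fold are excluded with a warning.
5. The model is refitted on the full outer training set and the outer
   test fold is scored.  Every subject is scored exactly once per
   repeat; inner folds never see outer test subjects (each fold record
   carries its index sets so this is asserted, not assumed).
6. The whole procedure is repeated with reshuffled folds (100 repeats at
   full scale); metrics are pooled per repeat into a single confusion
   matrix and reported as mean ± SD over repeats.

Reported criteria: sensitivity, specificity, accuracy, precision,
recall, and Fscore = TP/(TP + (FN+FP)/2); rates with zero denominators
are reported as undefined (NaN), not zero.  Because "likelihood" is
ambiguous as a summary, both exp(μ_logL) and the arithmetic mean of
P(yᵢ|xᵢ) are emitted, labeled explicitly.  Probabilities are clipped at
1e−12 before logs so separable fits cannot produce −∞.

**Discriminative scores.**  For visualization and confidence assessment,
each test subject's log odds xᵀw is divided by the maximum |xᵀw| over
all pooled test predictions of the run, giving scores in [−1, 1] whose
sign is the predicted label and whose magnitude is attained at least
once.

**Grids.**  The shipped `"full"` preset uses 200 log-spaced λ_S in
[0.01, 0.2512] (sLASSO), 100 log-spaced λ_G in [0.1, 0.6310] (gLASSO),
and all 200 combinations of 20 λ_S in [1e−6, 0.1] × 10 λ_G in
[0.0631, 0.3162] (sgLASSO).  The `"demo"` preset keeps the same ranges
with 20 / 20 / 10×2 points for desk-scale runs.

## Stability analysis

A nested-CV run yields many models (1000 at full scale).  A voxel is
selected in a model iff |w_j| > zero_tol; an area iff any member voxel
is.  The summary reports per-voxel and per-area selection counts and
frequencies, the per-model support size (mean ± SD), the union of
ever-selected voxels/areas, and the ">80 % occurrence" set (strict
inequality: frequency exactly 0.8 is excluded).  Per-area positive
(negative) weight summaries pool all positive (negative) selected
voxel-weights across models within the area — pooling order is a free
choice, and pooled-then-averaged was chosen and is stated here — then
normalize by the largest such mean across areas, giving values in
[−1, 1].  Because a group penalty can select an area through positive
voxels in some models and negative ones in others, sign-specific area
frequencies are also emitted.  Non-converged fits are excluded from the
tallies and counted separately; frequencies use the number of models
actually tallied as denominator.  Mean weight maps of frequently
selected voxels can be written back into volume space through the voxel
bookkeeping.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
at a scale chosen by the user:

- a toy 3-D volume partitioned into cuboid pseudo-atlas areas (axes are
  split into near-equal slabs of a factorization of the area count
  chosen to make blocks as cubic as possible);
- patients add `effect_size` to all voxels of the designated active
  areas; the active pattern of each patient is translated by an integer
  jitter drawn uniformly from [−jitter_max, +jitter_max]³ as a circular
  shift — circular so the active voxel count is constant and no mask is
  truncated at the volume edge — emulating inter-subject variability in
  functional localization;
- all subjects receive a spatially smooth noise field: white Gaussian
  noise filtered with a 3-D Gaussian kernel (σ = `smooth_sigma` voxels)
  and rescaled to marginal SD `noise_sd`;
- a fraction `outlier_rate` of matrix entries is replaced by values of
  magnitude drawn uniformly from [5.5, 8] with random sign — safely
  above the |Z| > 5 preprocessing threshold, which only defines the
  filter boundary, so the outlier distribution itself is a generator
  choice;
- a two-task "combined" mode generates two independent datasets with
  shared labels and concatenates them.

Everything is bit-reproducible given the seed, and the ground-truth
support (voxels and areas) is returned for recovery scoring.

What the generator does **not** emulate: haemodynamics or time series
(only contrast-map level data), realistic anatomical geometry, spatially
varying noise, correlated physiological confounds, site or scanner
effects, or label noise.  Tests passing on this generator therefore show
that the machinery is correct and that the group penalty behaves as
designed under the stated structure — not that any particular accuracy
level transfers to real cohorts.

### Default study conditions

The generator defaults define the reduced-scale conditions used
throughout the tests and the acceptance script, chosen once as a
realistic desk-scale miniature of a 62-subject, ~14k-voxel, 105-area
study:

| parameter | default | rationale |
|---|---|---|
| grid_shape | 12×12×6 (864 voxels) | ~16× fewer voxels than the study, same d ≫ n regime |
| n_areas | 24 | ~36 voxels/area, matching the study's ~134 voxels/area in spirit |
| n_per_class | 20 | slightly below the study's 31/class; keeps nested CV fast |
| active_areas | (1, 2, 3) | a small minority of areas carry signal |
| effect_size | 1.5 | moderate per-voxel effect (Cohen's d = 1.5 before smoothing-induced correlation) |
| smooth_sigma | 1.0 voxel | smooth maps, as after standard 8 mm smoothing at 4 mm voxels |
| jitter_max | 1 voxel | small inter-subject shift of functional loci |
| noise_sd | 1.0 | unit-variance Z-score noise |
| outlier_rate | 0.0 | outliers enabled explicitly where the filter is under test |

The group-recovery experiment uses a flatter design (10×10×4 grid, 20
areas of 20 voxels, 100 subjects per class, no smoothing or jitter) so
that exact support recovery is a well-posed target.

## Cohort statistics

Group comparisons from printed summaries: a two-sample t-test computed
from (n, mean, SD) pairs — pooled-variance by default, since it
reproduces the published semantic-task p-values from the published
summaries; Welch with Satterthwaite df reported alongside — and a
Pearson chi-square (optionally Yates-corrected) for 2×2 tables.  Both
variants are always reported side by side; no ordering between them is
assumed.  Recomputation from rounded summaries carries an uncertainty of
roughly one unit in the last printed digit of p, which is the tolerance
used when comparing to published values.

## Numerical choices, degenerate inputs

- Zero-variance columns are dropped (with a logged warning) rather than
  producing NaNs at normalization.
- An unpenalized fit with d > n is allowed for diagnostics but warns.
- Empty data, label mismatches, non-finite features, shape mismatches,
  and negative counts raise immediately with specific messages.
- `make_folds` refuses k larger than the smaller class and says to use a
  smaller k.
- All randomness flows through `numpy.random.default_rng` seeded from a
  single master seed per run; repeats derive child seeds from the master
  stream, so any subset of the computation is reproducible.

## Known limitations

- The FISTA solver is dense and single-threaded; it is sized for
  desk-scale matrices (tens of subjects × tens of thousands of voxels),
  not whole-brain voxel-wise time series.
- "Pooled"-mode normalization leaks test statistics by design (it
  replicates the original study's pipeline); use "train-only" mode when
  unbiased generalization estimates matter.
- The sign-specific area-occurrence rule is one reasonable reading of
  per-area weight bookkeeping; alternatives (per-model-then-average)
  would differ in the third decimal on typical ensembles.
- Welch and pooled t-tests are both offered, but with equal group sizes
  they almost coincide; nothing here addresses unequal-variance designs
  beyond that.
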