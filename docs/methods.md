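# Methods

`osteomap` implements a complete fracture-prediction analysis chain for
postmenopausal osteoporosis studies — synthetic cohort generation, a
DXA-style finite-element Bone Strain Index (BSI), complement scaling,
evolutionary split/variable selection, feed-forward classification with
cross-testing, and an Auto-Contractive-Map semantic connectivity map.
This note records the models, the defaults and why, and what the synthetic
data does and does not establish.

## Synthetic cohort generator

The reference population is 174 postmenopausal women (69 with an incident
vertebral fracture at follow-up, 105 without) described by 13 baseline
variables: menopause age, weight, age, BMI, and BMC / BMD / BSI at the
lumbar spine, femoral neck and total femur.  Only per-group means and SDs
and whole-population ranges are available, so the generator draws each
group from a **Gaussian copula with truncated-normal marginals whose parent
(μ, σ) are solved numerically so that the truncated distribution has
exactly the target group mean and SD** inside the published range.  This
matters: for several variables the published range bound sits within two
SDs of a group mean (fractured total-femur BSI: mean 1.751, SD 0.482, lower
bound 0.992), and naive truncate-after-drawing would bias the group mean by
roughly 2–3 standard errors at n = 10,000, which the calibration tests
would detect.  A zero-SD spec short-circuits to a constant column; a mean
outside its range is rejected at construction.

No covariances are published.  The default correlation matrix is built from
a low-rank factor model (hence positive semi-definite by construction):
a body-size factor (weight, BMI, BMC), a global bone-mass factor loading
positively on BMC/BMD and negatively on BSI, and one factor per skeletal
site giving within-site |r| ≈ 0.6 with BSI opposing BMD — a weaker bone
strains more under the same load, and the published variable/outcome
correlation panel shows BSI and mass indices loading in opposite
directions.  The matrix is an argument, not a constant; any symmetric PSD
unit-diagonal matrix is accepted.

Follow-up duration is log-normal matched to the published mean 3.34 and SD
1.91 years.  The published median (2.72) cannot simultaneously hold for any
log-normal (the mean/SD fit implies median 2.90); mean and SD were
preferred since the schema only carries the column for fidelity — nothing
downstream consumes it.

`assign_outcomes` is the second generation mode: a logistic model on
per-variable z-scores with the intercept calibrated by root finding so the
expected fracture fraction equals the requested prevalence.  It exists to
*plant* known structure (e.g. β = +5 on total-femur BSI makes high femoral
strain drive fracture) for the recovery experiments; the default two-group
mode reproduces the published group tables instead.

## Density phantoms and the FEM

Phantoms are parametric rasters of areal density (g/cm², 0.1 cm pixels):
a rectangular vertebral body (4.0 × 3.6 cm) and a simplified proximal femur
silhouette (vertical shaft, 45° neck capsule, circular head).  Density is
uniform at the target BMD plus optional smooth lateral modulation and pixel
noise, then re-centred so the mask-mean BMD is exact.

The BSI is the element-area-weighted mean von Mises equivalent strain over
the ROI from a **plane-stress, unit-thickness, constant-strain-triangle
linear-elastic solve**, times a scale constant.  Choices:

- *Meshing*: every in-mask pixel (or refinement² sub-pixel) splits into two
  triangles along its NW–SE diagonal (deterministic tie-break); element
  density is the owner pixel's.  Masks must be non-empty and 4-connected.
- *Material*: areal density converts to apparent density through an
  effective projection thickness (3.0 cm vertebra, 3.5 cm femur — the
  projection geometry is not recoverable from a DXA image, so these are
  declared surrogates), then to a modulus through the site-specific power
  law E = a·ρ^b (vertebra a = 4730 MPa, b = 1.56; femur a = 6850 MPa,
  b = 1.49; all configurable).  Non-positive densities floor at a small
  configurable modulus with a warning.  Poisson ratio 0.3 uniform.
- *Vertebral load case*: a standing trunk load of 0.6 × body weight × g
  (the published load regression is proprietary; the fraction is a
  configurable surrogate) applied as uniform downward traction on the
  superior endplate.  The inferior endplate rests on **frictionless
  rollers** (vertical support, one node pinned laterally) by default rather
  than full clamping: a clamped endplate adds corner singularities and a
  Poisson-constrained boundary layer that perturb the ROI-mean strain by a
  few percent and destroy the exact column-compression reference solution
  used for verification; rollers make the uniform phantom an exact
  uniaxial state at any refinement.  `vertebra_constraint="fixed"` restores
  clamping.
- *Femoral sideways fall*: head band and distal shaft section fully fixed,
  a horizontal medially-directed load of one body weight distributed over
  the greater trochanteric arc.
- *Equivalent strain*: von Mises strain with the out-of-plane component
  recovered from plane stress, ε_z = −ν(ε_x+ε_y)/(1−ν); verified against
  an independent principal-strain oracle and under coordinate rotation.
- *Scale*: default 1.0 (raw strain).  `calibrate_scale` fixes the free
  constant so a noise-free calibration phantom at the population-mean BMD
  yields the population-mean BSI of its site (lumbar 2.298, total femur
  1.638); absolute BSI units are not derivable from published material.
- *Solver*: sparse assembly, direct solve, equilibrium residual required
  < 1e-8 relative; under-constrained systems raise a diagnostic rather
  than returning garbage.

Verification: patch test (uniform tension reproduces the closed-form strain
to 1e-8), global force balance to 1e-8, < 1% ROI-mean change between
successive refinements, strict load linearity, and rank correlation −1
between BSI and BMD over a density sweep at fixed geometry.

## Preprocessing

Min–max scaling is exact linear rescaling with clipping (plus warning) for
out-of-range values under stored bounds — new records in a longitudinal
deployment should degrade gracefully, not crash.  The complement expansion
doubles k variables into `_high`/`_low` pairs with `high + low = 1` per
cell; a constant column or an already-expanded table is rejected.  The
complement form feeds the semantic map only; the classifiers consume the
selected variables min–max scaled, which keeps the two representations in
their separate roles.  Group comparisons use Welch's unequal-variance
t-test (the safer default when group SDs differ, as they visibly do here);
correlations are plain Pearson.

## TWIST-style selection

A genetic algorithm over the concatenated bit-string (record A/B
assignment, then variable mask) maximizes the mean accuracy of a probe
classifier trained A→B and B→A on the masked variables.  Degenerate
candidates (empty half, a half missing an outcome class, class-prevalence
gap > 0.1) score zero.  Defaults: population 24, 15 generations, uniform
crossover at 0.9, per-bit mutation 1/length, tournament of 3, elitism 1,
fitness ties broken toward fewer variables then lexicographic mask order
(parsimony, determinism).  The probe is a reduced feed-forward network
(4 hidden units, 60 epochs, fixed seed so a candidate's fitness is
reproducible); a nearest-class-centroid probe is available where speed
matters more than fidelity.  Population and generation counts are sized
for cohorts of a few hundred records — the planted-signal experiments show
they are sufficient to recover two informative variables out of eight at
n = 400 in ≥ 9/10 seeds.

## Classifier and protocols

One hidden layer of logistic units (width = number of inputs), 2-class
output, Adam at learning rate 0.01 for 500 epochs, early stopping off,
deterministic per seed — a deliberately plain architecture, since nothing
about the network itself is the object of study.  Metrics: sensitivity,
specificity and overall accuracy in percent from the 0.5-threshold
confusion matrix; AUC as the rank (Mann–Whitney) statistic with ties
halved, verified against the explicit positive–negative pair count.
A-B/B-A pooling is the **unweighted arithmetic mean** of arm metrics with
counts summed — this reproduces the published summary row for sensitivity,
specificity and accuracy exactly at printed precision.  (The published
pooled AUC of 0.824 matches neither the unweighted mean of the printed
arm AUCs, 0.8135, nor their record-weighted mean, ≈ 0.809; the package
reports the unweighted mean for AUC as well, consistent with the other
columns.)  The tripartite protocol trains the validation model on the
union of the two cross-testing subsets and scores a third subset that the
model never saw; overlapping subsets are rejected.

## Auto-Contractive Map and the semantic map

The Auto-CM recursion implemented here (signal contraction
`h = x(1 − v/C)`, `Net_i = Σ_j h_j (1 − w_ij/C)`, `o = h(1 − Net/C)`;
updates by the contracted residuals) has these properties, each asserted in
tests: weights start at a fixed small constant (no random initialization)
and training is full-batch per epoch, so the result is deterministic and
record-order invariant; the update form keeps every weight strictly below
C (default: the number of columns); the mono-dedicated weights v rise
monotonically to C, squeezing the transmitted signal to zero, which defines
convergence (mean output activation < 1e-6, epoch cap 1000).  The trained
hidden→output matrix integrates column co-activation: duplicate columns
attain the maximal pairwise weight, an r = 0.9 pair outranks an independent
column, an all-zero column never grows a connection.

Distances are `d_ij = 1 − w̄_ij / max(w̄)` on the symmetrized matrix, so
the strongest association sits at distance zero and weight ordering is
exactly inverted.  The semantic connectivity map is the Kruskal minimum
spanning tree of the complete distance graph (stable edge ordering for
deterministic ties), validated against exhaustive enumeration of all 125
labelled 5-node spanning trees via Prüfer sequences, and invariant under
monotone distance transforms.  Edge strengths are reported as
`w̄_ij / max(w̄)` in [0, 1].  The outcome enters as the complementary
indicator pair `new_fracture_yes` / `new_fracture_no`, so the map can place
the *absence* of fracture next to the variables that accompany it — in
planted cohorts where low total-femur BSI drives non-fracture, the map
recovers `Ftot_BSI_low — new_fracture_no` adjacency in ≥ 8/10 seeds, and
the same adjacency emerges in default end-to-end runs.

## Pipeline

Stages persist their outputs (CSV/JSON/GraphML, never binary) in the run
directory and consume only persisted predecessor files, so each CLI
subcommand re-runs in isolation.  One global seed expands to per-stage
seeds by `(seed · 1000003 + counter) mod 2³¹`, logged in the report; the
report carries a config hash and no timestamps, making reruns
byte-identical.  When the FEM stage is enabled it rebuilds per-patient
lumbar and total-femur BSI from phantoms at the patient's BMD (refinement 1
per patient for tractable runtimes; note this makes the FEM BSI a noisy
monotone function of BMD rather than independent information — the
generated BSI columns, which carry the published group structure, remain
available by disabling the stage).  Neck BSI has no dedicated load case
and passes through.

## What the synthetic data does not show

The generator reproduces published group moments, ranges and a plausible
correlation structure — not the joint distribution of a real clinical
cohort, its measurement error, scanner differences, or longitudinal
dynamics (no BMD change between baseline and follow-up is simulated; only
baseline predictors enter the prediction task).  Consequently the
classifier's pooled accuracy on synthetic cohorts (typically in the
65–90 % band across seeds) is a sanity corridor, not a reproduction of the
published real-data 79.56 %; likewise the exact published 9-variable
selection and the full published map topology are properties of the
unavailable data and are not claimed.  What the tests do establish is that
each stage satisfies its mathematical contract and that planted structure
of published-like effect size is recovered reliably.

## Problem sizes used by the test suite

Moment calibration uses 10,000 draws per group; Auto-CM oracles use
n = 500–2,000 with 3–28 columns; TWIST recovery uses n = 400 with 8
variables over 10 seeds; FEM verification uses 8×8 patch plates and
40×36-pixel phantoms at refinements 1–3; end-to-end pipeline tests use a
40-record cohort with reduced GA/epoch settings, with the full 174-record
default exercised by the CLI example in the README.
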