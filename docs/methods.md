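# Methods

## Feature model

The unit of analysis is a labelled segmentation volume: a 3D integer
grid plus a 4x4 affine mapping voxel indices (0-based, voxel centres)
to RAS millimetres. Structure membership follows the FreeSurfer aseg
label convention; the registry pools merged codes (bilateral thalamus
10+49, each cerebellar hemisphere's white matter and cortex) into one
voxel cloud. A structure's volume is its voxel count times the voxel
volume (|det| of the affine's 3x3 block); its centroid is the
unweighted mean of the voxel-centre RAS coordinates. Voxel counting is
the canonical volume source; volumes parsed from `aseg.stats` files are
accepted as an alternative and agree with counting exactly on 1 mm
synthetic fixtures.

Per subject, each of the 18 non-reference structures contributes a
thalamus-normalised volume, a Euclidean centroid distance to the
thalamus (mm), and a cosine distance between the two centroids taken as
position vectors. With the raw thalamus volume, sex (M=0/F=1) and age,
the cohort table has 57 feature columns in a fixed deterministic order
(`Thalamus_vol`, then `<Structure>_normvol/_euclid/_cosine` in registry
order, then `Sex`, `Age`).

Two choices here are genuinely open and are worth stating:

- **Cosine origin.** The cosine distance of two position vectors depends
  on the coordinate origin. We evaluate it from the native RAS origin —
  the only reading consistent with applying the two-vector formula to a
  pair of centroids — and expose the origin as a parameter. Translating
  a volume therefore changes the cosine features while leaving volumes
  and Euclidean distances untouched; this is asserted as a property in
  the test suite rather than hidden.
- **Distance normalisation.** Euclidean distances are reported raw in
  mm. An optional rescaling by the cube root of the thalamus volume is
  available behind a flag (default off) for users who want head-size
  control on the distance channel as well.

Numerical details: the cosine similarity is clamped to [-1, 1] before
subtraction and results within 1e-12 of the bounds are snapped to
exactly 0 or 2, so the analytic identities (distance of a vector to
itself, and to its negation) hold exactly in floating point. The
Minkowski implementation requires order p >= 1 and reduces to the
Euclidean distance at p = 2 to 1e-12.

## Quality control

A subject is excluded when any expected artifact is missing, empty
(zero bytes, a stats table without rows, or a label volume with no
foreground voxels), or lacks one of the registry's label codes. QC is a
pure, order-preserving filter over the manifest; unknown label codes in
a volume are ignored with a warning rather than treated as errors.

## Group statistics

Descriptives use the sample (n-1) standard deviation. The global test
per feature is the classical one-way fixed-effects ANOVA; post-hoc
pairwise contrasts (HC/PD, HC/PR, PD/PR) use Welch's t-test with
Welch-Satterthwaite degrees of freedom, two-sided, and are reported
regardless of the ANOVA outcome. Sex is compared with Pearson's
chi-squared test without continuity correction. Degenerate inputs
follow explicit conventions: identical samples give t=0, p=1; two
zero-variance samples with different means give an infinite statistic
with p=0 and a logged warning; an all-constant ANOVA with equal means
returns F=0.

Multiplicity is handled with Benjamini-Hochberg step-up adjustment.
The adjustment family is **all p-values within one category table**
(ANOVA and the three pairwise columns jointly; in the demographics
table the sex chi-squared joins the family). The family boundary is a
design choice — per-column or global families are equally defensible —
and it is applied consistently and tested against a brute-force
step-up implementation. Significance is declared at adjusted p <= 0.05.

## Classification workflow

Each binary task (HC/PD, HC/PR, PD/PR) proceeds as: random-forest
feature voting, a stratified split with 30% held out for testing, an
exhaustive grid search with stratified 5-fold cross-validation
(accuracy objective, ties broken by first-in-grid order) for logistic
regression, random forest and an RBF SVC, and held-out evaluation.
Feature voting keeps features whose impurity importance is at least the
mean importance (a top-k policy is available); the voting forest has
200 trees and a fixed seed. Logistic regression and the SVC sit behind
a standardising pipeline because the feature table mixes millimetre
distances with unit-scale ratios; random forests are scale-invariant
and stay raw. Default grids are LR C in {0.1, 1.0} (max_iter 100), RF
trees {50, 75, 100} x depth {3, 5} x min-leaf {2, 3, 4} x min-split
{2, 4}, and SVC C {0.1, 1, 10} x gamma {0.01, 0.1, scale}.

Evaluation reports confusion counts, accuracy, support-weighted
precision/recall/F1 (weighted averaging reproduces the canonical
worked example: a 17-per-class test set with 3+2 misclassifications
gives 0.85 accuracy and ~0.854 weighted precision), and the ROC/AUC of
the positive-class probability.

By default the feature vote is taken on the **full two-group
sub-cohort before splitting**, mirroring the replicated workflow; this
lets held-out rows influence selection and optimistically biases test
accuracy. A leakage-free variant (`select_on="train"`) restricts the
vote to the training partition and is what the null-calibration test
uses, since only it should be calibrated at 50% under the null.

The original study selected 11, 16 and 17 features for the three
tasks; selection counts here depend on the cohort and the policy, which
is why the policy is configurable and the full ranking is returned
alongside the selection.

### Ensemble

The three best binary models are aggregated per subject: each class
receives the sum of the probabilities assigned to it by the two binary
models in which it participates; scores are normalised to sum to one
and the argmax is the prediction. The confidence tier derives from the
margin between the two largest normalised scores: high >= 0.5,
moderate >= 0.25, low >= 0.1, else extremely low (cutoffs are package
choices, configurable in spirit — the tier names are standard, their
numeric boundaries are not externally defined). An exact tie falls back
to the fixed class order (CONTROL, PRODROMAL, PARKINSON) with the tier
forced to extremely low. Because the maximum attainable normalised
score is 2/3, the high tier is reached only when both models containing
the winning class are essentially certain and the third is
uninformative. The ensemble is evaluated on the same cohort its parts
were trained on unless the caller supplies held-out subjects; it has no
independent external validation, which is a stated limitation.

## Rough-set classifier

Discretisation places candidate cuts at midpoints between adjacent
distinct attribute values whose neighbourhoods span more than one
class, then greedily selects the cut discerning the most not-yet
discerned class-different object pairs until all discernible pairs are
split or a per-attribute budget is exhausted. Pairs identical on every
attribute are inherently inconsistent and reported as such. Rule
induction is sequential covering: seeded on an uncovered object of the
target class, a conjunction of single-bin interval conditions is grown
greedily (maximising accuracy, then positive coverage) until pure or
no condition improves; support and accuracy are recorded against the
full training table and covered target objects are removed.
Classification lets matching rules vote with weight support x accuracy;
no match or an exact tie is an abstention, counted against coverage.
With an unlimited cut budget on consistent data, training accuracy and
coverage reach 1.0. The design goal is the simplest faithful
Pawlak-style pipeline able to test whether threshold rules approach
logistic-regression accuracy — not bit-for-bit replication of any
specific rule-induction software (whose genetic-reduct and LEM-style
algorithms are materially different).

## Synthetic cohorts

The generator defines the study conditions the analysis is tested
under. The template places all 19 structures as ellipsoids (axis ratio
0.9 : 1.2 : 0.9) at atlas-plausible RAS offsets around a midline
origin, with volumes chosen so the ratios and distances that matter
land in realistic ranges: bilateral thalamus 12 000 mm^3, left amygdala
1350 mm^3 (normalised volume ~0.11), thalamus-hippocampus distance
~33 mm, thalamus-cerebellum ~54 mm. Inter-subject variability:
volumes are log-normal with cv = 0.08 (mean-exact), centroids are
jittered isotropically with sd = 0.6 mm. Demographics: age ~
Normal(62, 11) truncated to [40, 90]; female proportions 0.321 / 0.250
/ 0.429 for HC / PR / PD; optional motor scores with group means 0.79 /
4.86 / 23.89.

Default group effects encode the qualitative progression pattern the
battery should recover: volume scale 0.88 on the left amygdala, left
putamen and left accumbens in both PR and PD; additional 0.88 scales on
the left caudate and left ventral diencephalon in PD only; and small
centroid shifts of the left hippocampus (toward the thalamus) and right
pallidum (away) in both affected groups. With cv = 0.08 these
correspond to standardised effects around 1.1-1.4 — strong enough for
the prescribed recovery rate at n = 56 per group; the real-data effect
sizes are not recoverable from printed statistics alone, so these are
declared plausibility choices, not measured values. Volume scales apply
as scale^(1/3) per ellipsoid axis, so the expectation is exact.

Phantom mode rasterises each ellipsoid (voxel-centre-inside test) into
an auto-fitted grid; later structures must not overwrite earlier ones —
any voxel collision is an error, as is a structure extending beyond the
grid. Measured phantom volumes agree with ground truth within ~3%
(voxelisation) and centroids within half a voxel. Fast mode skips
rasterisation and computes the features analytically from the sampled
true anatomy (~8 ms per 168-subject cohort), which is what makes
thousand-replicate calibration studies affordable; it also supports
column-level standardised effects for power studies. `template_scale`
shrinks positions, radii, jitter and shifts uniformly for reduced-grid
runs. All randomness flows from one seed; identical seeds give
byte-identical cohorts, and with no effects the group labels are
exchangeable by construction.

What the generator does **not** emulate: realistic structure shapes or
cortical anatomy, MRI intensities, segmentation error, scanner/site
effects, or correlations between structures beyond those induced by
thalamus normalisation. Passing tests therefore demonstrate that the
pipeline recovers known effects under its own assumptions — not that
the real-data effect sizes or accuracies would be reproduced.

## Problem sizes in the test suite

The suite favours fast modes and reduced grids as its own design:
null-test calibration uses 2500 fast-mode replicates (rejection rates
checked against the (0.04, 0.06) band at alpha = 0.05), effect
recovery uses 100 replicates at full cohort size, oracle-equivalence
scans 21 reduced-scale phantoms with a pure-Python voxel loop, and the
classification experiments run once per session on a full 168-subject
cohort. The full run takes a few minutes on one CPU.

## Known limitations

- The cosine metric's origin dependence means harmonising the coordinate
  frame across subjects matters more for it than for any other feature.
- The replicated selection-before-split workflow leaks held-out
  information into feature selection (quantified by the calibration
  test of the leakage-free variant).
- The ensemble's three binary models share training subjects, so their
  probabilities are not independent and its accuracy on the training
  cohort is optimistic.
- Ellipsoid phantoms cannot probe segmentation-driven failure modes;
  results on real segmentations depend on upstream reconstruction
  quality, which QC only coarsely screens.
- Age is a candidate feature everywhere and no covariate adjustment is
  performed in the statistics.
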