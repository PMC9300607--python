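# Methods

## The morphological model

A lymph node is idealized as a solid ellipsoid with full principal
diameters *a ≤ b ≤ c* in mm. Two scalar descriptors summarize how far
it departs from a sphere:

- planar ratio `ratio_2d = a/c`, what a reader measures on a single
  slice;
- `sphericity = 2·∛(abc/8)/c = ∛(abc)/c`, the diameter of the
  equal-volume sphere over the longest diameter. The divisor 8 = 2³
  converts diameters to semi-axes inside the cube root.

Both are dimensionless, scale-invariant, and lie in (0, 1]. Since
a ≤ b ≤ c, `sphericity³ = (a/c)(b/c) ≥ (a/c)²`, giving the ordering
`(a/c) ≤ (a/c)^{2/3} ≤ sphericity ≤ (b/c)^{2/3} ≤ 1` with equalities
iff a = b = c. Metastatic infiltration rounds nodes, so both scores
rise with suspicion and classification uses the "score ≥ cutoff ⇒
metastatic" direction. Auto-orientation (flip when AUC < 0.5) exists
behind a flag and logs loudly, because a flipped score usually means an
upstream data error rather than a genuine inverted marker.

Axis triples are canonicalized (sorted ascending) on ingestion rather
than trusting column order; the formulas presume c is the longest
diameter and sorting makes them total. Diameters below 0.1 mm are
rejected as segmentation artifacts.

### Axis estimation from masks

For a solid uniform ellipsoid the coordinate variance along a principal
axis with semi-axis r is r²/5. `estimate_axes` therefore computes the
population covariance of the object's voxel centers in mm,
eigen-decomposes it, and returns diameters 2·√(5λ) sorted ascending —
exact for ellipsoids, rotation-invariant, and preferable to bounding
boxes or Feret diameters, which are not rotation-stable on coarse
grids. Objects under 50 voxels get a degraded-precision warning; the
discretization bias is O(h²) in the variance and negligible at the
0.25–0.5 mm spacings used in the tests. Whether a manual reader's
"longest diameter" is a principal-axis length or the longest in-plane
chord is ambiguous in general; the principal-axis convention is adopted
throughout and is self-consistent between the generator and the
estimator.

## Classifiers

**Youden threshold.** Candidate cutoffs are midpoints between
consecutive distinct scores; the cutoff maximizing
J = sensitivity + specificity − 1 is kept, ties resolved toward the
smaller cutoff (more sensitive, the conservative choice for a triage
test). A single distinct score yields J = 0 and a non-informative flag.

**Decision tree.** CART with Gini impurity, binary splits at midpoints
of consecutive distinct feature values, defaults max_depth = 4 and
min_leaf = 5 — on ~137 training nodes deeper trees with smaller leaves
memorize noise. Split ties resolve to the lower feature index (a, b, c
order) then the smaller threshold; leaf ties predict non-metastatic.
The defaults are tunable via `TreeParams`.

**Random forest.** 100 trees (the study's operating point, where its
error curve flattened), bootstrap resamples of size n, 2 of the 3
features sampled per split (⌈√3⌉), unrestricted depth with min_leaf = 1
as is conventional for bagged trees. Tree k draws its bootstrap and
split features from the stream seeded by (seed, k), so growing the
ensemble never reshuffles earlier trees. Out-of-bag error is the
majority-vote error over trees not containing each sample (ties to
non-metastatic, samples with no OOB vote excluded with a warning).
Importances are per-tree-normalized mean decreases in Gini impurity,
averaged over trees. Vote ties (possible with even n_trees) predict
non-metastatic; every tie rule in the package lands on the
"needs pathological confirmation" class so behaviour is deterministic
and documented rather than platform-dependent.

The tree and forest are implemented in-package because their exact
tie-break, seeding and serialization semantics are part of the
pipeline's contract; scikit-learn's CART is used in the test suite as
an independent cross-check of training accuracy.

## Patient-level logic

Pathology assigns patient truth by the whole-axilla rule: metastatic
iff any node is metastatic. Model calls aggregate the same way
(any-positive), keeping node- and patient-level analyses commensurable
and monotone — adding a positive node can never negate a positive
patient. Combination with an imaging read defaults to OR, which
provably never lowers sensitivity nor raises specificity relative to
either constituent (AND is the mirror image and remains available; the
mode is recorded in the output for provenance). OR is the default
because a combined method whose sensitivity exceeds both constituents —
the regime of interest for a rule-out test — is only achievable that
way. Patients missing a modality are excluded from that modality's
comparisons, with counts logged.

## Evaluation

Sensitivity tp/(tp+fn), specificity tn/(tn+fp), accuracy (tp+tn)/N —
called the correct classification rate (CCR) at patient level; each
metric's unit (node or patient) travels in the output so rates at
different units are never pooled. A rate whose denominator is empty is
flagged `None`, never silently NaN. ROC curves and trapezoid AUC come
from scikit-learn; the test suite verifies the AUC against an
exhaustive pairwise-concordance oracle (ties counted ½) on datasets up
to 200 nodes.

Method comparison uses the four-fold Pearson χ² on the 2×2 table of
correct/incorrect counts, χ² = N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)), df = 1,
**without** Yates continuity correction by default: on the comparison
tables implied by the validation counts the uncorrected p-values
(≈0.034, ≈0.015) reproduce the study's printed ones (0.031, 0.014)
while the corrected ones do not; the correction sits behind a flag.
P-values are reported to 3 decimals and no multiple-testing adjustment
is applied.

## The synthetic cohort generator

The generator emulates the study conditions rather than any particular
dataset: 43 patients, 1–10 nodes per patient (uniform), marginal node
metastasis prevalence 37/137 ≈ 0.27, patient truth by the any-node
rule, an ~11/43 post-NAC subgroup flag, and per-patient ultrasound/CT
reads drawn independently at configured sensitivity/specificity
(defaults: ultrasound 0.25/0.727 — the operating point implied by the
strict "metastatic call only" reading of the study's ultrasound
categories; CT 0.45/0.58, chosen to reproduce its ~49% patient-level
CCR on a 31/12 split). Only the binary read is modelled; the
dichotomization of graded ultrasound impressions happens upstream of
this package.

**Shapes.** Per node the generator draws the target sphericity s from
the class law (truncated normal on (0, 1]), the longest diameter c from
the class size law (normal, floored at 1 mm), b uniformly on
[s^{3/2}c, c] (the interval keeping a ≤ b), and solves a = s³c²/b, so
the realized sphericity is exactly s. Resampling is capped at 1,000
tries before a configuration error, keeping runtime bounded. Defaults —
non-metastatic sphericity 0.60 ± 0.08 and size 10 ± 3 mm, metastatic
0.85 ± 0.08 and 14 ± 4 mm — are placeholders in the clinically
plausible range (node diameters ~5–30 mm; a +0.25 sphericity shift for
metastatic nodes): no empirical (a, b, c) distribution is published.

**Within-patient clustering.** A patient is metastasis-prone with
probability prevalence/burden and each node of a prone patient is
metastatic independently with probability burden = 0.8; others are all
negative. The marginal node prevalence equals the configured value
exactly, while involvement clusters within patients as it does
clinically. The clustering also makes fully-involved axillae (all nodes
metastatic) occur at a realistic rate — about 5 per 43-patient cohort —
which matters because the training selector (below) needs them; with
fully independent node labels they would be rare accidents of small
node counts.

**NAC.** The post-NAC flag only labels a reporting subgroup; no shape
drift is simulated by default since no post-NAC shape distribution is
available, but an optional mean-shift parameter (`nac_sphericity_shift`)
can degrade the NAC subgroup's separation.

**Masks.** Each node can be voxelized as a rotated solid ellipsoid
(voxel centers inside the surface), one mask per node; spacings larger
than the smallest diameter are refused as undersampled. Voxel volume
converges to πabc/6 as spacing shrinks.

**What the generator does not emulate.** Real nodes are not exact
ellipsoids (hilum, lobulation, matted clusters), measurement error is
absent, imaging reads are independent of node shape given truth, and
class-conditional score distributions are clean unimodal laws. Passing
tests therefore demonstrate the pipeline's correctness and internal
consistency under the stated generative assumptions — not clinical
performance on real cohorts.

## Study design of the pipeline driver

Training follows the study: only patients whose nodes are *all*
metastatic or *all* non-metastatic enter the training node set (their
node-level labels are unambiguous without node-by-node pathology
mapping); validation is patient-level over the whole cohort. The driver
fits all four methods on the training nodes, predicts every node,
aggregates, combines with each available imaging modality (OR),
evaluates node-level resubstitution metrics and AUCs on the training
nodes — resubstitution at the Youden cutoff, labelled as such — plus
patient-level CCRs overall and on the NAC subgroup, and runs the χ²
comparisons of each method against the planar formula. Every output
file carries the run id (a hash of config and seed), the manifest
records versions, counts and the config, and an existing run directory
is never overwritten silently. Identical config and seed reproduce the
bundle byte-for-byte.

## Problem sizes and numerical choices

Default experiments use the 43-patient cohort (~240 nodes); the
calibration-style checks use larger draws — ~2,000 nodes for the forest
OOB-vs-holdout comparison, 10⁴ triples/nodes for distributional checks
— chosen so Monte-Carlo error is well below the asserted tolerances.
Axis-recovery checks rasterize at 0.25 mm (relative error well under
the 5% tolerance; the dominant term is the O(h²) moment bias).
Comparisons of floating-point impurities use strict inequality for
"better", making tie-breaks exact rather than epsilon-tuned.

## Known limitations

- Thresholds and tree metrics on the training nodes are resubstitution
  estimates; no cross-validation or confidence intervals (none are
  reported for the AUCs either, and no DeLong test).
- The forest OOB error is the only internal generalization estimate
  exposed.
- No nodal anatomical levels (axillary I–III), no N-staging, no CT
  intensity simulation, and no DICOM ingestion — inputs are measured
  axis tables or binary masks.
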