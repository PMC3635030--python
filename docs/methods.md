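# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limitations of `connage`. Everything stated
here is computed by the package's tests or analysis scripts; nothing is
an external empirical claim.

## Connectome construction

A scan's connectome is built ROI-series → detrend → band-pass → Pearson
correlation → Fisher z → vectorize.

- **ROI extraction.** A voxel belongs to an ROI when its *centre* lies
  within the sphere radius (Euclidean distance in mm through the image
  affine). Centre-in-sphere is the simplest defensible discretization
  given only a centre and a radius; partial-volume weighting is not
  attempted. All public coordinates are MNI mm; voxel indices never leak
  through the API.
- **Detrending** removes the least-squares fit of {1, t, t²} per ROI; it
  is an orthogonal projection, hence idempotent, and the output is exactly
  orthogonal to the polynomial basis. Detrending runs *before* the
  band-pass so polynomial edge discontinuities cannot ring into the
  passband. The two operations are exposed separately for users who need
  the other order.
- **Band-pass** is an ideal DFT-domain mask retaining 0.005 ≤ f ≤ 0.1 Hz
  with *inclusive* edges; DC is always removed, so filtered series have
  zero mean. The band must resolve at least one DFT frequency
  (n_volumes ≥ ~8 at TR = 2 s) and the upper edge must lie below Nyquist.
- **Fisher z** is arctanh with |r| clipped at 1 − 1e−7 so degenerate
  (perfectly correlated) synthetic inputs stay finite.
- **Feature numbering** is fixed: strict lower triangle, column-major,
  1-based — k(i, j) = (j−1)n − j(j−1)/2 + (i−j) for i > j. Three
  independently published table rows (pairs (60,7) → 632, (15,12) → 1037,
  (88,83) → 4802 at n = 100) pin this convention; any other enumeration
  contradicts them. The mapping and its inverse are tested exhaustively
  over all 4950 indices.

## Support-vector models

One dense primal–dual interior-point QP solver (Mehrotra
predictor-corrector, `connage.qp`) backs all three trainers. At this
package's problem sizes (≤ a few hundred training scans) exactness
matters more than speed: the solver reaches duality gaps ~1e−9 in 10–30
Newton iterations, and its objectives are verified against an independent
scipy optimizer to 1e−6 relative in the test suite. An SMO-style
coordinate method was considered and rejected: it would need a separate
variant for the multiclass problem, while a single QP interface covers
binary, regression, and multiclass uniformly.

- **Binary SVM** is trained in the standard dual with box constraint C
  and equality Σy_iα_i = 0. The bias is the mean over margin support
  vectors (0 < α < C); when none exist it is the midpoint of the
  KKT-feasible interval. Post-training invariants (0 ≤ α ≤ C, Σy_iα_i ≈ 0)
  are asserted in tests, not assumed.
- **ε-SVR** is trained in the (α, α*) dual; the common part
  min(α_i, α*_i) is subtracted after solving, which leaves predictions
  unchanged, never increases the dual objective, and makes the
  complementarity α_iα*_i = 0 exact. Note a geometric fact that
  surprises users: on noiseless linear data the ε-tube optimum is the
  *flattest* feasible line, so the recovered slope is the true slope
  minus 2ε/(x-range) — exactly 0.48 for slope 0.5 over a range of 10 at
  ε = 0.1. Tests assert this closed form.
- **Multiclass** uses the Weston–Watkins all-together formulation
  (margin constant 2, per-example-per-class slacks), solved in the primal
  as one QP; a common shift of all biases is a flat direction, fixed by
  the gauge Σ_m b_m = 0, which changes neither predictions nor the
  objective. Predictions are argmax of per-class scores with ties going
  to the smallest class label. At K = 2 the trained predictions coincide
  with the binary SVM on separable data (tested).
- **Kernels**: linear, and Gaussian RBF with σ = 2 by default (the tuned
  study value); σ is exposed. Weight vectors are extracted only for
  linear kernels — RBF "weights" have no per-feature meaning and the
  package refuses to produce them.
- Defaults mirror the tuned study parameters: k = 100, C = 0.1 (binary
  linear); k = 62, C = 1 (binary RBF); k = 28, C = 0.1 (three-class);
  k = 298, ε = 0.1, C = 1 (SVR).

## Feature filters

Classification folds rank features by |Welch t| (unequal-variance,
n−1 denominators); regression folds by |Pearson r| with age. Both are
ranking devices: no degrees of freedom or p-values are computed, and no
multiple-testing correction applies. Ties break toward the smaller
feature number so folds are exactly reproducible. Features with zero
variance in both groups score 0 (never NaN) and cannot outrank any
feature with signal; zero-variance features with differing group means
score ±inf and rank first, which is the correct limit of the statistic.
The filter runs on *scans* (3 per training subject), not subject
averages. For K > 2 classes the score is the maximum |Welch t| over all
class pairs, which reduces to the binary filter at K = 2.

## Cross-validation and significance

The unit of cross-validation is the subject: a fold removes all scans of
one subject, and the fold constructor makes a train/test subject overlap
structurally impossible (asserted every fold, plus mutation tests that
scribble over held-out scans and verify the trained model is
bit-identical). Subject-level classification is the majority vote over
the subject's scans with ties resolved by the sign of the summed decision
values — this rule is stated prominently because it affects accuracy; the
SVR analogue is the mean of scan predictions (the low-variance choice).
Accuracy denominators are subjects. Significance is the exact binomial
upper tail Pr(X ≥ n_correct) at chance ½ (1/K for K classes), computed by
direct summation — no normal approximation; n is at most 100 here.

Holdout tuning selects k and C (or ε) by LOOCV accuracy (or slope, ties
broken by R², then smaller k) on a randomly drawn subject subset, then
applies the winners to the **full dataset including the holdout**. This
mirrors the procedure this pipeline reproduces and carries a real
optimism bias; a user wanting unbiased error should nest the tuning or
exclude the holdout from the final evaluation.

## Interpretation

Consensus features are the intersection of per-fold selections. Each
consensus feature's reported weight is the *mean over folds* of its
linear-model coefficient (the fold-to-table aggregation is otherwise
underdetermined; the mean is seed-stable). A node's weight is half the
absolute signed sum of its incident consensus weights — the ½ constant is
ratified by published node-weight cells that equal exactly half the sum
of their printed incident feature weights (e.g. 0.5193 and 14.747 for
one superior-frontal ROI), and the signed-sum bookkeeping (each feature
incident to exactly two nodes) is asserted in tests. Published tables
print weight magnitudes; where incident signed weights disagree in sign,
half-sums of printed magnitudes will not reproduce a node weight, and no
attempt is made to guess unrecoverable signs.

## Synthetic cohorts

The generator emulates the *statistical* structure the analysis assumes,
not BOLD biophysics. For scan s of subject with age a, edge e:

    z_es = baseline_z + β_e (a − 50)/10 + u_(subject,e) + v_(s,e)

with u ~ N(0, subject_sd²) per subject-edge and v ~ N(0, scan_sd²) per
scan-edge, β_e = 0 for non-informative edges. Parameters and defaults:

| parameter | default | units | rationale |
|---|---|---|---|
| n_rois / n_volumes / TR | 100 / 128 / 2.0 s | — | the study's acquisition geometry |
| scans_per_subject | 3 | — | study design; also the LOOCV fold unit |
| baseline_z | 0.3 | z | typical resting-state inter-ROI coupling (r ≈ 0.29) |
| subject_sd, scan_sd | 0.25, 0.25 | z | between- vs within-subject noise; the 1:1 ratio is a free choice (nothing pins it) |
| n_informative_edges | 50 | — | planted truth; 1% of the feature space |
| edge_effect β | 0.1 (z/decade) | z per 10 y | order of magnitude giving d ≈ 1.5 between young/old groups (below) |

Ages are uniform within each group's range (only ranges and means are
known; uniform adds the least assumption). Planted slopes alternate in
sign across edges — aging strengthens some couplings and weakens others,
and a signed truth exercises the weight pipeline in both directions.
Sex alternates M/F within each group *in age-rank order*, so the sexes
are age-matched and the gender analysis — for which nothing is planted —
is genuinely null; with arbitrary-order alternation a chance M/F age
imbalance leaks the planted age effect into "gender" signal. The age
effect is linear in z-space and centred at 50 years, matching the SVR's
linear-predictability premise and keeping baseline_z the middle-aged
value.

`edge_effect_for_cohens_d` inverts the generative model in closed form:
the subject-level (scan-averaged) group-mean difference is
βΔage/10 and the within-group variance is
subject_sd² + scan_sd²/scans + β²Var(age)/100 (uniform age variance), so
the β giving a requested Cohen's d is
β = 10d √(v₀ / (Δage² − d²·Var(age))). The parameter-recovery conditions
(30+30 subjects, 50 edges at d = 1.5) use this calibration; d = 1.5 per
edge is large for a univariate effect but the multivariate task is what
is being recovered, and the permuted-label control verifies the pipeline
finds nothing when nothing is there.

All randomness flows from one integer seed through named
`numpy.random.SeedSequence` sub-streams, one per subject, so cohorts are
bit-reproducible and extensible without reshuffling existing subjects.

**Rendering.** `render_timeseries` draws Gaussian ROI series whose
population correlation is tanh of the planted z-matrix; arbitrary planted
matrices need not be positive semidefinite, so the target is first
projected to the nearest correlation matrix (Higham alternating
projections via statsmodels) and then factorized by eigendecomposition
with eigenvalues clipped at 0. Sampling error shrinks as 1/√n_volumes;
round-trip tests verify recovery within 3/√(T−3) (three Fisher-z standard
errors). `render_volumes` writes the series into 5 mm spheres of a 4D
NIfTI grid (background = white noise, affine maps voxel indices to mm)
for end-to-end testing of extraction. The bundled `synthetic_atlas`
places spheres on a regular lattice — it is a geometric stand-in, *not*
the published 100-ROI coordinate set, which is not printed in full in any
source this package reads.

**What the generator does not emulate** — hence what passing tests do
not show about real data: hemodynamic autocorrelation and low-frequency
structure (scan noise is white), motion and scanner drift artifacts,
heavy-tailed or spatially correlated noise, network-structured
connectivity beyond the planted edges, nonlinear age effects, and
site/scan-protocol differences (the study's differing voxel sizes across
scans are ignored). Real-data performance claims require real data.

## Problem sizes

Test and acceptance workloads are sized for a single desktop CPU: the
classification recovery study uses 60 subjects × 3 scans × 4950 features
(~25 s including its permuted control), the SVR study 65 subjects
(~20 s), and solver-vs-oracle comparisons use 50 random instances at
n ≤ 30 (binary/SVR) and n = 12, K = 3 (multiclass). The full suite runs
in about a minute.

## Known limitations

- The interior-point solver is dense; it is not intended beyond ~10³
  training examples.
- Grid search is exhaustive over the given axes; no warm starts.
- The multiclass model is linear-kernel only (kernelizing
  Weston–Watkins is possible but out of scope, and multiclass weights
  are not projected into node tables).
- `binomial_tail` sums pmf terms in float; for n ≤ 100 the absolute
  error is far below any decision threshold used here.
- The pipeline accepts real NIfTI input but performs none of the
  upstream preprocessing (slice timing, motion correction, registration,
  nuisance regression) that real resting-state data require.
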