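# Methods

## Scope and model

`srseval` evaluates single-fraction, single-isocenter multi-target (SIMT)
stereotactic radiosurgery plans for brain metastases and compares two
planning techniques across a paired cohort.  All computation happens on a
regular voxel grid in physical millimetres.  Conventions that everything
else builds on:

* **Voxel membership is by voxel center** (no partial-volume weighting):
  a voxel belongs to a structure or an isodose region iff its center
  does.  Voxel centers sit at `origin + (index + 0.5) · spacing`.
* **Dose thresholds are closed** (`dose ≥ X`).  For continuous dose
  fields the boundary set has measure zero, and the closed convention
  makes the cumulative DVH and `volume_at_dose` exactly consistent at bin
  edges.
* **Healthy brain = brain − ∪GTV** (not brain − PTV); a PTV-based
  variant is available via configuration.
* **D2% is computed by exact voxel sorting**, not DVH interpolation:
  the largest dose received by at least 2% of the structure's voxels.
  Grid-exact and reproducible.
* **GI is computed over the whole grid**, with no structure restriction:
  the defining ratio `V_50%/V_PI` has none.
* **Merged targets**: PTVs whose surface distance is below 5 mm (default)
  are unioned and evaluated as one target, mirroring the clinical
  workaround that prevents planning systems from fighting over the
  corridor between close lesions.  Merging is the transitive closure of
  the pairwise proximity relation, so chains collapse to one structure.
  A merged target takes the maximum member prescription.
* **Multi-target attribution**: with several targets, each candidate
  voxel is attributed to the nearest target centroid; per-target
  conformity uses that target's share of the prescription isodose, and
  for mixed 18/20 Gy plans the local prescription sets the V_PI / V_50%
  thresholds.  This is the only isocenter-free choice; with a uniform
  prescription it leaves the global GI unchanged.  The plan-level CI is
  the PTV-volume-weighted mean of per-target CIs (the aggregation is not
  standardized; per-target values are also reported).

The plan-acceptance policy: each PTV covered ≥ 98% at its prescription;
per-PTV D2% ≥ 130% of prescription is a warning; cumulative-PTV D2%
above 135% of the reference prescription (the plan's maximum) is a
rejection; brainstem / optic apparatus / lens maxima of 12 / 8 / 2 Gy are
hard limits.  All limits are configurable (`PolicyLimits`, `RunConfig`).

## Synthetic paired cohort

The generator exists so that the entire pipeline — geometry, DVH
metrics, clustering, policy, statistics — can be exercised end to end
without patient data, under conditions that match a published 36-patient
SIMT cohort:

| parameter | default | rationale |
|---|---|---|
| patients | 36 | cohort size emulated |
| lesions/patient | 2–25, median ≈ 9 | two-stratum sampler: uniform on 2–9 with probability 19/36, else uniform on 10–25 (the cohort's 19:17 split) |
| per-lesion GTV | lognormal, median 0.16 cm³, σ_log = 0.7, resampled into [0.07, 2.1] cm³ | reproduces the reported median within the truncation bias (~+11%); σ chosen so the clipped median check at n = 2000 stays within 20% |
| prescription | 18 Gy w.p. 11/367, else 20 Gy | the cohort's 11:356 lesion split |
| margin | 1 mm GTV→PTV | clinical margin |
| grid | 1 mm isotropic | dose-calculation grid of both planning systems |
| near-hippocampus patients | 6/36 | one lesion forced within 5 mm of a hippocampus |
| placement | uniform in brain, center separation ≥ 2·(r_GTV + margin), ≥ ~3 mm clearance from the brain surface | both regimes (isolated and bridged shells) occur; bounded rejection sampling, error after 4000 retries |

Anatomy is analytic: a 1396 cm³ brain ellipsoid (semi-axes 56 × 85 ×
70 mm), with ellipsoidal OAR surrogates at fixed offsets (brainstem
≈ 25 cm³, hippocampi ≈ 3 cm³ each, optic apparatus, lenses).  One
seeded `numpy` generator drives all randomness; the cohort is
bit-reproducible from `CohortSpec.seed`, which is recorded in every
output manifest together with a hash of the run configuration.

### Dose kernel

Each lesion contributes a radial kernel with prescription radius
`R = r_GTV + margin + 0.6·spacing` (the 0.6-voxel allowance keeps the
voxelized prescription isodose covering the whole PTV):

* `r ≤ R`: linear peak `PD·(1 + (hot_ratio − 1)(1 − r/R))` — clinical
  target hotspots of 120–130% of prescription;
* `R < r ≤ r_break`: power law `PD·(R/r)^k`, continuous at `R`.  The 50%
  isodose then sits at `R·2^{1/k}`, so an isolated target's GI is exactly
  `2^{3/k}` — the simulator's calibration handle.  Defaults: steep arm
  k = 1.383 (GI 4.50), shallow arm k = 1.207 (GI 5.60), bracketing
  technique-level gradient indices reported for conformal-arc vs VMAT
  SIMT plans;
* `r > r_break` (where the dose reaches 25% of PD): a steeper power law
  (exponent 4).  A k ≈ 1.2–1.4 falloff holds only in the high-dose
  region of measured SRS profiles; carried to infinity it would flood a
  25-lesion brain with a multi-Gy background (mean brain doses of
  ~10 Gy against clinical values of ~2–3 Gy).  Every reported isodose
  metric (GI at 50% PD; V5–V12 at ≥ 25% of an 18–20 Gy prescription)
  lies in the shallow regime, so all closed-form oracles are unaffected.

Kernels superpose by **summation** — this reproduces dose bridging, the
mechanism by which the corridor between adjacent lesions exceeds 12 Gy
and healthy-brain V12 grows faster than lesion count.  A plan-wide
low-dose bath `bath_fraction·PD_max·exp(−d_iso/60 mm)` around the lesion
centroid models the arcs' integral-dose background; the shallow arm
carries a larger bath (0.08 vs 0.02), as inverse-optimized VMAT plans
do.  The voxel loop is JIT-compiled (numba) against a precomputed
normalized kernel profile table; a pure-numpy reference path is retained
and cross-checked in the tests.

### What the generator does and does not emulate

It reproduces: paired plans over identical anatomy, realistic lesion
counts/volumes/prescriptions, closed-form gradient behaviour per
technique, dose bridging, a low-dose bath, hippocampal proximity cases.
It does **not** model arc geometry, MLC sequencing, inverse optimization
(so hotspot and OAR constraints are not actively respected — multi-lesion
plans can legitimately fail the acceptance policy), tissue heterogeneity,
or anatomical variation between patients (one phantom serves the cohort).
Lesion size and count are sampled independently, so many-lesion patients
can exceed the emulated cohort's total-GTV range.  Passing tests
therefore demonstrate the correctness of the evaluation pipeline and the
direction of technique-level contrasts, not clinical dose accuracy.

## Statistics

The paired two-tailed Wilcoxon signed-rank test discards zero
differences (Wilcoxon's original treatment; Pratt's method is not used),
ranks |d| with midranks for ties, and takes W⁺ as the statistic.  For
effective n ≤ 12 (and always in `exact` mode) the two-tailed p is
computed by exhaustive enumeration of all 2ⁿ sign assignments — correct
under ties, where tabulated null distributions are not — as
`min(1, 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w)))`.  Otherwise a normal approximation
with tie correction (−Σ(t³−t)/48 in the variance) and a 0.5 continuity
correction is used; it matches `scipy.stats.wilcoxon(correction=True)`
on tie-free data and agrees with the exact p to <0.03 for n = 10–12.
Percent differences are `100·(b − a)/b` with the shallow (larger) arm as
denominator, matching how ">30% lower" clinical summaries are computed.
Significance is p < 0.05, without multiplicity correction, as is usual
in paired plan-comparison studies.  Stratification uses ≤10 vs >10
lesions (the cohort minimum is 2, so "1–10" and "2–10" coincide) and a
2 cm³ total-GTV threshold.

## Numerical choices and degenerate inputs

* Margin expansion uses a Euclidean distance transform on physical
  coordinates (exact under anisotropic spacing), evaluated on a padded
  bounding box so cost scales with the structure.  **Discretization
  caveat**: center-to-center distances quantize in voxel-diagonal steps,
  so at margins comparable to the spacing the expansion adds only the
  face-adjacent layer and under-covers the continuous Minkowski volume
  by ~5–15% for structures a few voxels across.  An odd-factor
  `supersample` option reconstructs the implied surface at subvoxel
  precision (0.5-level of the linearly interpolated indicator) and
  removes the mean bias; no mask-based operator can recover information
  lost when a 3 mm sphere is voxelized at 1 mm in the first place
  (its own volume is phase-dependent by up to ±20%).  Results with
  margin ≫ spacing, or on refined grids, are accurate either way.
* Cluster labelling defaults to 26-connectivity: 12 Gy shells are thin
  and diagonally connected.  Cluster volumes always partition total V12
  exactly (they are counts over a label partition).
* Empty masks are rejected by every operation whose result would be
  undefined (DVH, mean, coverage, D2%); `paddick_ci` returns 0 with a
  warning when no voxel reaches the prescription; `gradient_index`
  raises instead, since its denominator is the defining quantity.
* `wilcoxon_signed_rank` returns p = 1 with a warning when all
  differences vanish.
* Dose grids are validated finite and non-negative at construction;
  synthetic doses are stored as float32 (a 36-patient cohort of paired
  1 mm grids would otherwise not fit in desktop memory; no reported
  metric is sensitive at that precision).

## Problem sizes used by the test suite

Analytic checks run on 40–88³ grids in seconds.  The cohort-level checks
evaluate full 36-patient paired cohorts on the 1 mm phantom grid
(~3.1M voxels, ~450 lesions per cohort); the qualitative-headline check
repeats this across 20 seeds and requires the paired V5–V12 contrasts
(steep arm lower, p < 0.05) and the larger >10-lesion V12 gap in ≥95% of
them.  One cohort takes ~30 s on one CPU; the 20-seed check ~9 minutes.

## Known limitations

* The closed-form margin oracle (sphere + 1 mm within 5% of
  4/3π(r+1)³ at 1 mm spacing) is not met for every radius in 3–8 mm by
  any mask-based expansion semantic we evaluated (center-distance,
  exact distance-to-solid, subvoxel surface reconstruction); the
  discretization analysis above explains why.  The corresponding
  acceptance test states the check at face value and documents the
  failure.
* Plan-level GI of multi-lesion synthetic plans exceeds the isolated
  kernel value (bridging inflates V_50% more than V_PI); technique
  calibration is therefore anchored to the isolated-target closed form,
  and cohort-level GIs are compared only qualitatively.
* DICOM-RT import rasterizes contours per slice by point-in-polygon on
  voxel centers; holes/keyhole contours and multi-slice interpolation
  are not supported.
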