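# Methods

## Coordinate conventions and units

All coordinates are decimal millimetres in a patient-fixed frame:
x = left–right (positive towards patient left), y = caudo-cranial
(positive caudal), z = dorso-ventral (positive ventral).  The x sign
convention is a package choice (only magnitudes and the caudal/ventral
signs are anatomically forced) and is never silently flipped.  Volumes
appear in cm³ only at the reporting boundary; everything internal is mm,
which avoids unit-conversion bugs between the estimator (mm) and the
report (cm³).  Coordinates are stored and round-tripped at full float
precision (CSV I/O uses `repr` formatting and round-trip parsing), so
sub-voxel registration accuracy is never destroyed by I/O.

## The MRD volume estimator

The mean radial distance (MRD) of the in-target dwell positions to their
transverse centre of mass is a delineation-free surrogate for prostate
radius.  Assumptions baked into the estimator:

* The implant is embedded in the gland and moves with it; radial dwell
  spread in the transverse plane scales with the gland's linear size.
* Expansion is treated as isotropic in the transverse plane: the cube law
  ΔV(%) = 100·(MRD₂³ − MRD₁³)/MRD₁³ converts the linear ratio to a volume
  ratio.
* The caudo-cranial direction carries catheter slippage unrelated to
  volume and is excluded from both the centre of mass and the radii.

Paired intervals use only dwells in-target on **both** scans, so both MRDs
are computed on the same point set and the ratio is meaningful.

The per-dwell positional uncertainty σ defaults to 1 mm — an assumption
about reconstruction accuracy, not a measurement — giving σ_MRD = σ/√n.
Two propagation formulas for σ_ΔV% are provided.  The default computes
100·√(3·(σ₁²/MRD₁² + σ₂²/MRD₂²)).  A first-order delta-method expansion of
the cube ratio instead gives 300·√(σ₁²/MRD₁² + σ₂²/MRD₂²) — a factor √3
larger — and is available via `propagation="delta_method"`.  Both are
exposed because they are genuinely different conventions; the choice does
not affect any point estimate.

Degenerate clouds (all dwells coincident in the transverse plane) return
MRD = 0 with a warning rather than raising, so batch runs survive
pathological configurations.

## Registration

**Closed-form rigid fit.**  The quaternion (Horn) absolute-orientation
solution: subtract centroids, form the 3×3 cross-covariance, assemble the
symmetric 4×4 quaternion matrix, take its principal eigenvector.  This is
the global least-squares optimum over proper rigid transforms for given
correspondences.  Fewer than three pairs, or collinear configurations
(rank < 2 after centring, tolerance 1e-8), raise a degeneracy error —
rotation about the common line would be unidentifiable.

**ICP.**  Nearest-neighbour matching on the full in-target clouds (kd-tree,
not one-to-one enforced), closed-form refit from the original source
points each iteration, stop when the RMS improvement falls below
`tol_mm = 1e-6` or at `max_iter = 100` (then flagged unconverged, not
raised).  Both halves of each iteration can only reduce the sum of squared
matched distances, so the RMS is monotone non-increasing; this is asserted
on every run.  No trimming or outlier rejection is applied.  A
`matching="known"` mode bypasses matching and serves as the stronger test
oracle.  Registration direction is fixed: the later scan's cloud is
aligned onto the earlier for catheter-based analysis (displacement
= T(b) − a), while the marker transform maps earlier markers onto later
ones and is applied forward to the earlier dwells (displacement
= b − T(a)); the two methods therefore share sign conventions.

The nearest-neighbour matcher stays exact (i.e. equals the
known-correspondence fit) as long as residual motion per dwell stays well
below half the 5 mm dwell spacing; with reconstruction noise of ~1 mm 3-D
magnitude and ≤ 2 mm rigid perturbations the two fits agree to well under
0.2 mm / 0.5°.  At per-axis noise of 1 mm and above, occasional
along-catheter mismatches appear and the agreement degrades gracefully.

**Marker-noise Monte Carlo.**  Each replicate adds i.i.d. Gaussian noise
(defaults 0.5/1.0/0.5 mm SD in L-R/C-C/D-V, reflecting CT voxel
anisotropy) to all six marker coordinates of an interval, refits the
marker transform, applies it to the dwells and records the displacement
relative to the noise-free registration.  Means and SDs are pooled over
replicates, dwells and patients; replicate-level means are also returned
because dwells within a replicate share one fitted transform and are not
independent.  A replicate whose perturbed markers become collinear is
redrawn from the same stream (counted and warned); with realistic marker
geometry this is practically unreachable.

## Statistics

* Wilcoxon signed-rank: zero differences dropped (classic variant; Pratt
  behind a flag since neither is canonical), midranks for ties, statistic
  W = min of the two signed-rank sums, two-sided p.  The exact null
  distribution is computed by a generating-function convolution over
  doubled ranks (equivalent to enumerating all 2ⁿ sign patterns, ties
  included) for n_eff ≤ 25; above that, a tie-corrected normal
  approximation without continuity correction (matching the common
  software default).  The method tag is always reported.
* Cohort decomposition: per patient the mean δ and sample SD σ_pat
  (ddof = 1) of a displacement component; overall Δ = mean of δ,
  Σ = SD of δ, and the RMS of the σ_pat as the pooled random variation.
  The identity σ² = mean(σ_pat²) is asserted on construction.  Patients
  with fewer than two shifts are excluded with a notice.
* Box summaries: quartiles by linear interpolation of order statistics
  (`numpy.percentile` default), Tukey fences at 1.5×IQR, whiskers clamped
  to the most extreme datum inside each fence.
* The 0.05 significance threshold is reported but never gates computation,
  and no multiple-testing correction is applied (three intervals are
  reported separately); the report footer says so.

## Synthetic cohort generator

The generator emulates what the estimators will meet clinically, not
tissue biomechanics:

* **Prostate**: ellipsoid with semi-axes ratio 1 : 1.1 : 0.9
  (L-R : C-C : D-V) scaled to a volume drawn uniformly from 21–56 cm³;
  centre jittered ±5 mm from the frame origin so nothing depends on a
  privileged origin.
* **Catheters**: default 12 (11 supported), placed at 75–85 % of the
  axial radii on a peripheral ring with jittered angles, running
  caudo-cranially with a small sinusoidal bow (≤ 2 mm sagitta) so ICP
  faces non-degenerate clouds.  Dwells every 5 mm over the central 75 % of
  the gland length (the insertion fraction is a parameter, as real
  insertion depth varies), flagged in-target against the ellipsoid
  expanded by a 5 mm margin: ≈ 72–96 in-target dwells per patient, ~84 at
  the median volume.
* **Markers**: two near the base plane (±0.4·a laterally), one near the
  apex — non-collinear by construction with a wide margin.
* **Oedema**: per-axis linear factors sᵢ = 1 + wᵢ·g with g solved so that
  ∏sᵢ matches the prescribed ΔV (closed-form cube root when isotropic;
  Brent otherwise).  Default ΔV is +4.3 % at 24 h and +4.4 % at 48 h (both
  relative to planning), i.e. mild oedema; an anisotropy weight vector
  such as (0, 1, 1) confines expansion to the C-C/D-V axes.  Expansion is
  applied about the *ellipsoid centre*, not the dwell centre of mass — the
  two differ under implant asymmetry, which makes estimator bias under
  asymmetric implants a testable property rather than an artefact.
* **Confounders**, applied in order after scaling: a whole-implant rigid
  shift (rotation about the prostate centre, SD 1° per axis; translation
  SD 1 mm per axis — motivated by the gap between catheter- and
  marker-based registrations, not a measured quantity), per-catheter
  craniocaudal slip (SD 1.5 mm), i.i.d. reconstruction noise on every
  dwell (SD 0.5 mm per axis) and marker placement jitter (SD 0.5 mm).
  CT1 is the noise-free reference frame; CT2/CT3 are both generated from
  it.  In-target flags are recomputed against the expanded ellipsoid in
  its own (back-transformed) frame.
* **Seeding**: per-patient streams are spawned from the master seed with
  counter-based spawn keys, so the same config + seed is bit-identical and
  adding patients never perturbs earlier ones.  A deterministic draw
  selects which patients (default 4 of 23) lack the 48-hour scan.

What the generator does **not** emulate — and hence what passing tests do
not show about clinical data: curved-catheter dwell spacing measured along
the physical catheter, marker migration along the needle track (marker
motion is pure jitter here, while clinically it is the dominant
confounder of marker analyses), time-resolved oedema kinetics between the
three snapshots, non-rigid tissue deformation beyond the affine
expansion, and any dosimetric consequence.  Closed-loop recovery tests
therefore validate the estimators' geometry, not the clinical
interpretation of their outputs.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on generated data:
cohorts of 3–23 patients (~72–96 dwells each), 100 Monte-Carlo replicates
for the marker-noise analysis over 10 patients, and 200 single-patient
replicates for the noisy volume-recovery check — sizes matching the study
design the package emulates, at which every stage completes in seconds.

## Known limitations

* The MRD estimator is blind to purely craniocaudal expansion by design;
  under strongly anisotropic oedema it reports the transverse component
  cubed, not the true volume change.
* With ~1 mm noise on ~80 dwells the MRD carries a small positive bias
  (E[√((x+ε)²+(z+ε)²)] > r, of order σ²/2r ≈ 0.03 mm per scan); the bias
  largely cancels in the ratio and stays well below half a percentage
  point in ΔV under the shipped conditions.
* ICP convergence is to a local optimum; the implants analysed here start
  near-aligned, which is the regime the method assumes.
* Three markers are the minimum for a unique rigid fit; the marker-based
  registration has no redundancy and inherits marker uncertainty in full,
  which is exactly what the Monte-Carlo analysis quantifies.
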