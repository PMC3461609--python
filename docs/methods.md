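# Methods

This note records the models, conventions and design choices behind
`ratpet`, in the order the pipeline runs.

## Geometry and resampling

All grids are axis-aligned lattices in a right-handed world frame measured in
millimetres; the world position of voxel index (0,0,0) is the grid origin,
and origins refer to voxel *centres*. Oblique or sheared grids are out of
scope. Rigid transforms are parameterised as fixed-axes Euler rotations in
degrees (applied x → y → z), a translation in mm, and an optional per-axis
scale (unit by default); internally a 4×4 homogeneous matrix is the canonical
form, and composition/inversion go through matrices with a
rotation-times-diagonal-scale decomposition check.

Resampling pulls each target voxel centre back through the inverse transform
and interpolates in the source: trilinear for activity images, nearest
neighbour for label volumes. Out-of-support voxels are filled with 0 kBq/mL —
the PET background is air — so resampling never invents activity. Identity
resampling onto the same grid is short-circuited and exactly lossless.
Workflow choices that an interactive tool would leave implicit (interpolation
mode, fill value) are therefore explicit parameters here.

## Template scaling

Individual animals are not MR-scanned, so the template is brought to subject
size by rescaling its voxel dimensions with the ratio of tympanic-bulla
distances (subject/template); the world origin and landmark coordinates scale
by the same factors, voxel values are untouched, and nominal region volumes
scale by the product of the axis factors. An `explicit` mode sets the voxel
dimensions directly (useful when published, rounded values such as
0.1 × 0.1 × 0.13 mm must be reproduced); when the explicit factors disagree
with the pure distance ratio by more than rounding the discrepancy is logged.
Label codes 1–7 follow the canonical region order (left striatum … 
cerebellum), 0 is background.

## Registration

The manual three-step alignment protocol (centre shift, rotation adjustment,
centre refinement) is replaced by a deterministic landmark fit with the same
structure: centroid translation, closed-form least-squares rotation (Kabsch,
with reflection guard), exact translation refinement. Only rotation and
translation are fitted; anatomical scale is fixed beforehand by template
scaling. Skull evidence comes either from thresholding the NaF image above an
intensity quantile (default 0.90) or from the inverted MR (bone is darkest);
both return world point clouds.

The three visual acceptance criteria are quantified on landmarks:

* (a) midsagittal offset — distance of the transformed bulla midpoint from
  the template midsagittal plane, plus a laterality check that each bulla
  lies in its own hemisphere (a left/right labelling error fails (a) even
  when the offset is small);
* (b) RMS over bulla + frontal-bone landmarks;
* (c) RMS over cranial-case + parietal/occipital landmarks.

Default thresholds are 0.5 mm for (a) and 1.0 mm RMS for (b)/(c): well below
the scanner FWHM (2.3–3.4 mm), so a "pass" means alignment errors are
sub-resolution. No numeric tolerance exists for the original visual
judgement; these values are declared, not inferred. An optional skull-cloud
RMS (nearest-neighbour distance between the transformed NaF cloud and the
inverted-MR cloud) is reported as a diagnostic but does not gate the pass
flags, because the two clouds sample the shell differently and their RMS
does not vanish even at the true pose. The fitted transform is applied
unchanged to every frame of the dynamic tracer image; the frame schedule is
metadata and passes through untouched.

## ROI projection and quantification

Template labels live on the fine MR grid; projection estimates, for each PET
voxel, the fraction of its volume inside each region by k³ subvoxel sampling
(default k = 4, symmetric subcell centres) mapped through the registration
transform with nearest-neighbour label lookup. Two inclusion rules:

* `threshold` (default 0.5): binary membership — a voxel counts when at
  least half of it lies inside. Volumes are then integer multiples of the
  1.807 mm³ PET voxel, which reproduces the granularity that a
  whole-voxel analysis exhibits at this resolution ratio.
* `fractional`: coverage fractions used directly as weights — the
  partial-volume-weighted statistic interactive ROI tools report; volumes and
  means are then nearly granularity-free.

Regional statistics: mean = weighted mean concentration (kBq/mL), volume =
Σweights × voxel volume (mm³), total activity = mean × volume in Bq (since
1 kBq/mL ≡ 1 Bq/mm³). %ID/g follows the formula in the README. A requested
time point maps to the single frame whose midpoint is nearest (frames are
never averaged; whether multi-frame averaging was intended in the original
workflow is unknowable, and single-frame is the simpler declared rule). The
21-frame schedule sums to 2670 s, so the nominal "45 min" time point falls
half a frame beyond the last midpoint; requests are accepted up to half the
final frame duration past the end of the scan and map to the final frame.

## Checkerboard validation

Both grids are filled with alternating 0/1 kBq/mL voxels (voxel high when
i+j+k+phase is even), ROIs are projected onto both (identity on the MR side,
supersampled projection on the PET side), and per-region volume, mean and
total are compared; PET totals are regressed on MR totals by OLS and the
means compared by a paired two-tailed t-test (degenerate perfect agreement
reports t = 0, p = 1). Regression uses total activity by default because the
per-region means all sit at ≈ 0.5 kBq/mL and carry no spread; a
mean-concentration variant exists behind a flag.

A structural fact worth recording: for a ~9-voxel region, threshold
inclusion cannot simultaneously keep the volume error small and the
checkerboard mean exactly balanced. Parity-balanced (mirror-symmetric)
voxel sets necessarily have even counts, and 16.4 mm³ is 9.07 voxels — the
nearest even counts are ≥ 10% off — while an odd-count set must miscount one
parity and shifts the mean by 1/N ≈ 11%. Fractional weighting has no such
floor; it is the appropriate statistic for cross-resolution mean and total
comparisons, and the validation therefore reports volumes under threshold
inclusion and partial-volume-weighted means alongside them.

## Reproducibility statistics

ICC uses the two-way mixed-effects model (subjects random, observers fixed)
in its single-rater forms, since observer comparisons are between individual
raters, not rater averages:

    ICC_C = (MS_R − MS_E) / (MS_R + (k−1) MS_E)
    ICC_A = (MS_R − MS_E) / (MS_R + (k−1) MS_E + (k/n)(MS_C − MS_E))

with exact F-based confidence limits for ICC_C and the Satterthwaite
approximation for ICC_A (McGraw & Wong). An all-equal table is reported as
undefined rather than NaN. Agreement labels: ≤ 0.40 poor to fair, 0.41–0.60
moderate, 0.61–0.80 substantial, 0.81–1.00 almost perfect (upper edges
inclusive). The between-observer COV pools all pairwise observer differences
across subjects (homogeneous within-subject variability assumed), takes
their sample SD and divides by the grand mean of the region × time cell; the
normaliser is the grand mean by choice, exposed as a parameter. Shapiro–Wilk,
paired t, two-way ANOVA and Bonferroni correction are thin wrappers over
scipy/statsmodels — standard tests, not contributions of this package.

## The digital phantom

The generator emulates only what the algorithms see: geometry, contrast,
volumes and kinetics — not anatomy or scanner physics (no PSF blur, scatter,
randoms or decay; images arrive "reconstructed and corrected").

* **Head**: ellipsoid (semi-axes 9 × 16 × 7.5 mm) with a 0.7 mm bone shell
  and two bulla spheres 11.4 mm apart; NaF puts 10 kBq/mL on bone versus
  0.5 kBq/mL in brain (20:1), the synthetic MR makes bone darkest so
  colour-scale inversion isolates the skull. Skull landmarks are placed
  analytically on the outer shell.
* **Regions**: seven axis-aligned ellipsoids with the template's nominal
  volumes (16.4, 15.1, 26.4, 46.1, 49.6, 15.7, 86.6 mm³). Each is rasterised
  with a per-region size calibration (bisection on a scale factor) so the
  voxelised volume matches the nominal volume to about one MR voxel.
  Centres are frozen at sub-voxel phases chosen once, by a deterministic
  scan, so that discretised volumes track nominal volumes on both grids and
  cross-resolution comparisons measure resolution rather than arbitrary
  grid phase: anterior-posterior offsets sit on the 0.1 mm MR pitch,
  mirror-commensurate lateral offsets are kept where an even PET voxel
  count fits the volume well, and both canonical grids are even-extent and
  origin-centred.
* **Kinetics**: each region follows monoexponential washout in %ID/g,
  anchored at the 5-minute frame (midpoint 345 s) to the calibrated peak
  values (striatum 1.06 %ID/g … medulla 0.67 %ID/g) and converted to
  kBq/mL via the %ID/g formula at 9900 kBq injected dose and 1.045 g/mL.
  The default half-time (≈ 986 s ≈ 16.4 min) joins the striatal 5- and
  45-minute uptakes (1.06 → 0.23). Frame values are curve values at frame
  midpoints.
* **Uptake plateau**: tracer uptake extends a 1.2 mm margin beyond each
  label boundary (nearest-region assignment where margins meet, background
  0.45 %ID/g elsewhere in brain). Real uptake does not step sharply at atlas
  label boundaries; without the plateau, partial-volume bias at ~10 PET
  voxels per region would dominate every quantification and the phantom
  would test partial-volume correction (out of scope) instead of
  registration and projection.
* **Observers**: manual-coregistration variability is simulated by Gaussian
  perturbations of the true pose (defaults 1° per rotation axis, 0.3 mm per
  translation axis), seeded and reproducible. Noise defaults to none so the
  validation chain is deterministic; Gaussian image noise is available.

What passing tests on this phantom do **not** show: robustness to
reconstruction artefacts, PSF-induced spill-over between neighbouring
regions, anatomically realistic region shapes, or intensity-based (rather
than landmark-based) registration performance. The interobserver statistics
on simulated observers characterise the pipeline's sensitivity to pose
perturbations, not human behaviour.

## Numerical choices and edge cases

* Rigid landmark fits require ≥ 3 non-collinear points; collinearity is
  detected by a rank check and rejected.
* Quantile thresholds are strict (>); a constant image is rejected because
  its quantile carries no information.
* Empty projected regions warn and are marked undefined; downstream
  statistics skip them.
* Trilinear interpolation never leaves the input value range (up to the
  0-fill); prefiltering is disabled so resampling is a convex combination.
* Problem sizes: the bundled template grid is 210 × 350 × 140 voxels
  (0.1 × 0.1 × 0.13 mm) and the PET grids are ~18–34 voxels per axis at
  1.218 mm; the full validation runs in seconds and the complete test suite,
  including the 100-pose registration property and the 10-subject ×
  3-observer reproducibility simulation, in well under a minute.

## Known limitations

Axis-aligned grids only; no intensity-based registration (landmarks must be
identified); no partial-volume correction; no kinetic modelling; single-frame
time points; the ICC implementation requires complete tables (no
missing-data variant).
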