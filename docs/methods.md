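# Methods

`lgequant` re-implements, as a tested pipeline, the analysis chain used to
compare isotropic 3D late gadolinium enhancement (LGE) cardiac MR against
the standard 2D short-axis (SAX) acquisition: geometric reslicing of the
3D volume onto the 2D slice geometry with resolution matching,
semi-automatic scar quantification, AHA 16-segment mapping, and
paired-method agreement statistics. Because clinical image data of this
kind are not shareable, every stage is validated on a synthetic left
ventricle phantom with analytic ground truth; the phantom is first-class,
tested code, not a fixture.

## Coordinate conventions

World coordinates are DICOM-style LPS millimetres. A `VolumeGrid` maps
0-based indices to world positions affinely: `origin` is the center of
voxel (0,0,0) (half-voxel convention) and the rows of `axes` are the
orthonormal direction cosines of the index axes. A `SliceGeometry` mirrors
the DICOM ImagePositionPatient / ImageOrientationPatient / PixelSpacing /
SliceThickness fields: `row_dir` is the direction of increasing column
index, `col_dir` of increasing row index, and the slab normal is their
cross product. NIfTI files (RAS affines) are converted on read/write;
DICOM series are read directly from those tags, with explicit errors for
non-uniform orientation or inter-slice gaps.

## Slab-averaged reslicing

To compare the two sequences slice by slice, the isotropic volume is
resampled onto each 2D slice's pixel grid, and its resolution is degraded
to the 2D acquisition's effective slice thickness: the reference plane is
shifted along its normal symmetrically in steps of the 3D resolution until
the span of the outermost planes reaches the 2D slice thickness, each
plane is sampled by trilinear interpolation on the regular grid (no
prefiltering, no extrapolation), and the output pixel is the arithmetic
mean across planes.

Numerical choices:

* **Plane count.** 7 mm is not an integer multiple of 2 x 1.25 mm, so the
  smallest symmetric span that covers the slab is used: k =
  ceil(thickness / (2 step)), i.e. 7 planes spanning 7.5 mm for 7 mm /
  1.25 mm. A `floor` variant is available (`span_rule`), and the offsets
  used are recorded in each image's metadata.
* **Step size.** The normal-shift step is the volume's isotropic spacing;
  for anisotropic input the minimum spacing is used and a warning emitted.
* **Out-of-support samples.** Sample points outside the volume's lattice
  hull are excluded from the mean; a pixel is invalid only when all of its
  plane samples fall outside. This keeps near-edge myocardium rather than
  discarding partially covered slabs; per-slice counts of partial and
  invalid pixels are reported.

Validation: trilinear sampling is exact (to 1e-9) for affine intensity
fields; on smooth random volumes the 7-plane mean agrees with a dense
0.1 mm normal-sampling slab average (computed through an independent
interpolation code path) to about 1% of the intensity range over random
oblique geometries — comfortably inside the 2% acceptance band.

## Scar quantification

Myocardium is the region between manually drawn (here: analytically
generated) epicardial and endocardial contours; a pixel belongs to a
region iff its center lies inside the polygon, boundary inclusive.
Two thresholding methods cover the two disease phenotypes:

* **FWHM** (ischemic scar): threshold = half the maximal signal inside a
  reference ROI drawn in visible scar. The raw pixel maximum is used (no
  smoothing or percentile surrogate).
* **mean + n SD** (inflammatory enhancement, n = 3): threshold = mean plus
  n sample standard deviations (n-1 denominator) of a remote-myocardium
  ROI.

Reference ROIs exist per slice; a slice without one inherits the reference
statistics (scar-ROI maximum, or remote mean and SD) from the nearest
slice that has one, ties broken toward the base, and the donor slice is
recorded in `threshold_source`. Scar = myocardial pixels with signal >=
threshold (inclusive, so a uniform region exactly at threshold is
detected). Masses follow slice summation: area x thickness x 1.05 g/ml
(the standard myocardial specific density; configurable). Global LGE
extent = 100 x scar mass / myocardial mass, flagged undefined for zero
myocardial mass. The contrast ratio is |mean blood - mean myocardium| /
mean blood on basal and apical slices.

**Blood-pool rim correction.** On magnitude LGE images the blood pool is
as bright as (FWHM regime) or far brighter than (3-SD regime) the
threshold, so myocardial pixels sharing their footprint with the cavity
are flagged as enhancement all around the endocardial border. Clinical
workflows remove such partial-volume artifacts by manual correction of the
automated detection; the package implements that correction as an
explicit, recorded removal mask: a rim band along the endocardial border
(base width 2 mm — about one acquired in-plane pixel plus interpolation
support — widened per slice by the endocardial narrowing estimated from
the neighbouring basal contour, which is how far cavity signal reaches
through a thick slab) is cleared of detected scar unless it lies within
two pixels of scar detected deeper in the wall, so genuinely transmural
scar reaching the border survives. Manual corrections are always explicit
add/remove masks with provenance; the low-level `quantify_slice` applies
none unless given.

## AHA 16-segment mapping

Slices are split base -> apex into three contiguous level groups as equal
as possible (remainder assigned basally first). Within a slice, pixel
angles are measured around the epicardial contour centroid, zero at the
anterior RV insertion point, advancing through the anterior ->
anteroseptal order; basal and mid levels use six 60-degree sectors
(segments 1-6, 7-12), the apical level four 90-degree sectors (13-16)
anchored at the same reference. The apical cap (segment 17) is not part of
the 16-segment model. Per-segment extent pools scar and myocardial areas
over the segment's slices before taking the ratio (area-weighted), and is
categorised 0 (none), 1 (0-25%], 2 (25-50%], 3 (50-75%], 4 (75-100%] —
half-open intervals so the printed integer boundaries (25 -> 1, 26 -> 2)
are preserved while continuous extents partition cleanly.

## Agreement statistics

Paired series (subjects with a missing value dropped and counted) are
compared with: Student's paired two-tailed t-test; Pearson correlation
(undefined for a constant series — explicit error); Bland-Altman bias =
mean(x - y) with 95% limits of agreement bias +/- 1.96 x sample SD of the
differences (the conventional multiplier, no small-sample t correction),
plus the per-pair (mean, difference) table for plotting; and the Wilcoxon
matched-pairs signed-rank test with Pratt zero handling — exact null
distribution for n <= 25 without zero differences, normal approximation
with continuity correction otherwise. A convenience exact-binomial McNemar
test compares paired binary detections. Calibration is checked by
simulation: the paired t-test's type-I error at alpha = 0.05 over 1000
null replicates (n = 20) must fall in the 99% binomial envelope
[0.037, 0.064].

## The synthetic left ventricle

The LV is a truncated half-ellipsoid shell: epicardial and endocardial
ellipsoids centred on the base plane, kept for z >= 0, apex at z = L.
Defaults: epicardial semi-axes (35, 35, 80) mm, endocardial (27, 27, 72)
mm — a 95 ml (100 g) myocardial shell in the range of the patient cohorts
this emulates. Signal levels are direct inputs (no inversion-recovery
physics): blood 440, remote myocardium 100 (contrast ratio 0.77, matching
the measured blood-myocardium contrast of such acquisitions), ischemic
scar 440 (infarct enhancement approaches the blood pool — the FWHM
regime). The myocarditis phenotype is parameterised by contrast-to-noise:
scar sits 5 noise SDs above remote (125 at the default SNR 20), the
low-contrast regime the 3-SD method exists for, and is modelled as an
outer-wall band with a thin (10% of wall) preserved epicardial rim, as in
mid-wall/outer-wall inflammatory enhancement. The infarct is a
subendocardial wedge (default 100 degrees, inferior/inferolateral, 65%
transmural, basal-to-mid span). Optional papillary lesions are small
hyperenhanced ellipsoids attached to the endocardial surface; they are
labelled separately and excluded from myocardial mass and extent
(papillary infarction is scored visually, not quantitatively).

Acquisition simulates partial volume by averaging the analytic signal over
each voxel footprint on a ~0.25 mm sub-voxel lattice (at least 5 samples
per axis), then adds Rician noise — magnitude MRI: |SI + n1 + i n2|,
n ~ N(0, sigma), sigma = remote SI / SNR — from seed-derived streams
(independent streams for the 2D and 3D acquisitions; identical spec and
seed reproduce bit-identical volumes). The 3D acquisition (1.25 mm
isotropic) uses a lattice rotated obliquely against the LV axis so that
reslicing is exercised on genuinely oblique geometry; the 2D acquisition
(1.4 x 1.4 mm, 7 mm slabs, no gap) is generated directly at the SAX
geometry. Ground truth (labels, masses at 1.05 g/ml, extent, per-segment
extents) is evaluated on a fine 0.25 mm lattice; quantified masses are
compared against truth restricted to the axial slab the contoured stack
actually covers, since the shell extends past the last contourable slice
near the apex.

The phantom also emits the contours a reader would draw: endo/epi ellipse
polygons per slice, a blood-pool ROI, a mid-wall annular-arc remote ROI
(60 degrees x ~2.2 mm — arc-shaped like a reader's remote ROI, and wide
enough that the 3-SD threshold's sample-SD estimate is stable), and a scar
reference ROI only on slices crossing the scar's axial span, so the
nearest-slice fallback is exercised exactly as enhancement-free slices do
in patients.

## What the phantom does and does not show

Passing recovery tests on this phantom demonstrates that the geometry,
thresholding arithmetic, fallback routing, segment bookkeeping and
statistics are correct, and that the reslicing pipeline does not by itself
distort quantification (noiseless 2D-native vs resliced-3D extents agree
within 0.05 percentage points; native recovery errors stay within 2
points of truth at SNR >= 20 for both phenotypes). It does not emulate:
surface-coil intensity gradients, inversion-time misadjustment, motion or
ghosting artifacts, epicardial fat (the background is signal-free, so an
enhancement band touching the epicardial surface would be diluted at 7 mm
slab thickness — one reason the myocarditis band is modelled with a spared
epicardial rim), trabeculation, or the distinct per-voxel noise spectra of
real 2D versus compressed-sensing 3D reconstructions.

Two deliberate, documented behaviours follow from the model. First,
noiseless mean+3SD thresholding is degenerate: the remote SD is exactly
zero, the threshold equals the remote mean, and the inclusive comparison
floods the myocardium — so the noiseless end-to-end equivalence check uses
the infarct/FWHM phenotype. Second, both acquisitions receive the same
per-voxel noise scale, so slab-averaged reslicing smooths the 3D noise and
lowers the resliced 3-SD threshold toward the remote mean; the resliced
myocarditis extent is consequently inflated by several percentage points
relative to truth and to the native 2D stack (visible as a negative 2D-3D
bias in the cohort agreement). This is a known fragility of n-SD
thresholding on smoothed images and is reported, not patched.

## Problem sizes

Default stacks are 10 SAX slices of 64 x 64 pixels; the isotropic volume
is roughly 100^3 voxels; truth lattices are 0.25 mm (about 27 M fine
voxels per phantom); cohorts in the analysis scripts and the acceptance
script use 6 patients per phenotype; the statistical calibration uses 1000
null replicates at n = 20. These sizes were chosen so every property is
measured on the same geometry the defaults describe while a full analysis
run stays in the minutes range on one CPU.
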