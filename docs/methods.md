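# Methods

This note documents the models behind `tomoqa`: what the simulator
emulates, how each estimator works, the defaults that matter, and what
passing tests do and do not establish about real scanner data.

## Coordinate frame and phantom geometry

All coordinates are millimetres in a right-handed frame fixed by the
package: x lateral, y depth from the chest wall (the chest-wall plane is
y = 0), z through-plane.  Volumes are stored (slice, row, col) =
(z, y, x) with row 0 at the chest-wall edge.

The printed dimensions of the phantom's test objects are encoded in
`tomoqa.geometry`: four 12-step gauges at 0.5 mm increments (6 mm full
extent); two folded bead ramps of 0.18 mm beads spaced 0.25 mm
vertically and rising 10 mm, the upper limb starting one spacing above
the lower limb's top bead and laterally offset at the fold; three 5 mm
aluminium beads 10 mm apart in z; nine low-contrast spheres of
0.8–10 mm; an aluminium square just inside the sphere circle.  The limb
bead counts are floor(rise / 2·spacing) + 1 for the lower limb and
whatever fills the remaining rise for the upper (21 + 20 by default),
so the folded set spans exactly 10 mm.

Exact x/y placements of the square, sphere circle, markers and gauges
are not fully dimensioned in published drawings of such phantoms; the
defaults here preserve the topology (spheres on a circle of radius
14 mm, square inside it, ramps left and right of centre, gauges along
the wall, a clear uniform band for noise ROIs) and are configurable
through the geometry JSON.  Sphere order around the circle alternates
large and small diameters so no two large spheres collide.  Contrast
fractions are not printed either; the defaults are effective contrasts
relative to background: spheres +2 %, aluminium square +20 %, gauge
steps +60 %, markers +100 %, ramp/z beads high-contrast metal
(+2500 % / +300 %).  Only effective contrast is modelled — no material
or beam physics.

## The simulator

`render` produces a reconstructed volume in four steps:

1. **Pose** is applied as a rigid rotation about the phantom centre
   (intrinsic z-y-x: yaw, pitch, roll) plus an in-plane translation —
   objects are moved, the grid is not resampled.
2. **Through-plane response**: each reconstructed slice applies a slice
   profile (Gaussian, triangular or rectangular; FWHM = nominal slice
   width; unit area) to the object function.  Because every solid is
   convex, a voxel column's intersection with it is a z-interval, so the
   convolution is evaluated exactly through the profile's CDF — no fine
   z-grid, no aliasing.
3. **In-plane sampling**: analytic intersection on a 3× supersampled
   grid, box-averaged to the 0.1 mm pixels (avoids aliasing the 0.18 mm
   beads), then an anisotropic Gaussian blur (σx, σy) — default
   (0.18, 0.12) mm, x worse, emulating tube-travel blur.
4. **Noise**: i.i.d. Gaussian with SD = base·(mAs/ref)^−½ (default 8 at
   50 mAs on a background of 1000).  Real reconstructed noise is
   correlated and only approximately square-root in mAs; the model
   implements exactly the law the analyses are designed to measure.

Out-of-plane artifacts are represented solely by the slice profile's
tails; there is no projection/reconstruction simulation, no scatter, no
detector MTF, no iterative-reconstruction nonlinearity.  Consequently,
passing tests validate the *estimators* (their geometry handling,
bias, and noise robustness), not vendor reconstruction behaviour; on
scanner data the same code measures whatever the reconstruction actually
delivers.

Every render pairs with a `truth_record` (posed object positions, slice
width, noise SD) used by the tests.  Grid defaults: 0.1 mm pixels, 1 mm
slice increment, 42 slices — matching sub-100-micron DBT pixel pitches
at desk-scale volume sizes (42 × 960 × 640 voxels, ~2 s per render).

## Estimators

**Chest wall.**  Human observers count visible gauge steps; the module
replaces the observer with a threshold: a step is visible when its mean
exceeds the local background (a strip beside the gauge) by k background
SDs (k = 2 default) and at least half the step is inside the field.
Steps are counted contiguously from the deepest toward the wall and the
extent is quantised to whole steps, matching the counting protocol; a
sub-step interpolated estimate is reported as informational.  The
measurement slice is the slice of maximal gauge contrast ± 1, averaged.

**SSP and slice width.**  Per bead, the maximum intensity over a small
window on the rows containing the ramp samples the SSP at the bead's z.
Window maxima carry a noise-dependent positive offset, so the background
is estimated with the *same* statistic (maxima over same-shaped tiles of
an adjacent strip), cancelling the offset in expectation; a light 1-px
in-plane smoothing before sampling scales every bead peak equally
(leaving the normalised SSP shape untouched) while suppressing the
noise entering the maxima.  A smoothing cubic spline with smoothing
factor n·(SD/peak)² tied to the estimated noise yields the continuous
curve; FWHM is linear interpolation of the half-maximum crossings.  The
volume-level slice width averages the FWHM over the five central slices.
Measured bias is within 5 % of the true width over 1–5 mm widths at
default noise, and individual measurements stay within 0.5 mm.  The
bead's own 0.18 mm size is ignored for the SSP (≪ slice widths).

**z-bead spacing.**  The through-slice profile (mean over a 1.5 mm-radius
disc at the bead's pose-corrected centre, windowed to half the nominal
bead separation so co-located beads don't interfere) is spline-fitted
and its peak located as the midpoint of the half-maximum crossings —
exact for symmetric profiles and robust to the flat plateau a 5 mm bead
produces at 1 mm slice widths.

**ASF.**  In-plane profiles through a bead centre along x and y,
maximum-projected across the slice set spanning the bead, background
subtracted and peak normalised; reported as ASF(x) and ASF(y).

**PSF/MTF.**  A background-subtracted patch (default 1.5 mm, below the
2 mm bead pitch) around an in-focus bead, recentred by centroid, is
Hann-windowed, zero-padded 4× and Fourier transformed; the modulus along
the frequency axes through DC, normalised at DC, gives MTF(x) and
MTF(y).  The window suppresses truncation ripple at the cost of a small
upward bias for wide PSFs in small patches — the closed-form Gaussian
check therefore uses a 6.5 mm synthetic patch where the effect is
< 1 %.  Contamination detection rejects patches with more than one
distinct lobe above 20 % of the peak.  Values above 1 are reported, not
clipped (anisotropic PSFs can push modulation above DC).  Headline
curves use only beads within 0.5 mm of an in-focus plane.  Optional
deconvolution divides by the transform of the bead's projected ball,
3(sin u − u·cos u)/u³ with u = 2πfr, with a floor ε = 0.05 below which
the curve is truncated and flagged.  The MTF label is "FT-of-PSF MTF":
for nonlinear, non-isoplanatic reconstructions the strict transfer-
function interpretation does not hold.

**Uniformity, SNR, CNR, noise law.**  Two 10 mm-radius regional ROIs
(anterior/lateral) tracked across slices; five 5 mm ROIs for global
uniformity, defined as 100 × (max − min of ROI means) / grand mean of
the five means — a relative measure because no cross-vendor pixel scale
exists; the denominator choice is recorded in report provenance.  SNR
uses a zero offset on the raw pixel scale (configurable for vendors
with a known rescale).  CNR measures noise in the background ROI, not
inside the square, avoiding contrast-dependent noise.  All ROI centres
are verified against every object footprint dilated by 2 mm.  The noise
law is fitted by least squares on log SD vs log mAs.

**Low contrast and contrast–detail.**  Sphere detection is a local-CNR
threshold (default 1.0) against an annulus that excludes neighbouring
objects; detectability is otherwise observer-dependent and observer/ROC
modelling is out of scope.  Contrast–detail circles are placed by a
deterministic hexagonal packing of non-overlapping circles inside the
object-free mask (reproducible without a placement seed; n capped by
what fits); the single-parameter hyperbola SD = k/d is fitted by least
squares, with the relative residual flagging departures.  The fit uses
diameters from 1 mm up; 0.8 mm circles hold too few pixels.

**Pose.**  Four dedicated 3 mm marker spheres at distinct corners and
depths; sub-voxel centroids by background-subtracted centre of mass in
a local box, then orthogonal Procrustes registration to the nominal
positions.  Angles use the intrinsic z-y-x convention (yaw about z,
pitch about y, roll about x), matching the simulator.  Estimates beyond
15° per axis are flagged unreliable.  Recovery over random poses within
±3° is accurate to better than 0.1° at default noise.  Downstream
modules receive the pose as a coordinate transform only.

## Determinism and I/O

All randomness flows from integer seeds (`AcquisitionModel.seed`; series
renders derive child seeds as seed·1000 + index).  Reports contain no
wall-clock values — any timestamp comes from acquisition metadata — so
identical inputs give byte-identical JSON/CSV.  DICOM secondary-capture
output stores 16-bit integers with rescale slope/intercept: the
simulator CLI quantises to integers first, making the round trip
voxel-identical; the TIFF+JSON path stores float32 losslessly.  Reading
applies only the declared rescale, and orientation conflicts resolve in
favour of the configured chest-wall edge with a warning.

## Problem sizes

The slice-width sweep (four widths × ten seeds) runs on a ramp-centred
geometry — the folded ramp set plus background margin — through the
identical code path as the full phantom; full-phantom renders back the
z-geometry, pose, chest-wall and end-to-end checks.  White-noise
contrast–detail sampling uses a 150 × 150 mm synthetic field so ≥100
non-overlapping circles fit at every diameter.

## Known limitations

- No projection/reconstruction physics: vendor-specific out-of-plane
  streaks, in-plane reconstruction filters and nonlinear iterative
  behaviour are not emulated, so absolute MTF/ASF shapes on real data
  will differ from the simulator's Gaussian-blur world.
- Gaussian, uncorrelated noise; real DBT noise is spatially correlated,
  which widens circle-mean SDs relative to the σ/√m law.
- Effective-contrast rendering only; no dose or attenuation modelling.
- ROI placements are figure-level approximations, configurable per
  site; the clearance check guards any customisation.
- Detection is a CNR threshold, not an observer model; ROC analysis is
  explicitly out of scope.
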