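# Methods

This note documents the models, algorithms and numerical choices behind
`mousecbct`, the assumptions they rest on, and what the synthetic phantoms
do and do not establish about real scans.

## Image model and coordinate conventions

Scans are 3-D scalar volumes with isotropic voxels (0.1 or 0.2 mm on real
scanners; phantoms use any spacing, 0.4 mm in most tests). Axis convention:
x lateral (the splitting axis), y anterior–posterior with the snout at low
y, z vertical with the bed at low z; mice are assumed prone in the standard
holder orientation. Voxel (i, j, k) owns the half-open cube
[i, i+1)·spacing from the volume origin, so its center is at
origin + (index + ½)·spacing. "Right" throughout the package means the +x
side of this coordinate system.

Intensities are reduced to an ordinal class scale by calibration: the two
most massive histogram modes are affinely mapped to air = 0 and soft
tissue = 1000 (arbitrary units). Every downstream threshold keys on class
*ordering* — acrylic sits between air and soft tissue, bone above soft
tissue, teeth above bone — not on absolute scanner units. Phantoms place
the classes at 0 / 500 / 1000 / 2500 / 4000 with Gaussian noise of
σ = 50 (5% of soft tissue) by default: visible, but far from defeating any
class threshold. Calibration fails loudly on volumes without a bimodal
air/tissue histogram.

## Scan splitting

Bed detection samples ~100 evenly spaced (x, y) voxel columns, keeps those
whose mean intensity is below the air/soft-tissue midpoint (no mouse
resting there), and takes per column the lowest acrylic-sized *descending*
intensity step (material below, air above; steps in [0.5, 1.52]× the
acrylic class, which excludes the twice-as-large tissue→air edges). A
least-squares plane is fitted with a median-height prefilter and one
residual-trimming pass, because columns clipping a mouse flank put their
point on the mouse surface instead of the bed. Everything at or below the
plane (plus a one-voxel margin) becomes air.

Row splitting uses two redundant 1-D signals smoothed by a 5 mm moving
average: the mean intensity of each sagittal plane (interior local minima
with ≥ 10% prominence are gaps between mice; each minimum is re-centered on
its flat valley, since an air gap has no unique minimum), and, when the
minima count disagrees with the expected mouse count, the tooth-density
voxel count per plane (local maxima are mouse centers; splits at
midpoints). If neither signal yields the expected count the scan fails
with both signals attached to the error log. Five-mouse holders are first
split vertically: platform top surfaces are clustered from the per-column
descending acrylic edges, the scan is cut above the top platform, the top
row is split like a three-mouse row, and the bottom row at the x midline.

Cleaning keeps the largest 26-connected component of the
tissue-or-denser mask (≥ midpoint of acrylic and soft tissue) and sets
every other voxel to air. This single rule removes nosecones, holder side
walls, residual bed and intruding neighbor limbs; a separate wall-plane fit
is unnecessary. A slot whose tissue volume is below a 1 cm³ equivalent is
flagged empty and not processed further — far below any mouse, far above
noise.

## Anatomy and the symmetry chain

Teeth are thresholded at the top class ± 15%, labeled with 6-connectivity
(adjacent clusters stay separable), and speckle-filtered at 20 voxels of
0.1 mm scale (scaled by spacing³). The most anterior, most inferior, and
most posterior cluster centroids are the front, bottom and back tooth
landmarks. Bone (band between soft tissue and teeth, 26-connected) is
classified positionally: components well posterior of the back tooth are
the shoulder pair; of the rest, the component nearest the bottom tooth is
the jaw and the most superior large component the cranium.

The symmetry chain has four nodes: snout (front tooth), cranium centroid,
neck pivot, and shoulder midpoint. The pivot is the horizontal-plane
intersection of the head axis (front→back tooth line) and the body axis
(through the shoulder midpoint, perpendicular to the shoulder pair),
clamped between cranium and shoulders; for a straight pose the axes are
parallel and the pivot falls midway. Left/right points come from the
shoulder centroids and the cranium's lateral extent and are symmetrized.
Chains can be re-fitted to reference segment lengths (per-segment midpoint
rescaling) when a subject's lengths are known from an earlier scan.

## Curvilinear grid and volume accounting

Each chain segment carries a rigid frame: tangent along the (horizontally
projected) segment, lateral horizontal and perpendicular to it, up
completing the frame. The resampling lattice attaches these frames sharply
— each axial station uses exactly the frame of the segment it falls in —
so the lattice midline lies exactly on the chain polyline and every
lateral lattice row is exactly perpendicular to its segment's mirror
plane. We first tried blending the frames smoothly across nodes; the
smoothed axis is then perpendicular to *neither* mirror plane near the
neck and produced a systematic one-sided excess of tens of mm³ at 20°
bends, with sign following the bend direction. The sharp construction
eliminates this by design.

The price of sharp stitching is that the lattice folds on the inside of a
bend and stretches on the outside. Volumes handle this exactly: each
voxel's dual cell (corners at neighbor midpoints, extrapolated at the
boundary) is decomposed into 24 tetrahedra — four per face, each triangle
joined to the face centroid and the cell centroid, a construction that
tiles any hexahedron — and the *signed* volumes are kept. Folded space
carries negative volume and cancels its own double count, so summed cell
volumes equal the covered region's volume in any pose (mean signed cell
volume stays within 0.2% of spacing³ even at 28° bend while individual
cells range several-fold either sign). A grid whose negative volume
exceeds 20% of its positive volume is rejected as self-intersecting.

Inside the dihedral wedge between two segments' mirror planes no mirror
correspondence exists at all; those axial stations (half-width
6 mm·tan(bend) plus 1.5 voxels around each stitch) are excluded from the
excess-tissue analysis. Buccal tumors sit anterior of the neck stitch, so
the exclusion costs at most a sliver of the largest tumors' posterior
tail.

Mirror refinement registers the resampled head against its own j-mirror by
gradient descent on mean squared intensity difference (normalized to 1 at
the start) plus `lambda_curv` (default 0.1) times the mean squared
discrete Laplacian of the displacement field. Gradients are analytic
(chain rule through the trilinear interpolation) and smoothed with a
σ = 2 lattice-unit Gaussian, which restricts updates to a smooth control
field; steps use backtracking, so the loss sequence is monotone
non-increasing, with a warning and unchanged grid if no step succeeds. Two
safeguards keep the registration from destroying the measurement itself:
the loss is evaluated only where tissue is present on *both* sides of the
midline (a unilateral tumor IS mirror asymmetry and must not drive the
registration), and displacements are capped at one lattice voxel per
component by default (the registration's job is sub-voxel alignment).

## Tumor detection

Tissue (≥ half the soft-tissue class) is volume-weighted and summed per
sagittal column on each side of the midplane; the difference is the
initial height map (mm³ per column; negative values retained). Filtering:
clamp negatives, 3×3 median, Gaussian of σ = 0.3 mm, zero below a
0.4 mm thickness equivalent (two voxels at the 0.2 mm scanner preset), keep
the largest 2-D connected region — the deliberate unilateral single-tumor
model. Back-projection marks, per selected column, the outermost
tumor-side tissue voxels down to the depth matched by the mirror side, and
carries them through the grid into scan coordinates (nearest voxel plus a
6-connected closing for sub-voxel cracks). The reported volume is the sum
of marked lattice cell volumes, not the scan-space voxel count.

Shape metrics diagonalize the covariance of tumor voxel-center coordinates
(equal-volume voxels, so effectively volume-weighted): eigenvalues sorted
descending, normalized as √λᵢ/Σ√λⱼ. The implied ellipsoid volume uses the
uniform-solid convention — a uniform ellipsoid with semi-axes (A, B, C)
has coordinate covariance (A², B², C²)/5, hence
V = (4π/3)·5^{3/2}·√(λ₁λ₂λ₃). Sphericalness is the fraction of tumor
voxels inside a sphere of the tumor's own volume, centered by a ±2-voxel
local search from the centroid. Tumor location is the centroid offset from
the back tooth expressed in the head frame (lateral, along-axis,
vertical).

## Growth model and fitting

The post-radiotherapy model is implemented exactly as its printed form,
V(t) = a·exp(−(t−b)²/c²) + d/(1+exp(−f(t−g))) + d + h, whose asymptotes
are d+h (early) and 2d+h (late). The standalone +d makes the "maximum
volume" reading of d hold only for the `drop_extra_d` variant (late
asymptote d+h), provided as a documented switch; the printed form is the
default. Synthetic truths tie h = −d so curves start near zero and plateau
at d, which is self-consistent under the printed form.

Fitting is separable least squares: a deterministic grid over the
nonlinear parameters (b within ±5 days of the irradiation day, c in
[2, 30] days, f in [0.05, 2] /day, g from just after irradiation to the
last measurement) with a closed-form solve for the amplitudes at each grid
point, followed by bounded local polish from the five best grid points. No
random initialization. Three statistical choices matter:

* amplitudes a and d are sign-constrained (NNLS with h split into a
  difference of nonnegative parts) — they are physical volumes, and
  unconstrained fits find mirror modes with a, d < 0 that fit noise
  better;
* the solve is inverse-volume weighted (floored at 5% of the curve
  maximum) because measurement errors are roughly proportional to volume —
  unweighted fitting tripled the regrowth-rate error;
* hinge residuals on a dense time grid penalize fitted curves that go
  negative anywhere in [0, t_max] — volumes are volumes, and the
  degenerate d+h ≪ 0 modes that mimic regrowth all violate this.

Under 10% multiplicative noise and 15 timepoints the regrowth-rate
tolerance of the recovery check sits close to the Cramér–Rao limit of the
7-parameter model; the fitted medians (f within 16–20% relative, g within
0.5–0.6 days across seeds) leave little margin, and parameters of tumors
that never regrow (zero logistic amplitude) are undefined and excluded
from recovery statistics, as such tumors are excluded from regrowth fits
generally.

Spline mean volumes use a second-order smoothing spline evaluated at 10
evenly spaced days in [8, 20] and averaged. The smoothing factor defaults
to n·σ̂² with σ̂² estimated from second differences (var of the second
difference of iid noise is 6σ²), so exactly constant or linear curves are
reproduced exactly; it is configurable.

The measurer-bias analysis fits, per mouse, a cubic polynomial predicting
caliper volume from CT volume and averages the residuals per day. Two
regression details are essential: the CT predictor is spline-smoothed per
mouse (regressing on raw noisy CT dilutes the fit — errors in variables —
and leaves a spurious volume-tracking component of R ≈ 0.3 in the "no
bias" residuals), and mice whose predictor spans under 10% of the cohort's
volume range get an intercept-only fit (a cubic on a near-constant
predictor fits noise and absorbs the very bias being measured). The raw
regression is available via `smooth_predictor=False`. Matched pairs
require exact day equality by default; linear interpolation across
methods' schedules is a separate, explicitly labeled mode.

## What the phantoms emulate — and what they do not

A phantom mouse is implicit solids on the class scale: soft-tissue body
and head ellipsoids, cranium and jaw shells, a bilateral shoulder pair,
three midline tooth clusters, an optional one-sided ellipsoidal cheek
tumor placed tangent to the cheek (a quarter of its lateral semi-axis
embedded, keeping it connected while the excess over the mirrored side
stays within ~5% of the analytic ellipsoid volume), acrylic bed planes and
holder platforms, hollow nosecone cylinders, and water-filled tubes whose
columns are filled to the requested volume within one voxel. The head —
cranium, jaw, teeth, tumor — rotates rigidly about a vertical neck pivot
by up to ±30°, the minimal pose variation that exercises the bendable
grid; with no tumor the head halves are exact mirror images about the bent
midline surface. Simulated growth cohorts draw plausible post-RT
parameters (regrowth doubling under ~4 days, as for aggressive
head-and-neck lines), include a 25% fraction of durably controlled tumors,
and can inject three independent caliper-bias effects: a reporting floor,
contextual inflation of small tumors by 0.4 of the daily cohort mean
(matching reported ~100 mm³ caliper readings for near-zero tumors), and
smoothing toward the previous record.

Deliberately not modeled: CT physics (beam hardening, scatter,
reconstruction artifacts, partial volume beyond trilinear interpolation),
soft-tissue contrast within organs, anatomical variation between animals,
non-rigid neck/jaw articulation, and tumors that cross the midline.
Passing phantoms therefore demonstrates the geometric and statistical
correctness of the pipeline — splitting, landmarking, symmetric
resampling, exact volume accounting, excess detection, model fitting — not
robustness to scanner artifacts or anatomical diversity; on real scans the
thresholds inherit their validity from the intensity calibration step.

## Problem sizes and tolerances used in the checks

Tests and the acceptance script run phantoms at 0.4 mm voxels
(three-mouse scans of roughly 200×85×35 voxels) with tumors of
20–500 mm³ and bends up to 25°; shape analytics use 0.1 mm reference
solids. Measured end-to-end: tumor volumes within 10% of truth (worst
case ~7%), tumor-free mice at or near 0 mm³ against a 2 mm³ floor,
pose-jitter repeatability with relative SD under 5% and SD growing with
volume from a near-zero intercept. Water-tube volumetry at 0.2 mm recovers
50–1000 µl within 2% (the phantom fills to one voxel; the measurement is
threshold + connected components). Grid volume conservation holds to 1e-9
relative over 100 random smooth warps. Tolerance choices repeat the
pipeline's own documented guarantees, not the other way around.

## Known limitations

* Orientation is assumed (snout toward low y, prone); there is no
  automatic pose detection.
* The four-node chain resolves one neck bend; strongly curled postures or
  jaw articulation are out of reach.
* The largest-region rule reports a single tumor; multifocal disease is
  deliberately out of scope, as are tumors crossing the midline.
* Mirror refinement is blind exactly where tissue exists on only one side
  of the midline — by design, so tumors survive registration — which means
  residual one-sided *artifacts* in that zone are also not corrected; the
  stitch-wedge exclusion handles the known such zone.
* The growth model's printed form is kept verbatim; its redundant +d makes
  d+h, not d, the early asymptote, and interpretability of d as "maximum
  volume" strictly holds only for the `drop_extra_d` variant.
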