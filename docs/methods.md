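# Methods

This note records the model assumptions, conventions, parameter choices and
known limitations of `psoctfib`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Instrument model and conventions

The package assumes a single-input-state PS-OCT instrument: a vertically
polarized beam (0, 1)ᵀ passes a quarter-wave plate at 45°, illuminates the
eye circularly, and is detected in two orthogonal channels H/V after the
return pass. A linear retarder with retardation δ and axis θ has the Jones
matrix

    J(δ, θ) = [[cos²θ + sin²θ e^{−iδ},   cosθ sinθ (1 − e^{−iδ})],
               [cosθ sinθ (1 − e^{−iδ}), cos²θ e^{−iδ} + sin²θ]]

and a retarder stack traversed in double pass contributes P·Pᵀ with P the
ordered single-pass product. Per voxel,

    R ∝ A_H² + A_V²,   δ = atan(A_V/A_H),   θ = (π − ΔΦ)/2 ,

with ΔΦ = arg(E_V) − arg(E_H). Two conventions are fixed here and used
consistently by the phantom, the extraction and the compensation:

* **Channel ordering in ΔΦ.** With the quarter-wave plate at +45°,
  defining ΔΦ = arg(E_V) − arg(E_H) makes the extracted axis equal the
  forward-model axis exactly (the opposite ordering negates it; only the
  formula θ = (π − ΔΦ)/2 is physically fixed, not the ordering). This
  choice makes round-trip tests exact to 1e−9 degrees.
* **Measured ("double-pass") retardation.** A layer whose per-pass Jones
  matrix is J(δ, θ) and which appears twice in the double-pass chain reads
  out as exactly δ through the extraction equation — the circular-input
  geometry halves the accumulated round-trip phase. Layer retardations
  quoted anywhere in this package (cornea ≈ 20°, HFL ≤ 14°, lesion 20–40°)
  are these measured values and are used directly as the per-pass matrix
  argument.
* Axis values are **relative**: the fiber optics of a real instrument add
  an unknown constant offset. Every downstream statistic (complex-space
  averages, circular variance, masks, areas, likelihoods) is invariant
  under a global axis offset, and the test suite asserts this.
* Angles are radians everywhere in the library API; degrees appear only in
  files, YAML specs and CLI output. Depth index 0 is the anterior-most
  pixel; depth intervals are inclusive.

## Anterior-segment compensation

Because cornea, RNFL and HFL are (to good approximation) pure linear
retarders with negligible diattenuation, their combined double-pass effect
is equivalent to one linear retarder. Its parameters (δ_R, θ_R) are read
from the extracted volumes at a reference surface below the HFL — the
IS/OS junction, or the lesion top where the IS/OS is destroyed — and
removed numerically: the per-voxel joint retarder J(2δ_m, θ_m) is rebuilt
from the measured state and sandwiched between J(−δ_R, θ_R) before
re-extraction. Implementation choices:

* **Reference smoothing.** (δ_R, θ_R) maps are median-filtered 5×5
  transversally (θ through its doubled-angle components) so a single
  speckle-corrupted surface voxel cannot corrupt a whole A-scan. Set
  `smooth=1` to disable; exactness tests do, because smoothing biases the
  reference where the HFL axis rotates quickly around the fovea.
* **Reference sampling depth.** The pipeline samples (δ_R, θ_R) two pixels
  below the detected reflectivity edge, i.e. on the bright reflector
  itself (`reference_sample_offset_px`). Sampling above the surface leaves
  a sliver of the HFL uncompensated; that residual is smooth across the
  map and can masquerade as locally uniform axis orientation in
  polarization-maintaining tissue.
* **Single-step vs iterative.** Compensating the whole anterior stack in
  one step is exact only for a single anterior layer. For a cornea (20°)
  plus HFL (14°) stack the worst-case axis error over all relative axes is
  1.24° (computed by `single_step_axis_error` and reported by the
  acceptance script), it varies slowly along circles about the fovea, and
  the extra 5×5-kernel circular variance it induces is below 1e−5 — two
  orders of magnitude under the seed threshold, so the approximation is
  immaterial for segmentation. The two-step variant (cornea at the ILM,
  then the residual at the IS/OS) removes the error on noise-free phantoms
  and is used as a cross-check.
* Columns whose reference is invalid (out of range, zero signal) are
  passed through unchanged, flagged, and excluded from all en-face
  statistics rather than interpolated.

## Depth-averaged axis map and masking

Axis orientations are π-periodic, so depth averaging uses doubled angles:
resultant(x, y) = mean_z exp(i2θ). The average is unweighted over valid
voxels; amplitude weighting was considered and rejected because the bright
reference surface would then dominate the span with noise-driven axis
values. Voxels are excluded when DOPU < 0.8 (depolarizing RPE), when
intensity < 2× the noise floor, or when they are flagged invalid. The noise
floor is the mean intensity of the top `margin_rows` (default 10) depth
pixels of each B-scan — the conventional signal-free vitreous margin; if
tissue reaches into that margin the estimate inflates silently, which is a
configuration contract, not a detected condition.

The lower integration boundary is reference + offset with a 2D Gaussian
offset bump: 100 px at the map center, 50 px at the edges, σ = ¼ of the
shorter map dimension (configurable; the distance between the posterior
retina and the birefringent sclera is largest in the macula). The DOPU
averaging window defaults to 5 (transverse) × 5 (axial) pixels and is
configurable.

## Segmentation

The 5×5 circular-variance map v = 1 − |mean exp(i2θ)| uses valid neighbors
only, with kernels cropped at map borders; pixels with no valid neighbor
get v = 1 and can never be segmented. Seeds are 8-connected components of
{v < 0.21} strictly larger than 100 px; growth adds 8-connected neighbors
with v < 0.36 to a fixpoint (implemented as component labeling of
{v < th₂}, which is the fixpoint of the iteration). All threshold
comparisons are strict, "larger than 100 pixels" included. An optional
region-of-interest polygon restricts both seeding and growth; area is the
pixel count times the en-face pixel area (187.5 µm² at the clinical
1024×250 grid over 8×6 mm).

The likelihood sweep runs the segmentation 18 times with th₁ = 0, 0.05, …,
0.85 and th₂ = th₁ + 0.15; masks nest with increasing thresholds, and each
pixel reports L_h = 1 − th₂* for the smallest th₂* that segments it (0 if
none). Note the default mask thresholds (0.21/0.36) are not on the sweep
grid: mask pixels are guaranteed L_h ≥ 0.6 (via the 0.25/0.40 run), not
L_h ≥ 0.64. Repeated-measurement statistics (`area_statistics`) use the
population (1/n) standard deviation.

## The phantom: what it emulates, and what it does not

The generator forward-models, per B-scan, the cumulative per-pass Jones
product of: a global corneal retarder (default 20° @ 30°); an RNFL field
whose axis is the azimuth about an optic-nerve-head center and whose
retardation decays away from it (peak 4°); a Henle-fiber-layer doughnut
(peak 10°, ring radius 0.75 mm, radial axis about the fovea at map
center); disk lesions of uniform axis whose retardation accrues linearly
over their thickness (default one disk, radius 1.1 mm, 30° cumulative);
and a depolarizing RPE band. Depolarization is modeled by inserting an
independent random linear retarder (uniform axis, uniform retardation in
[0, π]) per voxel at and below the RPE top — light that has traversed a
depolarizer carries no coherent state — which drives DOPU below 0.8 under
kernel averaging while staying in pure Jones formalism. Speckle multiplies
both channels by a shared circular complex Gaussian (polarization-
preserving, fully developed); channel noise is additive complex Gaussian
(σ = 0.005 per quadrature against a retina amplitude of 0.18, keeping
normal retina at DOPU ≥ 0.95 while the vitreous margin is noise-dominated).
Surfaces are gently tilted planes; ground truth (lesion mask, surfaces,
per-layer fields) is exact and seed-independent.

Default geometry is desk-scale: 256×64×512 voxels over the same 8×6 mm
field as the clinical 1024×250×1024 grid, at the same ≈1.39 µm axial pitch
(the clinical geometry is available as `CLINICAL_GEOMETRY`). Tests and the
acceptance suite run at this scale; the coarser transverse sampling makes
the fixed 5×5 kernels cover proportionally more retina, which erodes
lesion rims somewhat more than at clinical sampling (the recovered area on
the default phantom is ≈12% low, within the 15% repeatability envelope;
on a deliberately coarse 96×32 test grid the bias is larger and the tests
say so).

The phantom does **not** emulate: eye motion or tracking artifacts,
chromatic effects, diattenuation, depth-dependent axis rotation within a
layer, scanner distortion, realistic choroidal texture, or a birefringent
sclera (the lower integration boundary exists to exclude the sclera in
real data, and its geometry is exercised, but there is no scleral signal
to leak). Passing phantom tests therefore demonstrates the correctness of
the polarimetric chain and segmentation logic, not robustness to motion,
segmentation failures on pathological anatomy, or clinical
sensitivity/specificity.

## Numerical choices and degenerate inputs

* Voxels with A_H = A_V = 0 are flagged invalid (separate boolean mask,
  never a sentinel value) and excluded everywhere downstream.
* Sweep thresholds are rounded to 10 decimals before comparison to keep
  `arange` float wobble from flipping strict inequalities at exact
  threshold values.
* The reference-surface finder (a phantom-adequate stand-in for a full
  layer segmentation) takes the strongest axial gradient of the smoothed
  reflectivity below the ILM estimate, then median-filters the surface 5×5
  transversally; columns whose peak reflectivity stays below 3× the noise
  floor are invalid. Real data should import externally segmented
  surfaces (CSV) instead.
* Compensated tomograms are rebuilt from per-voxel pure states; DOPU is
  therefore always computed from the *uncompensated* channels.
* Equal seeds give bit-identical volumes; ground truth does not depend on
  the seed.

## Known limitations

* Axis calibration is relative; absolute axis orientations are out of
  scope.
* The lesion detection floor is 100 contiguous map pixels (≈0.019 mm² at
  clinical sampling, more at desk scale); smaller lesions are unreliable
  by construction.
* Depth-resolved local birefringence (iterative peeling beyond the
  two-step variant) and multi-input-state reconstructions are out of
  scope.
* Automatic exclusion of the optic-nerve-head scleral ring is not
  implemented; use the ROI polygon.
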