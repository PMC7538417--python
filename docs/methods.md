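# Methods

## Model and assumptions

The reconstruction assumes cells are **radially symmetric about the
central axis of their midplane outline**.  Under that assumption the 3D
body is the union of maximal spheres centered on the medial axis, with
radii equal to the local distance to the outline.  The package realizes
this literally: medial axis + Euclidean distance map → radius profile →
spheres → per-section circular cross-sections `r = sqrt(R² − Δz²)` →
stacked 2D regions.  The assumption holds well for fission yeast and other
cylindrical cells; it fails for flattened or branched morphologies (see
Limitations).

Voxel inclusion uses the half-voxel center rule: a pixel belongs to a
cross-section when its center lies inside the disk (boundary inclusive).
This approximates "include a voxel when the majority of its volume is
inside the sphere" to within half a voxel, makes the operation separable
per section, and is fixed so that the reconstruction is *exactly* equal to
a brute-force union-of-spheres voxelizer with the same rounding — a
property the test suite asserts as set equality.

Radii live in XY-pixel units; axial offsets are converted with
`z_spacing / pixel_size`, so anisotropic voxels are handled without
resampling.  The `z_spacing` used everywhere is the axially corrected one
(nominal spacing × correction factor); this is the only place the axial
distance calibration enters, which is why stacked (nuclear) volumes in µm³
scale linearly with the factor at constant voxel count, while extruded
(cell) volumes in µm³ are invariant and the voxel count changes instead.

## Skeleton construction

The skeleton primitive is the **medial-axis transform**
(`skimage.morphology.medial_axis`), whose pixels sit on true ridges of the
distance map.  Plain iterative thinning was evaluated and rejected: on
bent capsules it wanders up to 2 px off the medial axis, which reads ~10%
too little local radius and breaks the bend-invariance of extruded
volumes.

Raw medial axes of rasterized smooth shapes carry spurs.  With pruning
enabled (default) the skeleton is reduced to its **longest geodesic path**
(double BFS over 8-connected skeleton pixels), which removes every side
spur while keeping the full central axis of unbranched cells.  Because
thinning-type algorithms retract the axis away from free ends, the pruned
path is then **re-extended** from each endpoint along the local tangent
until the region boundary.  Extension pixels carry their own (shrinking)
distance-map radii, so the added spheres always remain inside the true
body; without the extension, reconstructions lose ~4% of their volume at
the hemispherical caps.

## Whole-cell segmentation from brightfield

In defocused brightfield sections each cell is surrounded by a dark
boundary band whose width grows with defocus and vanishes at focus.  The
most in-focus section is the one with minimal intensity standard
deviation.  Sections below focus are enhanced (Gaussian blur σ = 1 px,
unsharp mask radius 2 px, weight 0.6), Otsu-binarized, and averaged; a
second Otsu threshold on the averaged map yields a closed band around each
cell.  Components enclosed by bands (not connected to the image border)
are candidate cells; the band half-width is measured as the median of the
band's distance transform sampled on the band's medial axis, and each
region is enlarged by that half-width at sub-pixel precision (EDT
thresholding rather than an integer disk, which would leave a ±0.5 px
systematic in the recovered outline).

A known residual of this scheme: at strongly curved cell tips the band
threshold erodes slightly deeper than along straight sides, and a uniform
half-width enlargement cannot fully restore the caps.  On synthetic
scenes this leaves extruded cell volumes ~6–9% below truth (median),
which also shifts recovered N/C ratios up by ~0.01.  The error is a
property of the band-averaging segmentation, not of the extrusion: seeded
directly with the true midplane outline, the extrusion is accurate to
<1%.

## Nuclear segmentation and grouping

Per section: enhance (same defaults as above), Otsu, binary smoothing
(blur σ = 1 px, re-threshold at 0.5), then an Analyze-Particles-style
filter: components smaller than 0.5 µm² or with circularity
`4πA/P² < 0.6` are dropped (weak nucleolar signal produces crescents that
fail the cutoff).  Survivors are optionally dilated (default 0.1 µm) and
replaced by their area-preserving moment ellipse.

Z-grouping links regions in nearby sections greedily by centroid distance
(≤ 2.0 µm, ties to the larger area), bridging at most one missing section
(`max_link_gap = 1`) so that the largest-contiguous-run rule has effect on
intermittently missed sections.  Chains are discarded when they span fewer
than 5 sections, when any centroid lies > 3.0 µm from the chain mean
(nucleus moved during acquisition), or when the largest-area region —
the nuclear midplane — is the first or last region of the chain (clipped
nucleus).

The 0.1 µm dilation exists to capture fluorophore signal at the nuclear
periphery and by design inflates the nuclear ROI (~+15% in volume at
fission-yeast nuclear sizes).  Volumetric validation therefore runs with
`dilation_um = 0`; intensity extraction keeps the default.

## Shape-descriptor conventions

* **Perimeter**: Crofton estimate with 4 directions — near-unbiased on
  digitized smooth outlines (a rasterized disk scores circularity ≈ 1, a
  1-px line ≈ 0.17).  The same convention feeds the staircase surface
  formula, and the surface tests compare against an oracle built from the
  same per-section quantities, so the identity is exact by construction.
* **Feret diameters**: rotating calipers on the convex hull of pixel
  *corner* points; an a×b-pixel rectangle reports exactly
  (diagonal, min(a, b)).
* **Solidity**: pixel area over the pixel count of the filled convex hull
  (the regionprops convention; unbiased on digitized convex shapes).
* **Moment ellipse**: orientation and axis ratio from second moments,
  axes rescaled so the ellipse area equals the pixel area exactly; the
  rasterized fit iterates until the area matches within 1%.
* **Nuclear surface** uses Thomsen's prolate-spheroid approximation
  `S ≈ 4π((2(ab)ᴾ + b²ᴾ)/3)^(1/P)`, P = 1.6075 — exact at a = b and
  within 1.2% of the closed form at a/b = 2.

## Synthetic scenes

The generator emulates a high-resolution widefield acquisition of
fission yeast: 0.1071 µm pixels, 0.065 µm corrected section spacing,
cells in a flat layer with the focal plane 8 sections above their
midplane.  Strain presets draw lengths/widths per cell from uniform
ranges — wild type 8–13 × 3.9–4.3 µm, short mutants 5–7.5 µm, long
mutants 18–26 µm, bent cells with 25–55° arcs — with rejection-sampled
non-overlapping placements (1.2 µm clearance) and one seeded generator
for all randomness.  Nuclei are near-spherical prolate ellipsoids
(a/b = 1.05, minor axis capped to fit the cell width) sized to a target
N/C volume ratio of 0.125.

The brightfield model is geometric, not optical: a dark band of width
0.8 px per section of defocus centered on the midplane outline over a
bright background (1000 counts, band depth 600, Gaussian noise σ = 15);
sub-pixel-wide bands render as proportional partial-coverage darkening so
the focal section is uniquely featureless.  The nuclear channel renders
the ellipsoid at 2000 counts over a 100-count background (noise σ = 10)
with an interior nucleolar sphere at 0.7× signal.  No point-spread
function, shading or depth attenuation is simulated; passing tests
demonstrate the pipeline's geometric correctness and its robustness to
pixel noise, not performance on real optics.  The phantom rasterization
places boundaries generically between pixel centers (continuous random
placements), the unbiased case; lattice-aligned boundaries shift
distance-map radii by up to one pixel.

Problem sizes used in the test suite and acceptance script — a 20-cell
640×640 wild-type scene with ~75 optical sections plus a 10-cell bent
scene, and ≤64³ voxelizer instances — were chosen so the full suite
completes in a few minutes on one CPU while every rule and property is
still exercised at realistic cell sizes.

## Numerical and degenerate-input choices

Negative intensities after dark subtraction clamp to 0.  Constant
sections yield an empty Otsu mask rather than an error.  Regions thinner
than the thinning kernel are their own skeleton.  A skeleton that prunes
to nothing falls back to the region's medoid pixel.  Disk rasterization
ties (pixel center exactly at radius r) are inclusive, fixed to match the
voxelizer oracle.  Greedy linking breaks distance ties toward the larger
region.  Chromatic Z-shifts are integer sections only; sub-section
interpolation is deliberately avoided to prevent resampling artifacts.

## Limitations

* Radial symmetry is assumed per cell; flattened, branched or septated
  geometries reconstruct incorrectly (a septum in the midplane outline
  pinches the skeleton radius).
* One focus plane per field: cells must form a flat layer.
* Surfaces are full-voxel staircase estimates, not sub-voxel meshes; the
  staircase formula is self-consistent but resolution-dependent.
* No time-series support: each stack is processed independently.
* The 2D segmentation track is tuned for boundary-band brightfield
  stacks; other contrast modes should enter through the external
  label-mask import path.
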