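# Methods

## Physical model

A reconstructed cryo-SXT tomogram in the water window assigns each voxel
a linear attenuation coefficient (LAC, µm⁻¹). Attenuation follows the
Beer-Lambert law, so a per-voxel natural-log absorbance divides by the
voxel edge to give the LAC; the package performs this conversion
explicitly and refuses to convert a volume already tagged as LAC, since
unit provenance is the main failure mode of quantitative SXT analysis.
All lengths are carried in µm, attenuation in µm⁻¹; axis order is
(z, y, x) with voxel centres at (i + 0.5)·voxel_size.

The absorbed dose of an acquisition is computed as D = F·µ·E·Et/ρ with
strict-SI inputs (flux ph m⁻² s⁻¹, µ in m⁻¹, energy in J with an exact
eV conversion, exposure s, density kg m⁻³). µ for organic material is a
user input with the measured mitochondrial LAC (0.247 µm⁻¹ = 2.47×10⁵
m⁻¹) as the documented default; computing µ from atomic scattering
tables would require external tabulated data and is out of scope, so the
calculator is a transparent product/quotient whose linearity in every
numerator factor is property-tested.

## Synthetic phantoms

Real tomograms of isolated mitochondria are not bundled, so validation
uses a generator that emulates their salient features: ellipsoidal
objects with lengths ~N(0.90, 0.20²) µm and widths ~N(0.63, 0.12²) µm
(the measured population statistics), a cristae compartment formed by an
outer shell (thickness 0.05 µm) plus evenly spaced planar lamellae
joined to it, a matrix filling the remainder, and three LAC levels —
cristae 0.30, matrix 0.18, buffer 0.10 µm⁻¹ — preserving the contrast
ordering seen in the water window. Lamellae are planar because at 35-nm
resolution the merged membrane compartment reads as sheets; tubular
cristae are available as a config option. The number and spacing of
lamellae are placeholders (no quantitative cristae geometry was
available to emulate), chosen so that the matrix splits into several
basins and the complexity index spans its interesting range; the
generated cristae volume fraction (~55–70%) is therefore indicative, not
a claim about real populations.

Objects are placed by rejection sampling (cap 1000 tries) with a 5-voxel
(0.1 µm) clearance so that optical blur cannot bridge neighbours —
suspended organelles, unlike in-cell ones, are not in contact. Optics
degradation is a 3D Gaussian PSF with σ = FWHM/2.355 (default FWHM
0.035 µm, the better zone plate; FWHM below one voxel warns and skips),
followed by photon noise applied where photon statistics act: the LAC is
converted to a transmission through a nominal 1-µm path (a typical
specimen thickness), Poisson noise at `noise_scale` incident photons is
drawn, and the result converted back (σ_µ ≈ 1/(path·√(N·T)); the default
test level N = 3000 gives σ ≈ 0.02 µm⁻¹, a visibly noisy but workable
map). Everything is deterministic given the spec seed.

What the phantoms do **not** emulate: missing-wedge anisotropy,
reconstruction artefacts, capillary glass, co-isolated debris with
overlapping LAC, and partial-volume chemistry. Passing the recovery
tests therefore demonstrates the pipeline's correctness and noise
robustness, not field performance on arbitrary instruments.

## Identification

Voxels inside the LAC window (default 0.20–0.35 µm⁻¹, spanning the
isolated-mitochondria value 0.247 ± 0.04 and literature in-cell values
up to ~0.45) are thresholded with a hysteresis scheme: a lightly
denoised map (Gaussian, σ = 1 voxel — matched filtering against photon
noise) provides a robust core, which then grows into raw-window voxels
connected to it, keeping boundaries unbiased. A morphological opening
(radius 1) removes speckle, enclosed sub-window interiors are filled
(the window selects the carbon-dense envelope; the enclosed low-LAC
matrix still belongs to the organelle), components are labelled with
26-connectivity and filtered to 0.02–1.0 µm³. Mean LAC per object is
recomputed on the original, un-denoised volume. Objects are ordered by
descending volume with a bounding-box tie-break, making the output
invariant to input relabelling.

## Compartment segmentation

A two-class random forest (50 trees, seeded, single-threaded for
determinism) is trained on sparse voxel annotations over a fixed,
versioned feature bank: raw intensity, Gaussian smoothings at σ ∈
{1, 2, 4} voxels, gradient magnitude and Laplacian at the smallest σ,
and local variance in a 3³ window — the grey-level/edge/texture recipe
of trainable pixel-classification tools. Each class must contribute ≥ 50
voxels. Hard labels use a 0.5 probability threshold with no post-hoc
morphology, so the measurable surface is not smoothed by fiat. A
feature-signature check refuses to apply a classifier to a mismatched
configuration.

The binary cristae image is then split by a watershed on the Euclidean
distance transform of the non-cristae space, seeded from its interior
local maxima and from the exterior; basins the exterior cannot reach
become matrix. The EDT (not intensity) is the natural flooding surface
for a binary mask. Matrix components under 8 voxels are merged back into
cristae and sub-threshold pockets enclosed in matrix are filled —
speckle below what 35-nm optics can resolve at 20-nm voxels — and matrix
is barred from touching the background so the shell stays closed by
construction.

## Morphometry

Volumes are voxel counts × voxel volume, making cristae + matrix =
total exact by construction. Surface areas come from a triangle mesh:
the binary mask is padded, smoothed with a Gaussian (σ = 1 voxel) and
isosurfaced at 0.5 by marching cubes in physical coordinates —
voxel-face counting overestimates a sphere's area by ~50%, whereas this
mesh recovers it to < 1% at r = 30 voxels and converges with
resolution. A compartment so small that smoothing pushes it below the
isosurface level is meshed unsmoothed instead; compartments under 8
voxels are flagged unreliable, and any principal extent below the 35-nm
optic limit raises a sub-resolution flag (measurements at the limit of
resolution are reported, not suppressed).

Length and width are extents along the first and second principal axes
of the object's voxel cloud (plus one voxel so single-plane objects
have non-zero thickness); aspect ratio is width/length. The complexity
index MCI = SA_m³/(16π²V_m²) uses the **matrix** compartment's mesh
area and voxel volume; it is scale-invariant (k⁶ cancels) and bounded
below by 9/(4π) for closed surfaces. The resolvability rule is
inclusive: MCI ≥ 7. Virtual slicing resamples the label masks (nearest
neighbour) into a frame aligned with the requested principal axis and
reports per-slice cristae/matrix fractions; near-spherical objects with
degenerate axes fall back to the global z direction and are flagged.

## Reporting

Per-object tables round to 2 decimals in CSV (full precision in JSON
and in memory). Population statistics use the sample (n−1) standard
deviation; maximum-likelihood normal fits report µ̂ = mean and σ̂ with
the n denominator. Volume-fraction means average per-object fractions
rather than pooling volumes, which is the convention that makes a
population's fraction means consistent with its per-object rows.
Pipeline outputs are a pure function of (input, config, seed): reruns
reproduce CSV/JSON bytes exactly.

## Problem sizes and defaults

Validation phantoms use 80³–112³ grids at 20-nm voxels (1.6–2.24 µm
boxes holding 1–3 objects), photon noise at 3000 counts, and 50-tree
forests — sizes at which the full suite and the acceptance run each
finish in well under a minute while exercising every stage at realistic
contrast and noise. The acceptance recovery run uses 3 objects at 112³;
the digital-ball MCI check uses radius 30 voxels.

## Known limitations

- The classifier's 0.5 threshold slightly fattens cristae at blurred
  interfaces; matrix volume is biased a few percent low, and for
  objects near the resolution limit (width ≲ 0.45 µm) the bias can
  reach ~15% — mirroring the practical finding that the smallest
  objects cannot be reliably resolved at 35-nm optics.
- The dose reported for an acquisition is the incident-side estimate of
  the formula above; it does not model depth-dependent attenuation.
- Anisotropic voxels are accepted for volumes and meshes but virtual
  slicing requires isotropy.
- MRC voxel size is stored in float32 header fields; round-trips are
  exact only to that precision.
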