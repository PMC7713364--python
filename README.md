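# sxtmorph

Quantitative 3D morphometry of mitochondria from cryo-soft-X-ray
tomography (cryo-SXT), for structural cell biologists who want
label-free, per-organelle numbers rather than renderings.

In the water window (284–543 eV) organic material absorbs soft X-rays an
order of magnitude more strongly than water, so a reconstructed cryo-SXT
tomogram is a map of the **linear attenuation coefficient** (LAC, µm⁻¹)
— a quantitative, stain-free contrast. Isolated mitochondria suspended
in buffer sit in a characteristic LAC band (≈ 0.25 µm⁻¹, between buffer
and lipid-dense debris), which is enough to find them; at 35-nm optics
their interior resolves into two compartments: the carbon-dense
**cristae** compartment (the merged outer membrane, inner membrane and
intermembrane space) and the enclosed **matrix**.

`sxtmorph` implements the full analysis chain:

1. **LAC mapping** — per-voxel absorbance ÷ voxel size → LAC (µm⁻¹), and
   the absorbed dose of an acquisition, `D = F·µ·E·Et/ρ` (Gy).
2. **Identification** — LAC-window threshold (default 0.20–0.35 µm⁻¹,
   with hysteresis against photon noise), 26-connected components, and a
   physical size filter.
3. **Compartment segmentation** — a trainable random-forest voxel
   classifier (intensity/edge/texture feature bank, sparse manual-style
   annotations) produces the binary cristae image; a watershed on its
   Euclidean distance transform separates the enclosed matrix.
4. **Morphometry** — voxel-count volumes, smoothed-isosurface mesh
   surface areas, principal-axis length/width, virtual slicing profiles,
   and the **mitochondrial complexity index**

   $$\mathrm{MCI} = \frac{\mathrm{SA}_m^3}{16\pi^2 V_m^2}$$

   over the matrix compartment — scale-invariant, minimal at 9/(4π) ≈
   0.716 for a sphere, and increasing with every invagination. Objects
   with MCI ≥ 7 have resolvable cristae structure at 35-nm optics.
5. **Phantoms** — a synthetic generator of ellipsoidal mitochondria
   (0.90 ± 0.20 µm × 0.63 ± 0.12 µm) with cristae shell + lamellae and
   ground truth, degraded by a Gaussian PSF (FWHM 35 nm) and Poisson
   photon noise, for validation when real tomograms are unavailable.

Volumes travel as MRC2014 or TIFF stacks; reports as CSV/JSON; meshes as
STL/PLY.

## Worked example

```sh
python examples/04_segment_compartments.py
```

```
classifier trained on 568 annotated voxels
  object 1: cristae Dice 0.967, matrix volume 0.1079 µm³ (true 0.1090, -1.1%)
  object 2: cristae Dice 0.960, matrix volume 0.0932 µm³ (true 0.0943, -1.2%)
```

Two phantom mitochondria are blurred by the 35-nm PSF, corrupted by
photon noise (LAC σ ≈ 0.02 µm⁻¹), re-identified, and split into
compartments; the segmentation overlaps ground-truth cristae at Dice
0.96 and recovers matrix volume to ~1%. And the shape index itself
(`examples/05_morphometry.py`):

```
MCI(SA=1.62 µm², V=0.06 µm³) = 7.48 -> resolvable
sphere floor: MCI = 0.7162 = 9/(4π)

MCI vs number of cristae lamellae (fixed 0.90 × 0.63 µm envelope):
  0 lamellae: MCI   0.76  ... -> below_threshold
  2 lamellae: MCI   3.05  ... -> below_threshold
  4 lamellae: MCI   8.07  ... -> resolvable
  8 lamellae: MCI  34.32  ... -> resolvable
```

MCI rises strictly with cristae count at a fixed envelope, which is what
makes it a usable proxy for cristae complexity.

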