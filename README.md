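# histostack

MRI-guided 3D reconstruction of serial histology sections.

Cutting a fixated specimen into stained sections destroys its
through-plane geometry: every digitized section carries an arbitrary
in-plane offset and rotation, smooth distortion from processing,
staining variation, and noise.  Registering each section only to its
neighbour gives a smooth-looking stack, but pairwise errors accumulate
into the **banana effect** — a straight structure (a vessel, a fiber
tract, a needle track) reconstructs as a curve, and genuinely curved
anatomy is silently straightened.  `histostack` instead anchors the
reconstruction to a 3D MR volume of the same specimen:

1. preprocess the sections (gray conversion, background masking,
   downsampling, histogram matching to a reference section),
2. align neighbours by multi-pass rigid registration with normalized
   mutual information, `NMI = (H(A)+H(B))/H(A,B)`, and stack,
3. bias-correct (Gaussian-filter multiplicative model, FWHM 5 mm) and
   mask the MR reference,
4. iterate: affine-register the MR to the stack, reslice it, re-refine
   every section — rigidly and with a gated B-spline free-form
   deformation — against its MR plane, restack, and monitor volume NMI
   until it plateaus,
5. map the result into MR space through the inverse affine, apply the
   transforms at full resolution, or project onward to a template space.

The non-linear step is *gated*: a deformation is kept only when it
improves NMI on tissue, so when background mismatch or poor contrast
makes warping counterproductive the pipeline falls back to the
rigid/affine chain automatically.

A first-class phantom generator (`histostack.phantom`) builds 3D
specimens with known ground truth — curved specimen axes, oblique rods,
per-section rigid/deformation/staining/noise corruption, bias-field
hotspots, multi-channel coil data with coupled noise — so every stage
is testable end to end without any external data.  The package also
implements the adaptive (eigenvector, Walsh-style) multi-channel coil
combination used to produce low-SNR-robust guiding volumes, with
sum-of-squares as the baseline.

## Worked example

```python
import numpy as np
from histostack.phantom import (PhantomSpec, CorruptionSpec, make_phantom,
                                histology_contrast, mr_acquisition,
                                virtual_section, corrupt_sections)
from histostack.preprocess import background_mask, threshold_mask
from histostack.core import SectionSeries
from histostack.reconstruct import refine
from histostack.metrics import ncc

spec = PhantomSpec(grid_dims=(44, 96, 96), voxel_size=(200., 120., 120.),
                   n_blobs=12, specimen_fraction=0.6, specimen_bend=300.,
                   seed=13)
vol, labels, _ = make_phantom(spec)
tissue = histology_contrast(vol, labels)          # sections see tissue only
mr = mr_acquisition(vol)                          # MR sees specimen + formalin
mask = threshold_mask(mr, method=90.0)            # formalin removal
mr_masked = mr.with_data(np.asarray(mr.data) * (np.asarray(mask.data) > 0))

series, _ = virtual_section(tissue, thickness=200., keep_every=1)
keep = [i for i in range(len(series))
        if np.isin(labels.data[i], [2, 3]).mean() > 0.1]
series = SectionSeries([series[i] for i in keep], spacing=200.)
corrupted, truth = corrupt_sections(series, CorruptionSpec(
    max_rotation=6, max_translation=900, deform_amplitude=200,
    deform_wavelength=5000, noise_sd=3, seed=14))
corrupted = corrupted.map(
    lambda s: s.with_pixels(s.pixels, mask=background_mask(s)))

result = refine(corrupted, mr_masked, max_iter=5, tol=1e-3)
m = np.asarray(result.volume_in_mr.data) > 0
print("iterations:", result.iterations)
print("NMI trace:", [round(x, 4) for x in result.nmi_trace])
print("NCC vs clean specimen:",
      round(ncc(result.volume_in_mr.data[m], tissue.data[m]), 4))
```

Output on this configuration:

```
iterations: 3
NMI trace: [1.3274, 1.3286]
NCC vs clean specimen: 0.987
```

The trace is the volume NMI between the evolving stack and the resliced
MR after each accepted iteration — it is non-decreasing by
construction, and the loop stopped when the gain fell below `tol`.  The
final NCC compares the reconstruction (mapped into MR space through the
inverse affine) with the uncorrupted specimen: the guided loop has
undone per-section offsets of up to ~7 pixels, 6° rotations and 2-pixel
smooth deformations.

The same pipeline is scriptable from the shell:

```
histostack phantom --grid 44 96 96 --seed 13 --out work/
histostack preprocess --manifest work/sections/manifest.csv --out work/prep
histostack biascorrect --volume mr.nii --fwhm-mm 5 --out mr_corr.nii
histostack reconstruct --sections work/prep/manifest.csv --mri mr_corr.nii \
    --tol 1e-3 --max-iter 10 --out work/recon
```

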