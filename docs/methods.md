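# Methods

## The problem

A series of stained histological sections is digitized as independent 2D
images: the cutting step destroys the through-plane geometry, each
section lands on its slide with an arbitrary offset and rotation, and
histological processing adds smooth in-plane distortion, staining
variation from section to section, and noise.  Aligning each section
only to its neighbours produces a visually smooth stack but lets small
errors accumulate — the *banana effect*, in which a straight 3D
structure reconstructs as a curve and, conversely, truly curved anatomy
is silently straightened.  `histostack` reconstructs the 3D volume
under the guidance of an MR image of the same specimen, which preserves
the true geometry the way blockface photography would, without the
extra acquisition hardware.

## Pipeline

1. **Preprocessing** (`preprocess`): equal-weight RGB→gray conversion;
   background masking by Otsu threshold + erosion + connected-component
   pruning + dilation; factor-`k` block-mean downsampling (the
   bilinear-at-half-pixel equivalent for `k = 2`, with better
   anti-aliasing); inter-section intensity normalization by monotone
   histogram matching of foreground intensities onto a reference
   section.  The reference is chosen automatically: among sections with
   at-or-above-median foreground entropy, the one whose masked mean is
   closest to the series median (a manual override exists).  Matching
   uses a midpoint-CDF value mapping: each occurrence of a source value
   maps to the same reference quantile, taken at the *centre* of its tie
   block, which keeps heavily tied (piecewise-constant) histograms
   unbiased and makes the map idempotent and exact for integer
   self-matching.
2. **Inter-section rigid registration** (`register.register_rigid_2d`):
   multi-pass NMI maximization over (θ, tx, ty) with a coarse-to-fine
   block-mean pyramid per pass and a Powell search at each level.  The
   first pass begins with a ±18° rotation sweep at the coarsest level.
   A pass is accepted only if it improves NMI at working resolution;
   two consecutive non-improving passes end the search (the plateau is
   typically reached by pass 3–4).  Accepted transforms compose
   symbolically; pixels are interpolated once at the end.
3. **Stacking** (`reconstruct.stack`): absolute transforms are composed
   outward from an anchor section (the middle one, halving drift
   accumulation relative to first-section anchoring); z = index ×
   spacing.
4. **Bias correction of the MR reference** (`bias_field`): multiplicative
   model, bias = mask-normalized Gaussian smoothing
   (`smooth(V·M)/smooth(M)`, σ = FWHM/2√(2 ln 2) per axis; default
   FWHM 5 mm) and division, iterated 4 times.  Iteration matters:
   smoothing attenuates the very bump it estimates, so one pass leaves a
   low-frequency residual that re-estimation shrinks geometrically.
   The bias is normalized to masked mean 1, so bias × corrected
   reproduces the input exactly and correction commutes with global
   intensity scaling; `preserve_mean` restores the masked mean.
5. **Masking** (`preprocess.threshold_mask` / `transfer_mask`): formalin
   removal by thresholding (Otsu, optionally computed over non-zero
   voxels only so an empty background does not dominate; or a fixed
   threshold, the analogue of a manually chosen one), largest-component
   retention, closing; masks estimated on a homogeneous low-field image
   transfer to the high-field grid by nearest-neighbour resampling
   through the inter-modality affine.
6. **Iterative guided refinement** (`reconstruct.refine`): per iteration
   (a) 12-parameter affine registration of the MR volume to the current
   stack (NMI, Powell, coarse-to-fine, with a plausibility penalty on
   |scale−1| > 0.2 and |shear| > 0.15 — shrinkage between modalities is
   bounded, and an unbounded affine can latch the formalin shell onto
   the tissue boundary); (b) MR reslicing in stack space and pairing of
   each section with the MR plane at its z (linear interpolation);
   (c) per-section rigid re-refinement against its MR plane (wide
   search on the first iteration, local polish afterwards) followed by
   the gated non-linear step; (d) restacking and volume-NMI evaluation.
   Iterations are accepted only if volume NMI improves; the loop stops
   at gain < `tol` (default 10⁻³), a non-improving iteration, or
   `max_iter` (default 10).
7. **Gated non-linear registration** (`register.register_nonlinear_2d`):
   the dense displacement is estimated by a multi-scale demons scheme —
   intensity-difference forces after (i) remapping the moving
   intensities onto the fixed distribution and (ii) matching
   resolutions by light smoothing, with Gaussian fluid/diffusion
   regularization — and then projected onto a cubic-B-spline control
   lattice (spacing ≥ 4 px), which enforces the smoothness the
   corruption model assumes.  The field is **accepted only if it
   improves NMI evaluated on tissue** (the intersection of the fixed
   mask and the moving section's foreground) by a configurable margin;
   otherwise a zero field is returned.  If a majority of sections
   reject, the result is flagged affine-only and all fields are
   dropped — the fallback observed on real specimens when background
   mismatch dominates.
8. **Output geometry**: the per-section chains live in stack space; the
   final volume is additionally mapped into MR space through the
   *inverse* of the fitted affine (`ReconstructionResult.volume_in_mr`).
   This step is essential, not cosmetic: an affine fitted to a drifted
   stack absorbs part of the drift as scale/shear, so the loop's fixed
   point is an affinely transformed copy of the true geometry; undoing
   the affine restores the MR frame.
9. **Full resolution and template space**: transforms are stored in
   physical µm and are therefore resolution-independent;
   `apply_fullres` applies each chain to the original-resolution pixels
   in one interpolation, and `project_to_template` composes the
   histology→MR and (externally supplied) MR→template maps into a
   single interpolation onto the template grid.

## Coil combination (`coilcomb`)

`sos_combine` is the root-sum-of-squares baseline.  `adaptive_combine`
estimates local C×C channel covariances by box filtering channel
products over a block (default 3×7×3 voxels), noise-whitens them with a
supplied or background-estimated noise covariance, takes the principal
eigenvector per block as the weight vector, phase-references it to a
chosen channel, Gaussian-smooths the weight field across the block
lattice, and combines voxelwise.  The lattice smoothing is load-bearing
at low SNR: an unsmoothed per-block eigenvector partially fits the
block's own noise and inflates the combined background noise.  In the
noiseless limit the adaptive output is voxelwise proportional to
sum-of-squares; its advantage appears at low per-channel SNR with
correlated channel noise, where whitening buys the measured 1.2–1.5×
SNR factors on the 32-channel phantom (the real-data factors reported
for such acquisitions are of the same order).

## Similarity and QC metrics (`metrics`)

NMI uses the Studholme normalization (H(A)+H(B))/H(A,B), entropies in
bits, range [1, 2]; a second normalization MI/H(A,B) on a unit scale is
exposed for comparability with tools that report NMI below 1.  Inside
the rigid/affine optimizers the joint histogram is soft-binned
(partial-volume weighting) with the bin count capped at ~√N — hard
binning makes the cost piecewise-flat below one pixel.  NCC is Pearson
correlation on masked intensities.  GLCM homogeneity is the Haralick
inverse difference moment, Σ p/(1+(i−j)²), 64 gray levels over the
masked range, four distance-1 offsets, symmetric counting (co-occurrence
counting is implemented directly so masks are honoured).  SNR is
mean(signal ROI)/sd(noise ROI) with an optional Rayleigh correction
(÷√(2−π/2)) for magnitude backgrounds.  `rod_straightness` fits a
total-least-squares line through per-slice rod centroids and reports
the RMS perpendicular residual in µm; with a soft (anti-aliased) rod
indicator the statistic stays sub-voxel after resampling, and slices
with less than 30% of the median rod mass are dropped as clipped.

## The phantom (`phantom`) — what it emulates, and what it does not

The generator reproduces the *artifact taxonomy* the pipeline
addresses, not anatomy:

- a specimen ellipsoid inside a "formalin" shell inside empty
  background, with distinct intensity levels; the specimen axis can bow
  parabolically along z (`specimen_bend`, sagitta in µm) — genuine
  anatomical curvature through the cutting direction is exactly what
  neighbour-only stacking silently straightens;
- ellipsoidal "white matter" blobs with random 3D orientations, so
  their cross-sections drift and deform from slice to slice as real
  structures do;
- multiplicative cellular-scale texture, smooth in-plane (~250 µm) but
  decorrelating across sections (~60 µm along z): adjacent real Nissl
  sections share macrostructure, not cell layouts;
- an optional straight rod (oblique and/or off-centre) as the
  banana-effect probe, plus `rod_indicator` for sub-voxel straightness
  measurement;
- per-section corruption: uniform rigid draws (optionally a random
  walk — the drift regime), band-limited smooth deformation fields
  (amplitude < wavelength/2π, hence invertible), gain/gamma staining
  stripes `g·(I/I_max)^γ·I_max`, Gaussian noise.  Synthesis warps use
  cubic interpolation — a physically misplaced section is lossless, so
  the generator should not impose an interpolation ceiling on recovery;
- `histology_contrast` cuts sections from a tissue-only volume (the
  formalin compartment exists only in MR images of the fixated
  specimen), and `mr_acquisition` blurs the phantom with an acquisition
  PSF so resliced MR planes behave like real MR data rather than
  aliased texture;
- multi-channel coil data: Gaussian-magnitude, phase-ramped
  sensitivities centred on a Fibonacci sphere around the specimen, and
  complex Gaussian noise with neighbour-ring coupling (|c| = 0.4) —
  receive arrays are never noise-independent, which is the premise of
  whitened eigenvector combination.

Every perturbation is recorded (`PhantomTruth`), so each stage is
scored against ground truth.  What the phantom does **not** model:
realistic neuroanatomy, tears/folds (generable but not required to be
recoverable), MR physics (relaxation, k-space sampling), calibrated
paraffin shrinkage.  Passing tests therefore demonstrate that the
algorithms recover known geometry and intensity corruptions of
realistic magnitude — not that any particular anatomical study would
reach the same accuracy.

## Numerical choices

- Coordinates: physical µm throughout (mm only at NIfTI boundaries and
  in mm-quoted parameters), pixel/voxel centres, 0-based indices;
  transforms act on physical points; resampling is pull-back with
  chains flattened to a single interpolation (exact for nearest,
  < 10⁻⁶ for linear).  Rotation pivots default to the foreground
  centroid.
- Optimization: derivative-free Powell over physically scaled
  parameters (NMI is non-smooth; pyramids provide the basin).  Pyramid
  levels never shrink below ~32 px — coarser levels destroy the
  similarity signal on small inputs.
- Field inversion by fixed-point iteration (converges under the
  no-folding condition |∇u| < 1; residual < 0.1 px for default
  regularization).
- Degenerate inputs: constant images give NMI = 1 with a warning; NCC
  on constant input raises; Otsu on constant volumes raises;
  empty-foreground matching raises; all-background masking warns and
  returns an empty mask.
- Ties: reference selection breaks ties to the lowest index; eigenvector
  phase referencing falls back to the largest-|weight| channel.

## Study conditions and problem sizes

The `studies` module fixes the conditions used by both the test suite
and `scripts/acceptance.py`: rigid recovery on 40 sections of 256×256
at 85 µm (|θ| ≤ 10°, |t| ≤ 20 px); the banana phantom with a 2 mm
specimen-bend sagitta (across the specimen's own z-extent), a subtle
oblique off-centre rod, many short-z-span blobs, and ±450 µm
random-walk drift over ~38 sections of 144×144; bias hotspot of peak gain 3 and
20 mm FWHM corrected with the 5 mm filter (CV measured on the interior
tissue ROI, eroded by 2 voxels, to separate the bias from
partial-volume gradients); gain stripes 0.5–2.0 over 40 sections;
convergence over three phantom seeds at 96×96 under geometric
corruption (intensity stripes are studied separately — histogram
matching under varying class proportions imposes its own intensity
ceiling unrelated to convergence); 32-channel coil simulation at
per-channel SNR ≈ 4–5.  These sizes keep the full suite and the
acceptance script each within tens of minutes on a single CPU while
leaving every effect measurable; they are scaled-down but
mechanism-complete versions of the full-size problem.

## Known limitations

- The demons force is intensity-difference based; the histogram
  pre-match mono-modalizes typical histology↔MR pairs, but strongly
  non-monotone intensity relationships would need a true
  information-theoretic force.
- The affine plausibility bounds (20% scale, 0.15 shear) assume
  moderate shrinkage; heavily deformed specimens would need them
  widened deliberately.
- Reference selection assumes the majority of sections are well
  stained; a series dominated by poor sections can select a poor
  reference (the manual override exists for exactly that case).
- `match_slices` pairs planes by z only; large out-of-plane rotations
  of the specimen between modalities are handled by the affine, not by
  oblique reslicing per section.
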