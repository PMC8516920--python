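# Methods

This note documents the model, the synthetic data, the numerical choices,
and the limits of what the bundled experiments demonstrate.

## The translation model

The task is paired image-to-image translation: given a non-contrast chest CT
(NCCT) volume, predict the same anatomy as it would appear after iodinated
contrast (CECT). The model is the pix2pix conditional-GAN family member with
3D convolutions throughout.

**Windowed 3-channel representation.** CT HU span ~4000 values but the
clinically relevant contrast lives in narrow bands. Each volume is therefore
presented to the network as three window-normalized channels — lung/bone
(width 2000 / level 0), vascular (1000/200), mediastinal (500/50) — each
clamped and scaled to [−1, 1] (clamp-then-scale; the order is stated so
bit-exact tests are meaningful). Only channel 0 is converted back to HU at
inference, which pins the synthetic output range to [−1000, 1000] HU. Values
are float32 after normalization; HU are rounded to integers only when
writing 16-bit NIfTI.

**Generator.** A U-Net whose encoder blocks are strided convolution →
LeakyReLU(slope 0.2) → instance normalization and whose decoder blocks are
nearest-neighbor resize → convolution → ReLU → instance normalization, with
skip connections concatenating encoder block *i* onto decoder block *n−i*
followed by a ReLU, and a Tanh output. Depth and filter widths are
configuration-driven: the full-scale default is 8 blocks, base 64 filters
doubling to a cap of 512, for 512×512×16 inputs; in-plane axes halve at
every block while the slice axis halves only while its extent is even and
greater than one. Instance normalization carries learnable per-channel
affine parameters: a ReLU directly follows the normalized skip
concatenation, and without an affine shift the zero-mean normalized features
would lose half their support at that ReLU.

**Discriminator.** A PatchGAN on the 6-channel concatenation of the
condition (NCCT channels) and candidate (real or synthesized CECT channels).
The in-plane stack is the canonical 70-pixel recipe (three k=4/s=2 blocks,
then k=4/s=1, then a k=4/s=1 single-channel logit map). Through-plane,
kernels of 2 (stride 1) on the first three blocks and 1 afterwards give a
4-slice footprint, so each logit judges a 70×70×4 patch. The analytic
receptive-field recursion (r ← r + (k−1)·jump, jump ← jump·s) is implemented
and cross-checked against an empirical probe that backpropagates from a
single output unit and measures the nonzero-gradient extent; during the
probe, normalization statistics are held fixed, since the spatial mean
coupling of instance norm is not part of the convolutional geometry being
measured.

**Losses and schedule.** Generator loss = adversarial + 100·L1 (the fixed
1:100 weighting); adversarial terms are BCE-with-logits averaged over patch
cells (a least-squares variant is available behind `gan_mode="lsgan"`).
Discriminator real labels are smoothed one-sidedly to 0.9; fake labels stay
0. Adam with lr 2·10⁻⁴ and β₁ 0.5, batch size 1, 20 epochs, and a single
×0.1 learning-rate step after epoch 10. The decay wording admits several
readings (single step, per-epoch exponential, per-iteration); the single
step is implemented, and `decay_rate`/`decay_start_epoch` expose it. Each
epoch enumerates, in seeded shuffled order, every 16-consecutive-slice
window of every training volume (N−15 windows per N-slice volume).
Augmentation draws one integer in-plane shift per sample, uniform within
±`max_shift_px` (default 50), applied identically to input and target with
the vacated area filled at the window floor (−1 = air); shifting the pair
jointly is required to keep the voxelwise L1 correspondence meaningful.

**Inference.** All N−15 windows are synthesized and overlapping slices
averaged (accumulation in float64, so the result is order-independent to
~1e−6 HU) before the single reconversion of channel 0; averaging happens in
normalized space, which differs from averaging in HU space only in clamp
order. Volumes with fewer than 16 slices are rejected rather than silently
padded. Channels 1–2 of the output are computed and discarded (a debug flag
returns them).

## Synthetic phantoms

The generator of paired phantoms emulates the data contract of the clinical
development set — dual-energy virtual-non-contrast and CECT reconstructions
of one scan, i.e. *perfectly registered* pre/post pairs — not CT physics.
Geometry is schematic: an elliptical body cylinder with a subcutaneous fat
rim, two lung ellipsoids, a cardiac blood-pool ellipsoid indenting the lungs,
a descending-aorta cylinder, tubular pulmonary vessels, and spherical
mediastinal lymph nodes, all with exact label masks. Between NCCT and CECT
only the vascular compartment (aorta, vessels, blood pool; +205 HU by
default: 45 → 250) and the nodes (+45 HU: 45 → 90) change; each volume then
receives independent Gaussian noise (sd 10 HU), is rounded to integer HU and
clipped to [−1024, 3071]. Tissue values are conventional textbook numbers
(soft tissue 40, lung −800, fat −100 HU) and are configuration-exposed, not
claims about any patient population. The cardiac blood pool is included
because, in the evaluated slab (top of aortic arch to diaphragm), the
opacified cardiac chambers dominate the post-contrast change of real chest
CT; without it the paired difference would be a sparse fraction of a percent
of voxels and the phantom would not exercise the method on the signal it is
meant to learn.

What the phantom does *not* model: beam hardening, scanner kernels, spatially
correlated noise, respiratory motion, anatomical variability of organ
shapes, or partial-volume texture. Tests passing on phantoms therefore
demonstrate the pipeline's correctness and the method's learning dynamics,
not clinical image quality.

Annotations record each node's center voxel, short-axis diameter (mm), and
measuring slice; nodes are filtered at >5 mm (per-lesion lists) and >10 mm
("significant lymphadenopathy"). Voxel coordinates are 0-based, the axial
slice axis is last, slices run cranial→caudal, and all modules share that
convention.

## Evaluation

Similarity metrics are computed on the mediastinal evaluation window
(350/50) remapped to the 0–255 display scale — so MAE/PSNR magnitudes are
on the conventional 8-bit scale, not HU — per axial slice in 2D, restricted
to the slices spanned by the aorta mask, then pooled as median (IQR) with
the linear-interpolation quartile convention. MS-SSIM uses the canonical
5-scale weights (0.0448, 0.2856, 0.3001, 0.2363, 0.1333), an 11-tap Gaussian
window with σ = 1.5, 2× average-pool downsampling, the luminance term at the
coarsest scale, and shrinks the scale count (renormalizing weights, with a
warning) when a test image is too small for all five dyadic scales. The
perceptual distance (LPIPS form) sums unit-normalized per-layer squared
feature differences over a pluggable extractor; the bundled extractor is a
deterministic fixed-seed random-convolution pyramid — reproducible and
dependency-free, but not a trained perceptual model; a learned backbone can
be injected at call time and is never downloaded implicitly.

CNR follows the two printed formulas exactly: the RMS of the two fat-ROI
standard deviations as background noise, and |HU_DTA − HU_lesion| over that
noise. Lesion ROIs measure 90% of the node's short-axis diameter (converted
to voxels by in-plane spacing, rounded half-up, floor one voxel) on the
measuring slice; DTA and bilateral chest-wall fat ROIs are placed
automatically at the largest inscribed circle of the respective mask region
on that slice, capped at the lesion ROI size; the identical ROI geometry is
reused across NCCT/sCECT/CECT. Zero background noise (noiseless phantoms)
is surfaced per lesion as an undefined CNR with an error message.

## The desk-scale study and its convergence limits

The bundled smoke study trains the reduced model (64×64×16 phantoms at
4×4×8 mm, 3 encoder blocks, base 32 filters capped at 128, reduced
discriminator) for 5 epochs over 48 training pairs (240 generator updates)
and evaluates on 4 held-out pairs. Choices that deviate from the full-scale
defaults, and why: learning rate 5·10⁻³ with the decay step after epoch 3
(the full schedule's 2·10⁻⁴ over ~60 000 updates is scaled for a run two
orders of magnitude shorter); shift augmentation ±6 px (±50 px scaled by
image width); He-scaled weight initialization (a fixed std of 0.02 starves
early gradients at reduced filter counts).

At this scale the directional outcomes split. Structural similarity moves
decisively in the method's favour almost immediately (the generator denoises
and reproduces the enhancing anatomy's layout), and MS-SSIM(sCECT) >
MS-SSIM(NCCT) holds with a wide margin. Pixelwise MAE and node CNR are
late-training properties: MAE requires near-voxel-precise reconstruction of
thin structures (the fat rim, body boundary), and CNR requires the model to
enhance the 22-mm aorta *more than* adjacent nodes — a fine shape/size
discrimination at 4-mm voxels. In held experiments the windowed MAE of the
synthetic volume fell from ~15 (80 updates) to ~9.5 (400 updates) against a
non-contrast baseline of ~7.5, still declining roughly linearly in
log-updates; extrapolation puts the crossover near 10× the smoke budget,
which the 5-epoch cap and CPU wall-clock make unreachable here. The
end-to-end acceptance test reports all three directions per seed; the MAE
and CNR directions are expected to remain unmet at this compute scale, and
this is a scale limitation of the surrogate, not a property of the method at
its intended size.

## Other numerical choices and limitations

- Convolutions are lowered to BLAS matrix products (im2col for strided
  layers, zero-copy flat-offset GEMMs for unit-stride layers); gradients
  were verified against finite differences.
- The whole stack is single-precision except loss/averaging accumulations.
- Training is bit-reproducible for a fixed seed and configuration on a
  fixed BLAS; loss histories are asserted identical in tests.
- A single run seed fans out to per-stage seeds via a fixed hash, so stages
  are independently reproducible.
- The reduced-config generator and discriminator are small enough that a
  512×512×16 forward pass of the full-scale architecture is exercised in
  tests only with shrunken filter counts (the shape contract is
  filter-independent).
- DICOM reading applies rescale slope/intercept and sorts slices by
  position; mixed series, inconsistent pixel spacing, and non-monotone
  positions are rejected. No DICOM writing, PACS integration, or
  anonymization is provided.
- The observer study, JAFROC analysis, and dual-energy VNC reconstruction
  that accompany the clinical evaluation of this method are out of scope.
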