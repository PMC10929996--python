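# Methods

## Problem and model

`coretr` segments the gross tumor volume (GTV) of non-small-cell lung cancer
in 3D CT. The network is a hybrid of convolutional feature extraction and
deformable-transformer context modeling, assembled from three components:

**Encoder.** Two CNN backbones see the same patch at two resolutions. The
*shallow* branch runs on the 2x-trilinearly-upsampled patch: a stem of
Conv–InstanceNorm–ReLU layers (a 3³ layer, a 1³ channel-mixing layer, then 3³
layers; five in total at full depth) followed by six residual stages whose
first convolution strides by 2 (stage 1 excepted), doubling channels at each
downsampling up to a cap. The *deep* branch runs on the 2x-average-pooled
patch with the same stem and nine residual blocks grouped 2-2-2-1-1-1 over
the six scales. Residual blocks are Conv-IN-ReLU -> Conv-IN plus an identity
shortcut (1³ projection when shape changes), with 5³ kernels at full scale.
The deep branch's last stage does not stride: its ladder is 1,2,2,2,2,1, so
the coarsest deep map of a 96³ patch keeps a 3³ extent instead of collapsing
below one voxel.

**Ms-FPN.** Every backbone map is projected to a common channel width by a
1³ convolution and fused additively: top-down within each branch (coarse map
upsampled 2x trilinearly and added to the next finer scale) and across
branches (each fused deep map added, upsampled 2x, into the shallow map with
exactly twice its grid size). Because the two branch inputs differ by 4x in
resolution, cross-branch pairing is resolved by actual spatial dims, not by
stage index — top-down plus cross-backbone additive fusion, propagating from
high level to low level and from low resolution to high resolution. The
"2x Upsample" notation is read as *upsampling by a factor of two*; the
alternative scalar reading (upsampled values additionally doubled) is kept
available as `fpn_upsample_gain=2.0`.

**Deformable transformer.** The `token_scales` coarsest fused shallow maps
are flattened scale-major in H,W,D raster order. Spatial identity comes from
a sinusoidal 3D positional encoding: each axis owns C/3 channels (rounded to
an even width, remainder zero-padded) with frequencies `v_k =
10000^(-2k/(C/3))`, giving `sin(pos·v_k), cos(pos·v_k)` pairs; k=0 reduces to
`sin(pos)`. The three axis tables are concatenated per token. Encodings
enter through the *query* path of each attention layer (the deformable-DETR
convention): offsets and attention logits are predicted from `LN(x) + PoE`,
while the value stream stays encoding-free — this keeps the documented
property that zeroing all residual branches makes the entire stack an exact
identity. Each DeTrans layer is pre-norm: `x -> x + Attn(LN(x)) -> · +
FFN(LN(·))`. Attention per query predicts, per head and scale,
`n_sampling_points` continuous offsets around the token's own normalized
location plus logits softmax-normalized over scales x points; values are
trilinearly sampled from per-scale value grids, so cost is linear in sequence
length. Offset and logit nets start at zero (sample own location, uniform
weights), the stable-start convention.

**Decoder.** Tokens are reshaped back to grids (the exact inverse of the
flatten raster), then kernel-2/stride-2 transpose convolutions double
resolution step by step; at each scale the fused encoder map is merged by
concatenation + 1³ projection and refined by a residual block. Output logits
live at the patch's native resolution; with multi-resolution input enabled
the finer-than-native shallow map is average-pooled 2x and merged as an
extra skip at the final stage. A 1³ convolution yields single-channel
logits; sigmoid/thresholding happen outside the network.

## Numerical core

No GPU deep-learning framework is used: the network runs on a small
reverse-mode autodiff engine over float32 numpy arrays (`coretr.autodiff`),
with exactly the primitives the architecture needs. Convolutions use an
im2col single-GEMM formulation, falling back to a shifted-GEMM loop when the
unfolded buffer would exceed ~800 MB (large inference patches). Trilinear 2x
upsampling uses edge-clamped half-voxel-aligned weights (0.75/0.25), whose
transpose is the exact backward map. Grid sampling is differentiable in both
the grid values and the sampling coordinates (zero coordinate-gradient where
boundary clamping is active). Every primitive is verified against central
finite differences of a random linear functional (a random functional avoids
degenerate losses whose true gradient vanishes). All computation is
single-threaded-deterministic: fixed seeds give bit-identical runs on the
same platform.

## Preprocessing and training protocol

CT intensities are clipped to the fixed window [-1024, 3068] HU and min-max
normalized with those same fixed bounds (not per-volume extrema), so a given
HU value means the same normalized intensity in every scan. Resampling to
uniform spacing (default isotropic 1 mm, configurable) uses SimpleITK's
Hamming-windowed-sinc interpolator for images — note ITK's windowed-sinc
kernel is not renormalized, so a constant image is preserved only to ~0.5% —
and nearest-neighbor for masks (exactly binarity-preserving). Volumes
smaller than the patch are zero-padded (0 = air after normalization).

Training samples 4 random patches per volume per epoch, each patch centered
on a random tumor voxel with probability `fg_fraction` (default 0.5 —
unbiased sampling would starve the loss of foreground, since tumors occupy a
tiny fraction of a chest volume). Optimization is SGD (initial LR 1e-3,
Nesterov momentum 0.99, weight decay 3e-5, gradient-norm clipping at 12)
under polynomial LR decay (power 0.9), batch size 1. The loss is soft-Dice
(smoothing 1) plus voxel-wise BCE in the logit-stable form
`softplus(z) - z·t`; Dice+BCE is the standard choice for heavily
class-imbalanced 3D segmentation. A non-finite loss aborts with a
diagnostic. Nine augmentations (rotation, scaling, flipping, Gaussian noise,
Gaussian blur, brightness, contrast, simulated low resolution, gamma) run
spatial-first so injected noise is never interpolated; magnitudes follow
common practice for patch-based 3D segmentation and every transform is
individually togglable. "Brightness and contrast adjustment" is implemented
as two independent transforms. Whole volumes are segmented by sliding-window
tiling with probability averaging in overlaps and thresholding at 0.5.

## Synthetic phantoms

Phantoms emulate what the method needs from lung CT and nothing more: a
soft-tissue body ellipsoid (~40 HU) on air (-1000 HU), two low-density lung
ellipsoids (-800 HU), and 1–3 axis-aligned tumor ellipsoids of soft-tissue
density (0–100 HU) placed fully inside a lung with a one-voxel halo
(verified on the voxel grid, so multi-tumor masks are guaranteed distinct
6-connected components), plus optional additive Gaussian noise. The mask is
built geometrically, never by thresholding, so it is invariant to the noise
field and its volume has the analytic ellipsoid form — the oracle used to
validate voxelization (within 5% for radii of a few voxels and up). Dataset
sampling sweeps tumor radii end to end so generated cohorts span sub-1 cc to
>50 cc lesions, mirrors the single- vs multiple-tumor evaluation split, and
draws anisotropic spacings (slice thickness 1.5–3 mm).

What phantoms do *not* model: realistic tumor shape and texture, pleural or
vascular attachment, respiratory motion, scanner reconstruction physics,
contrast variation. Passing tests therefore demonstrate that the
architecture, optimization, inference and evaluation machinery are correct
and that the model class can represent and learn blob-like lesions in
context — not clinical-grade performance on real NSCLC data.

## Evaluation

Dice is 2|X∩Y|/(|X|+|Y|); both-empty is defined as 1, one-empty as 0. The
Hausdorff distance is the symmetric directed max over Euclidean distances
between foreground voxel centers, in physical mm (computed by exact distance
transform, validated against an O(n²) brute-force oracle to 1e-9); HD95
replaces each directed max with the 95th percentile. HD against an empty
mask is *undefined* and reported as NaN with a flag — never silently 0 or
infinity — and aggregate means skip undefined cases while reporting their
count. Cases are stratified by the number of 6-connected ground-truth
components; multiple-tumor cases also get per-lesion metrics with predicted
components matched by maximal overlap.

## Problem sizes used by the test suite and acceptance script

All pipelines run at desk scale on one CPU: 32³ phantom volumes at 2 mm
spacing, 16³ training patches, and a reduced model (base 8 channels or
narrower, 4 shallow / 6 deep residual blocks over 4 scales, 3³ residual
kernels, 12 pyramid channels, 2 DeTrans layers). The 96³ shape contract runs
the full six-scale, nine-block, 5³-kernel depth at 2 base channels. The
overfit check trains on five noise-free phantoms until training Dice
exceeds 0.9 (at most 200 epochs in the suite, 100 in the acceptance script;
convergence typically lands at 40–90); the ablation check trains full,
transformer-less, and single-resolution variants (3 seeds each) on a shared
noisy training set and compares mean Dice on a fixed 20-phantom test set —
a directional comparison; toy-scale magnitudes are not expected to match
clinical-scale results. These short toy runs use a constant learning rate
and a 0.7 foreground-sampling fraction: the polynomial schedule decays over
the run's own horizon, so at a few hundred total steps it would spend half
the run near zero LR and leave every variant equally untrained.

## Known limitations

- CPU-only numpy execution: full-scale (96³ patch, 32-channel) *training* is
  out of reach; the full-depth architecture is exercised forward-only.
- DICOM / RT-STRUCT ingestion is out of scope; NIfTI is the interchange
  format, conversion is upstream.
- Binary GTV-vs-background only; no organs-at-risk, no deep supervision, no
  test-time augmentation or ensembling.
- Checkpoints store weights + config + history, not optimizer state, so a
  resumed run is not bit-identical to an uninterrupted one.
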