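# Methods

## Problem and pipeline

The package analyses 2D midsagittal radiographic captures of the upper
airway, the view a clinician inspects when screening for obstructive sleep
apnoea risk.  The analysis has four stages:

1. **Semantic segmentation.**  A U-Net labels every pixel as background (0),
   nasopharynx (1), retropalatal pharynx (2) or retroglossal pharynx (3).
   The three airway segments are bounded by anatomical levels (nasal
   turbinate, hard palate, soft-palate margin, epiglottic base) and stack
   vertically in that order.
2. **Morphological postprocessing.**  Binary erosion/dilation with a 3×3
   element: small connected components (below `min_area_px`, default 25 at
   native resolution, 10 in the phantom tests) are removed per class, one
   opening round smooths the remaining boundary.  Inner and outer boundary
   extraction (mask XOR its erosion / dilation XOR mask) is exposed as a
   utility.
3. **CSAmin localisation.**  The airway "width" at a level is the count of
   airway pixels in that image row.  The predicted CSAmin height is the row
   with the minimum positive count, searched by default over the
   retropalatal + retroglossal band (the clinically relevant collapse
   sites); ties break to the topmost row (configurable).  Rows found on a
   reduced-resolution map are mapped back to the native frame by
   `round(row × native_height / frame_height)`.
4. **Evaluation.**  Pixel metrics (precision, recall, IoU, DSC, size
   difference) per class with an unweighted macro "overall" mean over the
   three airway classes, and agreement statistics for heights: Cohen's
   kappa on the 2×2 segment table, Bland–Altman limits of agreement,
   ICC, paired/two-sample t-tests, below-threshold error proportions.

## Coordinate and unit conventions

Row 0 is the top image row.  Heights are row indices on the 910-row native
frame.  Pixel spacing defaults to 200/910 ≈ 0.21978 mm/px; this value
reproduces all 80 printed px→mm conversions in the packaged height-error
table after 2-dp rounding and is recovered by a through-origin least-squares
fit of the mm column against the px column.  SDs are sample (n−1)
throughout.  Bland–Altman limits are mean ± 1.96·SD of the differences and
a point on a limit counts as within.

## The network

The encoder has `depth_levels` levels (default 4) with channels doubling
from `base_channels` (default 32), 2×2 max-pooling between levels, a
bottleneck block, and a mirrored decoder using ×2 bilinear upsampling and
skip concatenation; each block is `convs_per_block` × (3×3 convolution →
batch norm → ReLU), with 2 convolutions per block in the shallow variant
(`unet18`) and 4 in the deep one (`unet36`); the variant names are treated
as family labels, not as an enforced total layer count.  A 1×1 convolution
emits 4 class scores per pixel; prediction is the per-pixel argmax, resized
back to the native frame by nearest-neighbour.  The loss is per-pixel
cross entropy (optional inverse-frequency class weights, off by default)
and the optimiser is Adam (reference recipe: learning rate 1e-4, batch 8,
200 epochs, with resize/crop/flip/rotate augmentation).

The whole engine is plain numpy with hand-written backward passes (im2col
convolution, explicit batch-norm gradient, pooling masks, the transpose of
the upsampler); gradients are verified in the tests against central
differences in float64.  This keeps the dependency footprint to the
scientific Python stack and is fast enough for the problem sizes below.

**Row-coordinate input channel.**  The network input has two channels: the
grayscale image and a normalised row coordinate (0 at the top row, 1 at the
bottom).  In real captures the segment boundaries are visible anatomy; in
the phantom they are pure row conventions with no intensity signature, so a
translation-equivariant convnet has no robust signal for them.  The
coordinate channel supplies vertical position directly (the CoordConv
construction).  Without it the middle (retropalatal) class collapses on
phantom data; with it all three classes are learned.

## The phantom generator

Each phantom emulates the features of a midsagittal capture that the
pipeline actually consumes: a dark, smoothly curving air corridor
(radiolucent, default intensity 0.15) on a brighter soft-tissue background
(0.75), Gaussian pixel noise (SD 0.05), slight edge blur (σ = 1 px), and a
single dominant constriction at a known row.  The per-row corridor width is
a smoothly varying baseline (default 60 px at 910×910) with a Gaussian
notch (σ = 12 rows) down to `constriction_width_px` (default 12); after
integer rasterisation every non-constriction row is clamped to at least one
pixel wider, so the narrowest row is unique by construction and round-trip
tests need no tie handling.  Segment labels are assigned by row band;
boundary rows default to 380 and 560 with the corridor spanning rows
180–780.  Datasets vary corridor shape, baseline width and the constriction
row/width between samples while keeping the segment boundary rows fixed,
mimicking a cohort imaged with a common landmarking protocol.

The perturbation operator emulates an imperfect automatic segmentation:
row-correlated jitter of the corridor's left/right edges (SD in px),
false-positive blobs of a fixed area placed clear of the corridor and
labelled with the nearest band's class, and false-negative holes carved
from the foreground.  The all-zero spec is the identity.

What the phantom does **not** model: cervical vertebrae, dentition and
other bright distractors, intensity inhomogeneity, anatomical variation of
the boundary levels, and any visual cue at the segment boundaries (see
above).  Passing phantom tests therefore demonstrates that the pipeline's
mechanics are correct — not that the network reaches clinical accuracy on
patient images.

## Problem sizes and presets

The desk preset runs the full learning loop on one CPU: 96×96 phantoms
(corridor ~15 px wide, so that single-pixel boundary errors do not dominate
IoU), 64×64 network input, 3 levels, 8 base channels (~123k parameters),
learning rate 1e-3, batch 8, 40 epochs.  Sixty training phantoms and
twenty held-out phantoms train in ~1.5 min and reach a held-out macro IoU
around 0.88.  The overfit oracle trains on a single phantom generated at the
network resolution (64×64, so per-class Dice is not capped by resampling
quantisation) at the reference learning rate (1e-4) for 600 epochs, and
checks ≥98% same-phantom pixel accuracy and per-class Dice ≥ 0.95.  Phantom round-trip checks run 100 native-resolution
(910×910) phantoms: clean maps must localise exactly; with 1-px edge
jitter, three 5-px blobs, two holes and denoising, at least 95% must land
within 3 rows of the truth.

## Numerical and degenerate-input choices

- Morphology uses zero padding outside the frame (erosion removes the
  outermost ring of a full-frame mask); the structuring element defaults to
  the 3×3 square and is configurable to the 3×3 cross.
- Undefined 0/0 metric ratios are reported as `None` and excluded from
  macro means with a warning, never imputed as 0.
- Size difference is reported as an absolute pixel-count gap by default
  (signed available by flag), computed on the frame of its inputs.
- A paired t-test of two identical series reports t = 0, p = 1 rather than
  propagating the 0/0.
- The ICC defaults to the single-measure absolute-agreement form of the
  two-way model (ICC(A,1)); other forms are selectable.
- The segment of a CSAmin row is the majority airway class of that row,
  with ties assigned to the more inferior class.
- `locate_csamin` raises a descriptive error when the searched band
  contains no airway pixels (e.g. an all-background prediction).
- Label maps on disk use pure red/yellow/green with a per-channel tolerance
  of 10 for hand-edited inputs; unknown colours are an error naming the
  pixel, rather than silently mapping to background.

## Known limitations

- The unweighted Cohen's kappa of the packaged 2×2 segment table is 0.9419;
  the reference analysis printed 0.944.  The 0.002 gap (rounding or a
  variant computation upstream) is reported, not forced.
- The printed SD of the automatic-segmentation height error in mm (2.21)
  recomputes as 2.22 from the pixel column; the pixel-column SD (10.08)
  and all other summary cells reproduce exactly.
- Training determinism is per-machine (BLAS reduction order may differ
  across builds); the determinism tests compare runs within one session.
- The phantom's geometry parameters are plausible rather than calibrated:
  no pixel statistics of real airway widths were available.
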