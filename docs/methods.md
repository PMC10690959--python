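# Methods

`mvtseg` implements a two-stage ("cascaded") pipeline for segmenting the
two substructures of the hippocampal formation — the hippocampus proper
(class 1) and parts of the subiculum (class 2) — in a T1-weighted-like
3-D volume:

1. a **localization network** regresses an axis-aligned volume of
   interest (VOI) box `C = [x_c, y_c, z_c, w_c, h_c, d_c]` (continuous
   voxel-space center and extents) around the whole organ;
2. a fixed-size crop around the predicted center is segmented by a
   **morphological vision transformer (MVT)**, and the cropped
   segmentation is consolidated back into the original frame (class 0
   everywhere outside the VOI).

Everything below states the model, the defaults, and the reasoning
behind the genuinely open design choices.

## Numerical core

No deep-learning framework is used.  `mvtseg.nn` is a compact
reverse-mode automatic-differentiation core over float32 NumPy arrays,
providing exactly the operations the two networks need (3-D strided
convolutions and transposed convolutions as offset-decomposed BLAS
matmuls, multi-head self-attention, layer norm, GeLU/sigmoid/softplus,
and learnable grayscale morphology with subgradient flow through the
arg-extremum) plus Adam.  Training is single-threaded-deterministic:
given a seed, histories and parameters are bit-reproducible on the same
BLAS configuration.

## Localization model

**Hierarchy.** An initial 1³ convolution (no activation) forms `F_0`;
then `K` iterations `F_k = GeLU(Conv_{stride 2}(F_{k−1}))` halve the
grid per level (`K = 3`, constant channel width per level, default 8–16
channels).  A constant width is required because the fusion step sums
levels elementwise; the fused map is
`F_m = Σ_k CubicResample(F_k)`, with each level resampled to the size of
`F_1` by separable cubic convolution (Keys kernel, a = −1/2; the
resampling matrices have unit column sums, so constants are preserved
exactly, and the operation is a fixed linear map with an exact
transpose for the backward pass).

**Input features.** The stem sees seven channels: the min–max-normalized
intensity `I`, three normalized coordinate ramps `g`, and the products
`I·g`.  A head that global-average-pools cannot recover absolute
position from translation-equivariant features alone; the coordinate
and first-moment channels restore that information in closed form.

**Head.** The fused map is pooled as its zeroth and first spatial
moments — global averages of `[F, F·g̃x, F·g̃y, F·g̃z]` with centered
ramps `g̃ ∈ [−0.5, 0.5]` scaled by 64 — followed by a two-layer fully
connected stack.  Centered ramps make the first moments of a
homogeneous background vanish, so the pooled statistics are dominated by
the object.  The 6 raw outputs are scaled by a gain (default 256) and
mapped to box parameters as

- center = `sigmoid(raw) · (w, h, d)` — always inside the volume,
- extent = `softplus(raw) + 1` — always ≥ 1.

The final layer is zero-initialized: the untrained localizer predicts
the volume midpoint with near-unit extents, and training only has to
move small raw values (the gain converts them to voxel-scale outputs —
necessary because Adam at the default learning rate 2·10⁻⁴ moves each
parameter by at most `lr` per step, and the pooled object statistics are
of order 10⁻³).

**Structured initialization.**  The stem is initialized as an identity
passthrough of its 7 input features, and channel 0 of the first
hierarchy level as a matched filter for a compact bright object: a 3³
average of the intensity followed by a GeLU threshold at the normalized
mid-intensity (gain 50, bias −25).  Coordinate channels propagate
through center taps.  Rationale: with global pooling, background noise
power is not reduced by linear smoothing — only a nonlinearity that
suppresses the background before pooling makes the object moments
high-SNR, and gradient descent from a generic random start is very slow
to discover that structure at the fixed learning rate.  All of this
remains trainable; it is an initialization, not a frozen prior.

**Loss.**  `L_loc = ‖c − ĉ‖₂ + λ · Σ_axes sqrt(|e² − ê²|) / dim`, with
λ = 0.5.  The center term is a raw Euclidean distance in voxel units;
the size term is normalized by the image dimensions.  The absolute
value inside the root is a minimal repair: the printed form
`sqrt(w² − ŵ²)` is undefined when the predicted extent exceeds the true
one; `|·|` keeps the term symmetric and zero exactly at equality.  The
square root has an unbounded slope at equality; the implementation uses
a zero subgradient at 0.

**Ground-truth boxes** are tight boxes over the union foreground
(classes 1 ∪ 2) expanded by a 2-voxel margin and clipped to the volume;
center = (min+max)/2, extent = max − min + 1.

## Cropping and consolidation

Inference crops are **fixed-size** (default 32×32×24) windows around the
predicted center — not the predicted extent — so the segmenter always
sees uniformly sized inputs; predicted extents are still trained and
reported.  The window start is `floor(center − target/2)` per axis;
out-of-volume overhang is zero-padded.  A `CropRecord` stores the
source shape, clipped window, and padding, making
`consolidate ∘ crop_to_box` the exact identity on the window interior
(property-tested over random geometry, including corner boxes).

## Morphological vision transformer

**Learnable morphology.**  Non-flat grayscale operators with trainable
k³ structuring elements (SEs, default 5³):

- dilation `y(p) = max_q x(p+q) + se(q)`,
- erosion `y(p) = min_q x(p+q) − se(q)` (implemented through the exact
  duality `erode(x, se) = −dilate(−x, se)`),

with out-of-bounds window positions excluded from the extremum (−∞/+∞
padding semantics).  The layer is depthwise — one dilation SE and one
erosion SE per channel — and the two branch outputs are concatenated
(2× channels); cross-channel mixing is left to the following projection
convolution.  Gradients flow to both the SE weights and the input
through the selected window position (subgradient of the extremum).
SEs are initialized near-identity: small random negative weights with
`se(origin) = 0`.

**Architecture.**  `enc_layers` stride-2 3³ convolutions with GeLU →
morphology block (replaced by identity when `use_morphology=False`; the
ablation model then has strictly fewer parameters) → 1³ projection
convolution to the token width → each remaining spatial position
becomes one token; a linear projection plus learned absolute positional
embeddings feed `n_tx_layers` pre-norm transformer encoder blocks
(multi-head self-attention + 2× MLP) → unflatten → mirrored stride-2
transposed convolutions (kernel 4) → 1³ convolution to 3 classes →
per-voxel softmax.  Output spatial size equals input size for every
valid configuration.  Package defaults: `enc_channels (16, 32)`,
`token_dim 96`, 4 heads, 3 transformer layers.

**Losses.**  Generalized cross-entropy
`GCE = mean_voxels −Σ_c l_c log l̂_c` (natural log, predictions clipped
to ≥ 10⁻⁷) and generalized Dice loss per foreground class
`GDL_c = 1 − 2(Σ l·l̂ + ε)/(Σ l² + Σ l̂² + ε)`, ε = 10⁻⁶, averaged over
classes 1 and 2 and combined as `w_gce·GCE + w_gd·GDL` with default
weights (1, 1).  Background is excluded from the GDL because the loss
exists to counter foreground/background imbalance; including the
background channel would let it dominate.  Reductions are means (over
voxels for GCE, over foreground classes for GDL) so the weights are
scale-free.  A foreground class empty in both truth and prediction
contributes 0 (perfect agreement); the raw formula would yield −1 from
the ε terms alone.

**Training.**  The two models are trained separately; the cascade is
assembled at inference.  Segmenter training crops around ground-truth
box centers jittered by ±2 voxels per case per epoch, so the model
tolerates localization error.  Optionally each epoch adds
rigid/scale-augmented replicas per case (rotation ≤ 10°, scale ≤ 10 %,
shift ≤ 2 voxels; trilinear for images, nearest-neighbor for labels) —
the same augmentation family the synthetic cohort's pose variation
models.  Adam, lr 2·10⁻⁴, batch 4 by default; the best-on-validation
state is returned (validation fraction 0.2 of the training split).

## Synthetic phantoms

Each phantom is one compact organ in a 48³, 1 mm isotropic volume: two
half-ellipsoids sharing their cross-section semi-axes on a split plane
through the object centroid (anterior = class 1, semi-axes 6–10 voxels;
posterior = class 2, along-axis semi-length 5–9 voxels).  When the two
along-axis lengths agree this is exactly one ellipsoid cut by a tilted
plane; the shared plane guarantees face adjacency, and a 0.6-voxel
Gaussian blur plus noise makes the shared boundary genuinely fuzzy.
Pose: rotations up to ±10° per axis and center translation up to ±4
voxels.  Intensities: background 100, foreground 115 (15 % contrast),
substructure gap 6, Gaussian noise SD 7.5 (half the
foreground/background contrast) — a low-contrast, noisy, small-object
regime (each substructure is ≈ 1 % of the volume).  Generation is a
pure function of (parameters, seed); per-case seeds are `seed + index`.

What the phantoms do **not** model: MPRAGE physics, bias fields,
surrounding anatomy (ventricles, white matter), pathology, or
non-rigid anatomical variability.  Passing the end-to-end test shows
the cascade works in the intended small/low-contrast regime; it says
nothing about performance on real MRI.

## Evaluation metrics

Per class: DSC, Jaccard (1.0 when both masks empty, 0 when exactly one
is), signed volume difference (truth − prediction, mm³), center-of-mass
distance, and pooled symmetric surface distances: surfaces are
6-connectivity boundary voxels (volume edges count as background),
distances are Euclidean between voxel centers in mm, and HD95 / MSD /
RMSD are the 95th percentile (linear interpolation), mean, and RMS of
the pooled a→b ∪ b→a multiset.  Pooling (rather than max-of-directed
for HD95, or directed means) is the most common convention and is fixed
here.  Distance metrics are undefined for empty masks and reported as
missing, never coerced to 0.  Cohort level: mean ± sample SD per
metric, Bland–Altman bias and 1.96·SD limits on volumes, and Pearson
correlation of truth vs predicted volumes (per class and pooled over
all case/substructure pairs — the pooled value matches the
one-number-per-experiment volumetric agreement summary).

## The standard desk-scale experiment

`mvtseg.pipeline.run_benchmark` (also exposed through
`scripts/acceptance.py`) is the package's reference experiment, sized
for a single CPU: 60 phantoms (48³), the first 45 for training and the
last 15 held out; localizer with 8 base channels trained 60 epochs; MVT
with `enc_layers 3`, channels (8, 16, 32), token_dim 96, 3 transformer
layers, trained 40 epochs with 2 augmented replicas per case per epoch
and validation fraction 0.1; batch 4 and lr 2·10⁻⁴ throughout; λ = 0.5.
Inference averages the soft prediction over crops shifted by ±2 voxels
per axis (the same magnitude as the training crop jitter), which
stabilizes the boundary at negligible cost.  The deeper 3-level encoder
(48 tokens) was chosen over the 2-level variant (384 tokens) because it
trains ≈ 3× faster at equal accuracy at this problem size.  The
morphology ablation retrains only the segmenter with
`use_morphology=False` under the identical protocol.

Volumetric agreement is summarized by one correlation per experiment —
predicted vs true **whole-formation** volume (the union of both
substructures, the quantity atrophy and hippocampal-avoidance workflows
consume) — with per-substructure correlations reported alongside.  The
per-substructure correlations are systematically lower than the union's
(boundary voxels traded across the internal split plane cancel in the
union), a limitation of the tiny training budget documented below.

## Known limitations

- CPU-bound: minutes per training at desk scale; not intended for real
  datasets at full size.
- The localizer's structured initialization assumes a bright-on-dark
  compact object; inverted-contrast data would rely on training alone.
- At this scale the morphology ablation difference is within seed
  noise; the direction is reported, not guaranteed, per run.
- Bit-exact determinism holds for a fixed BLAS/threading configuration;
  across different BLAS builds only near-equality is expected.
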