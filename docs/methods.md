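# Methods

## The model

RNTNet is a hybrid image classifier for colorectal image analysis
(endoscopic frames and histology patches): a grouped-convolution residual
backbone extracts a spatial feature map, a transformer encoder with *mixed
attention* adds local and global context, and a dense softmax head produces
class probabilities.

**Backbone.** A ResNeXt-style network. The stem is a 7×7 stride-2
convolution (64 filters) followed by a 3×3 stride-2 max-pool — the
architecture description is silent about the layers before stage 1, so the
standard 50-layer residual-net stem is adopted, giving a total stride of 32.
Four stages of bottleneck blocks follow, with output widths
128/256/512/1024 and 3/4/6/3 blocks; each block is a 1×1 channel reduction,
a 3×3 grouped convolution (cardinality 32, stride 2 in the first block of
stages 2–4), a 1×1 expansion, and a ReLU over the sum with the skip path.
The skip is the identity when shapes match and a 1×1 projection convolution
otherwise. Bottleneck width is half the stage output width (the ResNeXt
convention). Spatial arithmetic is ceil-mode with zero padding, so a
300×300 input traverses 300 → 150 → 75 → 75 → 38 → 19 → 10 and yields a
10×10 map. There is no batch normalization anywhere in the backbone (none
is described); to keep the 16-block stack trainable without it, the
expansion convolution of every block is initialized near zero, so each
block starts as an identity and learns its residual progressively. All
other convolutions use seeded He-normal initialization.

**Tokenization.** The final feature map is cut into square patches of
`patch_cells` cells, each flattened and linearly embedded to dimension D,
with a learned additive positional embedding (removable by flag). The
calibrated default is `patch_cells = 2` on the 10×10 map — a 5×5 grid of
M = 25 tokens with D = 768 (see *Calibration* below).

**Mixed attention.** Three branches read the same token grid in parallel
and are fused per token:

* *Dense transformer branch*: `X_out = Norm(X + Atten(Q,K,V) + FFN(X))`
  with scaled-dot attention over all tokens and a two-layer FFN.
* *Overlapping block attention (OBA)*: B×B token blocks at stride s
  (defaults B = 4, s = 2, i.e. 50 % overlap), block-wise softmax attention,
  and a weighted overlap-average reassembly whose per-position weights sum
  to one. The weighting function over a block is uniform by default (plain
  averaging, chosen for determinism and testability); a Gaussian taper
  centred in each block is available. A parallel local-context path — 3×3
  convolution over the grid, ReLU, global average pooling, small FFN — is
  added to every block's output before the overlap average; how this path
  joins the attention path is not specified in the source description, and
  this placement keeps the merge convex.
* *Grid attention (GA)*: the grid is average-pooled with stride 2,
  zero-padded so G divides the side, partitioned into G×G interleaved
  (dilated) groups by coordinates modulo G (G = 2 by default), attended
  within each group, scattered back, and nearest-neighbour upsampled to the
  input grid.

Attention scores are passed through a row softmax in **all** branches.
The printed block-attention formula omits the softmax that the grid
formula includes; since the quantity is called an attention weight and
unnormalized weights break the convex-combination property (and training
stability), softmax is the default everywhere, with the raw-score variant
behind `softmax_attention=False`.

Fusion concatenates the branch outputs on the channel axis and projects
back to D with a learned linear map, followed by a layer norm; summation
fusion is available as a config variant but used nowhere by default. The
encoder applies `depth` such layers (default 1). The ablation arms —
backbone-only, encoder-only, and MHSA / OBA / GA / OBA+GA attention
variants — are all constructible from config alone.

**Head and loss.** Tokens are globally averaged (a learned class token is
deliberately not used, keeping the head independent of token count), passed
through a 256-unit ReLU layer with 20 % dropout, and mapped to class
logits; softmax gives the class distribution. Training minimizes
categorical cross-entropy; in the standalone loss the predicted
probabilities are clipped at 1e-12 before the log.

## Training protocol

Adam with initial learning rate 1e-4, batch size 64, and a fixed budget of
180 epochs is the default protocol; splitting is 80/20 stratified (classes
in the target datasets are balanced, so stratified and simple random
splitting nearly coincide, and stratified is testable — exact train size
⌊0.8 n⌋ with largest-remainder apportionment per class). There is no early
stopping by default; best-checkpoint selection by validation accuracy is an
addition and is flagged in the run log. One master seed drives weight
initialization, splitting and batch shuffling, so runs are bit-reproducible
on the same library stack.

The whole network runs on a compact NumPy reverse-mode autodiff core
(`rntnet.nn`) written for this package: tape-based tensors, grouped
convolution via im2col with a direct path for 1×1 kernels, ceil-mode
pooling, layer norm, softmax and batched matmul, with analytically derived
backward passes (verified against central finite differences in the test
suite).

## Calibration of the default configuration

The encoder's free dimensions are calibrated once so the default model
reproduces the published complexity budget (20.82 M parameters,
5.12 GFLOPs for one 300×300×3 forward pass). With the stated stage widths
the backbone costs 5.76 M parameters and 2.19 GMACs; because every encoder
weight is applied once per token, encoder FLOPs ≈ 2 × parameters × M, and
the budget pair is mutually consistent only near M = 25 tokens. The frozen
defaults are therefore `patch_cells = 2` (5×5 token grid), `embed_dim =
768`, `depth = 1`, `ffn_hidden = 2679`, giving 20.8195 M parameters and
5.109 GFLOPs under the 2-FLOPs-per-MAC convention (2.544 G under the plain
MAC convention; published complexity tables rarely state which is meant, so
both are always reported). FLOP accounting is op-level: dense/convolution/
attention products cost 2 FLOPs per multiply-accumulate, normalizations and
activations 1 FLOP per element.

## Attention cost scaling

The mixed block's attention cost is probed by counting only the attention
computation proper (score products, value aggregation, row softmax) over
token grids of side 4, 6, 8, 10 (M = 16…100 tokens) at fixed B, s, G and a
small fixed D. The grid and dense branches are exactly quadratic in M and
the block branch is roughly linear (block count grows with grid area at
fixed B), so the fitted log–log exponent lands at ≈ 1.81 — the
O(M²D²)-type regime. Projections and FFN are excluded because they are
identical for every attention variant and linear in M; including them would
measure the surrounding machinery, not the mechanism. The contrasting
dense count — attention across every token pair per block pair,
4 n² B⁴ D FLOPs — grows with exponent ≈ 6 in the feature-map side on the
same sweep, the O(M⁴D)-type growth the mixed design avoids.

## Synthetic fixture

The generator emulates the *structure* of the target datasets (8 balanced
classes, one folder per class, small RGB patches, 150 px native size) with
oriented sinusoidal gratings (class-specific frequency 0.06–0.27
cycles/px and orientation), band-passed noise and a sparse Gaussian-blob
field; generation is a pure function of (spec, seed). Classes are linearly
separable by radial frequency-band energies *by construction*, and a
nearest-centroid baseline on those features certifies > 90 % held-out
accuracy in the test suite — which is what makes the desk-scale training
check meaningful. A `hard` flag narrows the inter-class parameter gaps. A
`quadrant` option confines the class grating to one image quadrant
(pure noise elsewhere) for spatial-attribution probes. What the fixture
does **not** emulate: stain/color statistics, intra-class morphological
variability, inter-class feature sharing, label noise, or any clinical
signal — passing tests demonstrate that the pipeline's mechanics work, not
that the model would reach the published accuracies on real endoscopy or
histology data, which would require the original datasets and long GPU
training.

## Desk-scale problem sizes

CPU-scale jobs use the `reduced` preset: all widths divided by 4 (stage
widths 32/64/128/256, stem 16, embed 192, cardinality 8 so it still
divides the narrowed bottlenecks) with one encoder layer. The training
sanity job runs the default fixture (8 × 40 images resized to 300²) with
batch size 16 and learning rate 1e-3, stopping once validation accuracy
reaches 90 % (cap 30 epochs); it typically converges in 2–3 epochs.
Grad-CAM localization is probed on the same fitted model. Cross-validation
and sweep tests run 1-epoch fits on miniature slices at 96 px.

## Explainability

Grad-CAM uses the last stage-4 activation of the backbone as source layer
(the description does not name a layer; the final convolutional map is the
standard choice): channel weights are spatially averaged gradients of the
chosen class logit, the map is the ReLU of the weighted channel sum,
bilinearly upsampled to the input size and max-normalized. An all-negative
weighted sum yields an all-zero map flagged `degenerate` (normalization
skipped). Overlays use a jet colormap at α = 0.4.

## Numerical choices and edge cases

* Softmax and the fused cross-entropy subtract the row max before
  exponentiation; cross-entropy clips probabilities at 1e-12.
* Ceil-mode padding rules: convolution/pool padding is computed per input
  so output = ⌈input/stride⌉; OBA pads the grid bottom/right so
  (side − B) is a non-negative multiple of s; GA zero-pads so G divides
  the pooled side; tokenization zero-pads to a multiple of the patch size
  (or raises, naming the rule, when padding is disabled).
* Metrics: macro averaging throughout (balanced classes make macro ≈
  micro); per-class metrics with empty denominators are 0 with a warning;
  multi-class AUC is one-vs-rest with the micro average as the headline
  number; Cohen's kappa is unweighted; the per-class kappa used for the
  paired t-test is computed one-vs-rest, a documented construction.
* Cross-validation averages are true arithmetic means of the fold columns.
* The paired t-test refuses zero-variance differences explicitly.

## Known limitations

* CPU-only; the full-size configuration is practical for complexity
  accounting and single-image inference, not for 180-epoch training.
* Single-head attention projections (head count is not described); depth
  and head structure beyond the calibrated defaults are untested at scale.
* The fixture's linear separability means desk-scale accuracy says nothing
  about real-data performance (see above).
* Checkpoints store raw weights plus config and class order; no versioned
  migration between architecture revisions.
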