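# Methods

## Pipeline overview

The package classifies two-class ocular ultrasound B-scans (vitreous
opacity, VO, vs posterior vitreous detachment, PVD) in four stages:

1. **Preprocessing** — crop a fixed fundus window, bilinear-resize to a
   square network input, normalize each channel as `(x − mean)/std`.
2. **Embedding** — a convolutional branch with a channel+spatial attention
   block on its final feature map and a fully-connected head ending in the
   embedding layer. The siamese property is structural: there is exactly one
   parameter set, applied to both members of a pair.
3. **Contrastive training** — pairs are sampled per epoch (half positive by
   default), and `L = 1/(2N) Σ [y d² + (1−y) max(margin−d, 0)²]` is
   minimized with Adam.
4. **KNN readout** — training images are embedded into a labeled gallery;
   queries are classified by majority vote among the k nearest entries under
   Euclidean distance.

## Preprocessing conventions

- The shipped crop window is x ∈ [100, 400), y ∈ [50, 300) in top-left-origin
  pixel coordinates (a 300 × 250 window on 512 × 512 frames). Crop
  rectangles are half-open pixel intervals, which makes nested crops compose
  exactly.
- The pipeline order is fixed as crop → resize → normalize. Resizing is
  bilinear, clamped to [0, 1].
- Default normalization uses fixed mean = std = 0.5 per channel, mapping
  [0, 1] intensities onto [−1, 1]; a per-image estimated mode (mean 0,
  std 1 per channel) is available by configuration. Estimated mode rejects
  constant channels rather than dividing by zero.
- Grayscale scans are replicated to three channels so the same branch
  definitions serve 1- and 3-channel sources.
- Traditional augmentation applies its enabled transforms in the fixed order
  random-crop → rotation → vertical-flip → horizontal-flip → color-jitter.
  Flips are deterministic when enabled; crop geometry, angle and jitter
  factors come from the seeded generator, so augmentation is a pure function
  of (image, spec, seed).

## Attention block

Channel attention pools the feature map spatially (average and max), pushes
both C-vectors through one shared two-layer MLP, adds the results and applies
a sigmoid. Spatial attention pools along the channel axis, concatenates the
two planes and convolves with a single odd-sized kernel (default 7 × 7,
symmetric padding). The block applies channel then spatial attention, each
multiplying the feature it was computed from; disabled components are the
identity. Choices the block's published description leaves open, fixed here:

- MLP bottleneck ratio r = 16 (hidden width `max(C/r, 1)`), rectified hidden
  activation.
- One attention block per branch, placed after the final convolutional
  stage. (The block is cheap and could be stacked at several depths; a
  config hook allows that, but the default is a single block.)

Both operators are verified against straight-line pooled-descriptor
recomputations (explicit per-pixel loops, no shared code) to 1e-6, and the
zero-parameter case returns exactly 0.5 everywhere (σ(0)).

## Branch architectures

Four branch configurations are provided: `vgg16` (13 conv layers of 3 × 3 in
five stages with 2 × 2 max-pools; head FC(4096)→FC(512)→FC(100)), `alexnet`
(64@11×11/4 … 256@3×3 with 3 × 3/2 overlapping pools; same head widths),
`resnet18` (7 × 7/2 stem, four stages of two basic residual blocks with 1 × 1
downsample convolutions, global average pool; head FC(512)→FC(100)), and
`tiny` (three conv stages of width 8/16/32 on 64 × 64 inputs; head
FC(128)→FC(32)→FC(16)). Heads use rectified activations between layers and
no activation after the embedding layer — distances need an unbounded
embedding space. The `tiny` configuration exists so the full pipeline
trains on one CPU in seconds; it is an engineering profile, not a claim
about clinical-scale behavior.

Pretrained ImageNet weights are consumed, never produced; since no weight
files ship with the package, `pretrained=True` raises an explicit error
pointing to seeded random initialization.

## Numerical engine

The network core is a small reverse-mode autodiff engine on float64 NumPy
arrays (`ocusiam.nn`): convolution is im2col + matmul built from a single
gather primitive whose backward is a scatter-add; max-pooling routes
gradients to the (deterministic, first-index) arg-max; batch normalization
is composed from differentiable primitives with running statistics for
evaluation mode. Gradient correctness is tested two ways: every scalar
parameter of a micro convnet against central finite differences, and sampled
coordinates of every parameter tensor of the full tiny branch under the
contrastive objective (relative tolerance 1e-3; checking all ~270k scalars
individually would add nothing but runtime). The distance inside the loss is
`sqrt(d² + 1e-12)` so the gradient of a perfectly collapsed positive pair
stays finite.

## Training conventions

Defaults are the targeted study conditions: Adam at learning rate 1e-5,
batch size 50 pairs, 50 epochs. Decisions those conditions leave open, fixed
here:

- **margin = 1.0** — the common choice for unnormalized embeddings;
  configurable.
- **positive_fraction = 0.5** and **pairs_per_epoch = training-set size** —
  uniform random pairing on balanced two-class data would yield ~50%
  positives anyway; making the fraction exact removes a variance source.
- Batch size counts *pairs* (each contributing two images).
- The loss already averages over N; no additional normalization is applied.
- Pair sampling is reseeded per epoch from a hash of (seed, epoch), so runs
  are reproducible and epochs are independent draws.
- The desk profile raises the learning rate to 1e-3 and shortens training to
  8 epochs: at tiny-branch scale on well-separated synthetic data this
  converges in seconds, which is the profile's purpose.

## KNN readout

k = 2 by default, Euclidean distance, exact brute-force search. Tie rules
are fully specified because k = 2 on two classes ties whenever the
neighbors disagree: vote ties fall back to the single nearest neighbor
(making even k behave like k = 1 exactly in the disagreement case — which
is why small even and odd k give identical decisions on well-separated
galleries), and distance ties in the sort are broken by label
(lexicographic), then insertion order. The label-first tie-break makes
decisions invariant to gallery permutation even when equidistant points
carry different labels — an insertion-order-only rule would not be.

## Evaluation

Metrics are the standard single-positive-class accuracy / precision /
recall / F1 with the convention "0 plus a degenerate flag" for empty
denominators. The positive class defaults to PVD (the designation is
arbitrary on this problem and is recorded in every report); a macro average
over both designations is always reported alongside, since it is invariant
to the choice. Harnesses: a four-variant attention ablation (none /
channel / spatial / both) trained with shared seeds; a k sweep over one
fixed gallery; a classifier-head comparison fitting SVM, random-forest and
gradient-boosting heads (scikit-learn) on the same gallery embeddings.
Failed variants/heads are recorded as failed rows, never dropped.

## Synthetic data

The generator renders the class-defining morphology on a dark frame with a
brighter elliptical "fundus": VO-like images get `spot_count` disjoint
Gaussian-profile bright blobs inside the ellipse (placement rejection-sampled
with a separation that keeps supports disjoint above the 0.5 intensity
threshold); PVD-like images get one thickened curvilinear arc along the
posterior ellipse boundary, optionally only partially rendered. Speckle is
multiplicative uniform noise applied last. Defaults emulate the targeted
study regime: 220 images per class on 512 × 512 frames (where the shipped
crop window applies unchanged); `SyntheticSpec.for_size` scales lesion pixel
dimensions for smaller frames.

What this emulates — and does not: the generator reproduces the
discrete-vs-continuous lesion contrast and class balance, but not speckle
statistics of real tissue, probe geometry, shadowing or attenuation.
With noise 0 and the default regimes the classes are separable by counting
bright connected components, so passing end-to-end tests demonstrates that
the pipeline can learn and classify a solvable problem — not that it reaches
any particular accuracy on clinical scans, which are private to their
originating institution.

## Problem sizes used in tests and the acceptance script

Training-level tests and the acceptance script use 128 px noiseless frames,
30 images per class split 2:1 (20 train + 10 test per class), the tiny
branch at 64 px, and ≤ 8 training epochs — sizes chosen so the complete
pipeline, its ablation and its determinism checks all run comfortably on a
single CPU. Operator-level checks (attention, loss, metrics, KNN, gradients)
use small random instances at tight tolerances (1e-6 for algebraic oracles,
1e-3 relative for finite-difference gradients, exact equality for
determinism byte-comparisons).

## Known limitations

- No physically realistic ultrasound simulation; synthetic results validate
  the machinery only.
- Pretrained initialization requires externally supplied weight files.
- The NumPy engine is single-threaded and desk-scale; training the full
  VGG16 branch at 224 px is out of its intended envelope.
- Inference embeds each image once through the shared branch; with shared
  weights a duplicated-and-concatenated embedding cannot change any
  Euclidean ranking, so the plain embedding is used for the KNN readout.
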