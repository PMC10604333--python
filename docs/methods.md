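# Methods

## Problem and pipeline

`histofed` implements content-based retrieval of histopathology image
patches under federated training. Several sites each hold a private set of
H&E-stained tissue patches (benign/malignant, optionally tagged with an
objective magnification of 40–400×). No images ever leave a site; the sites
collaboratively train a convolutional auto-encoder (CAE) by exchanging only
model weights. After training the decoder is discarded and the encoder acts
as an unsupervised feature extractor: every archived patch is embedded into
a feature vector, and a query patch retrieves its K nearest archived patches
by Euclidean distance. Retrieval quality is scored with the any-match
statistic ACC@K plus precision/F1 over a per-query predicted label.

All tensor computation is implemented directly in NumPy (float64,
channels-last), including the convolution, transposed convolution and their
reverse-mode gradients. This keeps the whole pipeline dependency-light,
deterministic, and bit-reproducible given a seed in single-threaded
operation; the transposed convolution is defined as the exact adjoint of the
same-padded strided convolution, which both tests and the decoder geometry
rely on.

## Auto-encoder

Full geometry (224 × 224 × 3 input, all kernels 3 × 3, same padding):

* **Encoder** — four convolutions, filters `[32, 64, 128, 256]`, strides
  `[1, 2, 2, 2]`, ReLU. Same padding uses the `ceil(n / stride)` output-size
  convention (extra pixel on the bottom/right), so the spatial trace is
  224 → 224 → 112 → 56 → 28.
* **Residual bottleneck** — four stride-1 convolutions with filters
  `[64, 32, 1, 256]` (the single-channel stage is kept as specified; the
  filter list is configurable), ReLU between them; the block input is added
  to the block output, through a learned 1 × 1 projection when the channel
  counts differ, followed by a final ReLU.
* **Embedding head** — global average pooling over the 28 × 28 × 256
  activation, then one fully-connected layer to the 200-dimensional latent
  vector (linear). This is the smallest head consistent with "one feature
  vector with 200 features"; the latent width is configurable.
* **Decoder** — one fully-connected layer expands the latent vector back to
  28 × 28 × 256 (ReLU), then four transposed convolutions with filters
  `[128, 64, 32, 3]` and strides `[2, 2, 2, 1]` mirror the encoder trace.
  A sigmoid keeps reconstructions in [0, 1].
* **Skip connection** — one additive skip from the first encoder activation
  (224 × 224 × 32) to the decoder activation entering the final transposed
  convolution. Both ends sit at the stride-1 extremes of the network, so
  their spatial shapes match by construction; a channel mismatch is a
  configuration error naming both layers. The skip itself has no
  parameters, so toggling it does not change the parameter count.

Configuration invariants beyond the obvious ones: the decoder stride list
must be the encoder stride list reversed. The decoder's per-layer target
sizes are then taken from the mirrored encoder trace rather than recomputed
as `in × stride`, which makes reconstruction shape equal input shape for
*every* valid configuration, including odd sizes (e.g. 7 → 4 → 7 at stride
2). Bottleneck strides must be 1 (a residual add needs matching shapes).

Unstated design points resolved as: ReLU hidden activations, sigmoid output,
He-style initialisation (final decoder layer scaled gentler into the
sigmoid), zero biases, plain SGD. Inputs are normalised to [0, 1]; no stain
normalisation is applied — robustness to stain shift is instead probed by
the generator's per-client hue/saturation offsets.

Training minimises the mean squared reconstruction error (mean over all
pixels and channels) with per-batch updates `w ← w − η ∇ℓ(w; b)`. The
printed default learning rate is 1 × 10⁻⁶ (the full-scale setting); the
reduced experiments shipped here use 0.01, chosen so a 20-epoch run moves
the loss visibly at the small geometry. A non-finite loss aborts with a
diagnostic rather than silently diverging. With η = 0 the update is exactly
the identity, which tests exploit.

## Federation

The round loop is simulated sequentially in one process: broadcast global
weights, run each sampled client's local epochs, aggregate. The privacy
contract of a real deployment is preserved structurally — a client's images
are touched only inside its own local update, and only weight collections
cross the boundary (tests assert the access pattern with tracking wrappers).

* **FedAvg** (default): every tensor of the new global model is the
  sample-count-weighted mean `Σ (n_m / n) w_m`. A single update passes
  through bit-exactly; the aggregate of identical updates is that update;
  every aggregated element lies in the clients' elementwise envelope.
* **FedAdagrad** (alternative): the weighted-mean client delta Δ acts as a
  server pseudo-gradient; per tensor `v ← v + Δ²`,
  `w ← w + η_s Δ / (√v + τ)`, with `v` initialised to τ². Defaults
  η_s = 0.1, τ = 10⁻³. In the large-τ limit with η_s = 2τ the step reduces
  to the FedAvg delta, which the tests verify.
* Per-client epochs, batch size and learning rate are first-class
  (heterogeneous sites are the realistic case); aggregation still weights by
  sample count only. Client sampling (`sample_fraction < 1`) draws without
  replacement from a dedicated seeded stream; by default all clients
  participate every round.
* Each client owns a persistent shuffle stream seeded as
  `(seed, client_index)` that continues across rounds. Consequence: a
  single-client federation of R rounds × E epochs is *bit-identical* to
  plain local training for R·E epochs with the same stream — a strong
  end-to-end correctness check on the whole loop.
* A client failure mid-round aborts the round with the round and client
  named; there is no partial aggregation.

## Retrieval

The feature dictionary indexes the training + validation patches; test
patches are the queries. Search is an exhaustive Euclidean scan over the
raw 200-dimensional embeddings (no L2 normalisation, no approximate-NN
structure): at the scales involved an exhaustive scan is sub-second and
keeps results exact, so the brute-force full-sort oracle in the tests must
agree exactly. Ties break by insertion order (stable argsort), so
duplicated records rank adjacently. Cross-magnification search embeds the
query once and runs an independent top-K in each per-magnification index,
returning one ranked list per magnification.

## Evaluation

ACC@K (K = 5 by default) counts a query as correct when *any* of its top-K
hits shares the query label. Precision and F1 need one predicted label per
query, which the any-match protocol does not define; the default rule is a
majority vote over the top-K hit labels with ties resolved by the nearest
hit, with a rank-1 rule and a per-hit micro-averaged variant available
behind a flag. The positive class is malignant. ACC@K is monotone
nondecreasing in K and can never fall below majority-vote classification
accuracy at the same K. With no positive predictions, precision is reported
as 0 with a warning rather than NaN.

## Tiling

Raster slides are cut into non-overlapping 224 × 224 tiles (row-major,
0-based, half-open intervals encoded in the patch id); border remainders are
dropped. A tile is kept when at least 70% of its pixels count as tissue.
Tissue detection is deliberately simple: a pixel is tissue when its
mean-channel luminance is below 0.90 (background on an H&E slide is
near-white); Otsu's threshold is available as an option. Raising the
minimum-tissue fraction can only shrink the surviving set.

## Synthetic data generator

The generator renders two-class H&E-like textures: blobs of hematoxylin
purple on an eosin-pink background, Gaussian-blurred, with light pixel
noise. Benign patches carry 3 large blobs (radius 4.5 px at the 32-px
reference geometry), malignant patches 30 small ones (radius 2 px); the
classes therefore differ both in texture scale and in stained-area fraction
(≈19% vs ≈37%), so they are separable by the low-order statistics a pooled
CAE embedding captures — by design, since the generator exists to give the
pipeline a controllable, honestly learnable signal. Magnification scales
the field as a real objective would: at m× the blob radius grows with
√(m/40) and the count shrinks with 40/m (a smaller tissue area in view).
Each client can apply a hue/saturation offset emulating inter-center stain
drift. Class imbalance defaults to the 2480:5429 benign:malignant
proportion of the breast-histology corpus being emulated.

Default study conditions for the reduced experiments: two clients, 24/8/12
train/val/test patches each, 32-px patches, latent width 16, two rounds of
five local epochs, batch 8, SGD at 0.01. These sizes keep a full ten-seed
replication of the pipeline under a minute on one CPU while leaving the
retrieval task non-trivial.

What the generator does *not* emulate: real nuclear morphology,
chromatin texture, stain co-localisation, compression artifacts, or
gigapixel slide geometry. Passing tests therefore demonstrate the
correctness and learning dynamics of the pipeline, not clinical-grade
retrieval accuracy; headline numbers on real multi-gigabyte corpora are out
of scope at desk scale.

## Numerical and degenerate-input choices

* float64 everywhere; deterministic given seeds; no threading assumptions.
* Same padding splits an odd total pad with the extra pixel after (bottom/
  right).
* Distance ties and label-vote ties have the explicit rules above, so
  results are reproducible across platforms.
* Empty datasets, empty indexes, empty query sets, K < 1, shape and schema
  mismatches all raise informative errors; images smaller than one tile
  yield an empty patch list with a warning.
* Weight schemas are digests of (names, shapes); aggregation refuses
  mismatched schemas naming the offending client. Index files additionally
  record a digest of the weight *values*, so evaluating against an index
  built by different weights is refused.

## Known limitations

* The NumPy implementation is CPU-bound and single-threaded beyond BLAS;
  the full 224-px geometry is practical for encoding and demonstration,
  not for long training runs.
* The decoder-entry fully-connected layer dominates the parameter count at
  full geometry (200 → 28·28·256); it is the faithful "FC + reshape"
  mirror of the pooling head, not a size-optimised choice.
* The single-channel stage printed in the bottleneck filter list is honoured
  as specified even though it is an aggressive information bottleneck for
  the residual path; the filter list is configurable where that matters.
* FedAdagrad server hyperparameters default to η_s = 0.1, τ = 10⁻³ and were
  not tuned; FedAvg is the default strategy.
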