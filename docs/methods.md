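# Methods

## Problem and model

`grnpairs` predicts directed regulatory links (TF → target) from spatial
gene-expression images, treating link prediction as supervised binary
classification of image pairs. The biological premise: a TF and its target
tend to be co-expressed in the *same local territories* of the embryo, while
their *global* staining intensity can differ substantially — so whole-image
similarity is the wrong statistic, and a learned classifier must pick up
local pattern coincidence instead.

Each gene *i* owns a set of standardized grayscale images
X<sub>i</sub> = X<sub>i,l</sub> ∪ X<sub>i,v</sub> ∪ X<sub>i,d</sub>,
partitioned by viewing orientation (lateral, ventral, dorsal). Supervision
exists only at the gene-pair level, so the multi-instance problem
y<sub>ij</sub> = f(X<sub>i</sub>, X<sub>j</sub>) is reduced to
single-instance learning: every orientation-matched cross-product pair
(x<sub>i,o</sub><sup>(p)</sup>, x<sub>j,o</sub><sup>(q)</sup>) becomes one
training instance inheriting the pair's label. An instance is presented to
the CNN as a vertical concatenation with the TF image on top; the order is a
hard contract, not a convention — reversing it measurably changes
predictions, because TFs have distinct expression statistics.

At prediction time, per-instance probabilities are averaged over all
instances of a pair:

    score(i, j) = Σ_o Σ_p Σ_q f(x_i,o^(p) ⊕ x_j,o^(q)) / Σ_o |X_i,o|·|X_j,o|

and the decision applies a threshold of 0.5, with a score exactly at the
threshold called positive. Pairs with no shared non-empty orientation are
flagged unscorable and excluded from every metric denominator (counted and
reported, never silently zeroed).

## Architectures

Two backbones share the same head contract — a 128-unit fully connected
layer with tanh activation, batch normalization and dropout, followed by a
single sigmoid output:

* **`resnet50_style`** — the standard ResNet-50 layout (7×7/64 stride-2
  stem; 3×3 stride-2 max pool; bottleneck stages of 3/4/6/3 units with
  256/512/1024/2048 output channels; global average pooling). On the
  default 256×320 concatenated input the stage feature maps are 128×160,
  64×80, 32×40, 16×20 and 8×10. The dropout rate defaults to 0.3; it is a
  config knob because reasonable published settings vary (0.1–0.3).
  `pretrained_init` accepts a path to a saved weights file; no weights are
  bundled, and `freeze_backbone` exposes the fixed-feature-extractor
  variant in which only the head trains.
* **`small_cnn`** — three 3×3-conv/BN/ReLU/max-pool stages (8/16/32
  channels, 8× downsampling) followed by a *cross-half comparison* layer: a
  convolution whose kernel spans half the downsampled map vertically, so
  each output cell sees a position in the TF half together with the
  vertically aligned position of the target half, then global max pooling.
  The max asks "does a local co-expression coincidence exist anywhere?",
  which is exactly the decision variable of the task, and its translation
  invariance prevents the tiny-data failure mode where a flattened head
  memorizes absolute positions (observed during development as perfect
  training accuracy with chance-level held-out-gene accuracy).

The whole network stack (convolution via im2col + BLAS matmul, batch
normalization, pooling, dropout, fully connected layers, SGD with optional
momentum) is implemented in NumPy inside the package (`grnpairs.nn`); every
layer's backward pass is verified against numerical differentiation in the
test suite. Evaluation-mode scoring runs in float64 so a link score does
not depend on how instances were batched.

Training minimizes binary cross-entropy, computed from logits for
numerical stability (the sigmoid remains the scoring output). The loss
choice follows standard practice for a sigmoid binary classifier. The
reference optimizer settings are SGD with learning rate 0.001 for 60
epochs; CPU-scale synthetic runs use lr 0.01 with momentum 0.9 for 40
epochs with the rate halved at epochs 25 and 33, which converges reliably
at that problem size. Optional `class_weight="balanced"` reweights
instances so both classes contribute equally — instance counts per pair
vary, so inherited labels are not exactly balanced even when pairs are.
The best-validation-accuracy checkpoint is restored after training.

## Data construction

Positive pairs come from a high-confidence edge list; negatives are drawn
uniformly without replacement from TF × gene pairs excluding positives,
an optional exclusion network (partially supported links that must not be
called negative), and self-pairs, at a 1:1 ratio by default.

Splitting is at the **gene** level: the gene universe is partitioned, a
pair is a training pair iff both endpoints are train-genes, a test pair iff
both are test-genes, and mixed pairs are dropped (counted in the split
report). Because a pair needs both endpoints on one side, a pair-level
train fraction r requires gene-level odds √r/(1−√r): for the 4:1 pair split
the genes are partitioned roughly 2:1. A bounded retry loop reshuffles
until the achieved pair-level fraction is within tolerance (default 0.05)
of the target, then validation pairs are drawn from the training pairs at
rate 0.1 — their genes stay on the training side, so the test side remains
untouched. An exhaustive leakage scan (no gene supplies images to both
training instances and test pairs) is part of the acceptance suite.

## Synthetic corpus generator

The generator emulates standardized ISH-style collections: 8-bit grayscale
images (default 320×128) of a light elliptical embryo on white background,
dark staining blobs, a variable number of images per gene per orientation
(default 1–2, lower bound 0 allowed, at least one image per gene
guaranteed).

Each orientation has a fixed ring of `n_regions` region centers (the same
region index maps to different coordinates in different orientations, so
orientation matters, as in real embryos). Each gene activates
`active_regions_per_gene` (default 2) regions; staining is rendered as
Gaussian blobs (σ ≈ 0.11·min(H, W)) multiplied by a per-gene amplitude
drawn from `global_scale_range` times a per-image jitter (±10%,
staining-batch variation), plus Gaussian pixel noise (`noise_sd`, 8-bit
units), clipped to [0, 255].

Planted truth edges are sampled among TF–target pairs sharing ≥ 1 active
region; pairs sharing none form the certified-negative pool; sharing pairs
*not* planted are recorded as a "medium-confidence" analogue — used as the
negative-sampling exclusion set and as an all-positive independent test
set for the hit-ratio analysis. An explicit error names the shared-region
constraint when the requested edge count is infeasible. All randomness
flows from one `numpy.random.Generator` seeded by `spec.seed`, so corpora
are byte-reproducible.

What the generator does **not** emulate: real staining texture and
morphology variation, the 16 embryonic stages (a single stage range is
assumed), annotation vocabularies, registration artifacts, or
partially-out-of-frame embryos. Passing tests therefore demonstrate that
the pipeline recovers planted local co-expression under controlled
conditions — not that the architecture reaches any particular accuracy on
real embryo collections.

## Study conditions for the synthetic experiments

The signal-recovery experiment (test suite and `scripts/acceptance.py`)
uses 16 TFs × 48 targets (64 genes), 4 regions per orientation, 80×32
images, interaction density 0.12 (92 planted edges, matched 1:1 by
certified negatives), noise σ = 4, global scale range 0.6–2.4 (a > 4×
intensity span, so global intensity is deliberately uninformative). Images
are smaller than the 320×128 default so a from-scratch NumPy CNN trains in
about three minutes on one CPU; the gene universe is the smallest at which
the planted rule is recovered reliably rather than memorized (smaller
universes — ~30 genes — showed gene-identity memorization: perfect
validation accuracy, unstable held-out-gene accuracy). Under these
conditions held-out-gene accuracy is ≥ 0.9 across independent master
seeds, and the hit ratio on the all-positive medium-confidence analogue is
high with most hits above 0.8 — the qualitative pattern expected of the
method.

The no-signal control trains the same protocol on permuted labels. A
single permutation is a poor null at this corpus size: the permuted labels
retain a small residual correlation with the planted feature, the network
amplifies whatever consistent signal exists, and the null's test accuracy
lands near a base-rate extreme in either direction. The control therefore
uses an antithetic permutation pair {σ, 1−σ}; the mean of the two test
accuracies has expectation exactly 0.5 for a label-symmetric learner, and
it is measured on a label-balanced subset of the test pairs so that a
label-independent classifier is centred at 0.5. The trained model's
accuracy is required to clear 0.9 while the antithetic null mean stays
inside the binomial 95% interval around 0.5.

## Occlusion analysis

A constant-fill patch (default 32×32, stride 16 at full resolution; 16×16,
stride 8 for the 80×32 synthetic images) slides over the full concatenated
input, probing both the TF and target halves; each map value is baseline
minus occluded probability. The fill value defaults to the corpus
background intensity (232) rather than black: occluding with background
erases staining without introducing an out-of-distribution dark patch.
Negative values (occlusion raising the probability) are retained in the
stored map but clipped at zero for rendering. Localization is scored by
whether the argmax patch center falls inside the shared active region's
bounding box (±3σ) in either half.

## Numerical and design choices

* Ties: score exactly 0.5 → positive; top-K and top-fraction rankings break
  score ties by (tf_id, target_id) lexicographic order for reproducibility.
* Histogram bins [0,0.2), …, [0.8,1.0] are half-open with the last bin
  closed; an interior edge value falls in the upper bin.
* Top-10% false-positive ratio is computed over all test predictions (not
  positives only), as the fraction of actual negatives among the
  ⌈0.1·n⌉ highest-scoring pairs.
* F1 is defined as 0 (with a logged note) when there are no predicted
  positives; evaluation with zero scorable predictions is an error.
* Hub degree counts every incident retained edge (TF out-degree and target
  in-degree); the full degree distribution is always reported so any
  "dominant gene" cutoff can be applied as a query. `min_degree` is an
  explicit parameter.
* Accuracy on sampled-negative benchmarks may be *underestimated*:
  unrevealed true links can be sampled as negatives. This caveat is
  carried in the evaluation report's notes, not corrected for.
* The split of a pair set whose genes cannot satisfy the requested
  fractions within tolerance fails loudly, reporting the best achieved
  fraction.

## Known limitations

* No GPU path and no ImageNet pretraining: the ResNet-style backbone is
  architecture-complete and trainable, but training it at full 256×320
  scale in NumPy is impractical; it serves geometry audits, scoring and
  transfer-learning experiments with externally supplied weights.
* The generator's noise and intensity statistics are plausible
  placeholders, not calibrated to any real image collection.
* Scores are uncalibrated probabilities; no per-orientation weighting
  beyond the uniform mean is offered.
* GO/functional enrichment is out of scope; the network exporters emit
  SIF/GraphML/TSV and plain gene lists for external tools.
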