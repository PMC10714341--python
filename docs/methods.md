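# Methods

## Problem and model

`m7gformer` classifies 41-nt RNA windows centered on a candidate guanosine
as N7-methylguanosine (m7G) sites or non-sites. The positive class is a
window whose center G carries the modification; flanks are 20 nt on each
side. The classifier is a transformer encoder augmented with a
convolutional sublayer, fed by a multi-sense, multi-scale k-mer embedding.

### Embedding

Each window is tokenised at k-mer scales k = 1, 2, 3 by a stride-1 sliding
window; at scale k a base is covered by up to k distinct k-mers, so with
the three scales every base has six covering tokens. Positions near the
window edges whose covering k-mers would fall outside the sequence are
completed with a per-scale pad token that has its own learned embedding,
keeping the candidate count at exactly six everywhere. Each (scale, sense)
pair owns an embedding table; there are three senses, i.e. three
alternative vectors per token, intended to capture alternative contextual
readings of the same k-mer.

Fusion is two-stage additive soft attention with

    score_j = v . tanh(W e_j + b),      weights = softmax(scores)

applied first over the six scale candidates within each sense (one shared
parameter set) and then over the three sense vectors (a second parameter
set). Each fused vector is therefore a convex combination of its
candidates. Because the stage-1 score of a candidate depends only on its
table row, scores are evaluated once per vocabulary entry and gathered,
which is algebraically identical to per-occurrence evaluation and much
cheaper.

Learned sequence-start and sequence-end boundary vectors flank the 41
fused rows, producing a 43 x 64 token matrix. The 43-row token axis is a
pinned shape of the architecture; boundary tokens are this package's way
of realising it. A fixed sinusoidal position encoding

    PE(pos, 2i)   = sin(pos / b^(2i/d_model))
    PE(pos, 2i+1) = cos(pos / b^(2i/d_model))

with b = 1000 and d_model = 64 is added elementwise, with no scaling
factor. Learned (adaptive) position embeddings are exposed only as a
config stub that raises.

### Encoder and head

Each of the 3 encode blocks applies, in order: multi-head self-attention
(8 heads, per-head dimension d_k = 32, output projection 256 -> 64), a
convolutional sublayer, and a position-wise feedforward network (64 -> 64
-> 64 with ReLU). The convolutional sublayer is one layer of 64 size-1,
stride-1 filters — a per-position channel mix — computing
`ReLU(Dropout(W x + b))`. Every sublayer is wrapped post-norm as
`LayerNorm(x + Sublayer(x))` (epsilon 1e-5). Residual connections and
layer normalisation are not spelled out by the architecture's description
but are required in practice: without them a 3-block stack of this width
does not train.

The head mean-pools the 43 x 64 encoder output over the token axis (the
reduction to a 64-vector is otherwise unspecified; the sequence-start row
is available as an alternative pooling mode), then applies linear(64->16)
-> ReLU -> dropout -> linear(16->2) -> softmax. Predicted label is
p_pos >= 0.5.

Dropout rate is 0.5 everywhere dropout appears: inside the conv sublayer
(before the ReLU, per its defining expression), after the attention output
projection, after the FFN hidden activation, and between the two head
layers.

### Training

Adam (lr 1e-4, default moments), batch size 32, cross-entropy loss, a
fixed number of epochs with no early stopping or validation-based
selection; final-epoch parameters are the model. Minibatch order and
dropout masks derive from the run seed, so a (seed, config) pair
reproduces a run bit-identically. The reference protocol trains for 100
epochs; the sanity protocols in this repository use shorter schedules (see
below). Ten-fold cross-validation retrains from a fresh seeded
initialization (seed + fold index) per fold. Evaluation reports ACC, Pr,
Sn, Sp (percent), F1, AUC (tie-aware rank probability via scikit-learn),
MCC and mean per-sample cross-entropy; any ratio with a zero denominator
is reported as 0 and flagged rather than raised.

## Numerical engine

No deep-learning framework is used: the model runs on a small in-repo
reverse-mode autodiff engine over numpy arrays, with hand-written Adam.
Every vector-Jacobian product is verified against central finite
differences in the test suite, both per-operation and end-to-end through
the full model. Default arithmetic is float64, which is what the
structural unit tests rely on for 1e-9 agreement with loop-based oracles;
training casts parameters to float32 (`TrainConfig.precision`), roughly
halving step time with no measurable effect on the stochastic outcome
checks. Embedding scatter-gradients use a sort/reduceat grouped
accumulation; matmuls against 2-D weight matrices collapse the batch into
a single GEMM.

## Initialization

Linear weights are N(0, 1/fan_in); biases zero; layer-norm gain one,
shift zero. Embedding tables and boundary vectors are N(0, 1) — unit
scale, the convention of mainstream embedding layers — because the token
content must be commensurate with the O(1) position encoding: with tables
at scale 1/sqrt(d_model) the content is ~8x weaker than the PE, the
post-norm stack then produces near input-independent representations
(between-sample feature variation ~1% of feature magnitude), and training
stalls at chance loss. Soft-attention stage parameters use scale
1/sqrt(d_model), which keeps initial fusion scores O(1) for unit-scale
candidates.

## Resolved ambiguities

* Per-head dimension: the architecture's prose suggests d_model / h = 8
  while its parameter table pins d_k = 32; the table wins (W^O maps 256 ->
  64).
* "Kernel number: 1" is read as one convolutional layer of 64
  shape-preserving size-1 filters, since the output shape is documented as
  unchanged; a literal single output channel cannot preserve 64 channels.
* The 43-row token axis is realised with learned boundary vectors; the
  alternative (retained flank pads) would also produce 43 rows but mixes
  pad semantics into the sequence ends.
* Softmax scaling uses sqrt(32), consistent with the chosen d_k.
* Labels come from separate positive/negative FASTA files; DNA-alphabet
  input (T for U) is converted by default behind a flag; center-G
  validation is on by default with an override.
* Splits and folds are stratified and seeded by default. The 8:2 split
  fraction applies per class; fold assignment deals each shuffled class
  round-robin with a per-class starting offset so fold sizes differ by at
  most one overall and per class.

## Synthetic data

The generator emulates the benchmark's geometry — 41-nt windows, G fixed
at index 20, balanced classes — with iid uniform background and a planted
positional motif in positives only. The default motif is six one-hot
columns (AAUGGA) at offsets 14-19, immediately upstream of the center,
mixed with the uniform background at strength 0.9: effective per-position
probabilities 0.925/0.025, about 9 bits of planted information (12 bits
before mixing). Uniform background makes the planted motif the only
learnable structure, which is the point: passing the learning-sanity
checks shows the architecture can find and use positional sequence
signal. It does not show performance on real m7G data, whose flanks are
compositionally biased, redundant and structured; no claim about the
published benchmark numbers follows from these tests.

## Protocol sizes used by the checks

The learning-sanity protocol trains the full model on 400+400 synthetic
windows (8:2 split, 640 train / 160 held out) for 20 epochs on three
seeds, expecting held-out AUC >= 0.95; the same runs with permuted
training labels must stay within 40-60% held-out accuracy. The ablation
direction check compares the full model with the plain token-embedding
baseline (TE+Encoder: 1-mer, single sense, no PE, no conv) on identical
splits and seeds, expecting the full model's mean AUC not to be worse.
Twenty epochs is the package's short-protocol choice: on this task the
loss is still falling at epoch 20 but ranking is already saturated.

## Known limitations

* The occlusion importance map substitutes each alternative base at a
  position (never a pad token, which would be out-of-distribution) and
  reports the drop in p_pos. The original architecture's positional
  heat-map procedure is not described precisely enough to reproduce;
  occlusion is a well-defined stand-in, documented as such.
* CPU-only and small-scale by design; the reference 100-epoch, 741+741
  benchmark protocol runs, but expect minutes-to-hours, not seconds.
* k-mer scales above 3 are rejected by default (combinatorial
  vocabularies) behind an override flag.
* No probability calibration; threshold is fixed at 0.5.
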