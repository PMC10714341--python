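# m7gformer

Prediction of RNA N7-methylguanosine (m7G) sites from sequence alone.
m7G is a positively charged post-transcriptional modification of the N7
position of guanosine, involved in RNA stability, translation and disease;
locating modified sites experimentally (AlkAniline-seq, MeRIP-seq,
miCLIP-seq) is expensive, so sequence-based classifiers are used to
prioritise candidates. `m7gformer` is for computational biologists who
have candidate 41-nt windows centered on a G (20 nt of flank on each
side) and want calibrated-enough scores, the full evaluation protocol, and
interpretability outputs, reproducibly and without a GPU.

## Model

A window `R = r_1 … r_41` is tokenised at k-mer scales k = 1, 2, 3 with a
stride-1 sliding window (e.g. the 2-mers of `CAGCU` are `CA, AG, GC, CU`),
so each base is covered by six tokens (1 + 2 + 3, pad-completed at the
edges). Every token has three "sense" embeddings in R^64. Additive soft
attention — `score_j = vᵀ tanh(W e_j + b)`, weights `softmax(score)` —
fuses the six scale candidates within each sense, then the three sense
vectors, giving one 64-vector per base. Learned start/end boundary vectors
yield a 43 × 64 matrix, to which the fixed sinusoidal position encoding

```
PE(pos, 2i)   = sin(pos / 1000^(2i/64))
PE(pos, 2i+1) = cos(pos / 1000^(2i/64))
```

is added. Three encode blocks follow, each applying multi-head
self-attention (h = 8, d_k = 32), a size-1 convolutional sublayer
`ReLU(Dropout(WX + b))` to restore local feature extraction that pure
attention lacks, and a position-wise feedforward network, each wrapped as
`LayerNorm(x + Sublayer(x))`. Mean-pooling and a 64→16→2 softmax head give
`p(m7G | R)`. Training: Adam, lr 1e-4, batch 32, cross-entropy, dropout
0.5. Evaluation: ACC, Pr, Sn, Sp, F1, AUC, MCC, Loss, with stratified
8:2 split and 10-fold cross-validation protocols, four named ablation
variants, and occlusion-based positional importance.

The network runs on a small reverse-mode autodiff engine over numpy
(float64 by default, float32 during training); gradients are verified
against finite differences in the test suite.

## Worked example

```python
import m7gformer as mg

# synthetic benchmark stand-in: 41-nt G-centered windows, positives carry
# a ~9-bit motif at offsets 14-19
ds = mg.generate_dataset(mg.SynthConfig(n_pos=400, n_neg=400, seed=11))
train_set, test_set = mg.split_train_test(ds, mg.SplitSpec(seed=11))

model, losses = mg.train(None, train_set, mg.TrainConfig(epochs=20, seed=1))
report = mg.evaluate(model, test_set)
print(f"loss {losses[0]:.3f} -> {losses[-1]:.3f}")
print(f"ACC {report.ACC:.1f}%  AUC {report.AUC:.4f}  MCC {report.MCC:.3f}")
```

prints

```
loss 0.707 -> 0.232
ACC 91.9%  AUC 0.9817  MCC 0.838
```

i.e. cross-entropy falls from chance (ln 2 ≈ 0.693) to 0.23 over 20
epochs, and the held-out 160 windows are ranked almost perfectly
(AUC 0.982): the model has found the planted motif. On real data, use
`mg.read_labeled_fasta(pos_fasta, neg_fasta)` in place of the generator.

A command-line interface mirrors the library:

```
m7gformer synth --n-pos 400 --n-neg 400 --out-dir data
m7gformer train --pos data/positives.fasta --neg data/negatives.fasta --seed 1
m7gformer cv    --pos data/positives.fasta --neg data/negatives.fasta --k 10
m7gformer ablate --pos data/positives.fasta --neg data/negatives.fasta
m7gformer predict --checkpoint run/checkpoint.npz --fasta data/positives.fasta
```

Short narrative scripts, one per capability, live in `examples/`.

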