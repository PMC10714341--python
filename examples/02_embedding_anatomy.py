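"""Inspect the embedding pipeline: k-mers, coverage, fusion, position encoding.

Shows the sliding-window tokenisation, the six tokens covering one base,
the convex soft-attention fusion weights, and the 43 x 64 embedded matrix
fed to the encoder.
"""

import numpy as np

import m7gformer as mg
from m7gformer.embedding import (build_coverage, init_embedding_params,
                                 soft_attention_fuse)

print("2-mers of CAGCU:", mg.kmerize("CAGCU", 2).kmers)

cov = build_coverage(41, mg.TokenizerConfig())
print("tokens covering base 20 (scale, start):", cov.entries(20))
print("tokens covering base 0 (start -1 = pad):", cov.entries(0))

params = init_embedding_params(rng=np.random.default_rng(0))
cands = np.random.default_rng(1).normal(size=(6, 64))
fused, w = soft_attention_fuse(cands, params.scale_stage)
print(f"fusion weights (sum {w.sum():.6f}):", np.round(w, 3))
# Weights are a softmax over additive-attention scores, so the fused vector
# is a convex combination of the six candidate embeddings.

pe = mg.position_encoding()
print("position-encoding shape:", pe.shape)
print("row 0 starts:", np.round(pe[0, :6], 3), "(sin 0 / cos 0 alternating)")

ds = mg.generate_dataset(mg.SynthConfig(n_pos=1, n_neg=0, seed=0))
mat = mg.embed_sequence(ds[0], params)
print("embedded window:", mat.shape, "finite:", np.isfinite(mat).all())
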