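# Reference configuration: every key mirrors a ModelConfig / TrainConfig
# field and these values are the documented defaults.
d_model: 64          # embedding / encoder feature dimension
scales: [1, 2, 3]    # k-mer scales (six covering tokens per base)
n_senses: 3          # alternative embeddings per token
n_blocks: 3          # encode blocks
n_heads: 8           # attention heads
d_k: 32              # per-head q/k/v dimension
ffn_hidden: 64       # feedforward hidden width
head_hidden: 16      # output-layer hidden width
dropout: 0.5
pe_base: 1000.0      # sinusoidal position-encoding base b
use_position_encoding: true
use_conv: true
pooling: mean        # or "boundary" (sequence-start row)

learning_rate: 0.0001
batch_size: 32
epochs: 100
precision: float32
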