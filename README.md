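# apindel

Attention-based prediction of template-free CRISPR/Cas9 repair outcomes.

When Cas9 cuts genomic DNA (a blunt double-strand break 3 nt upstream of the
NGG PAM), the cell's end-joining machinery resolves the break into a
reproducible, sequence-dependent spectrum of short insertions and deletions:
NHEJ yields small indels at the junction, while MMEJ deletes the stretch
between short direct repeats (microhomologies) flanking the break. Because
the spectrum is determined largely by the local sequence, it can be
predicted from the ~60 bp around the cut. This package implements the
Apindel architecture for that prediction task, for genome-engineering
researchers who need per-outcome probabilities rather than coarse summary
statistics.

## The model

A target is a 60 bp window with the PAM's first base at 0-based index 33,
so the cut lies between indices 29 and 30. The predicted object is a
probability distribution over **557 repair classes**: 536 deletion classes
(cut-relative start + length, length < 30 bp, overlapping the −3..+2
window), 4 single-nucleotide insertions, 16 dinucleotide insertions, and
one class for insertions ≥ 3 bp. A deletion class is written `-5+4`
("4 bp deleted starting 5 nt upstream of the cut"); sequencing-pipeline
descriptors such as `D4_L-6R-1` are converted into this taxonomy, with
the `C{m}` microhomology component handled as an m-base rightward shift.

The network input is built without manual feature engineering:

1. the sequence is tokenized into 59 overlapping 2-mers
   (L = (60 − 2)/1 + 1), each keyed by (k-mer, position) — a closed
   vocabulary of 16 × 59 = 944 tokens;
2. GloVe vectors ψ(ω) ∈ R^d are fit to the log token co-occurrence counts
   by weighted least squares,
   J = Σ f(X_ij)(w_i·w̃_j + b_i + b̃_j − ln X_ij)², with
   f(x) = (x/x_max)^α below x_max and 1 above;
3. a fixed sinusoidal positional vector p_t (entries sin(ω_k t), cos(ω_k t)
   with ω_k = 10000^(−2k/d)) is added: ψ′(ω_t) = ψ(ω_t) + p_t.

The 59 × d matrix passes through a bidirectional LSTM (h_i ∈ R^C,
C = 2·units), an additive attention layer
a_i = softmax_i(w₂ᵀ tanh(W₁ h_i)), context pooling c = Σ a_i h_i, batch
normalization, an MLP, and a 557-way softmax. Training minimizes
categorical cross-entropy against *soft labels* (the observed per-target
outcome frequencies) with Adam, L1 penalties on the recurrent and attention
kernels, reduce-on-plateau learning-rate decay and early stopping on
validation MSE. The averaged attention vector (α₁,…,α₅₉) identifies which
sequence loci drive the prediction.

A seeded synthetic-data generator (`apindel.simulate`) emulates screen-like
data — NGG targets with mechanistic, strictly cut-local outcome
distributions (length-penalized deletions, microhomology bonuses,
−1-base-duplicating 1 bp insertions, multinomial read noise) — so the whole
pipeline is testable without downloading any screen dataset.

## Worked example

```python
import numpy as np
from apindel import SimConfig, GloveEmbedder, generate_dataset, enumerate_label_space
from apindel.network import IndelOutcomePredictor
from apindel.evaluate import evaluate_tasks, high_attention_regions

space = enumerate_label_space()
records = generate_dataset(SimConfig(n_targets=300, seed=7), space)
train, test = records[:240], records[240:]

model = IndelOutcomePredictor(
    embedder=GloveEmbedder(dim=32, max_iter=500, optimizer="adagrad", random_state=7),
    units=16, attention_T=16, mlp_hidden=64, dropout_p=0.2,
    learning_rate=3e-3, max_epochs=60, lr_patience=25, stop_patience=45,
    batch_size=64, random_state=7,
)
model.fit([r.sequence for r in train], np.stack([r.distribution for r in train]))
report = evaluate_tasks(model, test, space)
profile = model.attention_profile([r.sequence for r in test])
```

Output of this exact script (small demonstration scale — 240 training
targets and a reduced model, so task correlations are weak):

```
trained for 57 epochs; best validation MSE 5.60e-05
held-out MSE over 557 classes: 9.18e-05
AUC  : {'ins1': 0.43, 'del1': 0.59, 'deletion': 0.48, 'frameshift1': 0.56, 'frameshift2': 0.6, 'frameshift_overall': 0.51}
tau-b: {'ins1': -0.09, 'del1': 0.1, 'deletion': -0.07, 'frameshift1': 0.11, 'frameshift2': 0.09, 'frameshift_overall': 0.01}
high-attention regions (token positions): [(23, 29), (33, 36)]
top predicted outcomes for sim_00240: [('1+C', 0.048), ('1+G', 0.035), ('1+A', 0.034)]
```

The held-out MSE is the mean squared error over all (record, class) cells;
the six task columns collapse each 557-class distribution into 1 bp
insertion, 1 bp deletion, total deletion, and frameshift (1 bp / 2 bp /
overall) frequencies, scored by median-split AUC and Kendall tau-b. Even at
this tiny scale the high-attention regions sit over token positions 23–36 —
the cut lies between tokens 29 and 30 — reproducing the expectation that
the bases flanking the cleavage site dominate the prediction.

The same pipeline is available from the shell:

```bash
apindel simulate --seed 7 --n 300 --out data/
apindel fit-embedding --targets data/targets.fasta --out emb.npz --dim 32 --max-iter 500
apindel train --targets data/targets.fasta --outcomes data/outcomes.tsv \
    --embedding emb.npz --out model/ --units 16 --attention-t 16 --max-epochs 60
apindel predict  --model model/ --targets data/targets.fasta --out pred.tsv
apindel evaluate --model model/ --targets data/targets.fasta \
    --outcomes data/outcomes.tsv --out metrics.json
apindel attention --model model/ --targets data/targets.fasta --out profile.tsv
```

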