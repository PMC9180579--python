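# Methods

## The outcome taxonomy

Repair outcomes are summarized into 557 classes: 536 deletions, 4
single-base insertions, 16 dinucleotide insertions, and one ≥3 bp
insertion class. Coordinates are cut-relative integers with the blunt cut
between positions −1 and 0 (position 0 = first base 3′ of the cut); in the
60 bp input window this corresponds to the cut between 0-based indices 29
and 30, with the PAM's first base at index 33.

A deletion class is a (start, length) pair. The panel admits lengths
1–29 bp whose interval [start, start+length) overlaps the window from 3 nt
upstream to 2 nt downstream of the cut (positions −3..+1), with starts
floored at −26. The floor is a calibration constant: the window rule alone
admits length+4 starts per length (551 pairs in total), while capping the
per-length count at 28 — equivalently `start ≥ −26` — yields the published
panel size of exactly 536. The enumeration is an explicit, versioned
construction in `labels.enumerate_label_space`, pinned by tests; it is not
re-derived from the verbal rule at run time.

Sequencing descriptors (`D{size}_L{left}[C{m}]R{right}`,
`I{size}_L{left}R{right}`) convert via `start = left + 1 + m`,
`length = right − left − 1 − m`: a `C{m}` microhomology component shifts
the reported deletion m bases rightward and shortens the gap accordingly —
the unique affine rule consistent with the worked conversions
(`D1_L-2C1R1` → `0+1`, `D4_L-6R-1` → `-5+4`, `I1_L-1R0`+T → `1+T`).
Deletions outside the panel map to an explicit out-of-taxonomy sentinel;
aggregation drops them with a log and renormalizes (never imputes).

Strand orientation reflects position p to −1 − p, so a deletion [s, s+L)
maps to start −(s+L); this is the reflection consistent with a symmetric
60 bp window and is an involution, verified against brute-force interval
reflection in the tests. Inserted bases are reverse-complemented.

Frame classes are indel length mod 3; the ≥3 bp insertion class has
unknown true length and is treated as length 3 (in-frame) by default, with
a flag to exclude it from frameshift sums instead.

## Input encoding

Sequences are tokenized with a sliding window (k-mer size 2, step 1):
a 60 nt window gives 59 tokens at 1-based positions. Each (k-mer, position)
pair is a vocabulary entry (16 × 59 = 944); a configuration switch
collapses the vocabulary to the 16 bare k-mers instead (the positioned
vocabulary is the default).

GloVe vectors are fit to the symmetric token co-occurrence matrix
(window diameter 5, weight 1/distance within a sequence) by minimizing the
weighted least-squares objective over nonzero entries only. Defaults:
embedding dimension d = 150, truncation x_max = 10 000 with exponent
α = 0.75 (x_max = 'auto' uses the mean of the nonzero entries), up to
20 000 full-batch iterations. The word vector is w + w̃. The default
optimizer is fixed-step gradient descent with a step-halving safeguard: a
step that would increase the objective is rejected and the step halved, so
the logged objective trace is non-increasing by construction. AdaGrad is
available and converges far faster at small iteration budgets; the scaled
test profile uses it (500 iterations) because fixed-step descent at a few
hundred iterations leaves the k-mer-identity spread in the vectors an
order of magnitude below the positional-encoding scale, making sequences
nearly indistinguishable to the downstream network.

Positional encoding is the fixed sinusoid p_t(2k) = sin(ω_k t),
p_t(2k+1) = cos(ω_k t), ω_k = 10000^(−2k/d), added (not concatenated) to
the token vector; its dimension therefore equals the embedding dimension.
Positional dropout is 0 and is not implemented as a layer. For odd d the
final entry falls on the sine branch.

## Network and training

Architecture: BiLSTM (default 50 units per direction, feature dim
C = 100), additive attention a_i = softmax_i(w₂ᵀ tanh(W₁ h_i)) with
W₁ ∈ R^{T×C} (T = 64 by default; the hyperparameter is exposed), context
c = Σ a_i h_i, batch normalization on the context vector, one ReLU hidden
layer (width 128), dropout (p = 0.5), 557-way softmax. The LSTM uses ReLU
as the candidate/output activation as published, with tanh selectable;
gates are sigmoid and the forget-gate bias initializes to 1. L1 penalties
(λ = 1e−4) apply to the recurrent and attention kernels only — biases are
exempt.

Training: Adam at learning rate 1e−4, batch size 64, categorical
cross-entropy against soft labels, validation MSE as the monitored metric;
the learning rate is multiplied by 0.2 after 1 epoch without improvement,
training stops after 3 stale epochs (max 100), and the weights of the
best-validation epoch are restored. The softmax output bias is initialized
to the log of the mean training distribution (class priors), so
optimization starts at the best constant predictor and spends its budget
on sequence dependence. Dropout and batch-norm statistics are active in
training mode only; inference uses running averages (momentum 0.9,
ε = 1e−5). All randomness (init, shuffling, dropout masks) derives from a
single seed; identical configuration + seed reproduces datasets,
embeddings, histories, and predictions bit-for-bit. A non-finite loss
aborts with a diagnostic rather than training through NaNs.

The whole network — forward passes, backpropagation through time, Adam —
is implemented in NumPy. Gradients are verified against central finite
differences (≤ 1e−4 relative error across every parameter tensor; the
GloVe gradient to ≤ 1e−5).

### Scaled profile

Tests and demonstrations use a scaled profile (`scaled_test_config`):
d = 32, 16 units per direction, T = 16, MLP width 64, dropout 0.2,
learning rate 3e−3, batch 64, up to 120 epochs, plateau patience 25 and
stop patience 45. The published patience values (1 and 3 epochs) assume
hundreds of optimizer steps per epoch at full data scale; at 1600 training
records an epoch is ~25 steps, so the scaled profile stretches patience to
comparable step counts. Problem sizes used by the test suite: 2000
synthetic targets (1600/200/200 split) for the end-to-end properties,
40–120 targets for unit and pipeline tests.

## Evaluation

* Global MSE over all (record, class) cells.
* Six aggregate tasks per distribution: 1 bp insertion, 1 bp deletion,
  total deletion, frame-class-1, frame-class-2, and overall frameshift
  frequency (the sum of the last two). "1 bp frameshift" is read as frame
  class 1 (net indel length mod 3 = 1), not "frameshift caused by 1 bp
  indels"; the alternative reading is noted but not implemented.
* Median-split AUC: true task values are binarized at their median —
  strictly above = positive, ties at the median = negative (the paper-side
  rule is silent on ties; this choice is pinned by tests) — and the
  prediction is scored as a ranking with Mann–Whitney tie correction. The
  split uses the *true* values, the only reading that yields a label.
* Pearson correlation and Kendall tau-b (tie-corrected; task frequencies
  tie often). Degenerate inputs (zero or float-epsilon variance, empty
  classes, n too small) raise `UndefinedMetricError` instead of returning
  NaN.
* High-attention regions: maximal runs of token positions whose mean
  attention exceeds mean + 1 SD of the profile (no published rule exists;
  the threshold is configurable).

## Synthetic data generator

The generator emulates the data regime of pooled repair screens —
thousands of 60 bp NGG targets with per-target outcome frequencies
estimated from a few hundred UMI-deduplicated reads — with a mechanistic
ground truth confined to ±10 bp of the cut:

| parameter | default | meaning |
|---|---|---|
| `mh_decay` (τ) | 6 bp | deletion length penalty e^(−L/τ) |
| `mh_bonus` | 4 | multiplier per bp of exact flanking microhomology |
| `ins1_match_weight` / `ins1_other_weight` | 3 / 1 | 1 bp insertion duplicating the −1 base vs others |
| `background_del` | 0.25 | deletion weight scale; yields ≈ 2/3 deletion mass and ≈ 30% 1 bp-insertion mass, the balance real screens show |
| `ins2_weight`, `ins3_weight` | 0.02, 0.1 | small fixed weights for 2 bp and ≥3 bp insertions |
| `noise_counts` | 500 | multinomial read depth; 0 = store exact ground truth |
| `locality` | 10 bp | no base outside ±locality of the cut affects the distribution |

Microhomology length for deletion [s, s+L) counts exact matches between
the deleted prefix and the bases immediately 3′ of the deletion, using only
bases inside the locality window, so the distribution is a deterministic
function of the central 20 bp by construction. The ground truth is always
retained next to the noisy observation for oracle-based tests.

What the generator does *not* emulate: cell-line and repair-pathway
variation, large deletions and structural variants, insertion sequences
beyond 2 bp, position-dependent sequencing artifacts, or outcome coupling
between targets. Passing tests on this generator therefore demonstrate
that the pipeline is correctly plumbed and that the model can localize and
exploit cut-proximal signal — not that it attains screen-level accuracy on
real data.

## Known limitations

* The microhomology mechanism makes most between-target variance live in
  sparse, heavy-tailed deletion spikes (the bonus is multiplicative in MH
  length). Learning that structure from raw embeddings requires the
  network to discover pairwise base-equality features; at the scaled
  profile (2000 targets, 32-dim context) the model reliably learns the
  linearly decodable component (insertion-base preference, attention
  localization) but does not reliably clear the 20%-below-constant
  learnability bar that the end-to-end check demands — see that check's
  output for the measured margin on any given run.
* The deletion panel's −26 start floor is a calibration, not a derivation;
  alternative floors change the panel size.
* The short-sequence padding rule (cyclic "ATG" before reverse, "ATGC"
  after forward inputs) is a documented stand-in for an appendix-level
  convention that is not fully specified in the source description.
* Full-size training (d = 150, 50 units, 20 000 GloVe iterations) is
  supported but sized for real screen data on capable hardware; the test
  suite exercises the scaled profile only.
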