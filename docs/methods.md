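# Methods

This note records the models implemented, the choices made where the design
was genuinely open, and what the synthetic experiments do and do not show.

## Pipeline

Feature vectors (1 × 4096, non-negative) are treated as 1-D signals, reduced
to 1 × 2054 approximation coefficients by one level of the Daubechies-7
discrete wavelet transform, and classified by a bidirectional LSTM whose
timesteps are the individual coefficients. KNN and SVM baselines and DCT/FWHT
transform alternatives consume identical inputs and identical split plans so
that comparisons isolate the classifier or the transform.

## Wavelet stage

* **Filter bank.** The db1–db10 analysis lowpass filters are embedded as
  double-precision constants (the canonical published coefficients) and
  validated at construction against the orthonormality invariants:
  Σh = √2, Σh² = 1, orthogonality to even shifts, and quadrature-mirror
  highpass g[k] = (−1)^(k+1) h[L−1−k] with Σg = 0. Embedding rather than
  computing by spectral factorization at run time makes the filters exact,
  deterministic and auditable.
* **Convention.** Decomposition extends the signal by L−1 samples per side
  (half-point symmetric replication by default; periodic and zero-padding
  optional), convolves (valid part), and keeps odd-indexed outputs (origin
  0). Coefficient count: ⌊(n + L − 1)/2⌋ — exactly 2054 from 4096 with db7.
  Reconstruction upsamples by two, convolves with the time-reversed filters,
  and trims L−2 leading samples; round-trip error is at machine precision
  for every supported order, length and mode (property-tested, and checked
  against PyWavelets as an independent oracle in the test suite only — the
  implementation itself is self-contained).
* **cA vs cD.** The approximation branch feeds the classifier; a flag
  exposes the detail branch for experimentation.
* **Alternatives.** DCT is the orthonormal type-II variant (exact Parseval);
  FWHT is the 1/√n-normalized butterfly (involutive), requiring power-of-two
  length. Neither reduces dimension; both are provided as comparison arms.

## BiLSTM classifier

* **Cell.** Standard forget/input/candidate/output gate equations over the
  concatenation [h_{t−1}, x_t]; memory C_t = C_{t−1}∘f_t + i_t∘c̃_t; output
  h_t = o_t∘tanh(C_t). A scalar single-step implementation is the public,
  inspectable surface; training runs packed batched kernels whose gate
  blocks are ordered (f, i, o, c) so the three sigmoids evaluate in one
  vectorized call. Sigmoids are computed as (tanh(z/2)+1)/2: tanh neither
  overflows nor emits subnormal values, which keeps single-precision
  training off the pathologically slow denormal arithmetic path.
* **Readout.** Final hidden states of the forward pass and of the pass over
  the reversed sequence, concatenated (2 × 100 = 200), then inverted dropout
  (training only), two fully connected layers (64, then n_classes; ReLU
  between) and softmax. The final-state readout is the conventional
  sequence-to-label choice for this architecture.
* **Training.** Minibatch Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8) on mean
  cross-entropy, epoch-wise reshuffling from a seeded generator, global
  L2 gradient-norm clipping at threshold 1 (per-element clipping optional).
  Defaults: 400 epochs, batch 10, learning rate 0.01, 50% dropout — the
  reference operating point for full-scale training. Arithmetic is single
  precision by default (double optional); inference and gradient checking
  always run in double precision. Given a seed, training is bit-reproducible.
* **Backpropagation through time** is hand-written and verified by central
  finite differences (max relative error < 1e−5 at step 1e−6 on small
  models, with the relative-error denominator floored at 1e−4 because the
  probe itself carries ~1e−10 of cancellation noise). The backward pass
  truncates once the backpropagated signal falls below 1e−10 of its initial
  magnitude: those contributions are beneath the resolution of the
  accumulated weight gradients, and truncation prevents both wasted work and
  subnormal-arithmetic slowdowns on long sequences.
* **Weight initialization.** Glorot-uniform weights, zero biases except the
  forget-gate bias at 1 (keeps the memory path open early). Seed-controlled.

## Evaluation

* Binary metrics use the malignant-like class (index 1) as positive:
  accuracy, sensitivity, specificity (percent), Youden's J = sens + spec − 1.
  Zero denominators yield NaN plus an explicit `undefined` flag, never a
  silent zero. Display rounding is one decimal for percentages and two for
  J; logs keep full precision.
* Multiclass metrics are unweighted one-vs-rest macro averages by default; a
  micro-averaged option exists (on balanced test sets micro sensitivity
  equals accuracy, which is worth knowing when reading three-class tables).
* Repeated holdout draws per class ⌊0.7·n_c⌋ training samples (remainder to
  test): 56/56 → 39 + 39 train, 17 + 17 test. Stratified k-fold assigns each
  class round-robin to k folds, covering every sample exactly once. Both are
  seed-deterministic. Aggregation reports mean and sample (n−1) standard
  deviation per metric; per-split rows are retained so the summary is
  recomputable.
* ROC curves sweep the unique score thresholds; the trapezoidal area equals
  the Mann–Whitney concordance probability (tested against a brute-force
  pair count).

## Synthetic data generator

The generator emulates what the pipeline actually relies on in pretrained-CNN
activation vectors: non-negativity, sparsity, and class information carried
by localized high-amplitude discontinuities.

* Background: each entry is zero with probability `sparsity` (default 0.9),
  otherwise |N(0, base_scale)|. Gaussian noise (sd 0.05) perturbs active
  units only, then values re-rectify at zero, so the realized zero fraction
  stays at the configured sparsity.
* Spikes: each sample receives Poisson(rate_c) spikes of amplitude
  `base_scale × spike_scale` (default 12, ±20% per-spike jitter) placed on
  its class's anchor set — the Gaussian-quantile grid (`anchor_density` ×
  rate points, default density 2; window sd 5% of the width) of a
  class-specific window of the index range. Anchored placement makes
  same-class vectors share spike locations, which is what gives a
  nearest-neighbour classifier its raw-feature signal; the anchor density is
  the dial on how much same-class vectors overlap, i.e. on how hard the raw
  feature space is for a distance-based classifier. Identical (rate, window)
  settings make classes exactly identically distributed, which pins the
  chance-level contract.
* Windows default to fractions 0.03 … 0.97 of the index range across
  classes. Placing class windows against the two ends matters for the
  *final-state* BiLSTM readout: each direction's final state is most
  sensitive to late timesteps, and the two directions together cover both
  ends. An early design with mid-sequence windows produced data whose
  classes a linear probe could separate from the readout but that gradient
  training exploited far more slowly.
* Defaults model the two-class study scale: 56 + 56 samples, rates (20, 5)
  — a rate ratio of 4, "well separated" — at which a plain 5-NN on the raw
  4096-dim features scores in the mid-90s held out (comfortably above the
  90% learnability contract) while leaving the wavelet-reduced BiLSTM
  headroom to beat it.
* One `numpy` generator seeded by `config.seed` drives all draws in a fixed
  documented order; identical seeds give bit-identical datasets.

**What passing these tests shows — and does not.** The synthetic conditions
verify that every stage is implemented correctly and that the pipeline
extracts localized-discontinuity class structure end to end. They do not
certify performance on real CT/MR-derived features, whose discriminative
structure is richer (distributed correlations, amplitude effects, no clean
anchor geometry) and whose headline accuracies depend on private data.

## Scaled-down experiment sizes

Full-scale defaults (400 epochs) reflect the reference protocol; the
package's own end-to-end experiments and acceptance tests run a documented
scaled-down operating point chosen once for the synthetic study conditions:
50 epochs per split, learning rate 3e-4, dropout disabled. At 50 epochs the
short schedule needs a gentler, steadier optimizer setting than the
full-scale default (learning rate 0.01 is tuned for long training and
destabilizes the recurrent dynamics here), and dropout's multiplicative
noise on the readout costs more than its regularization buys on a
60-iteration-per-epoch budget. These are properties of the short protocol,
not corrections to the reference configuration, which remains the default.

## Known limitations

* Single decomposition level and 1-D transforms only; no wavelet packets or
  2-D DWT.
* The real pretrained-CNN extractor is an interface with a deliberate
  unavailability error; only the hashing mock backend ships. Image resizing
  policy for a real backend is documented at the adapter, not fixed here.
* One LSTM layer per direction; no stacking, attention, or sequence outputs.
* The training loop is CPU/numpy; it is tuned to be practical (workspace
  reuse, truncated BPTT, single precision) but makes no GPU claims.
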