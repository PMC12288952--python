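# Methods

## Problem

`m6aloco` predicts whether a fixed-length nucleotide window centered on an
adenosine carries an N6-methyladenosine (m6A) modification, and — just as
importantly — measures how much of a predictor's apparent skill survives
when evaluation respects genomic structure.  Standard random train/test
splits place windows from the same chromosome on both sides of the split,
so a model can score well by memorizing chromosome-specific background
(composition, regional biases) rather than learning transferable motif
biology.  Leave-one-chromosome-out (LOCO) evaluation removes that shortcut:
each fold holds out every window of one chromosome and trains on the rest.

## Data model and balancing

A dataset is an ordered set of records `(id, chromosome, sequence, label)`
with a common window length `L` (2001 nt at full scale).  Because negative
windows outnumber positives roughly 5:1 in the benchmark this package is
shaped around, the pipeline first builds balanced replicates: negatives are
shuffled (seeded) and dealt round-robin into `n_subsets` disjoint subsets
whose sizes differ by at most one, each paired with all positives to give a
1:1 replicate `D_i`.  No record is discarded; results can be averaged over
replicates.

## Feature encodings

* **k-mer composition** (default k=5): a 4^k = 1024-dimensional vector of
  step-1 sliding-window counts, indexed lexicographically over (A,C,G,T).
  Windows containing `N` contribute to no entry.  The default vector holds
  raw counts (for an N-free window the entries sum to `L-k+1`); an option
  divides by the number of valid windows.  The experiment pipeline uses the
  frequency-normalized form, which conditions the hybrid models' dense
  inputs far better than raw counts at any window length.
* **one-hot**: an `L x 4` binary matrix, columns (A,C,G,T); `N` rows are
  all-zero.  Positions-by-channels orientation is used throughout because
  the 1-D convolutions consume (length, channels); it is the transpose of
  the equivalent channels-by-positions presentation.

## Model family

All variants share a convolutional trunk over the one-hot matrix:
Conv1D(64 filters, kernel 23, stride 1, ReLU, length-preserving padding) ->
MaxPool(15) -> Dropout(0.5) -> Conv1D(128, 33, 1, ReLU, same padding) ->
MaxPool(15) -> Dropout(0.5) -> Flatten.  At L=2001 the length chain is
2001 -> 133 -> 8, so the flatten width is 8 x 128 = 1024.

* **SM** — trunk -> Dropout(0.5) -> Dense(1, sigmoid).
* **HM** — the raw 1024-dim k-mer vector is concatenated with the trunk
  output (width 2048) before Dropout and the sigmoid dense.
* **DHM** — the k-mer vector first passes Dense(64, ReLU); the deep k-mer
  embedding is concatenated with the trunk (width 1088).

One batch-normalization layer (momentum 0.99, eps 1e-3) is applied to the
fused vector between the final dropout and the output dense; a flag
disables it.  The narrative sources for this architecture mention batch
normalization without fixing its position, and give two readings of the
kernel sizes (13/23 vs 23/33); this package defaults to the layer table's
23/33 and exposes both as configuration.

Training follows a fixed regimen: Adam (lr 0.001, beta1 0.9, beta2 0.999),
batch size 64, binary cross-entropy, 70 epochs, no early stopping or
schedule.  The network core is a self-contained NumPy implementation
(explicit reverse-mode gradients for conv/pool/dense/dropout/batch-norm,
verified against central-difference numerical gradients in float64); with a
fixed seed, training is bit-for-bit reproducible single-threaded.

### Desk-scale profile

Tests and the bundled experiments use a reduced geometry chosen once for
CPU desk scale: L=201, kernels 11/11, pool 5 (length chain 201 -> 40 -> 8),
with the full-scale filter counts 64/128 retained so the flatten width
stays 1024 and the fused widths keep their full-scale values.  The training
regimen (lr, batch size, 70 epochs) is unchanged unless a run overrides
epochs explicitly.  The faithful L=2001 geometry remains the constructor
default.

## Splitting protocols

* **RS (random split)** — a stratified holdout of `round(0.2 n)` records,
  plus 5 stratified cross-validation folds partitioning the training pool.
  Stratification is on the label (on by default).
* **LOCO** — one fold per distinct chromosome label, ordered by natural
  sort (chr2 before chr10); the fold's test set is exactly that
  chromosome's records, its training pool all other chromosomes, with inner
  stratified CV partitions of the pool stored alongside.  Chromosome labels
  are opaque strings; nothing maps "chr23" to chrX.  A leakage auditor
  asserts zero train/test chromosome overlap per fold and is itself tested
  against deliberately corrupted plans.

Split plans serialize to JSON (mode, seed, per-fold id lists) for exact
reuse.

## Metrics

Accuracy, sensitivity, specificity and MCC are computed from the confusion
matrix at threshold 0.5 (a probability exactly at threshold counts as a
positive call).  Zero-denominator cases are reported as undefined with a
reason and excluded from aggregation with a disclosed count — never coerced
to 0.  AUC-ROC is the tie-corrected Mann-Whitney rank statistic, which
equals the trapezoidal ROC integral exactly on finite samples and is
invariant under strictly increasing score transforms.  Confidence intervals
over repeated evaluations use the normal approximation
`mu +/- z * s / sqrt(n)` with the sample (n-1) standard deviation
(z = 1.959964 at 95%), or a seeded percentile bootstrap.  Aggregation over
CV folds, chromosomes, or replicates is the unweighted mean of defined
values.  t-SNE views of internal embeddings (raw k-mer, deep k-mer, CNN,
fused taps) are seeded and written as CSV plus PNG.

## Synthetic data

The generator emulates the structure of a base-resolution m6A benchmark
without any download: windows of length L centered on an adenosine,
chromosome labels, ~1:5 class imbalance at the paper-scale preset
(10,424 / 54,949 windows, L=2001, chr1-chr23), and positives enriched for
the DRACH consensus `[AGT][AG]AC[ACT]` placed within a small jitter of the
window center (a concrete instance of the degenerate consensus is sampled
per insertion).  Desk-scale defaults are hundreds of records at L=201.

Two constructions matter for evaluation studies:

* **Motif-separable fixture** — insertion probability 1.0 for positives and
  0.0 for negatives, with `motif_exclusive=True` resampling chance
  occurrences of the consensus out of the background, so the motif is the
  sole and sufficient signal.  Used for learning-sanity checks.
* **Confounded pair** — chromosomes alternate between GC-shifted and
  AT-shifted groups (shift of 0.15*gamma probability mass per base), and a
  positive record lands in the GC-shifted group with probability
  (1+gamma)/2.  Motif insertion probabilities are equalized across classes
  here, so the composition shortcut is the only learnable signal.  It
  generalizes within chromosomes but not across them: random splits reward
  it; LOCO folds expose it.  The confounder lives purely in the background
  composition, never in the motif, so the "cheating" feature is cleanly
  separable from genuine signal.

What the generator does **not** model: transcript structure, tissue
specificity, real m6A-Atlas genomic context, homology between windows, or
non-uniform chromosome sizes.  Passing tests on synthetic data therefore
demonstrate the machinery (encodings, architecture, splitting, metrics,
and the leakage phenomenon), not clinical-grade predictive performance on
real transcriptomes.

## Experiment orchestration and seeds

`run_experiment` composes balance -> split -> encode -> train -> evaluate
-> report for each replicate x mode x variant, writing split plans,
checkpoints, per-fold and test reports, ROC points, a long-format summary
CSV, and a manifest (config, seed, versions, wall time).  All stage seeds
derive from one global seed via SHA-256 of `(seed, stage tags)` reduced
mod 2^31, so a single integer reproduces a run exactly.

## Numerical and design notes

* Pooling truncates (floor) — forced by the reference length chain
  2001 -> 133 -> 8.
* Conv padding is length-preserving ("same"), forced by the conv rows
  preserving length in the reference table.
* Predictions are clipped to [1e-7, 1-1e-7] so downstream logs are finite.
* The sigmoid is fused with the loss (logits + `log1p(exp(-|z|))`) for
  stability; dropout is inverted (identity at inference).
* Wrong-length sequences are rejected at the I/O boundary unless a pad
  policy (`center-crop` / `n-pad`) is selected; `U` maps to `T`; other
  non-ACGTN characters map to `N` with a warning.

## Known limitations

* The desk-scale profile's absolute numbers are not comparable to
  full-scale results on the real benchmark; only the qualitative contrasts
  (learnability, RS-vs-LOCO gap) are meaningful at this size.
* DHM's extra dense capacity memorizes small training sets faster than the
  trunk learns transferable features, so at ~1,000 records its held-out
  AUC trails SM/HM — an echo, at desk scale, of DHM's weaker
  chromosome-level generalization at full scale.
* The NumPy core is CPU-only and single-threaded deterministic; it is not
  intended for datasets beyond ~10^5 windows.
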