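# m6aloco

Hybrid k-mer + CNN prediction of N6-methyladenosine (m6A) sites in mRNA,
with leakage-aware evaluation: random splits (RS) versus
leave-one-chromosome-out (LOCO) cross-validation.

## Who this is for

m6A is the most abundant internal mRNA modification; predicting modified
adenosines from sequence alone is a standard epitranscriptomics task.  Most
published predictors are evaluated on random train/test splits, which let
windows from the same chromosome appear on both sides of the split — a
model can then score well by exploiting chromosome-specific background
rather than transferable motif biology.  This package is for
computational-biology practitioners who want (a) the hybrid model family
itself and (b) the machinery to measure how much of a model's apparent
skill survives chromosome-level holdout.

## The models

All three variants share a convolutional trunk over the one-hot encoded
window `x ∈ {0,1}^(L×4)` (L = 2001 by default):

    Conv1D(64, k=23, same, ReLU) → MaxPool(15) → Dropout(0.5)
    → Conv1D(128, k=33, same, ReLU) → MaxPool(15) → Dropout(0.5) → Flatten

giving a 1024-dim CNN feature vector (2001 → 133 → 8 positions × 128
channels).  The k-mer branch is the 4^5 = 1024-dim 5-mer composition
vector `[f(K₁), …, f(K₁₀₂₄)]`.

* **SM** (simple): CNN features → Dense(1, sigmoid)
* **HM** (hybrid): concat(CNN 1024, k-mer 1024) = 2048 → Dense(1, sigmoid)
* **DHM** (deep hybrid): k-mer → Dense(64, ReLU); concat(1024, 64) = 1088
  → Dense(1, sigmoid)

Training: Adam (lr 0.001), batch 64, binary cross-entropy, 70 epochs.
The neural-network core (convolution, pooling, dense, dropout, batch norm,
Adam, with exact reverse-mode gradients) is implemented in NumPy inside the
package and is bit-for-bit reproducible under a fixed seed.

Evaluation: accuracy, sensitivity, specificity, MCC and AUC-ROC (rank-based
Mann–Whitney estimator), with normal-approximation or bootstrap confidence
intervals; undefined metrics (zero denominators, single-class folds) are
reported as undefined with a reason, never silently zero.

LOCO follows the standard loop: split the data by chromosome; for each
chromosome train on all others, test on the held-out one, and average over
chromosomes.  A leakage auditor proves each plan has zero train/test
chromosome overlap.

## Worked example

A synthetic, chromosome-confounded dataset makes the RS-vs-LOCO contrast
reproducible in minutes with no download.  Labels are partially predictable
from chromosome-specific GC background (confound strength γ = 0.8), and the
motif signal is equalized between classes, so *everything* a model can
learn is a within-chromosome shortcut:

```bash
m6aloco run --mode both --variants HM --confounded --gamma 0.8 \
        --n-pos 250 --n-neg 250 --epochs 15 --seed 1 -o runs/confounded
```

The summary table (also written to `runs/confounded/summary.csv`) contains
one test-scope row per protocol:

```
 replicate mode variant scope  accuracy  sensitivity  specificity      mcc  auc_roc   n
         1   RS      HM  test  0.890000        0.920        0.860 0.781408 0.918800 100
         1 LOCO      HM  test  0.899467        0.500        0.500      NaN 0.529354 500
```

Read the AUC column: the same architecture on the same data discriminates
with AUC ≈ 0.92 when chromosomes are shared between train and test, and is
at chance (AUC ≈ 0.53) when every test chromosome is unseen — the RS figure
is entirely leakage.  (The LOCO accuracy stays high only because confounded
chromosomes are nearly single-class, which is why the per-fold AUC and the
undefined-metric disclosures matter.)  On an unconfounded control
(`--gamma 0`) the two protocols agree.

The library surface mirrors the CLI:

```python
import m6aloco as m

kv = m.encode_kmer("CAAATGTACG", 5)   # 6 windows over a 1024-dim vector
ds = m.generate(m.SynthConfig(n_pos=500, n_neg=500, L=201, seed=7))
bd = m.balance_negatives(ds, n_subsets=1, seed=0)[0]
plan = m.loco_split(bd)               # one fold per chromosome
m.audit_chromosome_leakage(plan, ds)  # raises on any overlap
```

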