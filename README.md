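# trendy

Transformer-enhanced inference of gene regulatory networks (GRNs) from
single-cell expression snapshots.

## The problem

A GRN over n genes is a signed directed graph: gene i activates (+1),
ignores (0) or represses (−1) gene j.  Single-cell experiments measure a
cells × genes expression matrix at each of a few time points, with no
cell correspondence across times.  The task is to recover the network
from those snapshots.

The mechanism-based WENDY approach estimates gene–gene covariances K0
and Kt (t time units apart, via graphical lasso) and solves

    min_A  ½ Σ_{i≠j} [ Kt − (I + tAᵀ) K0 (I + tA) ]²_{ij}

a non-convex least-squares problem derived from linearized expression
dynamics.  TRENDY wraps this solver in two transformer-encoder refiners
TE(k) (k input n×n matrices → one n×n output, with 2-D sinusoidal
positional encoding and segment embeddings, size-independent in n):

1. TE(k=1) maps the measured Kt to a pseudo-covariance Kt′ approximating
   Kt* = (I + tAᵀ_true) K0 (I + tA_true), the covariance the linearized
   model predicts under the true network; A1 = WENDY(K0, Kt′).
2. TE(k=3) maps (A1, K0, Kt) to the final score matrix A2.

Both refiners are trained on synthetic corpora generated by a stochastic
model of expression dynamics with known ground-truth networks.  The same
enhancement pattern applies post-hoc to other inference methods
(random-forest GENIE3-style, Kolmogorov–Smirnov SINCERITIES-style, or
any externally computed score matrix).  Networks are scored by
AUROC/AUPRC over off-diagonal edges.  See `docs/methods.md` for the
model, training protocol and design choices.

## Worked example

```python
import numpy as np
from trendy import (
    SimulationParams, generate_corpus, wendy_infer, score_grn,
)

# simulate 30 networks of 10 genes, 100 cells each, noise sigma = 0.1
corpus = generate_corpus(30, n=10, params=SimulationParams(), rng_seed=7)

aucs = []
for grn, data in corpus:
    a0 = wendy_infer(data.at_time(0.5), data.at_time(1.0), t=0.5)
    aucs.append(score_grn(grn, a0).auroc)
print(f"WENDY mean AUROC over {len(aucs)} networks: {np.mean(aucs):.3f}")
```

Output:

```
WENDY mean AUROC over 30 networks: 0.622
```

0.5 is chance level for the 90 off-diagonal edge decisions per network;
the covariance-matching solver alone reaches ≈ 0.6 under these study
conditions.  Training the two refiners on a larger corpus and calling
`trendy_infer` instead of `wendy_infer` is the full pipeline:

```python
from trendy import TEConfig, TrainConfig, train_trendy, trendy_infer

train = generate_corpus(2000, n=10, rng_seed=1)
val = generate_corpus(200, n=10, rng_seed=2)
te1, te3, info = train_trendy(
    train, val_corpus=val,
    te1_config=TEConfig(k=1, d=32, l=2, h=4),
    te3_config=TEConfig(k=3, d=32, l=2, h=8, standardize_inputs=True),
    train_config=TrainConfig(patience=5, seed=0),
)
result = trendy_infer(snap0, snap1, t=0.5, te1=te1, te3=te3)
result.A2      # refined score matrix
result.A1      # solver output on the refined covariance
result.Kt_prime  # the refined covariance itself
```

The same workflows are available from the shell:

```bash
trendy simulate --n-genes 10 --n-samples 100 --seed 1 --out-dir corpus/
trendy train --corpus-dir corpus/ --out-dir models/ --d 32 --l 2
trendy infer --expr0 expr_t0.5.csv --expr1 expr_t1.csv --t 0.5 \
             --te1 models/te1.npz --te3 models/te3.npz --out a2.csv
trendy evaluate --truth grn.csv --pred a2.csv
```

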