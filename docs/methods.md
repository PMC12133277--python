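# Methods

## The inference problem

A gene regulatory network (GRN) over n genes is a signed directed graph:
entry A[i, j] of its adjacency matrix is +1, 0 or −1 according to whether
gene i activates, ignores or represses gene j.  The observable is
single-cell expression data: at each measurement time a cells × genes
matrix of mRNA levels, with no correspondence between cells at different
times (measurement destroys the cell).  The package infers a real-valued
score matrix whose off-diagonal ranking predicts where true regulations
are; the diagonal (autoregulation) is not identifiable from this kind of
data and is excluded from every loss and metric.

## Expression model and synthetic data

Expression dynamics follow the standard nonlinear chemical-Langevin-type
SDE used across this literature:

    dX_j = V ( β · Π_i [1 + A_ij · X_i/(X_i+1)] − θ X_j ) dt + σ X_j dW_j

with rate scale V = 30, basal production β = 1, degradation θ = 0.2 and
noise intensity σ = 0.1 (σ ∈ {0.01, 0.1, 1} as a benchmark axis).  The
Hill-type saturation X/(X+1) bounds each regulator's multiplicative
effect to (0, 2).  Ground-truth networks are sampled entrywise i.i.d.
with P(−1, 0, +1) = (0.1, 0.8, 0.1).

Trajectories are integrated by Euler–Maruyama with step dt = 0.01 over
t ∈ [0, 1], recorded at 0.0, 0.1, …, 1.0, with 100 cells per network.
Two choices the model statement leaves open are fixed as follows:

- **Initial state.**  i.i.d. Uniform(0, 2β/θ) per gene per cell.  The
  interval spans the regulation-free equilibrium β/θ = 5, so early
  snapshots carry spread in every gene without committing to a
  particular stationary law.
- **Nonnegativity.**  An Euler step can overshoot below zero; each
  coordinate is clamped at 0 after every step.  The multiplicative noise
  σX dW vanishes at X = 0, so the clamp only removes discretization
  overshoot and expression levels stay nonnegative as they must.

What the generator does *not* emulate: transcriptional bursting and
discrete gene states, protein-level dynamics, measurement dropout and
missing values.  Tests passing on this generator therefore certify the
pipeline's behavior under the model's own assumptions, not performance
on degraded experimental single-cell data.

## Covariance estimation and the snapshot pair

Gene–gene covariances K0 (earlier snapshot) and Kt (later, t time units
apart) are estimated by graphical lasso (penalty 0.01 by default,
configurable); if the iteration fails to converge the estimator falls
back to the empirical covariance with a small ridge on the diagonal.
Covariances, not correlations, are used: the matching relation below is
derived for covariances.

When all eleven recorded times are available the default pair is
**(0.5, 1.0)**.  This was a genuinely open choice and was settled by
mechanism: the relaxation rate of the dynamics is Vθ = 6, so by t = 0.5
the cells have essentially forgotten the i.i.d. initial state and both
covariances reflect the network.  Using the (0.0, 1.0) pair instead
makes K0 the covariance of pure initial noise, which carries no network
information and measurably drives the covariance-matching solver to
chance-level rankings.  The pair remains configurable.

## WENDY: covariance matching

Linearizing the dynamics gives the evolution relation

    Kt ≈ (I + tAᵀ) K0 (I + tA) + D,       D diagonal, unknown,

and the solver minimizes the off-diagonal residual

    f(A) = ½ Σ_{i≠j} [Kt − (I + tAᵀ) K0 (I + tA)]²_{ij}

by BFGS on the flattened n² variables with the analytic gradient
(−t(K0 M Rᵀ + K0ᵀ M R) for M = I + tA and masked residual R), zero-matrix
initialization, gradient tolerance 1e−8, at most 1000 iterations.  The
problem is non-convex and its minimizer is not unique; the deterministic
zero start makes results reproducible.  Inputs with a single gene are
rejected (no off-diagonal residual exists).  The returned diagonal is
whatever the optimizer left there and carries no meaning.

## TE(k): the transformer refiner

A TE(k) model maps k input n×n matrices to one n×n output:

1. each scalar entry → a d-dimensional token (shared linear embedding);
2. a learned segment embedding per input group (omitted when k = 1);
3. a deterministic 2-D sinusoidal positional encoding added per group;
4. row-major flattening to an n²-token sequence, feature-axis
   concatenation to width d·k;
5. l standard post-norm encoder layers (h-head self-attention,
   ReLU feed-forward of width 4·d·k, dropout 0.1);
6. linear projection to one scalar per token, reshaped to n×n.

No weight depends on n, so one model serves any gene count.  Full-scale
defaults are d = 64, l = 7, with h = 4 for the stage-1 model and h = 8
for the stage-2 and enhancer models.

The positional encoding uses 1-based coordinates x (row), y (column) and
frequency index j = 1..d/4 with ω_j = 10^(−32(j−1)/d) — equivalently
10000^(−8(j−1)/d), the conventional base spread over a quarter of the
feature axis.  The first half of the d axis interleaves sin/cos of
(y−1)·ω_j and the second half interleaves sin/cos of (x−1)·ω_j, so
column information lives in the first half and row information in the
second.  The exponent scale is exposed as a module constant.

The neural core (tensor autodiff, attention, layer norm, Adam) is
implemented in numpy inside `trendy.nn`: a compact reverse-mode engine
sized for n²-token sequences at tens of genes.  Gradients of every
primitive are verified against central finite differences in the test
suite (in float64; the engine computes in float32 by default for speed).

## Two-stage training (TRENDY)

Stage 1 trains TE(k=1) to map the measured Kt to the pseudo-target

    Kt* = (I + tAᵀ_true) K0 (I + tA_true),

the covariance the linearized model would have produced under the true
network — a cleaner input for the solver than the raw Kt.  The stage-1
loss keeps the diagonal (a covariance diagonal is meaningful).  Stage 2
pushes every sample through the trained stage-1 model and the solver to
get A1 = WENDY(K0, Kt′), then trains TE(k=3) on (A1, K0, Kt) against
A_true with the diagonal excluded.  Inference mirrors this: K0, Kt →
Kt′ → A1 → A2, with all intermediates returned.  The stage-1 output is
symmetrized before entering the solver (its target Kt* is symmetric by
construction).

Training uses Adam (learning rate 0.001), at most 100 epochs, and early
stopping when the best validation masked-MSE fails to strictly improve
for 10 consecutive epochs (ties count as no improvement); the returned
weights are those of the best validation epoch.  Validation loss is the
early-stopping metric — it is the quantity available during training.
The default batch size is 16: with corpora of a few thousand samples,
smaller batches give the optimizer proportionally more update steps per
epoch, which measurably improves what the refiners learn at desk scale;
the value is configuration-exposed.  Full-scale corpus defaults are 10⁵
training and 10³ validation samples.

The stage-2 model standardizes each input matrix (per-sample z-score)
before embedding, via the model-level standardization switch stored in
its configuration (so inference applies it automatically).  Rationale:
covariance scales are heavy-tailed across networks — activator-rich
ground truths push expression levels and covariance entries orders of
magnitude above the typical sample — and feeding those raw scales to
the scalar embedding stalls early optimization badly enough that early
stopping fires before the model starts using Kt.  With standardization
the validation loss descends steadily.  The architecture default leaves
inputs raw; the two-stage workflow opts in.  Stage 1 stays raw on both
sides: its output must live on the covariance scale its consumer (the
solver) expects.

## Enhancing other methods

The stage-2 idea generalizes: any base method's score matrix can be
refined by a TE(k) trained against truth on synthetic corpora.  The
package ships light reimplementations of two base methods —

- **GENIE3-style**: per target gene, a random-forest regression of that
  gene on all others (100 trees, √-feature subsampling); the importance
  of regulator i for target j is the score AG[i, j].
- **SINCERITIES-style**: per gene, Kolmogorov–Smirnov distances between
  consecutive time-point marginals, normalized by interval length;
  each gene's next-interval shift is ridge-regressed on all genes'
  current-interval shifts (penalty by efficient leave-one-out CV,
  fallback 1.0), and coefficients are signed by partial Spearman
  correlation over pooled cells.

The enhancer for a GENIE3-style base uses k = 2 with inputs (AG, K),
where K is the graphical-lasso covariance of the same snapshot the base
method consumed (the latest of the configured pair).  SINCERITIES-style
and externally supplied matrices (e.g. an ODE-fitting method's output
loaded from CSV) use k = 1.  Targets are always the true network with
the diagonal excluded.

## Evaluation

Signed truth is binarized by nonzero-ness ("a regulation exists") and
predictions ranked by absolute score, off-diagonal only.  AUROC uses
midrank tie handling (equal to the normalized Mann–Whitney statistic);
AUPRC is the step-wise non-interpolated precision sum, which matters on
sparse truths where interpolation conventions shift the value.  Both are
1 for a perfect ranking and 0.5 for an exchangeable-random one.

## Numerical choices and degenerate inputs

- Graphical-lasso failure → empirical covariance + 1e−6·tr(K)/n ridge.
- Solver worse than its start (pathological line search) → the start is
  returned; the objective never exceeds its initialization value.
- A constant gene column in the GENIE3-style forest → zero importances.
- A gene with identical marginals at all times in SINCERITIES → exactly
  zero outgoing coefficients.
- All-positive or all-negative off-diagonal truth → metrics raise an
  explicit undefined-metric error.
- Ground truths with any entry outside {−1, 0, +1}, non-square inputs,
  mismatched gene counts, fewer than 3 cells, or non-finite covariances
  are rejected at construction.

## Scale of the shipped experiments

Reference experiments at full scale (10⁵ training samples, d = 64,
l = 7, GPU-class budgets) are far beyond a desk run; the
test suite instead runs a scaled-down directional experiment: 2000
training + 200 validation + 200 test networks at n = 10, reduced models
(d = 32, l = 2), early stopping with patience 5, at most 30 epochs per
stage.  At this scale the stage-1 refiner beats the identity map on
held-out covariance targets but its intermediate solver estimate A1 is
*worse* than the plain solver's A0 — improving A1 itself evidently
needs far larger stage-1 corpora — while the stage-2 model learns to
read the covariances directly and discount A1, so the end-to-end A2
still outranks A0.  The reported comparison is directional (refined vs.
plain ranking), not full-scale absolute scores.  The acceptance
script
(`scripts/acceptance.py`) recomputes the sampler distribution, simulator
equilibrium, solver exactness and the plain solver's synthetic AUROC
from scratch in a few minutes on one CPU.

## Known limitations

- The SDE generator omits bursting, protein dynamics and dropout; models
  trained on it inherit its assumptions.
- The covariance-matching relation is a first-order linearization; its
  error grows with t, and the solver's minimizer is not unique.
- The numpy neural core is single-threaded and CPU-bound; full-scale
  training (10⁵ samples, d = 64, l = 7) is out of desk reach.
- SINCERITIES sign assignment via pooled partial Spearman correlation is
  a simplification of the original's per-interval treatment.
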