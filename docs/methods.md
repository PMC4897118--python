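# Methods

## Model

`kfis` implements a kernel TSK fuzzy classifier for two-class expression
data.  The pipeline is: mean imputation per gene → per-gene min–max
normalization to [0, 1] (constant genes map to 0.5) → pooled-variance
t-test ranking and top-k gene selection → kernel subtractive clustering
(KSC) for rule induction → kernel TSK inference with a logistic output.

All feature-space geometry goes through the polarisation identity
`d²_φ(x,y) = K(x,x) − 2K(x,y) + K(y,y)`; the feature map φ is never
materialised.  Four kernels are supported (linear, polynomial, RBF,
tan-sigmoid).  The tan-sigmoid kernel is not positive semidefinite for all
parameters, so `d²_φ` can come out slightly negative; it is clamped to 0
with a logged warning rather than rejected, which keeps the downstream
exponentials well defined while still allowing this historically popular
kernel.

### Rule induction (KSC)

Potentials `p(xᵢ) = Σⱼ exp(−α d²_φ(xᵢ,xⱼ))`, `α = 4/r_a²`.  Centroid
selection follows the classic subtractive-clustering procedure: the global
potential maximum is always the first centroid (ties broken to the lowest
index, making the run fully deterministic); a later candidate with
remaining potential p* is accepted outright when `p* > ε·p₁*`, terminates
the loop when `p* < ε̄·p₁*`, and in the grey zone is accepted only when
`d_min/r_a + p*/p₁* ≥ 1` (d_min = feature-space distance to the nearest
accepted centroid), otherwise its potential is zeroed and the search
continues — so the loop always terminates.  Equality at either threshold
falls into the grey zone (strict comparisons).  After each acceptance all
potentials are revised with `β = 4/r_b²`, `r_b = η·r_a`, and clamped at 0;
the winner's own potential is set exactly to 0.

The membership width uses the standard subtractive-clustering convention
`σ = r_a · range/√8` per feature — on normalized data `σ = r_a/√8`, shared
by all rules.  No width formula is universal in the TSK literature; this
one makes the Gaussian's reach consistent with the neighbourhood the radius
r_a already defines, and its linearity in r_a is covered by tests.

### Inference and consequent estimation

Memberships are evaluated **per coordinate**: `Aⱼᵏ(x) =
exp(−d²_K(xⱼ, cⱼᵏ)/(2σⱼᵏ²))` with the kernel applied to the scalar j-th
coordinates; the firing strength is the product t-norm.  Each rule's
consequent is a representer expansion over the full training vectors,
`Rᵏ(x) = b₀ᵏ + Σᵢ αᵢᵏ K(xᵢ, x)` — the expansion is over training *points*
with full-vector kernels, which keeps the consequent's dimensionality
independent of the feature count and matches the representer form of
kernel regression.

Because the consequent parameters enter linearly, they are estimated in
closed form: with per-sample normalized weights `wₖ(t) = μₖ(t)/Σμ`, the
design row for sample t is the concatenation over rules of
`wₖ(t)·[1, K(x₁,xₜ), …, K(xₘ,xₜ)]`, and all `{b₀ᵏ, αᵏ}` are solved jointly
by ridge least squares (default λ = 1e-6; a singular system at λ = 0 falls
back to 1e-6 with a warning).  The closed-form solve is the standard TSK
consequent estimator and is fully deterministic; an iterative
stochastic-gradient variant was deliberately not used because it adds a
learning-rate/epoch schedule without changing the optimum of a linear
least-squares problem.

Targets: class labels {0,1} are mapped to `z = logit(clip(y, 0.05, 0.95))`
so that the logistic output `ŷ = (1+e^(−Y))⁻¹` applied to the fitted Y
recovers probabilities near the labels; fitting Y directly to {0,1} would
fight the link function.  The clip at 0.05 bounds the target magnitude at
±logit(0.95) ≈ ±2.94, which keeps the ridge problem well scaled.

If every firing strength for a sample underflows below 1e-300, uniform
rule weights are substituted with a warning (the weighted average is
otherwise 0/0).  The decision threshold on ŷ is 0.5, with ŷ = 0.5
classified positive.

## Preprocessing decisions

- **t-test**: pooled variance with unbiased (n−1)-weighted class
  variances, two-sided P from the t distribution with n₁+n₂−2 df.  A gene
  with zero pooled variance gets t = ±∞, p = 0 when the class means differ
  (ranked first) and t = 0, p = 1 when they coincide.  Ranking is by
  ascending P, ties by larger |t|, then lexicographic gene id —
  deterministic across platforms.  Top-k selection is therefore nested:
  the k₁ best genes are a prefix of the k₂ best for k₁ ≤ k₂.
- **Normalization leakage**: by default the (min, max) table is computed
  on training rows only and applied to held-out rows (values may leave
  [0,1]; they are not clipped).  `paper_order=True` (CLI `--paper-order`)
  restores the historically common global ordering — normalize and select
  once on all samples before splitting — which is leakage-prone but useful
  for comparing against published pipelines.
- Missing values are imputed with the gene's observed mean; a gene with no
  observed values is an error naming the gene.
- No multiple-testing correction is applied: the ranking is used for
  selection, not inference, and the historical pipelines this mirrors
  apply none.

## Evaluation decisions

- Interleaved F-fold plan (sample i → fold ((i−1) mod F)+1), no shuffling,
  so cross-validation is deterministic end to end.  Pooling all held-out
  predictions yields one confusion matrix covering every sample — the only
  convention that produces full-cohort confusion matrices.
- Metrics with a zero denominator are reported as 0 and flagged by name,
  never NaN.
- ROC/AUC delegates to scikit-learn's threshold sweep and trapezoid rule
  (ties grouped); tests verify exact agreement with brute-force
  Mann–Whitney concordance.
- Per-fold grid search maximises validation accuracy; ties prefer the
  smaller radius, then the smaller γ; fold winners are combined by the
  lower median (deterministic for even fold counts).  The default grids
  are r_a ∈ {0.1, …, 1.0} and γ ∈ {2⁻⁵, …, 2⁵}.

## Defaults

| parameter | default | meaning |
|---|---|---|
| squash factor η | 1.25 | revision radius r_b = η·r_a |
| accept ratio ε | 0.75 | outright acceptance above ε·p₁* |
| reject ratio ε̄ | 0.15 | termination below ε̄·p₁* |
| cluster radius r_a | 0.5 | neighbourhood scale in normalized space (tune by CV) |
| ridge λ | 1e-6 | consequent regularisation |
| kernel defaults | poly γ=1, c=0.5, d=3; rbf γ=0.5; tansig γ=0.5, c=0.1 | common settings for these kernels on [0,1]-normalized data |
| decision threshold | 0.5 | ŷ ≥ 0.5 → class 1 |

## Synthetic data

The generator emulates the *shape* of a classic two-class leukemia
microarray study: 72 samples × 500 genes by default (7129 available as the
"paper shape"), an imbalanced 47/25 class split, a small informative subset
(default 10 genes) mean-shifted by `effect_size` within-class standard
deviations (default 3) in the minority class, per-gene Gaussian baselines
(mean 7, SD 2, a log-intensity-like scale) with i.i.d. Gaussian noise
(SD 1), and uniformly planted missing values that never wipe out a whole
gene.  One private RNG stream per call makes every dataset bit-reproducible
from its seed.

What it does **not** model: probe/batch effects, intensity-dependent
variance, gene–gene correlation, heavy tails.  Passing recovery tests on
this generator therefore demonstrates the pipeline's correctness and its
statistical behaviour under idealised noise, not performance on real
microarrays.

Blob fixtures for clustering tests place isotropic Gaussian clusters at
scaled standard-basis vectors so every pair of centres is exactly
`separation` apart.

## Problem sizes and runtime

The test and acceptance workloads use 72 × 200 expression matrices
(10 informative genes), 10-fold cross-validation over 10 seeds per
condition, 50-point 2-D sets for the linear-kernel reduction checks and
200 random instances (n ≤ 50) for the AUC/concordance identity — sizes at
which every check is exact or statistically stable while the whole suite
completes in a few minutes on one CPU.

## Known limitations

- Strictly two-class; no multi-class extension.
- The consequent solve is O((R·(m+1))³) in rules × training points; with
  saturating kernels (RBF with small distances) R can approach m on
  high-dimensional normalized data, which is tolerable at microarray
  sample sizes (m ≤ ~100) but would not scale to thousands of samples.
- Probabilities come from a fixed logistic link, not a calibrated model.
- Kernel parameters are searched on a grid; no continuous optimisation.
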