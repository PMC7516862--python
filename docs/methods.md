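# Methods

## Model

`ibtreat` treats causal-effect estimation from observational data as a
compression problem. Under strong ignorability — all confounders are measured
during training — a representation `Z` of the covariates `X = (X1, X2)` that
(i) is compressed and (ii) retains the information in `X` relevant to the
outcome–treatment pair `(Y, T)` acts as a sufficient covariate: conditioning
on `Z` and `T` makes treatment assignment ignorable, so the average causal
effect can be written as the occupancy-weighted mean of class-specific
effects over values of `Z`.

Each covariate block has its own encoder (a 3-hidden-layer MLP, width 64,
ELU activations) emitting logits over `k_b` categories. A categorical sample
is drawn with the Gumbel-softmax relaxation: with Gumbel(0,1) noise `g` and
temperature `τ`, the relaxed weight vector is
`w_i ∝ exp((logits_i + g_i)/τ)`; as `τ → 0` this approaches the one-hot of
`argmax(logits + g)`. Each category owns a Gaussian embedding (learned mean
and scale). During training the branch embedding is the relaxed mixture of
component means plus reparameterised Gaussian noise scaled by the mixture of
component scales; at evaluation it is the selected component mean, noise-free.
The concatenation `Z = (V1, V2)` feeds three heads (same MLP shape): a
treatment head `σ(f1(z))` and two outcome heads with the observed treatment
selecting the head (teacher forcing): `μ̂ = t·f2(z) + (1−t)·f3(z)`. The
outcome family is Gaussian (shared learned log-variance, initialised at the
training outcome variance) or Bernoulli (logistic link), switched by config.

The training objective, in minimisation form, is

    KL(q(v1|x1)‖p(v1)) + KL(q(v2|x2)‖p(v2)) + λ·(NLL_y + NLL_t)

with batch-mean KL terms (variational upper bounds on the two compression
mutual informations) and teacher-forced negative log-likelihoods (whose
negative sum lower-bounds the relevance `I(Z;(Y,T))` up to the constant
entropy `H(y,t)`, dropped because it is parameter-free). Priors `p(v_b)` are
uniform categorical by default and configurable. One Monte-Carlo latent
sample per record per step is used.

### Design choices where the design was open

* **Discrete codes with Gaussian component embeddings.** Categories give a
  clustering structure (equivalence classes, auditable composition); the
  component embeddings give the continuous `z` the decoder needs. Component
  scales are learned with an additive floor of 1e-3.
* **Relaxed sample for gradients, hard argmax for evaluation.** No
  straight-through estimator; evaluation and cluster assignment use the
  noise-free argmax of the encoder logits.
* **Class effects from the decoder, not empirical cell means.** The effect of
  a class is `f2 − f3` evaluated at its component-mean embedding, which is
  defined even for classes whose occupants are all in one arm.
* **Transfer by integration.** With `X1` absent, `V1` is integrated over a
  Laplace-smoothed (pseudo-count 1) conditional `p(v1|v2)` tabulated from
  hard co-assignments on the training data, giving fractional occupancy; a
  hard modal-assignment mode exists behind a flag. With `k1 = 1` the transfer
  estimate coincides exactly with the full-covariate estimate.
* **Occupancy** is measured on whatever split is handed to the estimator, so
  within-sample and out-of-sample estimates are the same code path.
* **Minimisation form** of the bottleneck trade-off (negating the usual
  maximisation) to match optimiser convention; an extra weight on the
  treatment likelihood inside λ is not used — outcome and treatment terms
  enter equally.

## Parameters that matter

| parameter | default | meaning |
| --- | --- | --- |
| `k1`, `k2` | 4 | mixture components per branch; 4 matches the study conditions and the planted confounder granularity of the bundled generator |
| `embed_dim` | 3 | dimension of each component's Gaussian embedding |
| `λ` (`lam`) | 13.0 | relevance multiplier; the default sits on the saturated part of the information curve, favouring effect recovery over maximal compression |
| `temperature_init/final` | 1.0 → 0.5 | geometric Gumbel-softmax annealing over `anneal_epochs` (100), then held |
| `learning_rate` | 0.001 | Adam, β at common defaults; global-norm gradient clipping at 5.0 guards the low-temperature regime |
| `epochs`, `patience` | 300, 50 | early stopping on validation total loss (hard codes, final temperature); best snapshot returned, ties to the earlier epoch |
| `lr_decay` | 1.0 | optional geometric per-epoch learning-rate factor; used by convergence tests, not by ordinary fits |
| `split_fractions` | 0.6/0.1/0.3 | train/validation/test; test indices never reach a parameter update |

Gradients come from a minimal reverse-mode autodiff engine over float64 numpy
arrays written for this package; the test suite checks its gradients and the
full loss gradient against central finite differences at 1e-4 relative
tolerance.

## Synthetic data: what it emulates, what it does not

All generators record exact potential outcomes, the planted confounder, and
the regime (observational vs interventional), and are bitwise reproducible
from one seed.

* `gen_confounded_linear` (defaults n=2000, d=10, 4 confounder levels,
  effect 1.0, confounding strength 2.0, outcome noise sd 1.0): a discrete
  confounder shifts every covariate (alternating-sign loadings scaled so each
  covariate half separates adjacent levels by ~4σ — the confounder is
  *measured*, per strong ignorability, not hidden in noise), drives treatment
  through a logistic selection rule, and shifts the outcome level. The
  treatment effect is homogeneous, so the true ACE equals `effect_size`
  exactly and the naive contrast is biased by the confounder gap between
  arms (~1.6 outcome units at the defaults).
* `gen_ihdp_like` (n=900 before removal, d=26): a randomised design
  (treatment probability 1/3, binary subgroup prevalence 0.65) de-randomised
  by dropping 85% of treated units in the flagged subgroup, leaving roughly
  130 treated vs 600 control — the minority-treated-arm proportions of the
  classic infant-intervention benchmark. The outcome surface is a documented
  linear + subgroup-interaction construction of our own; reproducing any
  published response surface is a non-goal.
* `gen_twins_like` (n_pairs=1000, d=46): an ordinal 0–9 gestation confounder
  (column 0), synthetic auxiliary covariates half of which carry the
  confounder weakly, binary mortality decreasing in gestation and slightly
  lower for the heavier twin, and treatment assigned by
  `Bern(σ(w_o'x + w_h(z/10 − 0.1)))` with `w_o ~ N(0, 0.1 I)`,
  `w_h ~ N(5, 0.1)`; one twin per pair is observed. Covariates are synthetic
  stand-ins, not real natality fields.

Because covariates are clean Gaussians/Bernoullis with a planted
low-dimensional confounder, passing tests show that the method recovers
effects *when its assumptions hold*; they say nothing about hidden
confounding, covariate shift, heavy-tailed measurement error, or real-data
response surfaces.

## Numerical choices

* All arithmetic in float64; softmax/log-softmax via max-shift; Bernoulli
  likelihoods through `softplus` / `logaddexp` (no overflow); probabilities
  clipped at 1e-12 only in reporting paths.
* `compression_kl` treats `0·log(0/p)` as 0 and raises (rather than
  returning infinity) when the prior has zero mass where the posterior does
  not.
* Degenerate inputs fail loudly: non-binary treatments, empty batches,
  single-arm training splits, out-of-range cluster indices, requests to
  remove always-observed columns.
* Singular baseline design matrices fall back to a logged ridge of 1e-6.
* Seeds: every entry point takes one seed; internal streams (initialisation,
  shuffling, sampling noise, per-λ and per-k refits) are derived through
  `numpy.random.SeedSequence` spawning, all below 2³¹.

## Problem sizes used in the checks

The bundled test suite and `scripts/acceptance.py` work at n = 2000 with five
replicate studies for effect-recovery checks, five-point λ grids for
information curves, and 2000 twin pairs for the binary-outcome study — sizes
at which the planted-truth comparisons are stable while a full run stays in
the minutes range on one CPU core.

## Known limitations

* Binary treatments only; no continuous or multi-level interventions.
* No uncertainty quantification on the effect estimates (bootstrap deferred).
* The information-curve compression axis is the converged KL-sum bound — the
  quantity the objective actually controls — not an independent estimate of
  `I(Z;X)`.
* λ=0 (compression-only) drives encoder posteriors toward uniform but plain
  Adam stalls at a stationary point ~1e-2 from uniform in sup norm;
  `lr_decay` tightens this but exact uniformity is not reached.
* The transfer step assumes the train-time conditional `p(v1|v2)` still holds
  for test units — systematic missingness, not distribution shift.
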