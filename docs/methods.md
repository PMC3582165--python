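# Methods

## Problem setting

Two-class expression matrices (microarray or pseudobulk single-cell) have
thousands of genes and a few dozen samples. The goal is a *small* gene subset
whose linear-SVM classifier separates the classes well — a wrapper selection:
candidate subsets are scored by actually training and testing the downstream
classifier, so inter-gene correlations count, unlike univariate filters.

## Fitness of a gene subset

A candidate is a binary mask z over the current gene universe. Each class is
randomly partitioned into 5 folds of near-equal size; every pairing of one
fold per class is a test set (5 × 5 = 25 pairs) and the remaining samples
form the learning set. For each pair a soft-margin linear SVM
ŷ = sgn(Σᵢ aᵢ yᵢ ⟨xᵢ, x⟩ − b) is trained on the masked genes and scored by
test accuracy; the subset's fitness is the mean accuracy over the 25 pairs.
Alongside, each included gene i receives the squared component wᵢ² of the
primal weight vector w = Σₕ aₕ yₕ xₕ, averaged over the 25 pairs; excluded
genes get exactly 0. These per-gene weights feed back into the search.

Genes are standardized (zero mean, unit variance) using learning-set
statistics only, per pair, before training. This is on by default
(`standardize=True`): without it the squared-weight gene scores are
scale-dependent, which would conflate expression magnitude with
discriminative value. The SVM cost is C = 1 by default; both are exposed in
`SearchConfig`. The SVM is scikit-learn's `SVC(kernel="linear")` with a
tightened solver tolerance (1e-8) so the dual solution is accurate enough
for the squared-weight scores to be stable.

An all-zero mask is defined to have fitness 0 with zero weights rather than
raising: random sampling can produce it, and a 0 score drives it out of the
population.

## Inner search (estimation-of-distribution step)

Population size N = 40 binary strings, each bit initially Bernoulli(p₀ = 0.5)
so individuals start with about half of the genes. Per generation:

1. evaluate all unevaluated individuals (one shared CV plan per outer
   iteration, so fitness differences reflect gene content, not split noise);
2. retain the top ⌈N/2⌉ by fitness unchanged (elitism; ties prefer smaller
   subsets, then input order);
3. update the per-gene inclusion-probability vector incrementally,
   p ← (1 − lr)·p + lr·g with lr = 0.08, where the target
   g = ½·(freq + ŵ) blends the elites' per-gene bit frequency with their
   mean SVM gene weight min–max normalized to [0, 1] across genes (falling
   back to freq alone when the weight vector is flat or zero). The blend
   ratio is `blend` (default 0.5). This is a probability-incremental-learning
   rule in which classifier weights, not just selection counts, steer the
   model;
4. sample N − ⌈N/2⌉ offspring from the model (independent Bernoulli bits);
   next generation = elites ∪ offspring.

Probabilities are clamped to [ε, 1 − ε], ε = 10⁻³, so no gene is ever
absorbed permanently in or out and a dropped gene can re-enter by sampling.
The loop stops at 50 generations, or earlier when the best fitness has not
improved for `patience` = 10 generations (set `patience=None` to always run
the full 50). Elitism makes the best-fitness sequence non-decreasing by
construction.

## Outer loop (stepwise data reduction)

After an inner search converges, the gene universe is restricted to the
genes with final model probability ≥ θ = 0.9 *and* present in the best
individual's mask (if that intersection is empty, the best mask alone), and
the inner search restarts on the reduced matrix with a fresh CV plan. The
run ends when an iteration reproduces its own gene universe — the subset is
stable — or after 20 iterations (a hard termination guarantee; universe
sizes are non-increasing by construction, and strictly decreasing until the
stable iteration). The trace records gene count, best and mean fitness, and
the surviving gene ids per iteration; the final iteration's count equals its
universe size, which is the analogue of a published shrinkage sequence
ending in a repeated size.

θ = 0.9 with the best-mask intersection produces order-of-magnitude
shrinkage per iteration on benchmark-shaped inputs; both the threshold and
the update rule are configuration, not hard-coded.

## Comparator engines

*GA-SVM*: fitness-proportional parent selection, single-point crossover with
probability 0.8, per-bit mutation with probability 0.01, single-best elitist
carry-over. *PMBGA*: the same incremental model update but driven by parent
bit frequencies only (blend = 0 — no classifier-weight feedback), whole
population resampled from the model plus one elite, and the initial
probability vector perturbed by small uniform noise in [0, 0.01]. Both run
behind the identical fitness evaluator and the same outer reduction loop, so
ranking differences are attributable to the search strategy. GA-SVM has no
probability model; its reduction step keeps the best individual's mask.
Crossover/mutation rates and the PMBGA replacement scheme are design choices
of this package where the originals leave them open; all are
configuration-exposed.

## Missing values

KNN imputation (K = 5 by default): for a gene missing at sample s, the K
genes with the most similar profiles — smallest mean squared difference over
mutually observed samples, i.e. Euclidean distance scaled by the number of
shared coordinates — among genes observed at s are averaged (unweighted) to
fill the entry. Observed entries are never altered, so imputation is
idempotent; a gene missing everywhere is an error. No missingness-based gene
filtering is applied.

## Synthetic data

The generator emulates benchmark shape, not benchmark biology: i.i.d.
Gaussian background (sd `noise_sd`), a planted set of informative genes with
a mean shift of `effect_size`·`noise_sd` in the +1 class, an optional
uniform missing-entry mask, and optional decoy genes correlated (default
ρ = 0.8) with informative ones to stress multivariate selection. Presets
mirror the public benchmark shapes: `colon` 62 samples (40/22) × 2000 genes;
`dlbcl` 42 samples (21/21) × 4026 genes with 6% of entries masked; `small`
40 samples × 200 genes. Presets plant 10 informative genes at effect size 3
(per-gene Bayes accuracy ≈ 0.93, so a handful of planted genes supports
near-perfect classification — large but not degenerate signal). What passing
tests show: the machinery finds planted mean-shift signal and shrinks to it.
What they do not show: behaviour under real covariance structure,
heteroscedastic noise, batch effects, or non-shift class differences.

## Null behaviour

A wrapper that maximizes cross-validated accuracy over thousands of masks is
optimistically biased on null data: its *reported* fitness exceeds 0.5 even
when labels are pure noise, because the maximum of many ≈0.5-mean draws is
above 0.5. The package's null guard therefore re-evaluates the selected
subset on freshly generated null data (`SelectionResults.reevaluate` with an
independent dataset), where a correct implementation must sit near chance;
the in-search fitness is only bounded away from 1.0, which is what a
bookkeeping leak (test labels reaching training) would produce.

## Problem sizes in tests and the acceptance script

The test and acceptance runs use the generator presets above with
population sizes 12–40 and the default 50-generation cap with patience 10;
the 4026-gene runs use population 16. These sizes were chosen so a full
desk-scale verification completes in minutes while every qualitative claim
(planted-gene recovery, monotone elitism, strict shrinkage to a stable set,
null safety) is exercised at benchmark-shaped dimensions.

## Known limitations

- Marginal (univariate) probability model: no bivariate or Bayesian-network
  dependencies between genes are modelled.
- Two classes only; linear kernel only; no probability calibration.
- The stepwise reduction is greedy: a gene dropped early can only re-enter
  within an inner run (via ε), not after the universe has been cut.
- Reported fitness of the selected subset is optimistically biased (see
  Null behaviour); use held-out data for an honest accuracy estimate.
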