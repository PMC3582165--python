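# edasvm

Wrapper gene-subset selection for two-class expression data: an
estimation-of-distribution algorithm (EDA) searches over binary gene masks,
a cross-validated linear support vector machine scores them, and a stepwise
reduction loop shrinks thousands of genes to a small stable discriminative
subset. Crossover/mutation GA (GA-SVM) and frequency-only PMBGA comparator
engines run behind the identical fitness evaluator.

Intended for anyone selecting a handful of class-separating genes from a
genes × samples matrix with few samples — microarray benchmarks, pseudobulk
single-cell contrasts — where univariate filters miss multivariate signal.

## Method

A candidate subset is a binary string z over the gene universe. Its fitness
is the mean test accuracy of the linear SVM

    ŷ = sgn( Σᵢ aᵢ yᵢ ⟨xᵢ, x⟩ − b )

over 25 learning/test pairs built by crossing 5 random folds per class;
each included gene also receives the squared component of the primal weight
vector w = Σₕ aₕ yₕ xₕ, averaged over the pairs. Per generation, the top
half of the N = 40 individuals survives unchanged, and the per-gene
inclusion probabilities update incrementally,

    p ← (1 − lr)·p + lr·g,   lr = 0.08,

where g blends the elites' bit frequencies with their normalized SVM gene
weights; offspring are sampled from p. After convergence (≤ 50 generations)
the gene universe is cut to the genes with p ≥ 0.9 inside the best mask,
and the search restarts at the lower dimension until the subset is stable.
See `docs/methods.md` for the full model, defaults, and design choices.

## Worked example

```python
from edasvm import GeneSubsetSelector, SearchConfig
from edasvm.simulate import preset_design, generate

dataset, planted = generate(preset_design("small", seed=7))
selector = GeneSubsetSelector(dataset, engine="eda",
                              config=SearchConfig(pop_size=20))
results = selector.fit(seed=7)
print(results.summary())
```

prints

```
Gene subset selection results
==============================================================
engine:            eda
data:              40 samples (20 / 20) x 200 genes
config:            lr=0.08 N=20 gen<=50 elite=0.5 folds=5 C=1.0 theta=0.9
seed:              7
outer iterations:  5
--------------------------------------------------------------
iter   genes  best acc  mean acc inner gens
   1     200    1.0000    0.9822         11
   2      68    1.0000    0.9955         11
   3      19    1.0000    0.9838         11
   4       4    1.0000    0.9717         11
   5       2    1.0000    0.8985         11
--------------------------------------------------------------
selected genes (2): g049, g115
final best CV accuracy: 1.0000
```

The table is the reduction trace: starting from all 200 genes the universe
shrinks 200 → 68 → 19 → 4 → 2 across outer iterations while the best
cross-validated accuracy stays at 1.0; the final two genes are both planted
discriminative genes of the simulation (`sorted(set(results.selected_genes)
& planted)` → `['g049', 'g115']`). Note the reported accuracy of a selected
subset is optimistically biased — re-score on held-out data with
`results.reevaluate(dataset=...)` for an honest estimate.

The same run from the shell:

```sh
edasvm simulate --preset small --seed 7 --out sim/
edasvm run --data sim/expression.tsv --labels sim/labels.tsv \
           --engine eda --pop-size 20 --seed 7 --out run/
edasvm trace-plot --trace run/trace.jsonl --out run/trace.png
```

`run/` then holds the selected gene ids (TSV), the reduction trace and
per-generation logs (JSON lines), and a config echo that reproduces the run
byte-for-byte. Real data: pass your own tab-delimited genes × samples table
and a `sample_id <TAB> label` file; missing entries (`NA` or empty) are
KNN-imputed (K = 5) before the search.

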