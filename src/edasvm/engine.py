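"""The EDA-SVM search engine.

An inner search evolves a population of binary gene masks: each generation
the masks are scored by cross-validated linear-SVM accuracy, the top half is
retained unchanged (elitism), a per-gene inclusion-probability model is
nudged toward the elites' bit frequencies blended with their normalized SVM
feature weights, and the remainder of the next population is sampled from
the model.  An outer loop then restricts the gene universe to the genes the
converged model marks as likely (probability >= theta, intersected with the
best individual's mask) and restarts the search at the lower dimension,
until the gene set stabilizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .config import SearchConfig
from .cv import build_cv_plan
from .fitness import FitnessEvaluator

__all__ = [
    "Individual",
    "ProbabilityModel",
    "IterationRecord",
    "ReductionTrace",
    "init_population",
    "select_parents",
    "update_model",
    "sample_offspring",
    "run_inner_search",
    "run_eda_svm",
    "run_outer_loop",
]


@dataclass
class Individual:
    """A candidate gene subset: a binary mask with attached evaluation."""

    mask: np.ndarray
    fitness: float | None = None
    weights: np.ndarray | None = None

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    @property
    def evaluated(self) -> bool:
        return self.fitness is not None


@dataclass(frozen=True)
class ProbabilityModel:
    """Per-gene inclusion probabilities driving offspring sampling."""

    p: np.ndarray
    lr: float = 0.08

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "p", p)


@dataclass(frozen=True)
class IterationRecord:
    """One outer (stepwise-reduction) iteration of the search."""

    gene_count: int
    best_fitness: float
    mean_fitness: float
    selected_gene_ids: tuple
    n_generations: int


@dataclass
class ReductionTrace:
    """Per-outer-iteration record of the shrinking gene universe."""

    iterations: list = field(default_factory=list)

    def append(self, record: IterationRecord) -> None:
        self.iterations.append(record)

    @property
    def gene_counts(self) -> list:
        return [r.gene_count for r in self.iterations]

    @property
    def best_fitnesses(self) -> list:
        return [r.best_fitness for r in self.iterations]

    def __len__(self) -> int:
        return len(self.iterations)


def init_population(gene_count: int, pop_size: int, p0: float = 0.5,
                    rng=None) -> list:
    """Independent Bernoulli(p0) masks; all-zero masks are resampled once."""
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    if gene_count < 1:
        raise ValueError("gene_count must be >= 1")
    if pop_size < 2:
        raise ValueError("pop_size must be >= 2")
    rng = np.random.default_rng(rng)
    population = []
    for _ in range(pop_size):
        mask = (rng.random(gene_count) < p0).astype(np.int8)
        if not mask.any():
            mask = (rng.random(gene_count) < p0).astype(np.int8)
        population.append(Individual(mask=mask))
    return population


def select_parents(population: list, fraction: float = 0.5) -> list:
    """Top ceil(fraction * N) individuals by fitness.

    Ties are broken in favour of smaller subsets, then by stable input
    order, so equal-accuracy solutions with fewer genes win.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if any(not ind.evaluated for ind in population):
        raise ValueError("all individuals must be evaluated before selection")
    n_keep = math.ceil(fraction * len(population))
    order = sorted(
        range(len(population)),
        key=lambda i: (-population[i].fitness, population[i].n_selected, i),
    )
    return [population[i] for i in order[:n_keep]]


def update_model(model: ProbabilityModel, parents: list,
                 blend: float = 0.5, epsilon: float = 1e-3) -> ProbabilityModel:
    """Incremental update p <- (1 - lr) p + lr g toward the parents.

    The target g blends the parents' per-gene bit frequency with their mean
    SVM feature weight min-max normalized to [0, 1] across genes, so genes
    that carry classifier weight are reinforced beyond their mere selection
    frequency.  If the parents carry no weight information (all-zero or
    constant weight vector) the target falls back to the frequency alone.
    The result is clamped to [epsilon, 1 - epsilon] so no gene is ever
    irreversibly fixed in or out.
    """
    if not parents:
        raise ValueError("parents must be nonempty")
    if any(ind.weights is None for ind in parents):
        raise ValueError("all parents must carry weights")
    masks = np.stack([ind.mask for ind in parents]).astype(float)
    freq = masks.mean(axis=0)
    w = np.stack([ind.weights for ind in parents]).mean(axis=0)
    wmin, wmax = float(w.min()), float(w.max())
    if wmax > wmin:
        w_hat = (w - wmin) / (wmax - wmin)
    else:
        w_hat = freq
    g = (1.0 - blend) * freq + blend * w_hat
    p = (1.0 - model.lr) * model.p + model.lr * g
    p = np.clip(p, epsilon, 1.0 - epsilon)
    return ProbabilityModel(p=p, lr=model.lr)


def sample_offspring(model: ProbabilityModel, count: int, rng=None) -> list:
    """Draw ``count`` masks with independent Bernoulli(p_i) bits."""
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(rng)
    return [
        Individual(mask=(rng.random(model.p.shape[0]) < model.p).astype(np.int8))
        for _ in range(count)
    ]


def _evaluate_population(population: list, evaluator: FitnessEvaluator) -> None:
    for ind in population:
        if not ind.evaluated:
            res = evaluator.evaluate(ind.mask)
            ind.fitness = res.fitness
            ind.weights = res.weights


def run_inner_search(evaluator: FitnessEvaluator, config: SearchConfig,
                     rng=None):
    """Evolve masks on a fixed gene universe until convergence or the cap.

    Returns
    -------
    best : Individual
        Highest-fitness individual seen (smallest subset on ties).
    model : ProbabilityModel
        Final per-gene inclusion probabilities.
    log : list of dict
        Per-generation best/mean fitness and best subset size.
    """
    rng = np.random.default_rng(rng)
    n_genes = evaluator.n_genes
    population = init_population(n_genes, config.pop_size, config.p0, rng=rng)
    model = ProbabilityModel(p=np.full(n_genes, config.p0), lr=config.lr)
    log = []
    best: Individual | None = None
    flat = 0
    for gen in range(config.max_generations):
        _evaluate_population(population, evaluator)
        elites = select_parents(population, config.elite_fraction)
        leader = elites[0]
        if best is None or leader.fitness > best.fitness or (
            leader.fitness == best.fitness and leader.n_selected < best.n_selected
        ):
            if best is not None and leader.fitness <= best.fitness:
                flat += 1
            else:
                flat = 0
            best = Individual(mask=leader.mask.copy(),
                              fitness=leader.fitness,
                              weights=leader.weights.copy())
        else:
            flat += 1
        log.append({
            "generation": gen,
            "best_fitness": float(best.fitness),
            "mean_fitness": float(np.mean([i.fitness for i in population])),
            "best_size": best.n_selected,
        })
        model = update_model(model, elites, blend=config.blend,
                             epsilon=config.epsilon)
        if config.patience is not None and flat >= config.patience:
            break
        if gen == config.max_generations - 1:
            break
        n_offspring = config.pop_size - len(elites)
        offspring = sample_offspring(model, max(1, n_offspring), rng=rng)
        population = elites + offspring
    return best, model, log


def _reduce_universe(best: Individual, model: ProbabilityModel | None,
                     theta: float) -> np.ndarray:
    """Indices (into the current universe) surviving one reduction step."""
    if model is not None:
        keep = (model.p >= theta) & (best.mask.astype(bool))
        if not keep.any():
            keep = best.mask.astype(bool)
    else:
        keep = best.mask.astype(bool)
    return np.where(keep)[0]


def run_outer_loop(dataset, config: SearchConfig, seed: int,
                   inner=run_inner_search):
    """Stepwise data reduction around any inner search engine.

    Each iteration builds a fresh CV plan (shared by all individuals of that
    iteration), runs ``inner`` on the current gene universe, records the
    trace, and restricts the universe to the surviving genes.  Stops when
    the gene set is identical in two successive iterations or after
    ``config.max_outer_iterations``.

    Returns
    -------
    selected_gene_ids : list of str
    trace : ReductionTrace
    generation_logs : list of list of dict
        Inner per-generation logs, one list per outer iteration.
    """
    if dataset.labels is None:
        raise ValueError("dataset has no labels")
    if np.isnan(dataset.matrix).any():
        raise ValueError("dataset has missing values; run knn_impute first")
    seq = np.random.SeedSequence(seed)
    current = dataset
    trace = ReductionTrace()
    gen_logs = []
    for _ in range(config.max_outer_iterations):
        plan_seed, search_seed = seq.spawn(2)
        plan = build_cv_plan(current.labels, config.folds_per_class,
                             seed=int(plan_seed.generate_state(1)[0] % (2**31)))
        evaluator = FitnessEvaluator(current, plan, cost=config.cost,
                                     standardize=config.standardize)
        best, model, log = inner(evaluator, config,
                                 rng=np.random.default_rng(search_seed))
        keep = _reduce_universe(best, model, config.theta)
        selected_ids = tuple(current.gene_ids[i] for i in keep)
        trace.append(IterationRecord(
            gene_count=current.n_genes,
            best_fitness=float(best.fitness),
            mean_fitness=float(log[-1]["mean_fitness"]),
            selected_gene_ids=selected_ids,
            n_generations=len(log),
        ))
        gen_logs.append(log)
        if set(selected_ids) == set(current.gene_ids):
            break
        current = current.subset_genes(keep)
    return list(trace.iterations[-1].selected_gene_ids), trace, gen_logs


def run_eda_svm(dataset, config: SearchConfig = SearchConfig(), seed: int = 0):
    """Full EDA-SVM: inner probability-model search + stepwise reduction."""
    return run_outer_loop(dataset, config, seed, inner=run_inner_search)
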