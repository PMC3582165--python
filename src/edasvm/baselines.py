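"""Comparator search engines behind the same SVM fitness evaluator.

GA-SVM evolves masks with fitness-proportional selection, single-point
crossover and per-bit mutation, with single-best elitist carry-over.  PMBGA
is a marginal-probability EDA whose model update uses the selected parents'
bit frequencies only — no classifier-weight feedback — and replaces the
whole population from the model plus one elite.  Both reuse the stepwise
outer reduction loop, so their traces are directly comparable with EDA-SVM;
any ranking difference is attributable to the search strategy alone.
"""

from __future__ import annotations

import numpy as np

from .config import SearchConfig
from .engine import (
    Individual,
    ProbabilityModel,
    init_population,
    sample_offspring,
    select_parents,
    update_model,
    run_outer_loop,
    _evaluate_population,
)

__all__ = ["ga_step", "pmbga_step", "run_ga_svm", "run_pmbga", "ENGINES", "run_engine"]


def _fitness_proportional_pick(population: list, rng, size: int) -> list:
    fit = np.array([ind.fitness for ind in population], dtype=float)
    # Shift so the worst individual still has a small chance; uniform if flat.
    w = fit - fit.min() + 1e-9
    probs = w / w.sum()
    idx = rng.choice(len(population), size=size, p=probs)
    return [population[i] for i in idx]


def ga_step(population: list, cfg: SearchConfig, rng=None) -> list:
    """One GA generation: selection, crossover, mutation, single elite.

    Parent pairs are drawn fitness-proportionally; with probability
    ``crossover_prob`` a single-point crossover recombines them, then every
    bit flips independently with probability ``mutation_prob``.  The best
    individual of the current generation is carried over unchanged.
    """
    rng = np.random.default_rng(rng)
    if any(not ind.evaluated for ind in population):
        raise ValueError("population must be evaluated")
    n = len(population)
    n_genes = population[0].mask.shape[0]
    elite = select_parents(population, fraction=1.0 / n)[0]
    next_pop = [Individual(mask=elite.mask.copy(), fitness=elite.fitness,
                           weights=None if elite.weights is None
                           else elite.weights.copy())]
    while len(next_pop) < n:
        pa, pb = _fitness_proportional_pick(population, rng, 2)
        child = pa.mask.copy()
        if rng.random() < cfg.crossover_prob and n_genes > 1:
            point = int(rng.integers(1, n_genes))
            child = np.concatenate([pa.mask[:point], pb.mask[point:]])
        else:
            child = child.copy()
        flips = rng.random(n_genes) < cfg.mutation_prob
        child = np.where(flips, 1 - child, child).astype(np.int8)
        next_pop.append(Individual(mask=child))
    return next_pop


def pmbga_step(population: list, model: ProbabilityModel,
               cfg: SearchConfig, rng=None):
    """One PMBGA generation: frequency-only model update, full resampling.

    Equivalent to the EDA-SVM update with the weight-feedback term switched
    off (blend = 0); the new population is sampled wholly from the model,
    except for the single best individual which is carried over.
    """
    rng = np.random.default_rng(rng)
    if any(not ind.evaluated for ind in population):
        raise ValueError("population must be evaluated")
    parents = select_parents(population, cfg.elite_fraction)
    # weight vectors are deliberately ignored: blend fully on bit frequency
    safe_parents = [
        Individual(mask=p.mask, fitness=p.fitness,
                   weights=np.zeros_like(p.mask, dtype=float)
                   if p.weights is None else p.weights)
        for p in parents
    ]
    new_model = update_model(model, safe_parents, blend=0.0,
                             epsilon=cfg.epsilon)
    elite = parents[0]
    offspring = sample_offspring(new_model, len(population) - 1, rng=rng)
    next_pop = [Individual(mask=elite.mask.copy(), fitness=elite.fitness,
                           weights=None if elite.weights is None
                           else elite.weights.copy())] + offspring
    return next_pop, new_model


def _run_inner_ga(evaluator, config: SearchConfig, rng=None):
    """GA inner loop under the shared inner-search contract (model is None)."""
    rng = np.random.default_rng(rng)
    population = init_population(evaluator.n_genes, config.pop_size,
                                 config.p0, rng=rng)
    best = None
    flat = 0
    log = []
    for gen in range(config.max_generations):
        _evaluate_population(population, evaluator)
        leader = select_parents(population, fraction=1.0 / len(population))[0]
        improved = best is None or leader.fitness > best.fitness
        if improved or (leader.fitness == best.fitness
                        and leader.n_selected < best.n_selected):
            best = Individual(mask=leader.mask.copy(), fitness=leader.fitness,
                              weights=None if leader.weights is None
                              else leader.weights.copy())
        flat = 0 if improved else flat + 1
        log.append({
            "generation": gen,
            "best_fitness": float(best.fitness),
            "mean_fitness": float(np.mean([i.fitness for i in population])),
            "best_size": best.n_selected,
        })
        if config.patience is not None and flat >= config.patience:
            break
        if gen == config.max_generations - 1:
            break
        population = ga_step(population, config, rng=rng)
    return best, None, log


def _run_inner_pmbga(evaluator, config: SearchConfig, rng=None):
    """PMBGA inner loop: initial probabilities get small random feature scores."""
    rng = np.random.default_rng(rng)
    n_genes = evaluator.n_genes
    population = init_population(n_genes, config.pop_size, config.p0, rng=rng)
    p_init = np.clip(np.full(n_genes, config.p0) + rng.uniform(0, 0.01, n_genes),
                     config.epsilon, 1 - config.epsilon)
    model = ProbabilityModel(p=p_init, lr=config.lr)
    best = None
    flat = 0
    log = []
    for gen in range(config.max_generations):
        _evaluate_population(population, evaluator)
        leader = select_parents(population, fraction=1.0 / len(population))[0]
        improved = best is None or leader.fitness > best.fitness
        if improved or (leader.fitness == best.fitness
                        and leader.n_selected < best.n_selected):
            best = Individual(mask=leader.mask.copy(), fitness=leader.fitness,
                              weights=None if leader.weights is None
                              else leader.weights.copy())
        flat = 0 if improved else flat + 1
        log.append({
            "generation": gen,
            "best_fitness": float(best.fitness),
            "mean_fitness": float(np.mean([i.fitness for i in population])),
            "best_size": best.n_selected,
        })
        if config.patience is not None and flat >= config.patience:
            break
        if gen == config.max_generations - 1:
            break
        population, model = pmbga_step(population, model, config, rng=rng)
    return best, model, log


def run_ga_svm(dataset, config: SearchConfig = SearchConfig(), seed: int = 0):
    """GA-SVM with the shared stepwise outer reduction loop."""
    return run_outer_loop(dataset, config, seed, inner=_run_inner_ga)


def run_pmbga(dataset, config: SearchConfig = SearchConfig(), seed: int = 0):
    """PMBGA with the shared stepwise outer reduction loop."""
    return run_outer_loop(dataset, config, seed, inner=_run_inner_pmbga)


ENGINES = {"eda": None, "ga": _run_inner_ga, "pmbga": _run_inner_pmbga}


def run_engine(name: str, dataset, config: SearchConfig = SearchConfig(),
               seed: int = 0):
    """Dispatch by engine name: 'eda', 'ga' or 'pmbga'."""
    from .engine import run_eda_svm, run_inner_search

    if name == "eda":
        return run_eda_svm(dataset, config, seed)
    if name not in ENGINES:
        raise ValueError(f"unknown engine {name!r}; choose from eda, ga, pmbga")
    return run_outer_loop(dataset, config, seed, inner=ENGINES[name])
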