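"""Model/Results facade over the search engines.

``GeneSubsetSelector`` is constructed from an :class:`ExpressionDataset`
(or from TSV files); ``fit`` runs the chosen engine and returns a
``SelectionResults`` carrying the selected genes, the reduction trace, the
per-generation logs, and a ``summary()`` table.
"""

from __future__ import annotations

import io

import numpy as np

from .baselines import run_engine
from .config import SearchConfig
from .cv import build_cv_plan
from .dataset import ExpressionDataset, knn_impute, read_expression_table, read_labels
from .engine import ReductionTrace
from .fitness import FitnessEvaluator

__all__ = ["GeneSubsetSelector", "SelectionResults"]


class GeneSubsetSelector:
    """Wrapper gene-subset selection on a two-class expression dataset.

    Parameters
    ----------
    dataset : ExpressionDataset
        Labelled expression data.  Missing values are KNN-imputed at
        construction (``impute_k`` neighbours) unless already complete.
    engine : {'eda', 'ga', 'pmbga'}
        Search strategy: probability-model EDA with SVM-weight feedback
        (default), crossover/mutation GA, or frequency-only PMBGA.
    config : SearchConfig, optional
        Search parameters; keyword overrides may be passed instead.
    """

    def __init__(self, dataset: ExpressionDataset, engine: str = "eda",
                 config: SearchConfig | None = None, impute_k: int = 5,
                 **overrides):
        if dataset.labels is None:
            raise ValueError("dataset must carry class labels")
        if config is None:
            config = SearchConfig(**overrides)
        elif overrides:
            config = SearchConfig(**{**config.to_dict(), **overrides})
        if np.isnan(dataset.matrix).any():
            dataset = knn_impute(dataset, k=impute_k)
        self.dataset = dataset
        self.engine = engine
        self.config = config

    @classmethod
    def from_files(cls, data_path, labels_path, orientation="genes-as-rows",
                   **kwargs) -> "GeneSubsetSelector":
        labels = read_labels(labels_path)
        dataset = read_expression_table(data_path, orientation=orientation,
                                        labels=labels)
        return cls(dataset, **kwargs)

    def fit(self, seed: int = 0) -> "SelectionResults":
        """Run the search to a stable gene subset."""
        selected, trace, gen_logs = run_engine(self.engine, self.dataset,
                                               self.config, seed)
        return SelectionResults(self, selected, trace, gen_logs, seed)


class SelectionResults:
    """Outcome of one selection run.

    Attributes
    ----------
    selected_genes : list of str
        The stable gene subset.
    trace : ReductionTrace
        Gene count and fitness per outer iteration.
    generation_logs : list of list of dict
        Inner-search logs, one list per outer iteration.
    fitness : float
        Best cross-validated accuracy at the final iteration.
    """

    def __init__(self, model: GeneSubsetSelector, selected_genes,
                 trace: ReductionTrace, generation_logs, seed: int):
        self.model = model
        self.selected_genes = list(selected_genes)
        self.trace = trace
        self.generation_logs = generation_logs
        self.seed = int(seed)

    @property
    def fitness(self) -> float:
        return self.trace.best_fitnesses[-1]

    @property
    def n_iterations(self) -> int:
        return len(self.trace)

    def reevaluate(self, dataset=None, seed: int | None = None) -> float:
        """Cross-validated accuracy of the selected subset.

        By default re-scores on the training dataset with a fresh CV plan;
        pass an independent ``dataset`` (same gene ids) for an unbiased
        held-out estimate.
        """
        data = self.model.dataset if dataset is None else dataset
        cfg = self.model.config
        plan_seed = (self.seed + 104729) if seed is None else seed
        plan = build_cv_plan(data.labels, cfg.folds_per_class, seed=plan_seed)
        evaluator = FitnessEvaluator(data, plan, cost=cfg.cost,
                                     standardize=cfg.standardize)
        mask = np.isin(np.array(data.gene_ids), self.selected_genes).astype(np.int8)
        return evaluator.evaluate(mask).fitness

    def summary(self) -> str:
        """Human-readable run report."""
        buf = io.StringIO()
        cfg = self.model.config
        d = self.model.dataset
        n_pos = int(np.sum(d.labels == 1))
        n_neg = int(np.sum(d.labels == -1))
        buf.write("Gene subset selection results\n")
        buf.write("=" * 62 + "\n")
        buf.write(f"engine:            {self.model.engine}\n")
        buf.write(f"data:              {d.n_samples} samples "
                  f"({n_pos} / {n_neg}) x {d.n_genes} genes\n")
        buf.write(f"config:            lr={cfg.lr} N={cfg.pop_size} "
                  f"gen<={cfg.max_generations} elite={cfg.elite_fraction} "
                  f"folds={cfg.folds_per_class} C={cfg.cost} "
                  f"theta={cfg.theta}\n")
        buf.write(f"seed:              {self.seed}\n")
        buf.write(f"outer iterations:  {self.n_iterations}\n")
        buf.write("-" * 62 + "\n")
        buf.write(f"{'iter':>4} {'genes':>7} {'best acc':>9} "
                  f"{'mean acc':>9} {'inner gens':>10}\n")
        for i, rec in enumerate(self.trace.iterations, start=1):
            buf.write(f"{i:>4} {rec.gene_count:>7} {rec.best_fitness:>9.4f} "
                      f"{rec.mean_fitness:>9.4f} {rec.n_generations:>10}\n")
        buf.write("-" * 62 + "\n")
        buf.write(f"selected genes ({len(self.selected_genes)}): "
                  + ", ".join(self.selected_genes) + "\n")
        buf.write(f"final best CV accuracy: {self.fitness:.4f}\n")
        return buf.getvalue()

    def plot_trace(self, out_path=None, ax=None):
        from .trace import plot_trace

        return plot_trace(self.trace, out_path=out_path, ax=ax)
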