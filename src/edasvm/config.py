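"""Search configuration shared by all engines."""

from __future__ import annotations

from dataclasses import dataclass, asdict

__all__ = ["SearchConfig"]


@dataclass(frozen=True)
class SearchConfig:
    """Parameters of the wrapper search.

    Attributes
    ----------
    lr : float
        Learning rate of the incremental probability-model update (default
        0.08): the fraction by which the model moves toward the statistics of
        the selected parents each generation.
    pop_size : int
        Number of individuals per generation (default 40).
    max_generations : int
        Generation cap of one inner search (default 50).
    elite_fraction : float
        Fraction of the population retained unchanged each generation
        (default 0.5).
    folds_per_class : int
        Folds per class of the CV resampling; pairs = folds**2 (default 5,
        giving 25 learning/test pairs).
    cost : float
        SVM soft-margin cost C (default 1.0).
    theta : float
        Outer-loop reduction threshold on final marginal inclusion
        probabilities (default 0.9).
    p0 : float
        Initial per-gene inclusion probability (default 0.5, so initial
        individuals contain about half of the genes).
    patience : int or None
        Stop an inner search early after this many generations without
        improvement of the best fitness; None disables early stopping and
        always runs ``max_generations``.
    max_outer_iterations : int
        Hard cap on stepwise-reduction iterations (default 20).
    epsilon : float
        Probabilities are clamped to [epsilon, 1-epsilon] so no gene is ever
        permanently absorbed at 0 or 1 (default 1e-3).
    blend : float
        Weight of the normalized SVM feature weights (vs parent bit
        frequency) in the model update target (default 0.5).
    standardize : bool
        Per-gene standardization with learning-set statistics before SVM
        training (default True).
    crossover_prob, mutation_prob : float
        GA comparator operators (defaults 0.8 and 0.01).
    """

    lr: float = 0.08
    pop_size: int = 40
    max_generations: int = 50
    elite_fraction: float = 0.5
    folds_per_class: int = 5
    cost: float = 1.0
    theta: float = 0.9
    p0: float = 0.5
    patience: int | None = 10
    max_outer_iterations: int = 20
    epsilon: float = 1e-3
    blend: float = 0.5
    standardize: bool = True
    crossover_prob: float = 0.8
    mutation_prob: float = 0.01

    def __post_init__(self):
        checks = [
            (0.0 <= self.lr <= 1.0, "lr must be in [0, 1]"),
            (self.pop_size >= 2, "pop_size must be >= 2"),
            (self.max_generations >= 1, "max_generations must be >= 1"),
            (0.0 < self.elite_fraction <= 1.0, "elite_fraction must be in (0, 1]"),
            (self.folds_per_class >= 2, "folds_per_class must be >= 2"),
            (self.cost > 0, "cost must be positive"),
            (0.0 < self.theta <= 1.0, "theta must be in (0, 1]"),
            (0.0 < self.p0 < 1.0, "p0 must be in (0, 1)"),
            (self.max_outer_iterations >= 1, "max_outer_iterations must be >= 1"),
            (0.0 < self.epsilon < 0.5, "epsilon must be in (0, 0.5)"),
            (0.0 <= self.blend <= 1.0, "blend must be in [0, 1]"),
            (0.0 <= self.crossover_prob <= 1.0, "crossover_prob must be in [0, 1]"),
            (0.0 <= self.mutation_prob <= 1.0, "mutation_prob must be in [0, 1]"),
        ]
        if self.patience is not None and self.patience < 1:
            raise ValueError("patience must be >= 1 or None")
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    def to_dict(self) -> dict:
        return asdict(self)
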