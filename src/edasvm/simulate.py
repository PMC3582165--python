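"""Microarray-like synthetic data with planted discriminative genes.

The generator emulates the shape of two-class expression benchmarks — a few
dozen samples, thousands of genes, optional missing entries — with a known
ground truth: background expression is i.i.d. Gaussian noise, and a small
planted set of informative genes receives a mean shift (in noise-SD units)
in the +1 class.  Optionally, blocks of decoy genes correlated with the
informative ones can be added to stress multivariate selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import ExpressionDataset

__all__ = ["PlantedDesign", "generate", "PRESETS", "preset_design"]


@dataclass(frozen=True)
class PlantedDesign:
    """Parameters of one planted two-class dataset.

    effect_size is the between-class mean shift of informative genes in
    units of noise_sd; missing_fraction masks that fraction of all matrix
    entries uniformly at random.
    """

    n_samples_per_class: tuple = (20, 20)
    n_genes: int = 200
    n_informative: int = 10
    effect_size: float = 3.0
    noise_sd: float = 1.0
    missing_fraction: float = 0.0
    correlated_decoys_per_informative: int = 0
    decoy_correlation: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative must be <= n_genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0, 1)")
        if len(self.n_samples_per_class) != 2:
            raise ValueError("n_samples_per_class must give two class sizes")


def generate(design: PlantedDesign):
    """Draw one dataset from the design.

    Returns
    -------
    dataset : ExpressionDataset
        Samples x genes matrix with labels (+1 first class), NaN where
        masked.
    planted : set of str
        Gene ids of the informative genes.
    """
    rng = np.random.default_rng(design.seed)
    n1, n2 = design.n_samples_per_class
    n = n1 + n2
    X = rng.normal(0.0, design.noise_sd, size=(n, design.n_genes))
    labels = np.concatenate([np.ones(n1, dtype=int), -np.ones(n2, dtype=int)])
    informative = rng.choice(design.n_genes, size=design.n_informative,
                             replace=False)
    shift = design.effect_size * design.noise_sd
    X[np.ix_(labels == 1, informative)] += shift
    if design.correlated_decoys_per_informative > 0:
        # decoys = rho * (centred informative signal) + noise; they echo the
        # informative genes' sample-to-sample variation but not their shift
        pool = np.setdiff1d(np.arange(design.n_genes), informative)
        n_decoys = min(len(pool),
                       design.correlated_decoys_per_informative
                       * design.n_informative)
        decoys = rng.choice(pool, size=n_decoys, replace=False)
        rho = design.decoy_correlation
        for j, d in enumerate(decoys):
            src = informative[j % design.n_informative]
            base = X[:, src] - np.where(labels == 1, shift, 0.0)
            X[:, d] = rho * base + np.sqrt(1 - rho ** 2) * X[:, d]
    if design.missing_fraction > 0:
        miss = rng.random(X.shape) < design.missing_fraction
        # never blank out an entire gene profile (uninterpretable target)
        full = miss.all(axis=0)
        miss[0, full] = False
        X = np.where(miss, np.nan, X)
    width = len(str(design.n_genes))
    gene_ids = tuple(f"g{i:0{width}d}" for i in range(design.n_genes))
    sample_ids = tuple(f"s{i:03d}" for i in range(n))
    dataset = ExpressionDataset(X, gene_ids, sample_ids, labels=labels)
    planted = {gene_ids[i] for i in sorted(informative)}
    return dataset, planted


PRESETS = {
    # shapes of the public two-class benchmarks: 62 colon samples
    # (40 tumour / 22 normal) x 2000 genes; 42 lymphoma samples
    # (21 + 21 subtypes) x 4026 genes with ~6% missing entries
    "colon": dict(n_samples_per_class=(40, 22), n_genes=2000,
                  n_informative=10, effect_size=3.0, missing_fraction=0.0),
    "dlbcl": dict(n_samples_per_class=(21, 21), n_genes=4026,
                  n_informative=10, effect_size=3.0, missing_fraction=0.06),
    "small": dict(n_samples_per_class=(20, 20), n_genes=200,
                  n_informative=10, effect_size=3.0, missing_fraction=0.0),
}


def preset_design(name: str, seed: int = 0) -> PlantedDesign:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return PlantedDesign(seed=seed, **PRESETS[name])
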