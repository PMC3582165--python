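import numpy as np
import pytest

from edasvm.dataset import ExpressionDataset
from edasvm.simulate import PlantedDesign, generate


@pytest.fixture
def tiny_dataset():
    """4 samples x 3 genes with hand-written values; gene g1 separates."""
    matrix = np.array([
        [5.0, 1.0, 0.0],
        [6.0, 2.0, 1.0],
        [-5.0, 1.5, 0.5],
        [-6.0, 0.5, -0.5],
    ])
    return ExpressionDataset(
        matrix, gene_ids=("g0", "g1", "g2"),
        sample_ids=("s0", "s1", "s2", "s3"),
        labels=np.array([1, 1, -1, -1]),
    )


@pytest.fixture
def planted_small():
    """Planted two-class data: 20+20 samples, 60 genes, 5 informative."""
    design = PlantedDesign(n_samples_per_class=(20, 20), n_genes=60,
                           n_informative=5, effect_size=3.0, seed=7)
    return generate(design)
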