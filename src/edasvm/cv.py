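"""Repeated two-class cross-validation plans.

Each class is partitioned into ``folds_per_class`` subsets of roughly equal
size; every pairing of one subset from each class forms a test set, and the
remaining samples form the learning set.  With 5 folds per class this yields
the 25 learning/test pairs over which fitness is averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CVPlan", "build_cv_plan"]


@dataclass(frozen=True)
class CVPlan:
    """The full cross-product of per-class folds.

    Attributes
    ----------
    pairs : tuple of (learn, test)
        ``folds_per_class ** 2`` pairs of disjoint sample-index arrays whose
        union is all samples.
    folds_per_class : int
    seed : int
        Seed used to shuffle samples within each class.
    """

    pairs: tuple
    folds_per_class: int
    seed: int

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def build_cv_plan(labels, folds_per_class: int = 5, seed: int = 0) -> CVPlan:
    """Partition each class into folds and cross all test-fold pairings.

    Per class, samples are shuffled (deterministically from ``seed``) and
    split into ``folds_per_class`` subsets whose sizes differ by at most one.
    A test set is one subset from each class; the learning set is everything
    else.

    Raises
    ------
    ValueError
        If a class has fewer samples than ``folds_per_class``, or if any
        learning set would be empty (``folds_per_class`` = 1).
    """
    labels = np.asarray(labels)
    if folds_per_class < 2:
        raise ValueError(
            "folds_per_class must be >= 2 (a single fold leaves an empty "
            "learning set)"
        )
    classes = [1, -1] if set(np.unique(labels)) == {1, -1} else list(
        dict.fromkeys(labels.tolist())
    )
    if len(classes) != 2:
        raise ValueError(f"expected two classes, found {len(classes)}")
    rng = np.random.default_rng(seed)
    folds = {}
    for cls in classes:
        idx = np.where(labels == cls)[0]
        if len(idx) < folds_per_class:
            raise ValueError(
                f"class {cls} has {len(idx)} samples, fewer than "
                f"folds_per_class={folds_per_class}"
            )
        rng.shuffle(idx)
        folds[cls] = [np.sort(part) for part in np.array_split(idx, folds_per_class)]
    all_idx = np.arange(len(labels))
    pairs = []
    for fa in folds[classes[0]]:
        for fb in folds[classes[1]]:
            test = np.sort(np.concatenate([fa, fb]))
            learn = np.setdiff1d(all_idx, test)
            pairs.append((learn, test))
    return CVPlan(pairs=tuple(pairs), folds_per_class=folds_per_class, seed=int(seed))
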