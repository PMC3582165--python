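"""Gene-subset fitness: repeated cross-validated linear-SVM accuracy.

A candidate subset is a binary mask over genes.  Its fitness is the mean test
accuracy of a soft-margin linear SVM trained on the masked genes over the 25
learning/test pairs of a :class:`~edasvm.cv.CVPlan`; alongside, each included
gene receives a weight — the squared component of the SVM primal weight
vector w = sum_h a_h y_h x_h, averaged over the pairs — that the search
engine feeds back into its probability model.  Excluded genes have weight
exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .cv import CVPlan

__all__ = [
    "LinearSVMModel",
    "FitnessResult",
    "train_linear_svm",
    "accuracy",
    "feature_preweights",
    "FitnessEvaluator",
    "evaluate_individual",
]


@dataclass(frozen=True)
class LinearSVMModel:
    """A trained linear decision function sgn(w.x + b).

    ``dual_coef`` holds a_i * y_i for the support vectors (a_i >= 0 are the
    Lagrange multipliers), ``support_vectors`` the corresponding learning
    rows, so w = dual_coef @ support_vectors.
    """

    dual_coef: np.ndarray
    support_vectors: np.ndarray
    support_indices: np.ndarray
    intercept: float
    w: np.ndarray

    @property
    def n_features(self) -> int:
        return self.w.shape[0]

    def decision_function(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.w + self.intercept

    def predict(self, X) -> np.ndarray:
        d = self.decision_function(X)
        # sign with the 0 boundary assigned to +1
        return np.where(d >= 0, 1, -1)


def train_linear_svm(learning_matrix, learning_labels, cost: float = 1.0
                     ) -> LinearSVMModel:
    """Fit the maximum-margin soft-margin linear SVM.

    Raises
    ------
    ValueError
        If the learning set contains a single class or no features.
    """
    X = np.asarray(learning_matrix, dtype=float)
    y = np.asarray(learning_labels)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("learning matrix must be 2-d with >= 1 feature")
    if len(np.unique(y)) < 2:
        raise ValueError("learning set contains a single class")
    if cost <= 0:
        raise ValueError("cost must be positive")
    svc = SVC(kernel="linear", C=cost, tol=1e-8)
    svc.fit(X, y)
    # sklearn orders classes ascending (-1, +1); dual_coef_ is alpha_i * y_i.
    w = svc.coef_.ravel().astype(float)
    return LinearSVMModel(
        dual_coef=svc.dual_coef_.ravel().astype(float),
        support_vectors=svc.support_vectors_.astype(float),
        support_indices=svc.support_.astype(int),
        intercept=float(svc.intercept_[0]),
        w=w,
    )


def accuracy(predictions, truth) -> float:
    """Fraction of positions where prediction equals truth."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise ValueError(
            f"length mismatch: {predictions.shape} vs {truth.shape}"
        )
    if predictions.size == 0:
        raise ValueError("empty prediction vector")
    return float(np.mean(predictions == truth))


def feature_preweights(model: LinearSVMModel, mask) -> np.ndarray:
    """Per-gene squared primal weights, scattered to full gene length.

    ``model`` must be trained on exactly the genes where ``mask`` is 1; the
    returned vector has one entry per mask position, zero wherever the mask
    is zero.
    """
    mask = np.asarray(mask, dtype=bool)
    if int(mask.sum()) != model.n_features:
        raise ValueError(
            f"model has {model.n_features} features but mask selects "
            f"{int(mask.sum())} genes"
        )
    out = np.zeros(mask.shape[0], dtype=float)
    out[mask] = model.w ** 2
    return out


@dataclass(frozen=True)
class FitnessResult:
    """Averaged evaluation of one gene-subset mask over all CV pairs."""

    fitness: float
    weights: np.ndarray
    per_pair_accuracy: tuple


class FitnessEvaluator:
    """Evaluate masks against a fixed dataset and CV plan.

    Per-gene standardization statistics (learning-set mean and SD) are
    precomputed per pair for all genes, so evaluating a mask reduces to
    column slicing plus one SVM fit per pair.  Standardization uses
    learning-set statistics only; test samples are transformed with the same
    statistics, so no test information leaks into training.
    """

    def __init__(self, dataset, plan: CVPlan, cost: float = 1.0,
                 standardize: bool = True):
        if dataset.labels is None:
            raise ValueError("dataset has no labels")
        if np.isnan(dataset.matrix).any():
            raise ValueError("dataset has missing values; impute first")
        self.dataset = dataset
        self.plan = plan
        self.cost = float(cost)
        self.standardize = bool(standardize)
        X = dataset.matrix
        self._Z = []  # per pair: full matrix standardized by learning stats
        for learn, _test in plan.pairs:
            if self.standardize:
                mu = X[learn].mean(axis=0)
                sd = X[learn].std(axis=0)
                sd = np.where(sd > 0, sd, 1.0)  # constant gene -> centred zeros
                self._Z.append((X - mu) / sd)
            else:
                self._Z.append(X)

    @property
    def n_genes(self) -> int:
        return self.dataset.n_genes

    def evaluate(self, mask) -> FitnessResult:
        """Mean accuracy and mean per-gene weights over all CV pairs.

        An empty mask is the degenerate individual: fitness 0 with zero
        weights, so that search populations containing all-zero strings
        remain evaluable and such strings are selected against.
        """
        mask = np.asarray(mask, dtype=bool)
        if mask.shape[0] != self.n_genes:
            raise ValueError(
                f"mask length {mask.shape[0]} != gene count {self.n_genes}"
            )
        if not mask.any():
            return FitnessResult(0.0, np.zeros(self.n_genes), ())
        y = self.dataset.labels
        accs = []
        wsum = np.zeros(self.n_genes)
        for (learn, test), Z in zip(self.plan.pairs, self._Z):
            model = train_linear_svm(Z[np.ix_(learn, np.where(mask)[0])],
                                     y[learn], cost=self.cost)
            pred = model.predict(Z[np.ix_(test, np.where(mask)[0])])
            accs.append(accuracy(pred, y[test]))
            wsum += feature_preweights(model, mask)
        n = len(accs)
        return FitnessResult(
            fitness=float(np.mean(accs)),
            weights=wsum / n,
            per_pair_accuracy=tuple(accs),
        )


def evaluate_individual(dataset, mask, plan: CVPlan, cost: float = 1.0,
                        standardize: bool = True) -> FitnessResult:
    """One-shot form of :meth:`FitnessEvaluator.evaluate`."""
    return FitnessEvaluator(dataset, plan, cost=cost,
                            standardize=standardize).evaluate(mask)
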