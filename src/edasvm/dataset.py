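"""Two-class expression data: container, TSV I/O, and KNN imputation.

The central object is :class:`ExpressionDataset`, a samples x genes matrix of
real-valued expression levels (log-ratios or intensities) with ordered gene
and sample identifiers and a per-sample class indicator in {+1, -1}.  Missing
entries are represented as NaN and must be imputed (``knn_impute``) before a
dataset is fed to a search engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "read_expression_table",
    "write_expression_table",
    "read_labels",
    "write_labels",
    "knn_impute",
]

DEFAULT_MISSING_TOKENS = ("", "NA", "NaN", "nan", "N/A", "null")


@dataclass(frozen=True)
class ExpressionDataset:
    """Expression matrix with identifiers and binary class labels.

    Parameters
    ----------
    matrix : ndarray, shape (n_samples, n_genes)
        Expression values; missing entries are NaN.
    gene_ids : tuple of str
        Ordered, unique gene identifiers (columns of ``matrix``).
    sample_ids : tuple of str
        Ordered, unique sample identifiers (rows of ``matrix``).
    labels : ndarray, shape (n_samples,)
        Class indicator, +1 for the first class and -1 for the second.
    """

    matrix: np.ndarray
    gene_ids: tuple
    sample_ids: tuple
    labels: np.ndarray = field(default=None)

    def __post_init__(self):
        matrix = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if matrix.ndim != 2:
            raise ValueError("matrix must be 2-dimensional (samples x genes)")
        n_samples, n_genes = matrix.shape
        if len(self.sample_ids) != n_samples:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n_samples} matrix rows"
            )
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != n_samples:
            raise ValueError("duplicate sample ids")
        if self.labels is not None:
            labels = np.asarray(self.labels)
            if labels.shape != (n_samples,):
                raise ValueError("labels must have one entry per sample")
            values = set(np.unique(labels).tolist())
            if values != {1, -1}:
                raise ValueError(
                    f"labels must be +1/-1 with both classes present, got {sorted(values)}"
                )
            for cls in (1, -1):
                if int(np.sum(labels == cls)) < 2:
                    raise ValueError(f"class {cls:+d} has fewer than 2 samples")
            object.__setattr__(self, "labels", labels.astype(int))

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.matrix).sum())

    def with_labels(self, labels) -> "ExpressionDataset":
        return replace(self, labels=np.asarray(labels))

    def subset_genes(self, indices) -> "ExpressionDataset":
        """Restrict to the genes at ``indices`` (order preserved)."""
        indices = np.asarray(indices, dtype=int)
        return ExpressionDataset(
            matrix=self.matrix[:, indices],
            gene_ids=tuple(self.gene_ids[i] for i in indices),
            sample_ids=self.sample_ids,
            labels=self.labels,
        )


def _encode_labels(raw: pd.Series) -> np.ndarray:
    """Map arbitrary two-valued labels to +1/-1 by order of first appearance."""
    seen = list(dict.fromkeys(raw.tolist()))
    if len(seen) != 2:
        raise ValueError(f"expected exactly two classes, found {len(seen)}: {seen}")
    mapping = {seen[0]: 1, seen[1]: -1}
    return np.array([mapping[v] for v in raw], dtype=int)


def read_labels(path) -> dict:
    """Read a two-column TSV (sample_id, label) into an ordered mapping."""
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if frame.shape[1] < 2:
        raise ValueError("label file must have two tab-separated columns")
    # Tolerate a header line of the form "sample<TAB>label".
    first = frame.iloc[0]
    if str(first.iloc[0]).lower() in {"sample", "sample_id", "id"}:
        frame = frame.iloc[1:]
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


def write_labels(path, dataset: ExpressionDataset) -> None:
    with open(path, "w") as fh:
        for sid, lab in zip(dataset.sample_ids, dataset.labels):
            fh.write(f"{sid}\t{int(lab):+d}\n")


def read_expression_table(
    path,
    orientation: str = "genes-as-rows",
    labels=None,
    missing_tokens=DEFAULT_MISSING_TOKENS,
) -> ExpressionDataset:
    """Load a tab-delimited expression table.

    The file has one header row and one leading ID column.  With the default
    ``genes-as-rows`` orientation (the layout of the public colon and lymphoma
    benchmark files) the header holds sample ids and the ID column gene ids;
    ``samples-as-rows`` swaps the roles.  The returned dataset is always
    samples x genes.  Cells equal to one of ``missing_tokens`` become NaN and
    are counted as missing, never silently zeroed.

    Parameters
    ----------
    labels : mapping, sequence, or None
        Per-sample class labels, either a mapping from sample id or a sequence
        in file sample order.  Arbitrary two-valued labels are encoded +1/-1
        by order of first appearance.
    """
    if orientation not in ("genes-as-rows", "samples-as-rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    frame = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        na_values=list(missing_tokens),
        keep_default_na=False,
        dtype=str,
    )
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        for i, cell in enumerate(frame.iloc[:, j]):
            if isinstance(cell, float) and np.isnan(cell):
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric cell {cell!r} at row {frame.index[i]!r}, "
                    f"column {col!r}"
                ) from None
    if orientation == "genes-as-rows":
        matrix = values.T
        gene_ids = [str(g) for g in frame.index]
        sample_ids = [str(s) for s in frame.columns]
    else:
        matrix = values
        gene_ids = [str(g) for g in frame.columns]
        sample_ids = [str(s) for s in frame.index]
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicate gene ids in file")
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids in file")

    encoded = None
    if labels is not None:
        if isinstance(labels, dict):
            missing = [s for s in sample_ids if s not in labels]
            if missing:
                raise ValueError(f"no label for samples: {missing[:5]}")
            raw = pd.Series([labels[s] for s in sample_ids])
        else:
            raw = pd.Series(list(labels))
            if len(raw) != len(sample_ids):
                raise ValueError("label sequence length does not match sample count")
        encoded = _encode_labels(raw)
    return ExpressionDataset(matrix, gene_ids, sample_ids, labels=encoded)


def write_expression_table(path, dataset: ExpressionDataset,
                           orientation: str = "genes-as-rows") -> None:
    """Write the TSV dialect :func:`read_expression_table` reads.

    Missing entries are written as "NA".  Floats use repr so a write/read
    round-trip reproduces the matrix exactly.
    """
    if orientation not in ("genes-as-rows", "samples-as-rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")

    def fmt(x):
        return "NA" if np.isnan(x) else repr(float(x))

    with open(path, "w") as fh:
        if orientation == "genes-as-rows":
            fh.write("gene_id\t" + "\t".join(dataset.sample_ids) + "\n")
            for i, gid in enumerate(dataset.gene_ids):
                row = dataset.matrix[:, i]
                fh.write(gid + "\t" + "\t".join(fmt(x) for x in row) + "\n")
        else:
            fh.write("sample_id\t" + "\t".join(dataset.gene_ids) + "\n")
            for i, sid in enumerate(dataset.sample_ids):
                row = dataset.matrix[i, :]
                fh.write(sid + "\t" + "\t".join(fmt(x) for x in row) + "\n")


def knn_impute(dataset: ExpressionDataset, k: int = 5) -> ExpressionDataset:
    """Impute missing entries from the k nearest neighbouring gene profiles.

    For a gene with a missing value at sample ``s``, the k genes with the
    most similar expression profiles — smallest mean squared difference over
    mutually observed samples — among genes observed at ``s`` are found, and
    the missing value is replaced by the unweighted mean of their values at
    ``s``.  Observed entries are never altered, so the operation is
    idempotent.

    Parameters
    ----------
    k : int
        Number of neighbour genes averaged per missing entry (default 5).
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    X = dataset.matrix.T.copy()  # genes x samples
    miss = np.isnan(X)
    if not miss.any():
        return dataset
    all_missing = miss.all(axis=1)
    if all_missing.any():
        bad = dataset.gene_ids[int(np.where(all_missing)[0][0])]
        raise ValueError(f"gene {bad!r} is missing in all samples; cannot impute")

    n_genes, n_samples = X.shape
    obs = ~miss
    filled = np.where(miss, 0.0, X)
    targets = np.where(miss.any(axis=1))[0]
    imputed = X.copy()
    # Chunk targets so the (targets x genes x samples) broadcast stays small.
    chunk = max(1, int(2e7 // (n_genes * n_samples)) or 1)
    for start in range(0, len(targets), chunk):
        idx = targets[start:start + chunk]
        diff = filled[idx, None, :] - filled[None, :, :]          # t x g x s
        shared = obs[idx, None, :] & obs[None, :, :]              # t x g x s
        sq = np.where(shared, diff * diff, 0.0)
        n_shared = shared.sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.where(n_shared > 0, sq.sum(axis=2) / n_shared, np.inf)
        for row, g in enumerate(idx):
            d = dist[row].copy()
            d[g] = np.inf  # a gene is not its own neighbour
            for s in np.where(miss[g])[0]:
                cand = d.copy()
                cand[~obs[:, s]] = np.inf  # neighbour must be observed at s
                order = np.argsort(cand, kind="stable")
                valid = order[np.isfinite(cand[order])][:k]
                if len(valid) < k:
                    raise ValueError(
                        f"fewer than k={k} usable neighbours for gene "
                        f"{dataset.gene_ids[g]!r} at sample "
                        f"{dataset.sample_ids[s]!r}"
                    )
                imputed[g, s] = float(np.mean(X[valid, s]))
    return replace(dataset, matrix=imputed.T)
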