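"""Trace serialization (JSON lines) and iteration-curve plotting."""

from __future__ import annotations

import json

from .engine import IterationRecord, ReductionTrace

__all__ = ["write_trace", "read_trace", "write_generation_logs",
           "trace_series", "plot_trace"]


def write_trace(path, trace: ReductionTrace) -> None:
    """One JSON object per outer iteration."""
    with open(path, "w") as fh:
        for i, rec in enumerate(trace.iterations):
            fh.write(json.dumps({
                "iteration": i + 1,
                "gene_count": rec.gene_count,
                "best_fitness": rec.best_fitness,
                "mean_fitness": rec.mean_fitness,
                "n_generations": rec.n_generations,
                "selected_gene_ids": list(rec.selected_gene_ids),
            }, sort_keys=True) + "\n")


def read_trace(path) -> ReductionTrace:
    trace = ReductionTrace()
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            trace.append(IterationRecord(
                gene_count=int(d["gene_count"]),
                best_fitness=float(d["best_fitness"]),
                mean_fitness=float(d["mean_fitness"]),
                selected_gene_ids=tuple(d["selected_gene_ids"]),
                n_generations=int(d["n_generations"]),
            ))
    return trace


def write_generation_logs(path, gen_logs) -> None:
    """One JSON object per inner generation, tagged with its outer iteration."""
    with open(path, "w") as fh:
        for outer, log in enumerate(gen_logs, start=1):
            for entry in log:
                fh.write(json.dumps({"outer_iteration": outer, **entry},
                                    sort_keys=True) + "\n")


def trace_series(trace: ReductionTrace):
    """(iteration, gene_count, best_fitness) columns for plotting/export."""
    iters = list(range(1, len(trace) + 1))
    return iters, trace.gene_counts, trace.best_fitnesses


def plot_trace(trace: ReductionTrace, out_path=None, ax=None):
    """Accuracy and gene count versus outer iteration (two stacked panels)."""
    import matplotlib
    if out_path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    iters, counts, fits = trace_series(trace)
    if ax is None:
        fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(6, 6))
    else:
        ax1, ax2 = ax
        fig = ax1.figure
    ax1.plot(iters, fits, marker="o")
    ax1.set_ylabel("best CV accuracy")
    ax2.plot(iters, counts, marker="o")
    ax2.set_yscale("log")
    ax2.set_ylabel("gene count")
    ax2.set_xlabel("outer iteration")
    if out_path is not None:
        fig.savefig(out_path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
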