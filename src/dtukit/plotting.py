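"""Minimal per-gene visualization: isoform proportions by condition."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .model import AlignedExperiment, ExperimentData, align


def plot_gene(
    gene_id: str,
    data: ExperimentData | AlignedExperiment,
    out_path: str | Path,
) -> Path:
    """Grouped bars of mean isoform proportion per condition, with the
    individual replicates overplotted as points.

    Per-replicate proportions are each isoform's share of the gene's total
    in that replicate (undefined replicates, with zero gene expression, are
    skipped).  Raises ``KeyError`` for a gene absent from the annotation.
    """
    ax_data = data if isinstance(data, AlignedExperiment) else align(data)
    gidx = np.flatnonzero(ax_data.gene_ids == gene_id)
    if gidx.size == 0:
        raise KeyError(f"unknown gene {gene_id!r}")
    g = int(gidx[0])
    start = ax_data.gene_starts[g]
    stop = start + ax_data.gene_sizes[g]
    tx = ax_data.transcript_ids[start:stop]

    def rep_props(counts):  # counts: isoforms x replicates
        tot = counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = counts / tot
        return p[:, tot > 0]

    props = {
        "condition A": rep_props(ax_data.counts_a[start:stop]),
        "condition B": rep_props(ax_data.counts_b[start:stop]),
    }
    x = np.arange(tx.size)
    width = 0.35
    fig, axis = plt.subplots(figsize=(1.2 + 1.2 * tx.size, 3.5))
    for k, (label, p) in enumerate(props.items()):
        offset = (k - 0.5) * width
        mean = p.mean(axis=1) if p.size else np.zeros(tx.size)
        axis.bar(x + offset, mean, width=width, label=label, alpha=0.7)
        for r in range(p.shape[1]):
            axis.scatter(x + offset, p[:, r], s=12, color="black", zorder=3)
    axis.set_xticks(x)
    axis.set_xticklabels(tx, rotation=45, ha="right", fontsize=8)
    axis.set_ylabel("isoform proportion")
    axis.set_title(gene_id)
    axis.set_ylim(0, 1.05)
    axis.legend(fontsize=8)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path)
    plt.close(fig)
    return out_path
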