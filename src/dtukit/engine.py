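"""Vectorized single-pass DTU evaluation on replicate-summed counts.

This is the workhorse behind both the main run and the many re-runs the
reproducibility filters perform (one per bootstrap draw, one per replicate
pair), so everything is array arithmetic over gene segments: transcripts are
pre-sorted by gene (see :func:`dtukit.model.align`) and per-gene reductions
use ``reduceat`` over contiguous segments.  Results are numerically identical
to the scalar routines in :mod:`dtukit.stats` (tested), just batched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats as sps

from .model import AlignedExperiment
from .stats import bh_adjust


@dataclass
class ProvisionalResult:
    """Per-feature outcome of one filters -> tests -> BH -> effect pass.

    Gene arrays align with ``AlignedExperiment.gene_ids``; transcript arrays
    with ``AlignedExperiment.transcript_ids``.  Untested features carry NaN
    statistics.
    """

    # transcript level
    tx_detect_a: np.ndarray
    tx_detect_b: np.ndarray
    tx_eligible: np.ndarray
    tx_tested: np.ndarray
    tx_g: np.ndarray
    tx_df: np.ndarray
    tx_p: np.ndarray
    tx_padj: np.ndarray
    prop_a: np.ndarray
    prop_b: np.ndarray
    dprop: np.ndarray
    tx_call: np.ndarray
    # gene level
    gene_eligible: np.ndarray
    gene_tested: np.ndarray
    gene_g: np.ndarray
    gene_df: np.ndarray
    gene_p: np.ndarray
    gene_padj: np.ndarray
    gene_effect: np.ndarray
    gene_call: np.ndarray


def _segment_sum(values: np.ndarray, starts: np.ndarray) -> np.ndarray:
    return np.add.reduceat(values, starts)


def provisional_run(
    ax: AlignedExperiment,
    a_sum: np.ndarray,
    b_sum: np.ndarray,
    n_a: int,
    n_b: int,
    abundance_threshold: float,
    alpha: float,
    dprop_threshold: float,
) -> ProvisionalResult:
    """Run detection, eligibility, both G-tests, BH and effect classification
    on one pair of summed count vectors.

    ``a_sum``/``b_sum`` are per-transcript counts summed over the ``n_a`` /
    ``n_b`` replicates that produced them (detection thresholds apply to the
    implied means).  Returns provisional calls, before reproducibility
    filtering.
    """
    starts = ax.gene_starts

    # -- detection & eligibility -------------------------------------------
    det_a = (a_sum / n_a) >= abundance_threshold
    det_b = (b_sum / n_b) >= abundance_threshold
    det_any = det_a | det_b
    n_detected = _segment_sum(det_any.astype(np.int64), starts)
    gene_tot_a = _segment_sum(a_sum, starts)
    gene_tot_b = _segment_sum(b_sum, starts)
    gene_eligible = (n_detected >= 2) & (gene_tot_a > 0) & (gene_tot_b > 0)
    tx_eligible = ax.repeat_gene(gene_eligible) & det_any

    # -- gene-level G-test on isoforms x 2 tables --------------------------
    row_tot = a_sum + b_sum
    gene_n = gene_tot_a + gene_tot_b
    k_nonzero = _segment_sum((row_tot > 0).astype(np.int64), starts)
    gene_tested = gene_eligible & (k_nonzero >= 2)

    A_tx = ax.repeat_gene(gene_tot_a)
    B_tx = ax.repeat_gene(gene_tot_b)
    N_tx = ax.repeat_gene(gene_n)
    with np.errstate(divide="ignore", invalid="ignore"):
        e_a = row_tot * A_tx / N_tx
        e_b = row_tot * B_tx / N_tx
    # rel_entr(0, 0) -> 0 only when both args are 0; zero expected with
    # nonzero observed cannot occur here (E=0 implies row or column total 0)
    term = special.rel_entr(a_sum, np.where(e_a > 0, e_a, 1.0)) + special.rel_entr(
        b_sum, np.where(e_b > 0, e_b, 1.0)
    )
    term = np.where((row_tot > 0) & (N_tx > 0), term, 0.0)
    gene_g = np.maximum(2.0 * _segment_sum(term, starts), 0.0)
    gene_df = np.maximum(k_nonzero - 1, 1)
    gene_p = np.full(gene_g.shape, np.nan)
    gene_p[gene_tested] = sps.chi2.sf(gene_g[gene_tested], gene_df[gene_tested])
    gene_g[~gene_tested] = np.nan

    # -- proportions and effect sizes --------------------------------------
    with np.errstate(divide="ignore", invalid="ignore"):
        prop_a = np.where(A_tx > 0, a_sum / A_tx, np.nan)
        prop_b = np.where(B_tx > 0, b_sum / B_tx, np.nan)
    dprop = prop_b - prop_a
    gene_eligible_tx = ax.repeat_gene(gene_eligible)
    abs_dprop = np.where(gene_eligible_tx, np.abs(dprop), 0.0)
    abs_dprop = np.nan_to_num(abs_dprop, nan=0.0)
    gene_effect = np.maximum.reduceat(abs_dprop, starts)
    gene_effect[~gene_eligible] = np.nan

    # -- transcript-level 2x2 G-test (target vs pooled siblings) -----------
    sib_a = A_tx - a_sum
    sib_b = B_tx - b_sum
    tx_tested = tx_eligible & (row_tot > 0) & (sib_a + sib_b > 0)
    idx = np.flatnonzero(tx_tested)
    tx_g = np.full(a_sum.shape, np.nan)
    tx_p = np.full(a_sum.shape, np.nan)
    if idx.size:
        o = np.stack(
            [a_sum[idx], b_sum[idx], sib_a[idx], sib_b[idx]], axis=1
        )  # rows: target_a, target_b, sib_a, sib_b
        r1 = o[:, 0] + o[:, 1]
        r2 = o[:, 2] + o[:, 3]
        ca = o[:, 0] + o[:, 2]
        cb = o[:, 1] + o[:, 3]
        n = r1 + r2
        e = np.stack([r1 * ca, r1 * cb, r2 * ca, r2 * cb], axis=1) / n[:, None]
        g2 = 2.0 * special.rel_entr(o, np.where(e > 0, e, 1.0)).sum(axis=1)
        tx_g[idx] = np.maximum(g2, 0.0)
        tx_p[idx] = sps.chi2.sf(tx_g[idx], 1)
    tx_df = np.where(tx_tested, 1, 0)

    # -- BH correction, independent families per level ---------------------
    gene_padj = np.full(gene_p.shape, np.nan)
    if gene_tested.any():
        gene_padj[gene_tested] = bh_adjust(gene_p[gene_tested])
    tx_padj = np.full(tx_p.shape, np.nan)
    if tx_tested.any():
        tx_padj[tx_tested] = bh_adjust(tx_p[tx_tested])

    # -- provisional classification ----------------------------------------
    with np.errstate(invalid="ignore"):
        gene_call = gene_tested & (gene_padj < alpha) & (gene_effect >= dprop_threshold)
        tx_call = tx_tested & (tx_padj < alpha) & (np.abs(dprop) >= dprop_threshold)

    return ProvisionalResult(
        tx_detect_a=det_a,
        tx_detect_b=det_b,
        tx_eligible=tx_eligible,
        tx_tested=tx_tested,
        tx_g=tx_g,
        tx_df=tx_df,
        tx_p=tx_p,
        tx_padj=tx_padj,
        prop_a=prop_a,
        prop_b=prop_b,
        dprop=dprop,
        tx_call=tx_call,
        gene_eligible=gene_eligible,
        gene_tested=gene_tested,
        gene_g=gene_g,
        gene_df=gene_df.astype(int),
        gene_p=gene_p,
        gene_padj=gene_padj,
        gene_effect=gene_effect,
        gene_call=gene_call,
    )


def point_run(ax: AlignedExperiment, abundance_threshold, alpha, dprop_threshold):
    """Provisional run on the point-estimate counts."""
    return provisional_run(
        ax,
        ax.counts_a.sum(axis=1),
        ax.counts_b.sum(axis=1),
        ax.n_a,
        ax.n_b,
        abundance_threshold,
        alpha,
        dprop_threshold,
    )
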