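"""Bootstrap-based quality filters on provisional DTU calls.

Two reproducibility measures refine the calls:

* quantification reproducibility (Qrep): re-run the whole provisional
  pipeline on randomly drawn bootstrap iterations (one iteration per
  replicate per draw) and record the fraction of draws in which a feature's
  call stays positive.  High quantification uncertainty shows up as an
  unstable call.
* inter-replicate reproducibility (Rrep): re-run the pipeline once per
  cross-condition replicate pair (all n_a x n_b one-vs-one pairings) and
  record the fraction of pairs with a positive call.

Filters only ever remove calls: a provisional positive survives only if each
available fraction strictly exceeds its threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .engine import ProvisionalResult, provisional_run
from .model import AlignedExperiment

logger = logging.getLogger(__name__)


@dataclass
class ReproducibilityScores:
    """Per-feature reproducibility fractions; ``None`` when a measure was
    skipped (no bootstraps / too few replicates)."""

    gene_qrep: np.ndarray | None
    tx_qrep: np.ndarray | None
    gene_rrep: np.ndarray | None
    tx_rrep: np.ndarray | None
    n_quant_draws: int
    n_replicate_subsets: int


def quant_reproducibility(
    ax: AlignedExperiment,
    config: RunConfig,
    n_draws: int | None = None,
    rng_seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, int] | tuple[None, None, int]:
    """Fraction of bootstrap draws yielding a positive provisional call.

    Each draw samples one bootstrap iteration index per replicate (uniformly,
    with replacement, independently across replicates and draws) and re-runs
    filters, tests, BH and effect classification on the drawn counts.
    Deterministic given the seed.  Returns (gene fractions, transcript
    fractions, n_draws), or (None, None, 0) with a warning if any replicate
    lacks bootstraps.
    """
    if not ax.has_bootstrap:
        logger.warning(
            "quantification reproducibility skipped: not all replicates "
            "carry bootstrap iterations"
        )
        return None, None, 0
    n_draws = config.n_quant_draws if n_draws is None else n_draws
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(config.seed if rng_seed is None else rng_seed)
    gene_pos = np.zeros(ax.gene_ids.size, dtype=np.int64)
    tx_pos = np.zeros(ax.transcript_ids.size, dtype=np.int64)
    n_boot_a = [b.shape[1] for b in ax.boot_a]
    n_boot_b = [b.shape[1] for b in ax.boot_b]
    for _ in range(n_draws):
        a_sum = np.zeros(ax.transcript_ids.size)
        for boot, nb in zip(ax.boot_a, n_boot_a):
            a_sum += boot[:, rng.integers(nb)]
        b_sum = np.zeros(ax.transcript_ids.size)
        for boot, nb in zip(ax.boot_b, n_boot_b):
            b_sum += boot[:, rng.integers(nb)]
        res = provisional_run(
            ax,
            a_sum,
            b_sum,
            ax.n_a,
            ax.n_b,
            config.abundance_threshold,
            config.alpha,
            config.dprop_threshold,
        )
        gene_pos += res.gene_call
        tx_pos += res.tx_call
    return gene_pos / n_draws, tx_pos / n_draws, n_draws


def replicate_reproducibility(
    ax: AlignedExperiment, config: RunConfig
) -> tuple[np.ndarray, np.ndarray, int] | tuple[None, None, int]:
    """Fraction of one-vs-one cross-condition replicate pairings with a
    positive provisional call.

    All n_a x n_b pairs are evaluated (9 runs for a 3 vs 3 design).  With
    fewer than 2 replicates in either condition the subsetting is
    uninformative and the measure is skipped with a warning.
    """
    if ax.n_a < 2 or ax.n_b < 2:
        logger.warning(
            "inter-replicate reproducibility skipped: needs >=2 replicates "
            "per condition (have %d vs %d)",
            ax.n_a,
            ax.n_b,
        )
        return None, None, 0
    gene_pos = np.zeros(ax.gene_ids.size, dtype=np.int64)
    tx_pos = np.zeros(ax.transcript_ids.size, dtype=np.int64)
    n_pairs = 0
    for i in range(ax.n_a):
        for j in range(ax.n_b):
            res = provisional_run(
                ax,
                ax.counts_a[:, i],
                ax.counts_b[:, j],
                1,
                1,
                config.abundance_threshold,
                config.alpha,
                config.dprop_threshold,
            )
            gene_pos += res.gene_call
            tx_pos += res.tx_call
            n_pairs += 1
    return gene_pos / n_pairs, tx_pos / n_pairs, n_pairs


def compute_scores(ax: AlignedExperiment, config: RunConfig) -> ReproducibilityScores:
    """Both reproducibility measures at the configured settings."""
    gene_q, tx_q, n_draws = quant_reproducibility(ax, config)
    gene_r, tx_r, n_pairs = replicate_reproducibility(ax, config)
    return ReproducibilityScores(
        gene_qrep=gene_q,
        tx_qrep=tx_q,
        gene_rrep=gene_r,
        tx_rrep=tx_r,
        n_quant_draws=n_draws,
        n_replicate_subsets=n_pairs,
    )


def apply_reproducibility_filters(
    provisional_call: np.ndarray,
    rejection_cause: np.ndarray,
    qrep: np.ndarray | None,
    rrep: np.ndarray | None,
    qrep_threshold: float,
    rrep_threshold: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Demote provisional positives whose reproducibility is too low.

    A positive stays positive only if each available fraction strictly
    exceeds its threshold; the first failing measure (quantification before
    inter-replicate) becomes the rejection cause.  Returns (final_call,
    rejection_cause) without mutating the inputs.
    """
    call = np.asarray(provisional_call, dtype=bool).copy()
    cause = np.asarray(rejection_cause, dtype=object).copy()
    if qrep is not None:
        fail = call & ~(qrep > qrep_threshold)
        call[fail] = False
        cause[fail] = "low_quant_reproducibility"
    if rrep is not None:
        fail = call & ~(rrep > rrep_threshold)
        call[fail] = False
        cause[fail] = "low_replicate_reproducibility"
    return call, cause
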