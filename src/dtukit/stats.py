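"""The statistical core: G-tests of independence, BH correction, proportion
effect sizes and the significance-plus-effect classification.

Both DTU tests run on replicate-summed counts.  The gene-level test asks
whether a gene's isoform abundance ratios differ between conditions (an
isoforms x 2 contingency table); the transcript-level test compares each
transcript against the pooled abundance of its sibling isoforms (a 2 x 2
table).  G = 2 * sum O*ln(O/E) with expected counts from the table marginals,
no continuity correction, and a chi-squared null with
(rows-1)*(cols-1) degrees of freedom after dropping all-zero rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats as sps

REJECTION_CAUSES = (
    "none",
    "ineligible",
    "not_significant",
    "small_effect",
    "low_quant_reproducibility",
    "low_replicate_reproducibility",
)


class DegenerateTableError(ValueError):
    """Raised when a contingency table has fewer than two informative rows."""


def g_test(observed) -> tuple[float, int, float]:
    """G-test of independence on a rows x 2 table of non-negative counts.

    Cells may be real-valued (counts scaled from TPM stay fractional).
    Zero cells contribute 0 to G; rows whose total is 0 are dropped before
    the degrees of freedom are computed.

    Returns (G, df, p); raises :class:`DegenerateTableError` if fewer than
    two nonzero rows remain.
    """
    table = np.asarray(observed, dtype=float)
    if table.ndim != 2 or table.shape[1] != 2:
        raise ValueError(f"expected a k x 2 table, got shape {table.shape}")
    if np.any(table < 0):
        raise ValueError("negative counts in contingency table")
    table = table[table.sum(axis=1) > 0]
    if table.shape[0] < 2:
        raise DegenerateTableError(
            "degenerate table: fewer than 2 rows with nonzero totals"
        )
    col_tot = table.sum(axis=0)
    if np.any(col_tot <= 0):
        raise DegenerateTableError("degenerate table: a condition column sums to 0")
    row_tot = table.sum(axis=1)
    total = row_tot.sum()
    expected = np.outer(row_tot, col_tot) / total
    g = 2.0 * special.rel_entr(table, expected).sum()
    g = max(float(g), 0.0)  # clip tiny negative rounding residue
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    p = float(sps.chi2.sf(g, df))
    return g, df, p


def gene_level_test(gene_counts) -> tuple[float, int, float]:
    """G-test on a gene's isoforms x 2 table of replicate-summed counts."""
    return g_test(gene_counts)


def transcript_level_test(
    target: tuple[float, float], siblings: tuple[float, float]
) -> tuple[float, int, float]:
    """G-test of one transcript against its pooled sibling isoforms.

    ``target`` and ``siblings`` are (condition A, condition B) summed counts.
    For a 2-isoform gene this table equals the gene-level table up to row
    order, so the two tests coincide.
    """
    return g_test([list(target), list(siblings)])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p))):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return sps.false_discovery_control(p, method="bh")


def isoform_proportions(gene_counts) -> np.ndarray:
    """Per-isoform proportions and their change, from an isoforms x 2 table.

    Returns an array of rows (prop_a, prop_b, dprop) with dprop = prop_b -
    prop_a; proportions in each condition sum to 1.
    """
    table = np.asarray(gene_counts, dtype=float)
    col_tot = table.sum(axis=0)
    if np.any(col_tot <= 0):
        raise DegenerateTableError("gene has zero total expression in a condition")
    props = table / col_tot
    return np.column_stack([props[:, 0], props[:, 1], props[:, 1] - props[:, 0]])


def gene_effect_size(dprops) -> float:
    """A gene's effect size: the largest |dprop| among its isoforms."""
    dprops = np.asarray(dprops, dtype=float)
    return float(np.max(np.abs(dprops))) if dprops.size else 0.0


@dataclass
class Classification:
    dtu_call: np.ndarray  # boolean
    rejection_cause: np.ndarray  # str


def classify(
    tested: np.ndarray,
    p_adjusted: np.ndarray,
    effect: np.ndarray,
    alpha: float,
    dprop_threshold: float,
) -> Classification:
    """Provisional DTU calls: significant (BH-adjusted p < alpha) AND large
    enough effect (|dprop| >= threshold).

    The rejection cause records the first failed criterion, in the order
    ineligible -> not_significant -> small_effect.  Reproducibility causes
    are appended later by the reproducibility filters.
    """
    tested = np.asarray(tested, dtype=bool)
    p_adjusted = np.asarray(p_adjusted, dtype=float)
    effect = np.asarray(effect, dtype=float)
    significant = tested & (p_adjusted < alpha)
    big_enough = np.abs(effect) >= dprop_threshold
    call = significant & big_enough
    cause = np.full(tested.shape, "none", dtype=object)
    cause[~tested] = "ineligible"
    cause[tested & ~significant] = "not_significant"
    cause[significant & ~big_enough] = "small_effect"
    return Classification(dtu_call=call, rejection_cause=cause)


def find_switches(
    gene_ids,
    transcript_ids,
    prop_a,
    prop_b,
) -> list[tuple[str, str, str, bool]]:
    """Genes whose most abundant isoform differs between conditions.

    Inputs are parallel per-transcript arrays.  Returns (gene_id,
    dominant_in_a, dominant_in_b, tie) rows; ties on proportion are broken
    by lexicographic transcript ID and flagged.
    """
    gene_ids = np.asarray(gene_ids, dtype=object)
    transcript_ids = np.asarray(transcript_ids, dtype=object)
    prop_a = np.asarray(prop_a, dtype=float)
    prop_b = np.asarray(prop_b, dtype=float)
    switches = []
    for gene in sorted(set(gene_ids)):
        mask = gene_ids == gene
        txs, pa, pb = transcript_ids[mask], prop_a[mask], prop_b[mask]
        if np.any(np.isnan(pa)) or np.any(np.isnan(pb)):
            continue

        def dominant(props):
            top = np.max(props)
            winners = sorted(txs[props == top])
            return winners[0], len(winners) > 1

        dom_a, tie_a = dominant(pa)
        dom_b, tie_b = dominant(pb)
        if dom_a != dom_b:
            switches.append((gene, dom_a, dom_b, tie_a or tie_b))
    return switches
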