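"""Pre-test eligibility: which transcripts and genes enter statistical testing.

Isoform-ratio changes are only defined for genes expressed in both
conditions with at least two detected isoforms; transcripts below the
abundance threshold count as not detected.  Detection applies to the mean
abundance across a condition's replicates, so it is invariant to the
replication level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import AlignedExperiment, ExperimentData, align

REASONS = (
    "ok",
    "unannotated",
    "absent_in_a_condition",
    "single_isoform",
    "below_abundance_threshold",
)


@dataclass(frozen=True)
class EligibilityRecord:
    feature_id: str
    level: str  # "gene" | "transcript"
    eligible: bool
    reason: str

    def __post_init__(self):
        assert self.eligible == (self.reason == "ok")


def detect_transcripts(
    data: ExperimentData | AlignedExperiment, abundance_threshold: float
) -> dict[str, tuple[bool, bool]]:
    """Per-transcript detection flags (condition A, condition B).

    A transcript is detected in a condition iff its mean count across that
    condition's replicates is >= the threshold; at threshold 0 every
    transcript is detected everywhere.
    """
    ax = data if isinstance(data, AlignedExperiment) else align(data)
    mean_a = ax.counts_a.mean(axis=1)
    mean_b = ax.counts_b.mean(axis=1)
    det_a = mean_a >= abundance_threshold
    det_b = mean_b >= abundance_threshold
    return {
        t: (bool(a), bool(b))
        for t, a, b in zip(ax.transcript_ids, det_a, det_b)
    }


def eligible_features(
    data: ExperimentData | AlignedExperiment,
    detection: dict[str, tuple[bool, bool]],
    unannotated: list[str] | None = None,
) -> list[EligibilityRecord]:
    """One record per feature, with the first failing reason in the fixed
    order unannotated -> absent_in_a_condition -> single_isoform ->
    below_abundance_threshold.

    A gene is eligible iff >=2 of its isoforms are detected in at least one
    condition and its summed expression is nonzero in both conditions; a
    transcript is eligible iff its gene is and it is detected somewhere.
    """
    ax = data if isinstance(data, AlignedExperiment) else align(data)
    records: list[EligibilityRecord] = []
    for tx in unannotated or []:
        records.append(EligibilityRecord(tx, "transcript", False, "unannotated"))

    det_a = np.array([detection[t][0] for t in ax.transcript_ids])
    det_b = np.array([detection[t][1] for t in ax.transcript_ids])
    det_any = det_a | det_b
    n_detected = np.add.reduceat(det_any.astype(int), ax.gene_starts)
    tot_a = np.add.reduceat(ax.counts_a.sum(axis=1), ax.gene_starts)
    tot_b = np.add.reduceat(ax.counts_b.sum(axis=1), ax.gene_starts)

    gene_reason: dict[str, str] = {}
    for g, nd, ta, tb, size in zip(
        ax.gene_ids, n_detected, tot_a, tot_b, ax.gene_sizes
    ):
        if ta <= 0 or tb <= 0:
            reason = "absent_in_a_condition"
        elif size < 2 or nd < 2:
            reason = "single_isoform" if size < 2 else "below_abundance_threshold"
        else:
            reason = "ok"
        gene_reason[g] = reason
        records.append(EligibilityRecord(g, "gene", reason == "ok", reason))

    for tx, gene, da, db in zip(ax.transcript_ids, ax.tx_gene_ids, det_a, det_b):
        greason = gene_reason[gene]
        if greason != "ok":
            reason = greason
        elif not (da or db):
            reason = "below_abundance_threshold"
        else:
            reason = "ok"
        records.append(EligibilityRecord(tx, "transcript", reason == "ok", reason))
    return records


def eligibility_frame(records: list[EligibilityRecord]) -> pd.DataFrame:
    """Exportable eligibility table (feature_id, level, eligible, reason)."""
    return pd.DataFrame(
        [(r.feature_id, r.level, r.eligible, r.reason) for r in records],
        columns=["feature_id", "level", "eligible", "reason"],
    )
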