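"""End-to-end orchestration: load inputs, call DTU, report with provenance.

``call_dtu`` is the library entry point (ExperimentData + RunConfig in,
result tables out); ``run_dtu`` wraps it with file I/O for the CLI, writing
gene/transcript result TSVs, the eligibility table, the isoform-switch list,
a summary and a machine-readable provenance record.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .engine import ProvisionalResult, point_run
from .filters import eligibility_frame, eligible_features
from .io import read_annotation_gtf, read_annotation_tsv, read_sample
from .model import AlignedExperiment, DataError, ExperimentData, align
from .reproducibility import (
    ReproducibilityScores,
    apply_reproducibility_filters,
    compute_scores,
)
from .simulate import TruthSet, score_against_truth
from .stats import classify, find_switches

logger = logging.getLogger(__name__)


@dataclass
class DtuResult:
    """Everything one run produces."""

    gene_table: pd.DataFrame
    transcript_table: pd.DataFrame
    eligibility: pd.DataFrame
    switches: pd.DataFrame
    summary: dict
    provenance: dict


def _cause_tally(causes) -> dict[str, int]:
    vals, counts = np.unique(np.asarray(causes, dtype=str), return_counts=True)
    return {str(v): int(c) for v, c in zip(vals, counts)}


def call_dtu(
    data: ExperimentData | AlignedExperiment,
    config: RunConfig,
    with_reproducibility: bool = True,
) -> DtuResult:
    """Run the full DTU pipeline on in-memory data.

    Stages: eligibility filtering, gene- and transcript-level G-tests on
    replicate-summed counts, per-level BH correction, effect-size
    classification, then (optionally) the quantification- and
    inter-replicate-reproducibility filters.
    """
    ax = data if isinstance(data, AlignedExperiment) else align(data)
    logger.info(
        "stage=align transcripts=%d genes=%d dropped_unannotated=%d",
        ax.transcript_ids.size,
        ax.gene_ids.size,
        ax.n_unannotated,
    )
    prov: ProvisionalResult = point_run(
        ax, config.abundance_threshold, config.alpha, config.dprop_threshold
    )
    if with_reproducibility:
        scores = compute_scores(ax, config)
    else:
        scores = ReproducibilityScores(None, None, None, None, 0, 0)

    gene_cls = classify(
        prov.gene_tested, prov.gene_padj, prov.gene_effect, config.alpha, config.dprop_threshold
    )
    tx_cls = classify(
        prov.tx_tested, prov.tx_padj, prov.dprop, config.alpha, config.dprop_threshold
    )
    gene_call, gene_cause = apply_reproducibility_filters(
        gene_cls.dtu_call,
        gene_cls.rejection_cause,
        scores.gene_qrep,
        scores.gene_rrep,
        config.qrep_threshold,
        config.rrep_threshold,
    )
    tx_call, tx_cause = apply_reproducibility_filters(
        tx_cls.dtu_call,
        tx_cls.rejection_cause,
        scores.tx_qrep,
        scores.tx_rrep,
        config.qrep_threshold,
        config.rrep_threshold,
    )

    gene_table = pd.DataFrame(
        {
            "gene_id": ax.gene_ids,
            "n_isoforms": ax.gene_sizes,
            "eligible": prov.gene_eligible,
            "tested": prov.gene_tested,
            "g_statistic": prov.gene_g,
            "df": prov.gene_df,
            "p_value": prov.gene_p,
            "p_adjusted": prov.gene_padj,
            "effect_size": prov.gene_effect,
            "quant_rep_fraction": scores.gene_qrep
            if scores.gene_qrep is not None
            else np.nan,
            "replicate_rep_fraction": scores.gene_rrep
            if scores.gene_rrep is not None
            else np.nan,
            "dtu_call": gene_call,
            "rejection_cause": gene_cause.astype(str),
        }
    )
    transcript_table = pd.DataFrame(
        {
            "transcript_id": ax.transcript_ids,
            "gene_id": ax.tx_gene_ids,
            "detected_a": prov.tx_detect_a,
            "detected_b": prov.tx_detect_b,
            "eligible": prov.tx_eligible,
            "tested": prov.tx_tested,
            "g_statistic": prov.tx_g,
            "df": prov.tx_df,
            "p_value": prov.tx_p,
            "p_adjusted": prov.tx_padj,
            "prop_a": prov.prop_a,
            "prop_b": prov.prop_b,
            "dprop": prov.dprop,
            "quant_rep_fraction": scores.tx_qrep
            if scores.tx_qrep is not None
            else np.nan,
            "replicate_rep_fraction": scores.tx_rrep
            if scores.tx_rrep is not None
            else np.nan,
            "dtu_call": tx_call,
            "rejection_cause": tx_cause.astype(str),
        }
    )

    detection = {
        t: (bool(a), bool(b))
        for t, a, b in zip(ax.transcript_ids, prov.tx_detect_a, prov.tx_detect_b)
    }
    eligibility = eligibility_frame(eligible_features(ax, detection))

    eligible_gene_mask = prov.gene_eligible
    switch_rows = find_switches(
        ax.tx_gene_ids[ax.repeat_gene(eligible_gene_mask)],
        ax.transcript_ids[ax.repeat_gene(eligible_gene_mask)],
        prov.prop_a[ax.repeat_gene(eligible_gene_mask)],
        prov.prop_b[ax.repeat_gene(eligible_gene_mask)],
    )
    switches = pd.DataFrame(
        switch_rows, columns=["gene_id", "dominant_a", "dominant_b", "tie"]
    )

    summary = {
        "genes_total": int(ax.gene_ids.size),
        "genes_tested": int(prov.gene_tested.sum()),
        "genes_called_dtu": int(gene_call.sum()),
        "gene_rejection_causes": _cause_tally(gene_cause),
        "transcripts_total": int(ax.transcript_ids.size),
        "transcripts_tested": int(prov.tx_tested.sum()),
        "transcripts_called_dtu": int(tx_call.sum()),
        "transcript_rejection_causes": _cause_tally(tx_cause),
        "isoform_switches": int(len(switches)),
        "transcripts_dropped_unannotated": int(ax.n_unannotated),
        "quant_reproducibility_draws": scores.n_quant_draws,
        "replicate_reproducibility_subsets": scores.n_replicate_subsets,
    }
    logger.info(
        "stage=call genes_tested=%d genes_called=%d tx_tested=%d tx_called=%d",
        summary["genes_tested"],
        summary["genes_called_dtu"],
        summary["transcripts_tested"],
        summary["transcripts_called_dtu"],
    )
    provenance = {
        "package_version": __version__,
        "config": config.to_dict(),
        "n_replicates": [ax.n_a, ax.n_b],
        "sample_ids": {"condition_a": ax.sample_ids_a, "condition_b": ax.sample_ids_b},
        "transcripts_dropped_unannotated": int(ax.n_unannotated),
    }
    return DtuResult(
        gene_table=gene_table,
        transcript_table=transcript_table,
        eligibility=eligibility,
        switches=switches,
        summary=summary,
        provenance=provenance,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_experiment(config: RunConfig) -> ExperimentData:
    """Read the samples and annotation a RunConfig points at."""
    if config.annotation:
        annotation = read_annotation_tsv(config.annotation)
    elif config.gtf:
        annotation = read_annotation_gtf(config.gtf)
    else:
        raise DataError("config must provide an annotation TSV or a GTF")
    reps_a = [read_sample(p) for p in config.samples_a]
    reps_b = [read_sample(p) for p in config.samples_b]
    library_sizes = {
        r.sample_id: max(int(r.abundance.sum()), 1) for r in reps_a + reps_b
    }
    return ExperimentData(
        condition_a=reps_a,
        condition_b=reps_b,
        annotation=annotation,
        library_sizes=library_sizes,
    )


def run_dtu(config: RunConfig) -> DtuResult:
    """File-level run: read inputs, call DTU, write the output bundle."""
    data = load_experiment(config)
    result = call_dtu(data, config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    float_fmt = "%.10g"
    result.gene_table.to_csv(out / "genes.tsv", sep="\t", index=False, float_format=float_fmt)
    result.transcript_table.to_csv(
        out / "transcripts.tsv", sep="\t", index=False, float_format=float_fmt
    )
    result.eligibility.to_csv(out / "eligibility.tsv", sep="\t", index=False)
    result.switches.to_csv(out / "switches.tsv", sep="\t", index=False)
    checksums = {}
    for p in [*config.samples_a, *config.samples_b, config.annotation, config.gtf]:
        if p is None:
            continue
        p = Path(p)
        target = p / "quant.sf" if p.is_dir() else p
        if target.exists():
            checksums[str(p)] = _sha256(target)
    result.provenance["input_checksums"] = checksums
    (out / "provenance.json").write_text(
        json.dumps(result.provenance, indent=2, sort_keys=True) + "\n"
    )
    lines = [f"{k}: {json.dumps(v)}" for k, v in result.summary.items()]
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return result


DPROP_SWEEP = (0.05, 0.1, 0.2)
QREP_SWEEP = (0.8, 0.85, 0.9, 0.95)
RREP_SWEEP = (0.55, 0.65, 0.75, 0.85)


def run_benchmark(
    data: ExperimentData | AlignedExperiment,
    config: RunConfig,
    truth: TruthSet,
    dprop_sweep=DPROP_SWEEP,
    qrep_sweep=QREP_SWEEP,
    rrep_sweep=RREP_SWEEP,
    with_reproducibility: bool = True,
) -> pd.DataFrame:
    """Sensitivity/FDR/MCC over a grid of effect-size and reproducibility
    thresholds, scored against an injected-DTU truth set (gene level).

    The pipeline is recomputed per effect-size threshold (the per-draw
    classification inside the reproducibility scores depends on it); the
    reproducibility thresholds are then applied to the fixed scores.
    """
    ax = data if isinstance(data, AlignedExperiment) else align(data)
    rows = []
    for dprop_thr in dprop_sweep:
        cfg = RunConfig(
            **{**config.to_dict(), "dprop_threshold": dprop_thr}
        )
        res = call_dtu(ax, cfg, with_reproducibility=with_reproducibility)
        gt = res.gene_table
        universe = set(gt.loc[gt["tested"], "gene_id"]) | set(truth.dtu_genes)
        have_scores = with_reproducibility and not np.all(
            np.isnan(gt["quant_rep_fraction"].to_numpy(dtype=float))
        )
        q_values = qrep_sweep if have_scores else (None,)
        r_values = rrep_sweep if have_scores else (None,)
        for q in q_values:
            for r in r_values:
                called = gt["dtu_call"].to_numpy(dtype=bool)
                if q is not None:
                    # re-apply filters at the swept thresholds
                    provisional = gt["tested"].to_numpy() & (
                        gt["p_adjusted"].to_numpy() < cfg.alpha
                    ) & (gt["effect_size"].to_numpy() >= dprop_thr)
                    qrep = gt["quant_rep_fraction"].to_numpy(dtype=float)
                    rrep = gt["replicate_rep_fraction"].to_numpy(dtype=float)
                    called = provisional & (qrep > q)
                    if not np.all(np.isnan(rrep)):
                        called &= rrep > r
                call_set = set(gt.loc[called, "gene_id"])
                s, fdr, mcc = score_against_truth(call_set, universe, truth.dtu_genes)
                rows.append(
                    {
                        "dprop_threshold": dprop_thr,
                        "qrep_threshold": q,
                        "rrep_threshold": r,
                        "n_called": len(call_set),
                        "sensitivity": s,
                        "fdr": fdr,
                        "mcc": mcc,
                    }
                )
    return pd.DataFrame(rows)
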