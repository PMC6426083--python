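"""Synthetic two-condition bootstrapped count data with known DTU truth.

The generator emulates a replicated RNA-seq experiment at the count level:
per-gene expression drawn log-normally, split across isoforms by a Dirichlet,
per-replicate counts drawn negative-binomially, and quantification
uncertainty emulated by multinomial resampling of each replicate's counts at
fixed library size (each bootstrap iteration preserves the replicate's
library size exactly).

DTU is injected by swapping the mean abundances of the two most abundant
isoforms of selected well-expressed multi-isoform genes in condition B — the
classic isoform-switch design.  A :class:`TruthSet` records the injected
genes, the swapped transcript pair and the injected effect size so
sensitivity/FDR/MCC can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .io import write_annotation_tsv
from .model import AnnotationMap, ExperimentData, ReplicateQuant


@dataclass
class SimulationConfig:
    """Study-design knobs for the generator.

    Defaults mirror the benchmark designs the package is validated on:
    2,000 genes with 1-6 isoforms, 3 replicates per condition, negative
    binomial dispersion 0.1 (typical bulk RNA-seq overdispersion), 100
    bootstrap iterations, and per-gene mean expression log-normal around
    ~100 counts.  ``n_dtu_genes = 0`` gives the null design (identical
    condition means).
    """

    n_genes: int = 2000
    min_isoforms: int = 1
    max_isoforms: int = 6
    n_replicates_a: int = 3
    n_replicates_b: int = 3
    mean_log: float = float(np.log(100.0))
    sd_log: float = 1.0
    dispersion: float = 0.1
    n_bootstrap: int = 100
    n_dtu_genes: int = 0
    min_injected_dprop: float = 0.0
    well_expressed_min_mean: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.min_isoforms < 1 or self.max_isoforms < self.min_isoforms:
            raise ValueError("need 1 <= min_isoforms <= max_isoforms")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_dtu_genes < 0 or self.n_bootstrap < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class TruthSet:
    """Registry of injected DTU events."""

    dtu_genes: set[str] = field(default_factory=set)
    dtu_transcripts: set[str] = field(default_factory=set)
    injected_dprop: dict[str, float] = field(default_factory=dict)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = m + dispersion * m^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if dispersion == 0:
        out[pos] = rng.poisson(mean[pos])
    else:
        size = 1.0 / dispersion
        p = size / (size + mean[pos])
        out[pos] = rng.negative_binomial(size, p)
    return out


def simulate_experiment(config: SimulationConfig) -> tuple[ExperimentData, TruthSet]:
    """Generate a two-condition bootstrapped experiment and its truth set.

    Condition B shares condition A's per-isoform means except at the
    injected genes, where the two most abundant isoforms (judged on
    condition-A means, ties broken by transcript ID) have their means
    swapped.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_iso = rng.integers(config.min_isoforms, config.max_isoforms + 1, config.n_genes)
    gene_ids = np.array([f"g{i:05d}" for i in range(config.n_genes)], dtype=object)
    gene_mean = rng.lognormal(config.mean_log, config.sd_log, config.n_genes)

    tx_ids: list[str] = []
    tx_gene: list[str] = []
    means_a = np.empty(int(n_iso.sum()))
    pos = 0
    for g, (gid, k, gm) in enumerate(zip(gene_ids, n_iso, gene_mean)):
        props = rng.dirichlet(np.ones(k))
        means_a[pos : pos + k] = gm * props
        for j in range(k):
            tx_ids.append(f"{gid}.t{j}")
            tx_gene.append(gid)
        pos += k
    tx_ids_arr = np.asarray(tx_ids, dtype=object)
    annotation = AnnotationMap(zip(tx_ids, tx_gene))
    tx_gene_arr = np.asarray(tx_gene, dtype=object)

    # candidate genes for injection: >=2 isoforms, well expressed, and a
    # swap that moves proportions by at least min_injected_dprop
    means_b = means_a.copy()
    truth = TruthSet()
    if config.n_dtu_genes > 0:
        candidates = []
        pos = 0
        for gid, k, gm in zip(gene_ids, n_iso, gene_mean):
            if k >= 2 and gm >= config.well_expressed_min_mean:
                seg = means_a[pos : pos + k]
                order = np.lexsort((tx_ids_arr[pos : pos + k], -seg))
                top, second = pos + order[0], pos + order[1]
                dprop = (means_a[top] - means_a[second]) / seg.sum()
                if dprop >= config.min_injected_dprop:
                    candidates.append((gid, top, second, dprop))
            pos += k
        if len(candidates) < config.n_dtu_genes:
            raise ValueError(
                f"only {len(candidates)} genes qualify for injection; "
                f"{config.n_dtu_genes} requested"
            )
        chosen = rng.choice(len(candidates), size=config.n_dtu_genes, replace=False)
        for ci in chosen:
            gid, top, second, dprop = candidates[ci]
            means_b[top], means_b[second] = means_b[second], means_b[top]
            truth.dtu_genes.add(gid)
            truth.dtu_transcripts.update((tx_ids[top], tx_ids[second]))
            truth.injected_dprop[gid] = float(dprop)

    def make_condition(prefix: str, n_reps: int, means: np.ndarray) -> list[ReplicateQuant]:
        reps = []
        for r in range(n_reps):
            counts = _nb_draw(rng, means, config.dispersion).astype(float)
            bootstrap = None
            if config.n_bootstrap > 0:
                lib = int(counts.sum())
                if lib > 0:
                    draws = rng.multinomial(lib, counts / lib, size=config.n_bootstrap)
                    bootstrap = draws.T.astype(float)
                else:
                    bootstrap = np.zeros((counts.size, config.n_bootstrap))
            reps.append(
                ReplicateQuant(
                    sample_id=f"{prefix}{r + 1}",
                    transcript_ids=tx_ids_arr.copy(),
                    abundance=counts,
                    bootstrap=bootstrap,
                )
            )
        return reps

    data = ExperimentData(
        condition_a=make_condition("A", config.n_replicates_a, means_a),
        condition_b=make_condition("B", config.n_replicates_b, means_b),
        annotation=annotation,
        library_sizes={},
    )
    data.library_sizes = {
        rep.sample_id: max(int(rep.abundance.sum()), 1) for rep in data.replicates
    }
    # stash for writers / inspection (not part of the formal data model)
    data.tx_gene_ids = tx_gene_arr
    data.means_a = means_a
    data.means_b = means_b
    return data, truth


def null_split(
    pool: list[ReplicateQuant],
    group_size: int,
    rng_seed: int,
    annotation: AnnotationMap,
) -> ExperimentData:
    """Split a single-condition replicate pool into two disjoint pseudo-
    condition groups, sampled without replacement.

    Any DTU called between the groups is by construction a false positive.
    Deterministic given the seed.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    if len(pool) < 2 * group_size:
        raise ValueError(
            f"pool of {len(pool)} cannot supply two disjoint groups of {group_size}"
        )
    rng = np.random.default_rng(rng_seed)
    picked = rng.choice(len(pool), size=2 * group_size, replace=False)
    return ExperimentData(
        condition_a=[pool[i] for i in picked[:group_size]],
        condition_b=[pool[i] for i in picked[group_size:]],
        annotation=annotation,
        library_sizes={
            pool[i].sample_id: max(int(pool[i].abundance.sum()), 1) for i in picked
        },
    )


def score_against_truth(
    called: set[str], universe: set[str], truth_positive: set[str]
) -> tuple[float, float, float]:
    """Sensitivity, FDR and Matthews correlation of a call set.

    ``universe`` is every feature a call could have been made on;
    sensitivity = TP/(TP+FN), FDR = FP/(TP+FP) (0 when nothing is called),
    MCC from the 2x2 confusion counts (0 when undefined).
    """
    called = set(called) & set(universe)
    truth_positive = set(truth_positive) & set(universe)
    tp = len(called & truth_positive)
    fp = len(called - truth_positive)
    fn = len(truth_positive - called)
    tn = len(universe) - tp - fp - fn
    sensitivity = tp / (tp + fn) if (tp + fn) else 0.0
    fdr = fp / (tp + fp) if (tp + fp) else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return float(sensitivity), float(fdr), float(mcc)


# ---------------------------------------------------------------------------
# writers emitting the dialects the readers accept, for end-to-end testing
# ---------------------------------------------------------------------------


def write_salmon_dir(
    rep: ReplicateQuant, out_dir: str | Path, effective_length: float = 1000.0
) -> Path:
    """Write one sample as a Salmon-style directory: ``quant.sf`` plus a
    ``bootstraps.tsv`` matrix when bootstraps are present."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts = rep.abundance
    per_len = counts / effective_length
    denom = per_len.sum()
    tpm = per_len / denom * 1e6 if denom > 0 else np.zeros_like(counts)
    with open(out_dir / "quant.sf", "w") as fh:
        fh.write("Name\tLength\tEffectiveLength\tTPM\tNumReads\n")
        for t, tp, c in zip(rep.transcript_ids, tpm, counts):
            fh.write(
                f"{t}\t{int(effective_length) + 200}\t{effective_length:.3f}"
                f"\t{tp:.9g}\t{c:.9g}\n"
            )
    if rep.bootstrap is not None:
        with open(out_dir / "bootstraps.tsv", "w") as fh:
            header = "\t".join(
                ["transcript_id"] + [f"bs{i}" for i in range(rep.bootstrap.shape[1])]
            )
            fh.write(header + "\n")
            for t, row in zip(rep.transcript_ids, rep.bootstrap):
                fh.write(t + "\t" + "\t".join(f"{v:.9g}" for v in row) + "\n")
    return out_dir


def write_kallisto_h5(rep: ReplicateQuant, path: str | Path) -> Path:
    """Write one sample in the Kallisto ``abundance.h5`` layout."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("est_counts", data=rep.abundance)
        h5.create_dataset(
            "aux/ids", data=np.array([t.encode() for t in rep.transcript_ids])
        )
        if rep.bootstrap is not None:
            for i in range(rep.bootstrap.shape[1]):
                h5.create_dataset(f"bootstrap/bs{i}", data=rep.bootstrap[:, i])
    return path


def write_experiment(
    data: ExperimentData, out_dir: str | Path, truth: TruthSet | None = None
) -> Path:
    """Write a whole experiment in the Salmon dialect plus annotation (and
    truth registry, if given) under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for cond, reps in (("A", data.condition_a), ("B", data.condition_b)):
        for rep in reps:
            write_salmon_dir(rep, out_dir / cond / rep.sample_id)
    write_annotation_tsv(data.annotation, out_dir / "annotation.tsv")
    if truth is not None:
        write_truth_tsv(truth, out_dir / "truth.tsv")
    return out_dir


def write_truth_tsv(truth: TruthSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tinjected_dprop\n")
        for g in sorted(truth.dtu_genes):
            fh.write(f"{g}\t{truth.injected_dprop.get(g, float('nan')):.6g}\n")


def read_truth_tsv(path: str | Path) -> TruthSet:
    truth = TruthSet()
    with open(path) as fh:
        next(fh)
        for line in fh:
            gene, dprop = line.rstrip("\n").split("\t")
            truth.dtu_genes.add(gene)
            truth.injected_dprop[gene] = float(dprop)
    return truth
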