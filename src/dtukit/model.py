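"""Shared data model: annotation, per-replicate quantifications, experiments.

Differential transcript usage (DTU) compares the *relative* abundances of a
gene's isoforms between two conditions.  The containers here hold everything
the caller needs: a transcript-to-gene map, per-replicate abundance vectors
(optionally with bootstrap iterations capturing read-assignment uncertainty),
and the two-condition experiment layout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

COUNTS = "counts"
TPM = "TPM"


class AnnotationError(ValueError):
    """Raised for malformed or self-contradictory annotation input."""


class DataError(ValueError):
    """Raised for malformed or inconsistent quantification input."""


class AnnotationMap:
    """A transcript-to-gene correspondence.

    Each transcript maps to exactly one gene; identifiers are compared as
    exact strings (no version-suffix stripping — silent ID munging is a known
    source of annotation-mismatch failures).
    """

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        mapping: dict[str, str] = {}
        for tx, gene in pairs:
            if not tx or not gene:
                raise AnnotationError(
                    f"empty identifier in annotation entry ({tx!r}, {gene!r})"
                )
            prev = mapping.get(tx)
            if prev is not None and prev != gene:
                raise AnnotationError(
                    f"conflicting gene for {tx}: {prev!r} vs {gene!r}"
                )
            mapping[tx] = gene
        self._map = mapping

    def gene_of(self, transcript_id: str) -> str:
        return self._map[transcript_id]

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._map

    def __len__(self) -> int:
        return len(self._map)

    def __eq__(self, other) -> bool:
        return isinstance(other, AnnotationMap) and self._map == other._map

    @property
    def transcripts(self) -> list[str]:
        return sorted(self._map)

    @property
    def genes(self) -> list[str]:
        return sorted(set(self._map.values()))

    def items(self):
        return self._map.items()

    def isoforms_of(self) -> dict[str, list[str]]:
        """Gene -> sorted list of its annotated transcript IDs."""
        out: dict[str, list[str]] = {}
        for tx, gene in self._map.items():
            out.setdefault(gene, []).append(tx)
        for txs in out.values():
            txs.sort()
        return out


@dataclass
class ReplicateQuant:
    """One sample's transcript abundances, optionally with bootstrap iterations.

    ``bootstrap`` is a transcripts x iterations matrix of re-quantified
    abundances (inferential replicates) aligned to ``transcript_ids``.
    """

    sample_id: str
    transcript_ids: np.ndarray  # shape (T,), dtype str/object
    abundance: np.ndarray  # shape (T,), non-negative
    bootstrap: np.ndarray | None = None  # shape (T, B)
    unit: str = COUNTS
    tpm: np.ndarray | None = None  # alternative view when reading Salmon output

    def __post_init__(self):
        self.transcript_ids = np.asarray(self.transcript_ids, dtype=object)
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.transcript_ids.shape != self.abundance.shape:
            raise DataError(
                f"{self.sample_id}: abundance length {self.abundance.size} "
                f"!= transcript count {self.transcript_ids.size}"
            )
        if np.any(self.abundance < 0):
            raise DataError(f"{self.sample_id}: negative abundances")
        if self.bootstrap is not None:
            self.bootstrap = np.asarray(self.bootstrap, dtype=float)
            if self.bootstrap.shape[0] != self.transcript_ids.size:
                raise DataError(
                    f"{self.sample_id}: bootstrap matrix has "
                    f"{self.bootstrap.shape[0]} rows for "
                    f"{self.transcript_ids.size} transcripts"
                )
            if np.any(self.bootstrap < 0):
                raise DataError(f"{self.sample_id}: negative bootstrap values")
        if self.unit not in (COUNTS, TPM):
            raise DataError(f"unknown abundance unit {self.unit!r}")

    @property
    def n_bootstrap(self) -> int:
        return 0 if self.bootstrap is None else self.bootstrap.shape[1]

    def reorder(self, transcript_ids: np.ndarray) -> "ReplicateQuant":
        """Return a copy aligned to the given transcript order (a permutation
        or subset of this replicate's transcripts)."""
        index = {t: i for i, t in enumerate(self.transcript_ids)}
        try:
            idx = np.array([index[t] for t in transcript_ids], dtype=int)
        except KeyError as exc:
            raise DataError(
                f"{self.sample_id}: transcript {exc.args[0]!r} absent"
            ) from None
        return ReplicateQuant(
            sample_id=self.sample_id,
            transcript_ids=np.asarray(transcript_ids, dtype=object),
            abundance=self.abundance[idx],
            bootstrap=None if self.bootstrap is None else self.bootstrap[idx],
            unit=self.unit,
            tpm=None if self.tpm is None else self.tpm[idx],
        )


@dataclass
class ExperimentData:
    """A two-condition replicated experiment plus its annotation."""

    condition_a: list[ReplicateQuant]
    condition_b: list[ReplicateQuant]
    annotation: AnnotationMap
    library_sizes: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.condition_a or not self.condition_b:
            raise DataError("each condition needs at least one replicate")
        universe = frozenset(self.condition_a[0].transcript_ids)
        for rep in [*self.condition_a, *self.condition_b]:
            if frozenset(rep.transcript_ids) != universe:
                raise DataError(
                    f"replicate {rep.sample_id} has a different transcript "
                    "universe from the others"
                )
        for sid, size in self.library_sizes.items():
            if size <= 0:
                raise DataError(f"library size for {sid} must be positive")

    @property
    def replicates(self) -> list[ReplicateQuant]:
        return [*self.condition_a, *self.condition_b]

    @property
    def transcript_universe(self) -> list[str]:
        return sorted(self.condition_a[0].transcript_ids)


@dataclass
class AlignedExperiment:
    """Experiment matrices aligned to one transcript order, grouped by gene.

    Transcripts are sorted by (gene_id, transcript_id) so per-gene reductions
    are contiguous segments (``gene_starts`` are reduceat offsets).
    Transcripts absent from the annotation are dropped (count recorded).
    """

    transcript_ids: np.ndarray  # (T,)
    tx_gene_ids: np.ndarray  # (T,) gene of each transcript
    gene_ids: np.ndarray  # (G,) unique genes, sorted
    gene_starts: np.ndarray  # (G,) segment offsets into transcript arrays
    gene_sizes: np.ndarray  # (G,) isoforms per gene
    counts_a: np.ndarray  # (T, n_a)
    counts_b: np.ndarray  # (T, n_b)
    boot_a: list[np.ndarray] | None  # per replicate (T, B)
    boot_b: list[np.ndarray] | None
    sample_ids_a: list[str]
    sample_ids_b: list[str]
    n_unannotated: int = 0

    @property
    def n_a(self) -> int:
        return self.counts_a.shape[1]

    @property
    def n_b(self) -> int:
        return self.counts_b.shape[1]

    @property
    def has_bootstrap(self) -> bool:
        return self.boot_a is not None and self.boot_b is not None

    def repeat_gene(self, values: np.ndarray) -> np.ndarray:
        """Broadcast a per-gene vector onto transcripts."""
        return np.repeat(values, self.gene_sizes)


def align(data: ExperimentData) -> AlignedExperiment:
    """Build the aligned, gene-sorted matrix view of an experiment.

    Requires count-unit abundances (scale TPM first) and a shared transcript
    universe; unannotated transcripts are dropped with a logged count.
    """
    for rep in data.replicates:
        if rep.unit != COUNTS:
            raise DataError(
                f"replicate {rep.sample_id} is in {rep.unit}; scale to counts "
                "before testing (see scale_tpm_to_counts)"
            )
    universe = list(data.condition_a[0].transcript_ids)
    annotated = [t for t in universe if t in data.annotation]
    n_unannotated = len(universe) - len(annotated)
    if n_unannotated:
        logger.warning(
            "dropping %d/%d transcripts absent from the annotation",
            n_unannotated,
            len(universe),
        )
    if not annotated:
        raise DataError("no quantified transcript is present in the annotation")
    order = sorted(annotated, key=lambda t: (data.annotation.gene_of(t), t))
    tx_ids = np.asarray(order, dtype=object)
    tx_genes = np.asarray([data.annotation.gene_of(t) for t in order], dtype=object)
    # contiguous gene segments
    boundaries = np.flatnonzero(
        np.r_[True, tx_genes[1:] != tx_genes[:-1]]
    )
    gene_ids = tx_genes[boundaries]
    gene_sizes = np.diff(np.r_[boundaries, tx_genes.size])

    reps_a = [r.reorder(tx_ids) for r in data.condition_a]
    reps_b = [r.reorder(tx_ids) for r in data.condition_b]
    counts_a = np.column_stack([r.abundance for r in reps_a])
    counts_b = np.column_stack([r.abundance for r in reps_b])
    all_boot = all(r.bootstrap is not None for r in reps_a + reps_b)
    boot_a = [r.bootstrap for r in reps_a] if all_boot else None
    boot_b = [r.bootstrap for r in reps_b] if all_boot else None
    return AlignedExperiment(
        transcript_ids=tx_ids,
        tx_gene_ids=tx_genes,
        gene_ids=gene_ids,
        gene_starts=boundaries,
        gene_sizes=gene_sizes,
        counts_a=counts_a,
        counts_b=counts_b,
        boot_a=boot_a,
        boot_b=boot_b,
        sample_ids_a=[r.sample_id for r in reps_a],
        sample_ids_b=[r.sample_id for r in reps_b],
        n_unannotated=n_unannotated,
    )
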