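"""Readers for quantification output and annotation, plus TPM scaling.

Supported inputs: Salmon ``quant.sf`` tables (per-sample directory or file),
Kallisto ``abundance.h5`` HDF5 files (including bootstrap vectors), a generic
bootstrap TSV matrix (transcripts x iterations), and annotation as either a
two-column TSV or a GTF whose ``transcript_id``/``gene_id`` attributes are
parsed (coordinates are never interpreted).
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .model import COUNTS, TPM, AnnotationError, AnnotationMap, DataError, ReplicateQuant

logger = logging.getLogger(__name__)

SALMON_COLUMNS = ["Name", "Length", "EffectiveLength", "TPM", "NumReads"]

_TX_HEADERS = ("transcript_id", "target_id", "txname", "transcript", "tx_id")
_GENE_HEADERS = ("gene_id", "parent_id", "geneid", "gene")


def _find_column(columns: list[str], candidates: tuple[str, ...], kind: str) -> str:
    lowered = {c.lower(): c for c in columns}
    for cand in candidates:
        if cand in lowered:
            return lowered[cand]
    raise AnnotationError(
        f"no {kind} ID column found: expected one of {list(candidates)}, "
        f"got {columns}"
    )


def read_annotation_tsv(path: str | Path) -> AnnotationMap:
    """Read a transcript-to-gene map from a headered TSV.

    The transcript and gene columns are located by name (case-insensitive;
    ``transcript_id``/``target_id``/... and ``gene_id``/``parent_id``/...).
    Duplicate rows are tolerated; a transcript mapped to two different genes
    is an error naming the transcript.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise AnnotationError(
            f"{path}: annotation needs >=2 columns, found {list(df.columns)}"
        )
    tx_col = _find_column(list(df.columns), _TX_HEADERS, "transcript")
    gene_col = _find_column(list(df.columns), _GENE_HEADERS, "gene")
    df = df.dropna(subset=[tx_col, gene_col])
    return AnnotationMap(zip(df[tx_col], df[gene_col]))


def write_annotation_tsv(annotation: AnnotationMap, path: str | Path) -> None:
    """Write the two-column TSV dialect ``read_annotation_tsv`` accepts."""
    rows = sorted(annotation.items())
    with open(path, "w") as fh:
        fh.write("transcript_id\tgene_id\n")
        for tx, gene in rows:
            fh.write(f"{tx}\t{gene}\n")


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_annotation_gtf(path: str | Path) -> AnnotationMap:
    """Extract the transcript-to-gene map from GTF attributes.

    Only the attribute column is read; any feature type carrying both
    ``transcript_id`` and ``gene_id`` contributes, and features without a
    ``transcript_id`` (e.g. gene lines) are ignored.
    """
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 9 tab-separated GTF fields, "
                    f"got {len(fields)}"
                )
            attrs = dict(_ATTR_RE.findall(fields[8]))
            if not attrs:
                raise AnnotationError(
                    f"{path}:{lineno}: unparsable attribute column "
                    f"{fields[8]!r}"
                )
            tx = attrs.get("transcript_id")
            if tx is None:
                continue
            gene = attrs.get("gene_id")
            if gene is None:
                raise AnnotationError(
                    f"{path}:{lineno}: transcript_id without gene_id"
                )
            pairs.append((tx, gene))
    return AnnotationMap(pairs)


def read_bootstrap_tsv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read the generic bootstrap matrix: first column transcript ID, the
    remaining columns one quantification iteration each.

    Returns (transcript_ids, matrix of shape transcripts x iterations).
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise DataError(f"{path}: bootstrap table needs >=2 columns")
    ids = df.iloc[:, 0].astype(str).to_numpy(dtype=object)
    mat = df.iloc[:, 1:].to_numpy(dtype=float)
    if np.any(mat < 0):
        raise DataError(f"{path}: negative bootstrap values")
    return ids, mat


def read_salmon_quant(
    path: str | Path,
    bootstrap_tsv: str | Path | None = None,
    sample_id: str | None = None,
) -> ReplicateQuant:
    """Read a Salmon ``quant.sf`` (a file or its containing directory).

    Point abundances are the estimated read counts (``NumReads``); the TPM
    column is retained as an alternative view.  If ``bootstrap_tsv`` is not
    given but a ``bootstraps.tsv`` sits next to ``quant.sf``, it is used.
    """
    path = Path(path)
    if path.is_dir():
        quant_path = path / "quant.sf"
        if bootstrap_tsv is None and (path / "bootstraps.tsv").exists():
            bootstrap_tsv = path / "bootstraps.tsv"
    else:
        quant_path = path
    if not quant_path.exists():
        raise DataError(f"no quant.sf found at {path}")
    df = pd.read_csv(quant_path, sep="\t")
    missing = [c for c in SALMON_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(
            f"{quant_path}: missing columns {missing}; expected "
            f"{SALMON_COLUMNS}, found {list(df.columns)}"
        )
    ids = df["Name"].astype(str).to_numpy(dtype=object)
    counts = df["NumReads"].to_numpy(dtype=float)
    tpm = df["TPM"].to_numpy(dtype=float)
    bootstrap = None
    if bootstrap_tsv is not None:
        b_ids, bootstrap = read_bootstrap_tsv(bootstrap_tsv)
        if list(b_ids) != list(ids):
            order = {t: i for i, t in enumerate(b_ids)}
            try:
                bootstrap = bootstrap[[order[t] for t in ids]]
            except KeyError as exc:
                raise DataError(
                    f"{bootstrap_tsv}: transcript {exc.args[0]!r} missing "
                    "from bootstrap table"
                ) from None
    if sample_id is None:
        sample_id = quant_path.parent.name or str(quant_path)
    return ReplicateQuant(
        sample_id=sample_id,
        transcript_ids=ids,
        abundance=counts,
        bootstrap=bootstrap,
        unit=COUNTS,
        tpm=tpm,
    )


def read_kallisto_h5(path: str | Path, sample_id: str | None = None) -> ReplicateQuant:
    """Read a Kallisto ``abundance.h5``: estimated counts, transcript IDs and
    any bootstrap count vectors (assembled in iteration order)."""
    path = Path(path)
    with h5py.File(path, "r") as h5:
        try:
            ids = np.asarray(
                [t.decode() if isinstance(t, bytes) else str(t) for t in h5["aux/ids"][...]],
                dtype=object,
            )
            counts = np.asarray(h5["est_counts"][...], dtype=float)
        except KeyError as exc:
            raise DataError(f"{path}: missing HDF5 dataset {exc.args[0]!r}") from None
        if ids.size == 0:
            raise DataError(f"{path}: zero transcripts")
        if counts.size != ids.size:
            raise DataError(
                f"{path}: est_counts length {counts.size} != ids length {ids.size}"
            )
        bootstrap = None
        if "bootstrap" in h5:
            keys = sorted(h5["bootstrap"], key=lambda k: int(re.sub(r"\D", "", k) or 0))
            vectors = []
            for key in keys:
                vec = np.asarray(h5["bootstrap"][key][...], dtype=float)
                if vec.size != ids.size:
                    raise DataError(
                        f"{path}: bootstrap vector {key} has length {vec.size}, "
                        f"expected {ids.size}"
                    )
                vectors.append(vec)
            if vectors:
                bootstrap = np.column_stack(vectors)
    if sample_id is None:
        sample_id = path.parent.name if path.name == "abundance.h5" else path.stem
    return ReplicateQuant(
        sample_id=sample_id,
        transcript_ids=ids,
        abundance=counts,
        bootstrap=bootstrap,
        unit=COUNTS,
    )


def read_sample(path: str | Path, sample_id: str | None = None) -> ReplicateQuant:
    """Dispatch on input layout: ``.h5`` to the Kallisto reader, anything
    else to the Salmon reader."""
    p = Path(path)
    if p.suffix == ".h5":
        return read_kallisto_h5(p, sample_id=sample_id)
    if p.is_dir() and (p / "abundance.h5").exists():
        return read_kallisto_h5(p / "abundance.h5", sample_id=sample_id)
    return read_salmon_quant(p, sample_id=sample_id)


def scale_tpm_to_counts(quant: ReplicateQuant, library_size: int) -> ReplicateQuant:
    """Rescale TPM abundances to pseudo-counts at a given library size.

    Every point and bootstrap value is multiplied by ``library_size / 1e6``
    (so TPMs summing to 1e6 sum to the library size afterwards); values are
    left unrounded.  Count-based tests are under-powered on raw TPM, hence
    the scaling.
    """
    if quant.unit != TPM:
        raise DataError(f"{quant.sample_id}: abundances are already in counts")
    if library_size <= 0:
        raise DataError("library_size must be positive")
    factor = library_size / 1e6
    return ReplicateQuant(
        sample_id=quant.sample_id,
        transcript_ids=quant.transcript_ids,
        abundance=quant.abundance * factor,
        bootstrap=None if quant.bootstrap is None else quant.bootstrap * factor,
        unit=COUNTS,
        tpm=quant.abundance.copy(),
    )
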