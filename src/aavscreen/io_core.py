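"""Core domain containers and readers/writers for the standard formats.

The pipeline consumes a 10x-style MTX triplet (matrix.mtx + barcodes.tsv +
features.tsv), a variant-barcode FASTA with a pool-abundance table, a
marker-gene TSV and read-level evidence TSVs. All tabular output is
tab-delimited with a header row; gzip is handled transparently by extension.
"""

from __future__ import annotations

import gzip
import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from Bio import SeqIO

from .errors import FormatError, ReconciliationError, ValidationError

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGT")

READ_TABLE_COLUMNS = ["source", "cell_barcode", "umi", "payload"]
READ_SOURCES = ("scrna", "pcr")


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass
class CellGeneMatrix:
    """Sparse cells × genes UMI count matrix with per-cell totals.

    ``n_umi`` is the total transcriptome UMI count of each cell, the
    denominator for all per-cell expression normalization downstream.
    """

    cell_ids: list[str]
    gene_ids: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell barcodes")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene identifiers")
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise FormatError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise ValidationError("counts must be nonnegative integers")
        self.counts = sp.csr_matrix(self.counts)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_umi(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel().astype(np.int64)

    def n_umi_of(self) -> dict[str, int]:
        return dict(zip(self.cell_ids, self.n_umi.tolist()))

    def drop_empty_cells(self) -> "CellGeneMatrix":
        """Return a copy without zero-nUMI cells (logged)."""
        keep = self.n_umi > 0
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("dropping %d cells with zero total UMI", n_dropped)
        return CellGeneMatrix(
            [c for c, k in zip(self.cell_ids, keep) if k],
            list(self.gene_ids),
            self.counts[keep],
        )


@dataclass(frozen=True)
class VariantEntry:
    variant_id: str
    barcode_seq: str
    pool_fraction: float
    dilution_factor: float


@dataclass
class VariantLibrary:
    """The injected pool: variant ids, barcode tags, pool fractions.

    ``dilution_factor`` is pool_fraction x n_variants, so a perfectly
    equimolar pool has factor 1.0 for every member and dilution correction
    is then a no-op. Under-represented members get factor < 1 and their
    metrics are boosted by the correction.
    """

    entries: list[VariantEntry]

    def __post_init__(self) -> None:
        ids = [e.variant_id for e in self.entries]
        seqs = [e.barcode_seq for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate variant ids")
        if len(set(seqs)) != len(seqs):
            raise ValidationError("duplicate barcode sequences")
        for s in seqs:
            if not s or not set(s) <= DNA_ALPHABET:
                raise ValidationError(f"barcode {s!r} is not over ACGT")
        total = sum(e.pool_fraction for e in self.entries)
        if self.entries and abs(total - 1.0) > 1e-9:
            raise ValidationError(f"pool fractions sum to {total}, expected 1")
        for e in self.entries:
            if e.dilution_factor <= 0:
                raise ValidationError("dilution factors must be positive")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def variant_ids(self) -> list[str]:
        return [e.variant_id for e in self.entries]

    def barcode_of(self) -> dict[str, str]:
        return {e.variant_id: e.barcode_seq for e in self.entries}

    def dilution_of(self) -> dict[str, float]:
        return {e.variant_id: e.dilution_factor for e in self.entries}

    @property
    def barcode_length(self) -> int:
        lengths = {len(e.barcode_seq) for e in self.entries}
        if len(lengths) != 1:
            raise ValidationError("variant barcodes have mixed lengths")
        return lengths.pop()

    @classmethod
    def from_fractions(cls, fractions: Mapping[str, float],
                       barcodes: Mapping[str, str]) -> "VariantLibrary":
        n = len(fractions)
        entries = [
            VariantEntry(v, barcodes[v], f, f * n)
            for v, f in sorted(fractions.items())
        ]
        return cls(entries)

    @classmethod
    def equimolar(cls, barcodes: Mapping[str, str]) -> "VariantLibrary":
        n = len(barcodes)
        return cls.from_fractions({v: 1.0 / n for v in barcodes}, dict(barcodes))


@dataclass
class MarkerDB:
    """cell_type -> marker gene sets, plus the eligible gene universe."""

    markers: dict[str, set[str]]
    gene_universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.gene_universe:
            self.gene_universe = set().union(*self.markers.values()) if self.markers else set()
        for ct, genes in self.markers.items():
            if not genes:
                raise ValidationError(f"cell type {ct!r} has no marker genes")
            missing = genes - self.gene_universe
            if missing:
                raise ValidationError(
                    f"markers of {ct!r} absent from gene universe: {sorted(missing)[:5]}"
                )

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.markers)


# ---------------------------------------------------------------------------
# MTX triplet I/O
# ---------------------------------------------------------------------------

def read_count_matrix(matrix_path: str | Path, barcodes_path: str | Path,
                      features_path: str | Path) -> CellGeneMatrix:
    """Load a 10x-style MTX triplet into a cells × genes matrix.

    The MTX follows the 10x convention of genes (features) in rows and
    cells in columns; the returned matrix is transposed to cells × genes.
    Cells whose total UMI count is zero are dropped (logged), since every
    downstream normalization divides by the per-cell total.
    """
    with _open_text(barcodes_path) as fh:
        cell_ids = [line.strip().split("\t")[0] for line in fh if line.strip()]
    with _open_text(features_path) as fh:
        feature_rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    # two-column features (id, symbol) use the symbol; one-column files as-is
    gene_ids = [row[1] if len(row) > 1 else row[0] for row in feature_rows]

    with _open_text(matrix_path, "rb") as fh:
        try:
            mat = scipy.io.mmread(io.BytesIO(fh.read()))
        except Exception as exc:
            raise FormatError(f"cannot parse MTX file: {exc}") from exc
    n_genes, n_cells = mat.shape
    if n_genes != len(gene_ids) or n_cells != len(cell_ids):
        raise FormatError(
            f"MTX declares {n_genes} features x {n_cells} barcodes but sidecar "
            f"files list {len(gene_ids)} features and {len(cell_ids)} barcodes"
        )
    m = CellGeneMatrix(cell_ids, gene_ids, sp.csr_matrix(mat.T))
    return m.drop_empty_cells()


def write_count_matrix(m: CellGeneMatrix, matrix_path: str | Path,
                       barcodes_path: str | Path, features_path: str | Path) -> None:
    """Write the MTX triplet (genes × cells on disk, 10x convention)."""
    scipy.io.mmwrite(str(matrix_path), sp.coo_matrix(m.counts.T), field="integer")
    with _open_text(barcodes_path, "wt") as fh:
        fh.writelines(c + "\n" for c in m.cell_ids)
    with _open_text(features_path, "wt") as fh:
        fh.writelines(f"{g}\t{g}\n" for g in m.gene_ids)


# ---------------------------------------------------------------------------
# Variant library I/O
# ---------------------------------------------------------------------------

def read_variant_library(fasta_path: str | Path,
                         abundance_path: str | Path) -> VariantLibrary:
    """Read the variant-barcode FASTA plus the deep-sequencing abundance TSV.

    Emits a warning (never a failure) if any pool fraction lies more than
    10x above or below the pool mean, the ±1-log band within which
    normalization across samples is considered reliable.
    """
    barcodes: dict[str, str] = {}
    with _open_text(fasta_path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in barcodes:
                raise ValidationError(f"duplicate FASTA record {rec.id!r}")
            barcodes[rec.id] = str(rec.seq).upper()

    ab = pd.read_csv(abundance_path, sep="\t")
    if not {"variant_id", "pool_fraction"} <= set(ab.columns):
        raise FormatError("abundance table needs columns variant_id, pool_fraction")
    if ab["variant_id"].duplicated().any():
        raise ValidationError("duplicate variant ids in abundance table")
    fractions = dict(zip(ab["variant_id"].astype(str), ab["pool_fraction"].astype(float)))

    fasta_ids, table_ids = set(barcodes), set(fractions)
    if fasta_ids != table_ids:
        raise ReconciliationError(
            f"FASTA/abundance id mismatch: only-FASTA={sorted(fasta_ids - table_ids)} "
            f"only-table={sorted(table_ids - fasta_ids)}"
        )
    for v, f in fractions.items():
        if f <= 0:
            raise ValidationError(f"pool fraction of {v!r} must be > 0, got {f}")

    mean_frac = sum(fractions.values()) / len(fractions)
    for v, f in sorted(fractions.items()):
        if f > 10 * mean_frac or f < mean_frac / 10:
            logger.warning(
                "variant %s pool fraction %.4g is more than 1 log from the pool "
                "mean %.4g; dilution correction may be unreliable", v, f, mean_frac
            )
    return VariantLibrary.from_fractions(fractions, barcodes)


def write_variant_library(lib: VariantLibrary, fasta_path: str | Path,
                          abundance_path: str | Path) -> None:
    with _open_text(fasta_path, "wt") as fh:
        for e in lib:
            fh.write(f">{e.variant_id}\n{e.barcode_seq}\n")
    pd.DataFrame(
        {"variant_id": [e.variant_id for e in lib],
         "pool_fraction": [e.pool_fraction for e in lib]}
    ).to_csv(abundance_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Marker DB and read tables
# ---------------------------------------------------------------------------

def read_marker_db(path: str | Path,
                   gene_universe: Iterable[str] | None = None) -> MarkerDB:
    """Read a (cell_type, gene) TSV into a MarkerDB."""
    df = pd.read_csv(path, sep="\t")
    if not {"cell_type", "gene"} <= set(df.columns):
        raise FormatError("marker table needs columns cell_type, gene")
    markers: dict[str, set[str]] = {}
    for ct, sub in df.groupby("cell_type"):
        markers[str(ct)] = set(sub["gene"].astype(str))
    universe = set(gene_universe) if gene_universe is not None else set()
    if universe:
        return MarkerDB(markers, universe | set().union(*markers.values()))
    return MarkerDB(markers)


def validate_read_table(reads: pd.DataFrame) -> pd.DataFrame:
    """Check the (source, cell_barcode, umi, payload) schema and invariants."""
    missing = set(READ_TABLE_COLUMNS) - set(reads.columns)
    if missing:
        raise FormatError(f"read table missing columns {sorted(missing)}")
    if len(reads):
        bad = set(reads["source"].unique()) - set(READ_SOURCES)
        if bad:
            raise ValidationError(f"unknown read sources {sorted(bad)}")
        for col in ("cell_barcode", "umi"):
            if reads[col].str.len().nunique() != 1:
                raise ValidationError(f"{col} lengths vary within the table")
        if (reads["payload"].str.len() == 0).any():
            raise ValidationError("empty payloads")
    return reads


def read_read_table(path: str | Path) -> pd.DataFrame:
    reads = pd.read_csv(path, sep="\t", dtype=str)
    return validate_read_table(reads)


def write_read_table(reads: pd.DataFrame, path: str | Path) -> None:
    reads.to_csv(path, sep="\t", index=False)


def to_anndata(m: CellGeneMatrix):
    """View a CellGeneMatrix as an AnnData (shared semantics, no copy of ids)."""
    import anndata as ad

    return ad.AnnData(
        X=m.counts.astype(np.float32),
        obs=pd.DataFrame(index=pd.Index(m.cell_ids, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(m.gene_ids, name="gene")),
    )
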