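"""Barcode-capacity calculator, saturation simulator, in vitro summary.

How many distinct variants can a random barcode of length L nt distinguish,
and how many of those barcodes does a droplet experiment of a given size
actually observe? Capacity is exact (4^L); recovery is simulated: each of
``n_cells`` cells receives Poisson(moi) infecting genomes drawn uniformly
from the barcode space, and a fixed number of tagged UMIs per cell is
captured from those genomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_core import CellGeneMatrix, VariantLibrary, validate_read_table

logger = logging.getLogger(__name__)


def barcode_capacity(length: int) -> int:
    """Number of distinct DNA barcodes of the given length: 4^L, exact."""
    if length < 1:
        raise ValueError("barcode length must be >= 1")
    return 4 ** length


@dataclass
class CapacityResult:
    barcode_length: int
    theoretical_capacity: int
    n_cells: int
    moi: float
    capture_per_cell: int
    unique_recovered: int       # distinct barcodes among captured UMIs
    unique_infecting: int       # distinct barcodes among all infecting genomes
    seed: int

    def as_dict(self) -> dict:
        return asdict(self)


def simulate_saturation(length: int, n_cells: int = 8000, moi: float = 1000,
                        capture_per_cell: int = 100, seed: int = 0) -> CapacityResult:
    """Simulate barcode recovery from a uniformly random barcode library.

    Each cell draws Poisson(moi) infecting genomes uniform over the 4^L
    barcode space; ``capture_per_cell`` expressed molecules per cell are
    then sampled (with replacement) from that cell's genomes as tagged
    UMIs. ``unique_recovered`` counts distinct barcodes across all
    captured UMIs; ``unique_infecting`` counts distinct barcodes across
    all genomes regardless of capture.
    """
    if min(length, n_cells, capture_per_cell) < 1 or moi <= 0:
        raise ValueError("all parameters must be positive")
    rng = np.random.default_rng(seed)
    capacity = barcode_capacity(length)
    genomes_per_cell = rng.poisson(moi, size=n_cells)
    genomes_per_cell = np.maximum(genomes_per_cell, 1)  # every cell was infected
    total = int(genomes_per_cell.sum())
    genomes = rng.integers(0, capacity, size=total, dtype=np.int64)
    starts = np.concatenate(([0], np.cumsum(genomes_per_cell)[:-1]))
    highs = np.repeat(genomes_per_cell, capture_per_cell)
    offsets = rng.integers(0, highs)
    captured = genomes[np.repeat(starts, capture_per_cell) + offsets]
    return CapacityResult(
        barcode_length=length,
        theoretical_capacity=capacity,
        n_cells=n_cells,
        moi=float(moi),
        capture_per_cell=capture_per_cell,
        unique_recovered=int(np.unique(captured).size),
        unique_infecting=int(np.unique(genomes).size),
        seed=seed,
    )


def expected_unique(capacity: int, n_draws: int) -> float:
    """Closed-form expectation: capacity * (1 - (1 - 1/capacity)^n_draws)."""
    return capacity * -np.expm1(n_draws * np.log1p(-1.0 / capacity))


def invitro_summary(reads: pd.DataFrame, lib: VariantLibrary,
                    downsample_to: int = 300_000, seed: int = 0,
                    whitelist=None) -> dict:
    """Infectivity summary for a cultured-cell (HEK293-style) run.

    Reads are uniformly downsampled without replacement to
    ``downsample_to`` (skipped with a warning when fewer are available),
    cell barcodes are corrected, and, with no droplet QC applied, the cell
    count is the number of distinct corrected barcodes carrying at least
    one assigned tagged UMI; expression is distinct (cell, UMI) pairs per
    such cell. When no whitelist is given, barcodes seen more than once
    serve as their own whitelist (singletons are error-corrected into
    Hamming-1 neighbors or dropped).
    """
    from .aav_quant import assign_reads_to_variants, correct_cell_barcodes

    validate_read_table(reads)
    rng = np.random.default_rng(seed)
    if len(reads) > downsample_to:
        idx = rng.choice(len(reads), size=downsample_to, replace=False)
        reads = reads.iloc[np.sort(idx)].reset_index(drop=True)
    elif len(reads) < downsample_to:
        logger.warning("only %d reads available; downsampling skipped", len(reads))
    if reads.empty:
        logger.warning("no reads; empty summary")
        return {"n_cells_detected": 0, "mean_gfp_umis_per_cell": float("nan"),
                "per_variant": pd.DataFrame(columns=["variant_id", "n_cells", "n_umis"])}

    if whitelist is None:
        vc = reads["cell_barcode"].value_counts()
        whitelist = vc[vc > 1].index.tolist() or vc.index.tolist()
    corrected = correct_cell_barcodes(reads, whitelist)
    assignments, _ = assign_reads_to_variants(corrected, lib)
    if assignments.empty:
        logger.warning("no assignable reads; empty summary")
        return {"n_cells_detected": 0, "mean_gfp_umis_per_cell": float("nan"),
                "per_variant": pd.DataFrame(columns=["variant_id", "n_cells", "n_umis"])}
    pairs = assignments[["cell_barcode", "umi"]].drop_duplicates()
    n_cells = pairs["cell_barcode"].nunique()
    per_variant = (
        assignments.drop_duplicates(["cell_barcode", "umi", "variant_id"])
        .groupby("variant_id")
        .agg(n_cells=("cell_barcode", "nunique"), n_umis=("umi", "size"))
        .reset_index()
    )
    return {
        "n_cells_detected": int(n_cells),
        "mean_gfp_umis_per_cell": float(len(pairs) / n_cells),
        "per_variant": per_variant,
    }
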