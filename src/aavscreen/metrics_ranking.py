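"""Published per-(variant, cell type) metrics, co-infection sets, rankings.

Three quantities summarize a variant's performance in a sample: the number
of infected cells, the percent of cells of each type infected (dilution
corrected), and the mean tagged transcripts per 100,000 among infected
cells. Co-infection structure is summarized as exact variant-subset
intersection sizes (the upset-plot counts), and the ranking view is a
percent-infected vs expression scatter with Pareto-frontier flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .aav_quant import CellVariantCounts
from .io_core import VariantLibrary

logger = logging.getLogger(__name__)

TOTAL = "Total"
UNASSIGNED = "unassigned"

METRICS_COLUMNS = ["sample_id", "cell_type", "variant_id", "n_cells_type",
                   "n_infected", "pct_infected", "mean_tx_per_100k"]


def compute_metrics(counts: CellVariantCounts, expr: pd.DataFrame,
                    types: Mapping[str, str], lib: VariantLibrary,
                    sample_id: str = "sample") -> pd.DataFrame:
    """Per (variant, cell type) infection and expression metrics.

    ``types`` maps every cell barcode to its assigned type ("unassigned"
    allowed). A cell of a type counts as infected by a variant when it has
    at least one tagged UMI for it. pct_infected is
    n_infected / n_cells_type * 100 / dilution_factor; mean_tx_per_100k is
    the mean of the (already dilution-corrected) per-cell tagged_per_100k
    over infected cells of the type, missing (NaN) when none are.
    A "Total" row per variant covers all cells including unassigned.
    """
    dilution = lib.dilution_of()
    type_of = dict(types)
    missing = set(counts.table["cell_barcode"]) - set(type_of)
    if missing:
        logger.info("%d infected cells lack a type; counted as unassigned", len(missing))
        for cb in missing:
            type_of[cb] = UNASSIGNED

    cells_by_type: dict[str, set[str]] = {}
    for cb, t in type_of.items():
        cells_by_type.setdefault(t, set()).add(cb)
    all_cells = set(type_of)

    expr_by = {
        (cb, v): x for cb, v, x in zip(expr["cell_barcode"], expr["variant_id"],
                                       expr["tagged_per_100k"])
    }
    infected_by_variant: dict[str, set[str]] = {v: set() for v in lib.variant_ids}
    for cb, v in zip(counts.table["cell_barcode"], counts.table["variant_id"]):
        infected_by_variant.setdefault(v, set()).add(cb)

    rows = []
    type_rows = [t for t in sorted(cells_by_type) if t != UNASSIGNED] + [TOTAL]
    for v in lib.variant_ids:
        hit_cells = infected_by_variant.get(v, set())
        for t in type_rows:
            members = all_cells if t == TOTAL else cells_by_type.get(t, set())
            if not members:
                continue
            infected = hit_cells & members
            n_inf = len(infected)
            pct = n_inf / len(members) * 100.0 / dilution[v]
            vals = [expr_by[(cb, v)] for cb in infected if (cb, v) in expr_by]
            mean_tx = float(np.mean(vals)) if vals else np.nan
            rows.append((sample_id, t, v, len(members), n_inf, pct, mean_tx))
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


@dataclass
class UpsetCounts:
    """Exact variant-subset intersection sizes over infected cells."""

    intersections: dict[frozenset[str], int]
    set_sizes: dict[str, int]
    n_infected_cells: int = 0
    max_subset_size: int = 0

    def as_frame(self) -> pd.DataFrame:
        rows = [
            ("&".join(sorted(s)), len(s), n)
            for s, n in sorted(self.intersections.items(),
                               key=lambda kv: (-kv[1], "&".join(sorted(kv[0]))))
        ]
        return pd.DataFrame(rows, columns=["subset", "subset_size", "n_cells"])


def upset_intersections(counts: CellVariantCounts) -> UpsetCounts:
    """Count cells by the exact set of variants infecting them."""
    by_cell: dict[str, set[str]] = {}
    for cb, v in zip(counts.table["cell_barcode"], counts.table["variant_id"]):
        by_cell.setdefault(cb, set()).add(v)
    intersections: dict[frozenset[str], int] = {}
    set_sizes: dict[str, int] = {}
    for cb, variants in by_cell.items():
        key = frozenset(variants)
        intersections[key] = intersections.get(key, 0) + 1
        for v in variants:
            set_sizes[v] = set_sizes.get(v, 0) + 1
    return UpsetCounts(
        intersections, set_sizes,
        n_infected_cells=len(by_cell),
        max_subset_size=max((len(s) for s in intersections), default=0),
    )


def scatter_summary(metrics: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready (pct_infected, mean_tx_per_100k) table with Pareto flags.

    Within each cell type (and the Total rows) a variant is on the Pareto
    frontier when no other variant is at least as good on both axes and
    strictly better on one. Rows with no infected cells (missing mean
    expression) are never flagged.
    """
    if metrics.empty:
        raise ValidationError("empty metrics table")
    out = metrics.rename(columns={"pct_infected": "x", "mean_tx_per_100k": "y"})[
        ["sample_id", "cell_type", "variant_id", "x", "y"]
    ].copy()
    flags = []
    for _, row in out.iterrows():
        if not np.isfinite(row["y"]):
            flags.append(False)
            continue
        peers = out[(out["cell_type"] == row["cell_type"])
                    & (out["sample_id"] == row["sample_id"])
                    & (out["variant_id"] != row["variant_id"])]
        dominated = (
            (peers["x"] >= row["x"]) & (peers["y"].fillna(-np.inf) >= row["y"])
            & ((peers["x"] > row["x"]) | (peers["y"].fillna(-np.inf) > row["y"]))
        ).any()
        flags.append(not dominated)
    out["pareto"] = flags
    return out
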