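"""Read-level barcode evidence -> per-cell, per-variant UMI counts.

The chain: correct cell barcodes against the transcriptome whitelist,
assign each read to a variant by its barcode tag keeping only unique hits,
resolve rare multi-variant UMI collisions by majority rule, merge the
deeper PCR view with the standard scRNA-seq view of the same molecules,
and normalize to tagged transcripts per 100,000 with dilution correction.

Every filtering step tallies what it discarded; tallies are returned on the
result objects and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError, ReconciliationError, ValidationError
from .io_core import CellGeneMatrix, VariantLibrary, validate_read_table

logger = logging.getLogger(__name__)

ASSIGNMENT_COLUMNS = ["source", "cell_barcode", "umi", "variant_id", "read_count"]


@dataclass
class CellVariantCounts:
    """Per-(cell, variant) distinct-UMI counts with provenance.

    ``table`` columns: cell_barcode, variant_id, umi_count, sources
    (comma-joined subset of {scrna, pcr}); ``umi_sets`` retains the
    distinct UMIs behind each count so merging across sources can union
    them rather than double-count shared molecules.
    """

    table: pd.DataFrame
    umi_sets: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)
    discards: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)


def _hamming1_neighbors(barcode: str) -> Iterable[str]:
    for i, base in enumerate(barcode):
        for b in "ACGT":
            if b != base:
                yield barcode[:i] + b + barcode[i + 1 :]


def correct_cell_barcodes(reads: pd.DataFrame, whitelist: Iterable[str]) -> pd.DataFrame:
    """Correct read cell barcodes against the transcriptome whitelist.

    Exact matches pass through; a barcode at Hamming distance 1 from
    exactly one whitelist entry is corrected to it; at distance 1 from
    several, the whitelist entry with the highest exact-match read
    abundance wins and abundance ties discard the read; anything at
    distance >= 2 from every entry is discarded. Mirrors the standard
    droplet-pipeline correction of PCR-introduced barcode errors.
    """
    validate_read_table(reads)
    wl = list(dict.fromkeys(whitelist))
    if not wl:
        raise ValidationError("empty whitelist")
    wl_set = set(wl)
    if len(reads):
        read_len = len(reads["cell_barcode"].iloc[0])
        wl_len = len(wl[0])
        if read_len != wl_len or any(len(w) != wl_len for w in wl):
            raise FormatError("cell-barcode length mismatch with whitelist")

    abundance = (
        reads[reads["cell_barcode"].isin(wl_set)]["cell_barcode"]
        .value_counts().to_dict()
    )
    mapping: dict[str, str | None] = {}
    tallies = {"exact": 0, "corrected": 0, "ambiguous": 0, "unmatched": 0}
    for bc in reads["cell_barcode"].unique():
        if bc in wl_set:
            mapping[bc] = bc
            continue
        hits = [nb for nb in _hamming1_neighbors(bc) if nb in wl_set]
        if not hits:
            mapping[bc] = None
            continue
        if len(hits) == 1:
            mapping[bc] = hits[0]
            continue
        by_abundance = sorted(hits, key=lambda h: (-abundance.get(h, 0), h))
        top = abundance.get(by_abundance[0], 0)
        runners = [h for h in hits if abundance.get(h, 0) == top]
        mapping[bc] = by_abundance[0] if len(runners) == 1 else None

    corrected = reads["cell_barcode"].map(mapping)
    keep = corrected.notna()
    tallies["exact"] = int(reads["cell_barcode"].isin(wl_set).sum())
    tallies["corrected"] = int((keep & ~reads["cell_barcode"].isin(wl_set)).sum())
    tallies["unmatched"] = int((~keep).sum())
    logger.info("cell-barcode correction: %s", tallies)
    out = reads[keep].copy()
    out["cell_barcode"] = corrected[keep]
    return out.reset_index(drop=True)


def _min_pairwise_hamming(seqs: list[str]) -> int:
    best = len(seqs[0])
    arrs = [np.frombuffer(s.encode(), dtype="S1") for s in seqs]
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            best = min(best, int((arrs[i] != arrs[j]).sum()))
    return best


def assign_reads_to_variants(reads: pd.DataFrame, lib: VariantLibrary,
                             max_mismatch: int = 0) -> tuple[pd.DataFrame, dict]:
    """Scan payloads for variant barcodes, keeping unique hits only.

    A read counts for a variant when its payload contains the variant's
    barcode (exactly by default, or within ``max_mismatch`` substitutions
    at the best-matching offset). Reads hitting zero or more than one
    variant are discarded and tallied. Survivors aggregate to read counts
    per (source, cell barcode, UMI, variant).
    """
    validate_read_table(reads)
    if not len(lib):
        raise ValidationError("empty variant library")
    bc_len = lib.barcode_length
    barcodes = lib.barcode_of()
    if max_mismatch > 0:
        min_d = _min_pairwise_hamming(list(barcodes.values()))
        if 2 * max_mismatch >= min_d:
            raise ConfigError(
                f"max_mismatch={max_mismatch} is unsafe: minimum pairwise barcode "
                f"distance is {min_d}; unique-hit semantics require "
                f"2*max_mismatch < {min_d}"
            )

    bc_arrays = {v: np.frombuffer(s.encode(), dtype="S1") for v, s in barcodes.items()}
    tallies = {"assigned": 0, "no_hit": 0, "multi_hit": 0}
    hits_per_read: list[str | None] = []
    for payload in reads["payload"]:
        hit_variants = []
        if max_mismatch == 0:
            for v, s in barcodes.items():
                if s in payload:
                    hit_variants.append(v)
        else:
            parr = np.frombuffer(payload.encode(), dtype="S1")
            for v, sarr in bc_arrays.items():
                best = bc_len
                for off in range(0, len(parr) - bc_len + 1):
                    d = int((parr[off : off + bc_len] != sarr).sum())
                    if d < best:
                        best = d
                if best <= max_mismatch:
                    hit_variants.append(v)
        if len(hit_variants) == 1:
            hits_per_read.append(hit_variants[0])
            tallies["assigned"] += 1
        elif not hit_variants:
            hits_per_read.append(None)
            tallies["no_hit"] += 1
        else:
            hits_per_read.append(None)
            tallies["multi_hit"] += 1

    logger.info("variant assignment: %s", tallies)
    out = reads.copy()
    out["variant_id"] = hits_per_read
    out = out[out["variant_id"].notna()]
    agg = (
        out.groupby(["source", "cell_barcode", "umi", "variant_id"], sort=True)
        .size().rename("read_count").reset_index()
    )
    return agg, tallies


def resolve_umi_collisions(assignments: pd.DataFrame) -> dict[str, CellVariantCounts]:
    """Enforce one variant per UMI, then count distinct UMIs per cell.

    A UMI tags a single captured mRNA molecule, so only one variant barcode
    should ever appear under a given (source, cell, UMI); when several do
    (PCR/sequencing errors), the variant with the most reads for that UMI
    is kept, and exact ties drop the UMI entirely (tallied). Returns one
    CellVariantCounts per source.
    """
    if assignments.empty:
        return {}
    out: dict[str, CellVariantCounts] = {}
    for source, sub in assignments.groupby("source"):
        kept_rows = []
        dropped_ties = 0
        for (cb, umi), grp in sub.groupby(["cell_barcode", "umi"], sort=True):
            max_reads = grp["read_count"].max()
            winners = grp[grp["read_count"] == max_reads]
            if len(winners) > 1:
                dropped_ties += 1
                continue
            kept_rows.append((cb, winners["variant_id"].iloc[0], umi))
        resolved = pd.DataFrame(kept_rows, columns=["cell_barcode", "variant_id", "umi"])
        umi_sets = {
            (cb, v): frozenset(g["umi"])
            for (cb, v), g in resolved.groupby(["cell_barcode", "variant_id"], sort=True)
        }
        table = pd.DataFrame(
            [(cb, v, len(s), source) for (cb, v), s in sorted(umi_sets.items())],
            columns=["cell_barcode", "variant_id", "umi_count", "sources"],
        )
        if dropped_ties:
            logger.info("source %s: dropped %d tied UMIs", source, dropped_ties)
        out[source] = CellVariantCounts(table, umi_sets,
                                        {"umi_ties_dropped": dropped_ties})
    return out


def merge_sources(pcr: CellVariantCounts | None,
                  scrna: CellVariantCounts | None) -> CellVariantCounts:
    """Union the PCR-enriched and scRNA-seq views of the infection table.

    The deeper PCR table is the backbone; every (cell, variant) pair seen
    only in the scRNA-seq data is added, whether or not that cell appears
    in the PCR table. For pairs in both, the UMI count is the size of the
    union of distinct UMIs across sources (the same molecule sequenced in
    both runs is one molecule). Provenance is recorded per pair.
    """
    empty = CellVariantCounts(
        pd.DataFrame(columns=["cell_barcode", "variant_id", "umi_count", "sources"]))
    pcr = pcr if pcr is not None else empty
    scrna = scrna if scrna is not None else empty
    keys = set(pcr.umi_sets) | set(scrna.umi_sets)
    rows, umi_sets = [], {}
    for key in sorted(keys):
        s_pcr = pcr.umi_sets.get(key, frozenset())
        s_sc = scrna.umi_sets.get(key, frozenset())
        union = s_pcr | s_sc
        provenance = ",".join(
            name for name, s in (("pcr", s_pcr), ("scrna", s_sc)) if s
        )
        umi_sets[key] = frozenset(union)
        rows.append((key[0], key[1], len(union), provenance))
    table = pd.DataFrame(rows, columns=["cell_barcode", "variant_id",
                                        "umi_count", "sources"])
    return CellVariantCounts(table, umi_sets)


def normalize_expression(counts: CellVariantCounts, m: CellGeneMatrix,
                         lib: VariantLibrary,
                         rescale_to_top_variant: bool = False) -> pd.DataFrame:
    """Tagged transcripts per 100,000, dilution-corrected.

    tagged_per_100k = umi_count / nUMI(cell) * 100,000 / dilution_factor.
    Cells absent from the transcriptome matrix failed upstream QC and are
    dropped with a tally. With ``rescale_to_top_variant`` the whole table
    is additionally divided by the dilution factor of the variant infecting
    the most cells (an optional global rescaling; rankings are unaffected),
    reported in the extra column ``tagged_per_100k_rescaled``.
    """
    dilution = lib.dilution_of()
    unknown = set(counts.table["variant_id"]) - set(dilution)
    if unknown:
        raise ReconciliationError(f"variants absent from library: {sorted(unknown)}")
    n_umi = m.n_umi_of()
    tab = counts.table
    in_matrix = tab["cell_barcode"].isin(n_umi)
    n_dropped = int((~in_matrix).sum())
    if n_dropped:
        logger.info("normalize: dropped %d rows for cells absent from matrix", n_dropped)
    tab = tab[in_matrix].copy()
    tab["tagged_per_100k"] = [
        cnt / n_umi[cb] * 1e5 / dilution[v]
        for cb, v, cnt in zip(tab["cell_barcode"], tab["variant_id"], tab["umi_count"])
    ]
    if rescale_to_top_variant and len(tab):
        top = tab.groupby("variant_id")["cell_barcode"].nunique().sort_index()
        ref = top[top == top.max()].index[0]
        tab["tagged_per_100k_rescaled"] = tab["tagged_per_100k"] / dilution[ref]
    return tab.reset_index(drop=True)


def quantify(reads: pd.DataFrame, m: CellGeneMatrix, lib: VariantLibrary,
             max_mismatch: int = 0,
             rescale_to_top_variant: bool = False) -> tuple[CellVariantCounts, pd.DataFrame]:
    """The full chain: correct -> assign -> resolve -> merge -> normalize."""
    corrected = correct_cell_barcodes(reads, m.cell_ids)
    assignments, _ = assign_reads_to_variants(corrected, lib, max_mismatch=max_mismatch)
    per_source = resolve_umi_collisions(assignments)
    merged = merge_sources(per_source.get("pcr"), per_source.get("scrna"))
    expr = normalize_expression(merged, m, lib,
                                rescale_to_top_variant=rescale_to_top_variant)
    return merged, expr
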