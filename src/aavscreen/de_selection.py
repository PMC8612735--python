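"""Directed-evolution analytics.

Covers the three analyses run on DE sequencing data: extraction and
translation of the random 7-mer peptide inserts (with their constant LA/A
linkers, 10 aa total), per-round pseudo-count fold-increase ranking of
variants across rounds of selection, and percent-of-total fold ranking of
the barcoded subset library recovered from tissue versus injected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .errors import ConfigError, ValidationError

logger = logging.getLogger(__name__)

STOP = "*"


@dataclass
class InsertCount:
    """One unique translated insert with its synonymous DNA support."""

    aa_insert: str
    dna_variants: set[str] = field(default_factory=set)
    read_count: int = 0


@dataclass
class InsertExtraction:
    inserts: list[InsertCount]
    n_reads: int
    n_discarded: int

    def as_frame(self) -> pd.DataFrame:
        rows = [(i.aa_insert, i.read_count, len(i.dna_variants)) for i in self.inserts]
        df = pd.DataFrame(rows, columns=["aa_insert", "read_count", "n_dna_variants"])
        return df.sort_values(["read_count", "aa_insert"],
                              ascending=[False, True]).reset_index(drop=True)


def extract_inserts(reads: Sequence[str], linker5: str = "LA", linker3: str = "A",
                    insert_len: int = 7) -> InsertExtraction:
    """Translate in-frame amplicons and count unique peptide inserts.

    Each read is translated with the standard codon table and scanned for
    the ``linker5`` + ``insert_len`` residues + ``linker3`` window; the full
    window (10 aa for a 7-mer library) is the insert identity, so synonymous
    DNA collapses onto one peptide. Reads with a stop codon inside the
    window, too short to span it, or with no linker match are discarded and
    tallied, never raised.
    """
    window = len(linker5) + insert_len + len(linker3)
    counts: dict[str, InsertCount] = {}
    discarded = 0
    for read in reads:
        read = read.strip().upper()
        if len(read) < 3 * window:
            discarded += 1
            continue
        aa = str(Seq(read[: len(read) - len(read) % 3]).translate())
        hit, hit_pos = None, -1
        for i in range(0, len(aa) - window + 1):
            win = aa[i : i + window]
            if (win.startswith(linker5) and win.endswith(linker3)
                    and STOP not in win):
                hit, hit_pos = win, i
                break
        if hit is None:
            discarded += 1
            continue
        start_nt = hit_pos * 3
        dna = read[start_nt : start_nt + 3 * window]
        entry = counts.setdefault(hit, InsertCount(hit))
        entry.dna_variants.add(dna)
        entry.read_count += 1
    inserts = sorted(counts.values(), key=lambda c: (-c.read_count, c.aa_insert))
    return InsertExtraction(inserts, n_reads=len(reads), n_discarded=discarded)


def _validate_round_counts(rc: pd.DataFrame) -> pd.DataFrame:
    if rc.shape[1] < 2:
        raise ValidationError("need at least two rounds (plasmid + final)")
    arr = rc.to_numpy()
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer) and np.any(arr != np.round(arr)):
        raise ValidationError("round counts must be nonnegative integers")
    return rc


def round_frequencies(rc: pd.DataFrame, pseudo: float = 1.0) -> pd.DataFrame:
    """Pseudo-count-adjusted per-round frequencies (each column sums to 1).

    The pseudo-count is added to every variant's raw count before the round
    total, so adjusted frequencies still sum to one within each round and a
    variant absent from the plasmid library gets a finite fold increase.
    """
    _validate_round_counts(rc)
    adj = rc.astype(float) + pseudo
    totals = adj.sum(axis=0)
    if (totals == 0).any():
        raise ValidationError("a round has zero adjusted total; use pseudo > 0")
    return adj / totals


def rank_fold_increase(rc: pd.DataFrame, pseudo: float = 1.0) -> pd.DataFrame:
    """Rank variants by fold increase of final-round vs plasmid frequency.

    Columns of ``rc`` are rounds in order, column 0 the plasmid library.
    fold = freq_last / freq_first on pseudo-count-adjusted frequencies;
    ranking is descending by fold with ties broken lexicographically by id.
    """
    freqs = round_frequencies(rc, pseudo=pseudo)
    first, last = freqs.columns[0], freqs.columns[-1]
    out = pd.DataFrame(
        {
            "variant_id": freqs.index.astype(str),
            "freq_first": freqs[first].to_numpy(),
            "freq_last": freqs[last].to_numpy(),
        }
    )
    out["fold_increase"] = out["freq_last"] / out["freq_first"]
    out = out.sort_values(["fold_increase", "variant_id"],
                          ascending=[False, True]).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def rank_subset_barcodes(recovered: Mapping[str, int],
                         injected: Mapping[str, int]) -> pd.DataFrame:
    """Rank barcoded subset-library variants by percent-of-total fold change.

    fold = (% of total reads in the recovered sample) /
           (% of total reads in the injected library);
    both sides are normalized by their run's total read count first. No
    pseudo-count is applied here: a variant with zero injected reads has an
    undefined ratio and is an input error.
    """
    if set(recovered) != set(injected):
        raise ValidationError("recovered and injected variant sets differ")
    if not injected:
        raise ValidationError("empty count tables")
    for v, c in injected.items():
        if c <= 0:
            raise ValidationError(f"variant {v!r} has zero injected reads")
    rec_total = sum(recovered.values())
    inj_total = sum(injected.values())
    if rec_total <= 0:
        raise ValidationError("no recovered reads")
    ids = sorted(injected)
    out = pd.DataFrame(
        {
            "variant_id": ids,
            "pct_recovered": [100.0 * recovered[v] / rec_total for v in ids],
            "pct_injected": [100.0 * injected[v] / inj_total for v in ids],
        }
    )
    out["fold"] = out["pct_recovered"] / out["pct_injected"]
    out = out.sort_values(["fold", "variant_id"],
                          ascending=[False, True]).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
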