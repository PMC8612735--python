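"""Ground-truthed synthetic fixtures for the whole pipeline.

Emulates the statistical structure of a barcoded-capsid single-cell screen:
a tissue of typed cells whose identities are defined by elevated marker
genes, per-(variant, cell type) infection probabilities, Poisson tagged-UMI
expression, and a read-level view of those molecules from two sources — the
standard scRNA-seq run and a deeper PCR re-amplification of the same
prepped library (same cell barcodes and UMIs, more duplicates, more
sequencing errors to resolve).

Gene counts are negative-binomial, the standard overdispersed model for
UMI counts; marker genes are elevated by a constant fold in their own type
so that clustering and marker ranking have honest signal to find.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_core import CellGeneMatrix, VariantLibrary, validate_read_table
import scipy.sparse as sp

logger = logging.getLogger(__name__)

CELL_BARCODE_LEN = 16
UMI_LEN = 12
_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for one simulated sample.

    Defaults reflect a small but realistic droplet scRNA-seq experiment:
    markers up 8-fold in their own type, per-gene baseline mean 0.5 UMIs,
    PCR source sampled 20x deeper than the scRNA-seq source, and a 0.5%
    per-base substitution error on the variant barcode in each read.
    """

    n_cells: int
    cell_type_proportions: Mapping[str, float]
    marker_spec: Mapping[str, list[str]]
    variants: VariantLibrary
    infection_rate: Mapping[tuple[str, str], float]
    expression_rate: Mapping[str, float]
    n_background_genes: int = 50
    marker_fold: float = 8.0
    baseline_mean: float = 0.5
    dispersion: float = 2.0
    pcr_capture_gain: int = 20
    barcode_error_rate: float = 0.005
    collision_rate: float = 0.0
    doublet_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        props = dict(self.cell_type_proportions)
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ConfigError("cell type proportions must sum to 1")
        if set(self.marker_spec) - set(props):
            raise ConfigError("marker_spec names unknown cell types")
        for (v, ct), p in self.infection_rate.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"infection rate for ({v},{ct}) outside [0,1]")
            if v not in self.variants.variant_ids:
                raise ConfigError(f"infection rate names unknown variant {v!r}")
        for v, r in self.expression_rate.items():
            if r < 0:
                raise ConfigError("expression rates must be >= 0")
        if not 0.0 <= self.barcode_error_rate <= 1.0:
            raise ConfigError("barcode_error_rate outside [0,1]")
        if self.pcr_capture_gain < 1:
            raise ConfigError("pcr_capture_gain must be >= 1")

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.cell_type_proportions)

    @property
    def gene_ids(self) -> list[str]:
        markers = [g for ct in sorted(self.marker_spec) for g in self.marker_spec[ct]]
        background = [f"BG{i:04d}" for i in range(self.n_background_genes)]
        genes = list(dict.fromkeys(markers)) + background
        if len(set(genes)) != len(genes):
            raise ConfigError("marker genes collide with background gene names")
        return genes


@dataclass
class TruthTable:
    """Per-cell ground truth: type, infecting variants, true tagged UMIs."""

    cells: pd.DataFrame  # columns: cell_barcode, true_type
    tagged_umis: dict[str, dict[str, int]]  # cell_barcode -> {variant: count>0}

    def infecting_variants(self, cell_barcode: str) -> set[str]:
        return set(self.tagged_umis.get(cell_barcode, {}))

    def infected_fraction(self, variant: str, cell_type: str | None = None) -> float:
        cells = self.cells
        if cell_type is not None:
            cells = cells[cells["true_type"] == cell_type]
        if not len(cells):
            return float("nan")
        hit = sum(
            1 for cb in cells["cell_barcode"] if variant in self.tagged_umis.get(cb, {})
        )
        return hit / len(cells)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cb, ttype in zip(self.cells["cell_barcode"], self.cells["true_type"]):
            for v, k in sorted(self.tagged_umis.get(cb, {}).items()):
                rows.append((cb, ttype, v, k))
        return pd.DataFrame(rows, columns=["cell_barcode", "true_type",
                                           "variant_id", "true_tagged_umis"])


def _random_dna(rng: np.random.Generator, n: int, length: int) -> list[str]:
    draws = rng.integers(0, 4, size=(n, length))
    return ["".join(_BASES[row]) for row in draws]


def _unique_random_dna(rng: np.random.Generator, n: int, length: int) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        for s in _random_dna(rng, n - len(out), length):
            if s not in seen:
                seen.add(s)
                out.append(s)
    return out


def random_variant_barcodes(n: int, length: int = 25, min_distance: int = 5,
                            seed: int = 0) -> list[str]:
    """Seeded random barcodes with a minimum pairwise Hamming distance.

    Mimics the distinct GFP-proximal tags cloned per variant; the distance
    floor keeps single sequencing errors from turning one tag into another.
    """
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    attempts = 0
    while len(chosen) < n:
        cand = rng.integers(0, 4, size=length)
        if all(int((cand != c).sum()) >= min_distance for c in chosen):
            chosen.append(cand)
        attempts += 1
        if attempts > 10000 * n:
            raise ConfigError("cannot satisfy barcode distance constraint")
    return ["".join(_BASES[c]) for c in chosen]


def simulate_tissue(config: SimConfig) -> tuple[CellGeneMatrix, TruthTable]:
    """Draw a typed tissue, its UMI count matrix, and infection ground truth.

    Cell types are multinomial in the configured proportions; gene counts
    are negative-binomial with mean ``baseline_mean`` (markers elevated
    ``marker_fold``-fold in their own type); infections are Bernoulli per
    (variant, type); tagged UMI counts are Poisson with the variant's
    expression rate, and a cell counts as infected by a variant only when
    at least one tagged molecule was actually made.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids
    types = config.cell_types
    props = np.array([config.cell_type_proportions[t] for t in types])

    type_idx = rng.choice(len(types), size=config.n_cells, p=props)
    cell_types_drawn = [types[i] for i in type_idx]
    cell_barcodes = _unique_random_dna(rng, config.n_cells, CELL_BARCODE_LEN)

    # per-(type, gene) NB mean; markers elevated in their own type
    mean = np.full((len(types), len(genes)), config.baseline_mean)
    gene_pos = {g: j for j, g in enumerate(genes)}
    for ti, t in enumerate(types):
        for g in config.marker_spec.get(t, []):
            if g not in gene_pos:
                raise ConfigError(f"marker gene {g!r} absent from gene list")
            mean[ti, gene_pos[g]] *= config.marker_fold

    r = config.dispersion
    cell_means = mean[type_idx]  # n_cells x n_genes
    p = r / (r + cell_means)
    counts = rng.negative_binomial(r, p)
    # guarantee nonzero nUMI so no cell is dropped at load
    empty = counts.sum(axis=1) == 0
    if empty.any():
        counts[empty, 0] += 1

    matrix = CellGeneMatrix(cell_barcodes, genes, sp.csr_matrix(counts))

    tagged: dict[str, dict[str, int]] = {}
    for ci, (cb, ct) in enumerate(zip(cell_barcodes, cell_types_drawn)):
        per_cell: dict[str, int] = {}
        for v in config.variants.variant_ids:
            rate = config.infection_rate.get((v, ct), 0.0)
            if rate > 0 and rng.random() < rate:
                k = rng.poisson(max(config.expression_rate.get(v, 0.0), 0.0))
                if k > 0:
                    per_cell[v] = int(k)
        if per_cell:
            tagged[cb] = per_cell

    truth = TruthTable(
        pd.DataFrame({"cell_barcode": cell_barcodes, "true_type": cell_types_drawn}),
        tagged,
    )
    return matrix, truth


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        current = arr[i].decode()
        options = [b for b in "ACGT" if b != current]
        arr[i] = options[rng.integers(0, 3)].encode()
    return arr.tobytes().decode()


def simulate_reads(truth: TruthTable, library: VariantLibrary,
                   config: SimConfig) -> pd.DataFrame:
    """Emit the read-level evidence for every true tagged molecule.

    Each true tagged UMI yields one scrna-source read and
    ``pcr_capture_gain`` pcr-source reads sharing the same cell barcode
    and UMI (the PCR run re-amplifies the already-prepped library, so
    molecule identity is preserved). Payloads are the variant barcode with
    independent per-base substitution errors. With ``collision_rate`` > 0
    a fraction of UMIs additionally carry one pcr read from a different
    variant, exercising the downstream majority-rule collision resolver.
    """
    rng = np.random.default_rng(config.seed + 1)
    barcode_of = library.barcode_of()
    all_variants = library.variant_ids
    rows: list[tuple[str, str, str, str]] = []

    for cb in truth.cells["cell_barcode"]:
        per_cell = truth.tagged_umis.get(cb, {})
        for v, n_umis in sorted(per_cell.items()):
            if v not in barcode_of:
                raise ConfigError(f"infecting variant {v!r} absent from library")
            for umi in _unique_random_dna(rng, n_umis, UMI_LEN):
                true_bc = barcode_of[v]
                rows.append(
                    ("scrna", cb, umi, _mutate(rng, true_bc, config.barcode_error_rate))
                )
                for _ in range(config.pcr_capture_gain):
                    rows.append(
                        ("pcr", cb, umi, _mutate(rng, true_bc, config.barcode_error_rate))
                    )
                if config.collision_rate > 0 and rng.random() < config.collision_rate:
                    others = [o for o in all_variants if o != v]
                    intruder = others[rng.integers(0, len(others))]
                    rows.append(
                        ("pcr", cb, umi,
                         _mutate(rng, barcode_of[intruder], config.barcode_error_rate))
                    )

    reads = pd.DataFrame(rows, columns=["source", "cell_barcode", "umi", "payload"])
    return validate_read_table(reads)


def simulate_de_rounds(n_variants: int, n_rounds: int,
                       enrichment: Mapping[str, float] | None,
                       depth: int, seed: int = 0) -> pd.DataFrame:
    """Simulate read counts over rounds of directed-evolution selection.

    Round 0 is the plasmid library at uniform frequencies; each subsequent
    round multinomially resamples ``depth`` reads from the previous round's
    frequencies scaled by each variant's per-round enrichment multiplier.
    Returns a variants × rounds count table (column ``round_0`` .. ).
    """
    if n_rounds < 1:
        raise ConfigError("need at least one round of selection")
    if depth <= 0:
        raise ConfigError("sequencing depth must be positive")
    enrichment = dict(enrichment or {})
    ids = [f"V{i:04d}" for i in range(n_variants)]
    mult = np.array([enrichment.get(v, 1.0) for v in ids])
    if np.any(mult <= 0):
        raise ConfigError("enrichment multipliers must be > 0")

    rng = np.random.default_rng(seed)
    freqs = np.full(n_variants, 1.0 / n_variants)
    cols = {"round_0": rng.multinomial(depth, freqs)}
    for r in range(1, n_rounds + 1):
        prev = cols[f"round_{r - 1}"].astype(float)
        prev_freq = prev / prev.sum() if prev.sum() else np.full(n_variants, 1 / n_variants)
        w = prev_freq * mult
        cols[f"round_{r}"] = rng.multinomial(depth, w / w.sum())
    return pd.DataFrame(cols, index=pd.Index(ids, name="variant_id"))
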