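"""Shared fixtures: small ground-truthed synthetic samples.

All fixtures are generated programmatically with fixed seeds; nothing is
read from disk except through tmp_path round-trips inside tests.
"""

import numpy as np
import pytest

from aavscreen import VariantLibrary, random_variant_barcodes, simulate_tissue
from aavscreen.synthetic_data import SimConfig

CELL_TYPES = ["rod", "cone", "bipolar", "rgc"]


def marker_spec(n_markers: int = 10) -> dict[str, list[str]]:
    return {t: [f"{t.upper()}_{j}" for j in range(n_markers)] for t in CELL_TYPES}


def make_library(n_variants: int = 6, seed: int = 3) -> VariantLibrary:
    barcodes = random_variant_barcodes(n_variants, length=25, min_distance=5,
                                       seed=seed)
    return VariantLibrary.equimolar(
        {f"VAR{i:02d}": bc for i, bc in enumerate(barcodes)})


def make_config(n_cells: int = 500, *, library: VariantLibrary | None = None,
                infection_rate: float = 0.1, expression_rate: float = 3.0,
                barcode_error_rate: float = 0.0, collision_rate: float = 0.0,
                seed: int = 7, **overrides) -> SimConfig:
    lib = library if library is not None else make_library()
    return SimConfig(
        n_cells=n_cells,
        cell_type_proportions={t: 1 / len(CELL_TYPES) for t in CELL_TYPES},
        marker_spec=marker_spec(),
        variants=lib,
        infection_rate={(v, t): infection_rate
                        for v in lib.variant_ids for t in CELL_TYPES},
        expression_rate={v: expression_rate for v in lib.variant_ids},
        barcode_error_rate=barcode_error_rate,
        collision_rate=collision_rate,
        seed=seed,
        **overrides,
    )


@pytest.fixture(scope="session")
def library() -> VariantLibrary:
    return make_library()


@pytest.fixture(scope="session")
def noiseless_sample(library):
    """500-cell noiseless tissue + truth, shared read-only across tests."""
    config = make_config(500, library=library)
    matrix, truth = simulate_tissue(config)
    return config, matrix, truth
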