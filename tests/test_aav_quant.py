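"""Barcode evidence -> infection table: correction, assignment, merging."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from aavscreen import (
    CellGeneMatrix,
    VariantLibrary,
    assign_reads_to_variants,
    correct_cell_barcodes,
    merge_sources,
    normalize_expression,
    quantify,
    resolve_umi_collisions,
    simulate_reads,
)
from aavscreen.aav_quant import CellVariantCounts
from aavscreen.errors import ConfigError, FormatError, ReconciliationError


def reads_frame(rows):
    return pd.DataFrame(rows, columns=["source", "cell_barcode", "umi", "payload"])


class TestCorrectCellBarcodes:
    def test_exact_match_passes_through(self):
        reads = reads_frame([("pcr", "AAAA", "TT", "ACGT")])
        out = correct_cell_barcodes(reads, ["AAAA", "CCCC"])
        assert out["cell_barcode"].tolist() == ["AAAA"]

    def test_unique_one_mismatch_corrected(self):
        reads = reads_frame([("pcr", "AAAT", "TT", "ACGT")])
        out = correct_cell_barcodes(reads, ["AAAA", "CCCC"])
        assert out["cell_barcode"].tolist() == ["AAAA"]

    def test_ambiguous_equal_abundance_discarded(self):
        reads = reads_frame([("pcr", "AAAT", "TT", "ACGT")])
        out = correct_cell_barcodes(reads, ["AAAA", "AAAC"])
        assert len(out) == 0

    def test_ambiguous_resolved_by_abundance(self):
        reads = reads_frame(
            [("pcr", "AAAA", "T1", "X"), ("pcr", "AAAA", "T2", "X"),
             ("pcr", "AAAC", "T3", "X"), ("pcr", "AAAT", "T4", "X")])
        out = correct_cell_barcodes(reads, ["AAAA", "AAAC"])
        assert out.loc[out["umi"] == "T4", "cell_barcode"].tolist() == ["AAAA"]

    def test_distance_two_discarded(self):
        reads = reads_frame([("pcr", "AATT", "TT", "ACGT")])
        assert len(correct_cell_barcodes(reads, ["AAAA", "CCCC"])) == 0

    def test_length_mismatch_is_format_error(self):
        reads = reads_frame([("pcr", "AAAAA", "TT", "ACGT")])
        with pytest.raises(FormatError):
            correct_cell_barcodes(reads, ["AAAA"])


LIB = VariantLibrary.equimolar({"A": "AAAAAA", "B": "AATTAA", "C": "CCGGCC"})


class TestAssignReads:
    def test_unique_hit_assigned(self):
        reads = reads_frame([("pcr", "CCCC", "TT", "GGAAAAAAGG")])
        out, tallies = assign_reads_to_variants(reads, LIB)
        assert out[["variant_id", "read_count"]].values.tolist() == [["A", 1]]
        assert tallies == {"assigned": 1, "no_hit": 0, "multi_hit": 0}

    def test_multi_hit_discarded(self):
        # payload contains both A's and B's barcode
        reads = reads_frame([("pcr", "CCCC", "TT", "AAAAAATTAA")])
        out, tallies = assign_reads_to_variants(reads, LIB)
        assert len(out) == 0
        assert tallies["multi_hit"] == 1

    def test_no_hit_discarded(self):
        reads = reads_frame([("pcr", "CCCC", "TT", "GGGGGGGGGG")])
        out, tallies = assign_reads_to_variants(reads, LIB)
        assert len(out) == 0 and tallies["no_hit"] == 1

    def test_mismatch_tolerance_with_safe_radius(self):
        lib = VariantLibrary.equimolar({"A": "AAAAAAAA", "B": "TTTTTTTT"})
        reads = reads_frame([("pcr", "CCCC", "TT", "GGAAAAAAATGG")])
        out, _ = assign_reads_to_variants(reads, lib, max_mismatch=1)
        assert out["variant_id"].tolist() == ["A"]

    def test_unsafe_mismatch_radius_is_config_error(self):
        lib = VariantLibrary.equimolar({"A": "AAAAAA", "B": "AAATTT"})  # distance 3
        reads = reads_frame([("pcr", "CCCC", "TT", "AAAAAA")])
        with pytest.raises(ConfigError):
            assign_reads_to_variants(reads, lib, max_mismatch=2)

    def test_noiseless_simulation_assignments_match_truth(self, library,
                                                          noiseless_sample):
        config, _, truth = noiseless_sample
        reads = simulate_reads(truth, library, config)
        out, _ = assign_reads_to_variants(reads, library)
        triples = set(zip(out["cell_barcode"], out["umi"], out["variant_id"]))
        n_true_umis = sum(sum(d.values()) for d in truth.tagged_umis.values())
        # scrna + pcr sources see the same molecules
        assert len(triples) == n_true_umis
        for cb, per_cell in truth.tagged_umis.items():
            seen = {v for c, _, v in triples if c == cb}
            assert seen == set(per_cell)


class TestResolveCollisions:
    def test_majority_rule_keeps_dominant_variant(self):
        a = pd.DataFrame(
            [("pcr", "c1", "u1", "K912", 3), ("pcr", "c1", "u1", "AAV2", 1)],
            columns=["source", "cell_barcode", "umi", "variant_id", "read_count"])
        out = resolve_umi_collisions(a)["pcr"]
        assert out.table[["cell_barcode", "variant_id", "umi_count"]].values.tolist() \
            == [["c1", "K912", 1]]

    def test_single_variant_umi_kept(self):
        a = pd.DataFrame([("scrna", "c1", "u1", "A", 1)],
                         columns=["source", "cell_barcode", "umi", "variant_id",
                                  "read_count"])
        out = resolve_umi_collisions(a)["scrna"]
        assert out.table["umi_count"].tolist() == [1]

    def test_tied_umi_dropped(self):
        a = pd.DataFrame(
            [("pcr", "c1", "u1", "A", 2), ("pcr", "c1", "u1", "B", 2)],
            columns=["source", "cell_barcode", "umi", "variant_id", "read_count"])
        out = resolve_umi_collisions(a)["pcr"]
        assert len(out.table) == 0
        assert out.discards["umi_ties_dropped"] == 1

    def test_idempotent_on_resolved_output(self):
        a = pd.DataFrame(
            [("pcr", "c1", "u1", "A", 3), ("pcr", "c1", "u1", "B", 1),
             ("pcr", "c1", "u2", "B", 2), ("pcr", "c2", "u1", "A", 5)],
            columns=["source", "cell_barcode", "umi", "variant_id", "read_count"])
        first = resolve_umi_collisions(a)["pcr"]
        # rebuild an assignment table from the resolved per-UMI evidence
        resolved_rows = [("pcr", cb, u, v, 1)
                         for (cb, v), umis in first.umi_sets.items() for u in umis]
        again = resolve_umi_collisions(pd.DataFrame(
            resolved_rows, columns=["source", "cell_barcode", "umi", "variant_id",
                                    "read_count"]))["pcr"]
        assert again.umi_sets == first.umi_sets


def cvc(rows):
    """rows: (cell, variant, umis iterable, source)"""
    umi_sets = {(c, v): frozenset(u) for c, v, u, _ in rows}
    table = pd.DataFrame([(c, v, len(u), s) for c, v, u, s in rows],
                         columns=["cell_barcode", "variant_id", "umi_count",
                                  "sources"])
    return CellVariantCounts(table, umi_sets)


class TestMergeSources:
    def test_pcr_only_pair_retained(self):
        merged = merge_sources(cvc([("c1", "A", {"u1"}, "pcr")]), None)
        assert merged.table["umi_count"].tolist() == [1]
        assert merged.table["sources"].tolist() == ["pcr"]

    def test_scrna_only_cell_added(self):
        merged = merge_sources(cvc([("c1", "A", {"u1"}, "pcr")]),
                               cvc([("c2", "B", {"u9"}, "scrna")]))
        pairs = set(zip(merged.table["cell_barcode"], merged.table["variant_id"]))
        assert pairs == {("c1", "A"), ("c2", "B")}

    def test_umi_union_across_sources(self):
        merged = merge_sources(cvc([("c1", "A", {"u1", "u2"}, "pcr")]),
                               cvc([("c1", "A", {"u2", "u3"}, "scrna")]))
        assert merged.table["umi_count"].tolist() == [3]
        assert merged.table["sources"].tolist() == ["pcr,scrna"]

    def test_self_merge_identity(self):
        x = cvc([("c1", "A", {"u1", "u2"}, "pcr"), ("c2", "B", {"u3"}, "pcr")])
        merged = merge_sources(x, x)
        assert merged.umi_sets == x.umi_sets
        assert merged.table["umi_count"].tolist() == x.table["umi_count"].tolist()

    def test_membership_commutative(self):
        a = cvc([("c1", "A", {"u1"}, "pcr")])
        b = cvc([("c2", "B", {"u2"}, "scrna")])
        m1 = merge_sources(a, b)
        m2 = merge_sources(b, a)
        assert set(m1.umi_sets) == set(m2.umi_sets)


class TestNormalizeExpression:
    def _matrix(self, n_umi_by_cell):
        cells = list(n_umi_by_cell)
        return CellGeneMatrix(
            cells, ["g1"],
            sp.csr_matrix(np.array([[n_umi_by_cell[c]] for c in cells])))

    def test_hand_arithmetic(self):
        lib = VariantLibrary.equimolar({"A": "AAAA"})
        m = self._matrix({"c1": 4000})
        out = normalize_expression(cvc([("c1", "A", {"u1", "u2"}, "pcr")]), m, lib)
        assert out["tagged_per_100k"].tolist() == [pytest.approx(50.0)]

    def test_dilution_factor_halves_value(self):
        lib = VariantLibrary.from_fractions({"A": 2 / 3, "B": 1 / 3},
                                            {"A": "AAAA", "B": "CCCC"})
        # dilution factor of A = 2/3 * 2 = 4/3; use 2.0 via a 4-member pool
        lib2 = VariantLibrary.from_fractions(
            {"A": 0.5, "B": 0.5 / 3, "C": 0.5 / 3, "D": 0.5 / 3},
            {"A": "AAAA", "B": "CCCC", "C": "GGGG", "D": "TTTT"})
        assert lib2.dilution_of()["A"] == pytest.approx(2.0)
        m = self._matrix({"c1": 4000})
        out = normalize_expression(cvc([("c1", "A", {"u1", "u2"}, "pcr")]), m, lib2)
        assert out["tagged_per_100k"].tolist() == [pytest.approx(25.0)]

    def test_unknown_variant_is_reconciliation_error(self):
        lib = VariantLibrary.equimolar({"A": "AAAA"})
        m = self._matrix({"c1": 100})
        with pytest.raises(ReconciliationError):
            normalize_expression(cvc([("c1", "Z", {"u1"}, "pcr")]), m, lib)

    def test_cells_absent_from_matrix_dropped(self):
        lib = VariantLibrary.equimolar({"A": "AAAA"})
        m = self._matrix({"c1": 100})
        out = normalize_expression(
            cvc([("c1", "A", {"u1"}, "pcr"), ("cX", "A", {"u2"}, "pcr")]), m, lib)
        assert out["cell_barcode"].tolist() == ["c1"]


class TestEndToEnd:
    def test_noiseless_pipeline_recovers_truth_exactly(self, library,
                                                       noiseless_sample):
        config, matrix, truth = noiseless_sample
        reads = simulate_reads(truth, library, config)
        counts, expr = quantify(reads, matrix, library)
        recovered = {
            (cb, v): n for cb, v, n in zip(counts.table["cell_barcode"],
                                           counts.table["variant_id"],
                                           counts.table["umi_count"])
        }
        expected = {(cb, v): n for cb, d in truth.tagged_umis.items()
                    for v, n in d.items()}
        assert recovered == expected

    def test_collisions_resolved_by_majority(self, library):
        from conftest import make_config
        from aavscreen import simulate_tissue

        config = make_config(120, library=library, collision_rate=0.3, seed=21)
        matrix, truth = simulate_tissue(config)
        reads = simulate_reads(truth, library, config)
        counts, _ = quantify(reads, matrix, library)
        recovered = {
            (cb, v): n for cb, v, n in zip(counts.table["cell_barcode"],
                                           counts.table["variant_id"],
                                           counts.table["umi_count"])
        }
        expected = {(cb, v): n for cb, d in truth.tagged_umis.items()
                    for v, n in d.items()}
        # intruder reads are always a minority (1 read vs gain=20), so the
        # majority rule recovers the truth exactly despite the collisions
        assert recovered == expected
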