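"""Six-type RNA/protein concordance: examples, partition property, FC pairs."""

import numpy as np
import pandas as pd
import pytest

from protatlas.concordance import (
    classify_six_types,
    classify_type,
    compute_fc_pairs,
    type_enrichment,
    type_percentages,
)
from protatlas.core import AnnotationTable, GeneSetCollection
from protatlas.simulate import simulate_rna_protein_pairs

from conftest import build_matrix


def order_free_oracle(fc_rna, fc_protein):
    """The six disambiguated predicates evaluated independently (no
    precedence): returns the set of satisfied types.  The partition holds
    exactly when this set is a singleton for every pair."""
    a, b = np.log2(fc_rna), np.log2(fc_protein)
    big_r, big_p = abs(a) >= 1, abs(b) >= 1
    same = a * b > 0
    sat = set()
    if not big_r and not big_p:
        sat.add("Type1")
    if big_p and not big_r:
        sat.add("Type2")
    if big_r and not big_p and not same:
        sat.add("Type3")
    if big_r and not big_p and same:
        sat.add("Type4")
    if big_r and big_p and not same:
        sat.add("Type5")
    if big_r and big_p and same:
        sat.add("Type6")
    return sat


class TestWorkedExamples:
    @pytest.mark.parametrize("fc_rna,fc_protein,expected", [
        (1.5, 1.2, "Type1"),     # small change at both levels
        (1.1, 3.0, "Type2"),     # large protein change, small RNA change
        (3.0, 1.9, "Type4"),     # large RNA change, small consistent protein change
        (3.0, 0.9, "Type3"),     # large RNA change, small opposite protein change
        (3.0, 0.3, "Type5"),     # large opposite changes
        (3.0, 4.0, "Type6"),     # large consistent changes
        (0.3, 0.25, "Type6"),    # consistent downregulation
        (0.4, 5.0, "Type5"),     # opposite: RNA down, protein up
    ])
    def test_examples(self, fc_rna, fc_protein, expected):
        assert classify_type(fc_rna, fc_protein) == expected

    def test_fc_of_exactly_one_never_type5(self):
        for other in (0.2, 5.0, 1.0):
            assert classify_type(1.0, other) != "Type5"
            assert classify_type(other, 1.0) != "Type5"

    def test_invalid_fc_rejected(self):
        with pytest.raises(ValueError):
            classify_type(-1.0, 2.0)
        with pytest.raises(ValueError):
            classify_type(0.0, 2.0)


class TestPartition:
    def test_grid_every_point_exactly_one_type(self):
        ratios = np.geomspace(0.1, 10.0, 100)
        for r in ratios:
            for p in ratios:
                sat = order_free_oracle(r, p)
                assert len(sat) == 1, (r, p, sat)
                assert classify_type(r, p) == next(iter(sat))

    def test_unambiguous_cells_match_printed_definitions(self):
        rng = np.random.default_rng(2)
        for _ in range(2000):
            a, b = rng.uniform(-3, 3, 2)
            t = classify_type(2.0**a, 2.0**b)
            # magnitude cells
            if abs(a) < 1 and abs(b) < 1:
                assert t == "Type1"
            if abs(b) >= 1 and abs(a) < 1:
                assert t == "Type2"
            if abs(a) >= 1 and abs(b) >= 1:
                assert t == ("Type6" if a * b > 0 else "Type5")

    def test_percentages_sum_to_100(self):
        pairs, _ = simulate_rna_protein_pairs(500, seed=1)
        typed = classify_six_types(pairs)
        pct = type_percentages(typed, by=None)
        assert pct["percent"].sum() == pytest.approx(100.0, abs=1e-9)


class TestFcPairs:
    def _matrix(self):
        # one region, prenatal F120 and postnatal P3, 2 replicates
        specs = [("F120", "V1")] * 2 + [("P3", "V1")] * 2
        return build_matrix({"P1": [4.0, 4.0, 8.0, 8.0],     # doubles
                             "P2": [10.0, 10.0, 10.0, 10.0],  # flat
                             "P3": [6.0, 0.0, 3.0, 3.0]},     # halves (with dropout)
                            specs)

    def _ann(self):
        return AnnotationTable(gene_symbol={"P1": "G1", "P2": "G2", "P3": "G3"})

    def _rna(self, rows):
        return pd.DataFrame(rows, columns=["gene", "region", "prenatal_mean",
                                           "postnatal_mean"])

    def test_equal_means_both_layers(self):
        rna = self._rna([("G2", "V1", 5.0, 5.0)])
        out = compute_fc_pairs(self._matrix(), rna, self._ann(), "V1")
        assert out.iloc[0]["fc_rna"] == pytest.approx(1.0)
        assert out.iloc[0]["fc_protein"] == pytest.approx(1.0)

    def test_protein_doubles_rna_halves(self):
        rna = self._rna([("G1", "V1", 8.0, 4.0)])
        out = compute_fc_pairs(self._matrix(), rna, self._ann(), "V1")
        assert out.iloc[0]["fc_rna"] == pytest.approx(0.5)
        assert out.iloc[0]["fc_protein"] == pytest.approx(2.0)

    def test_detected_mean_excludes_dropout(self):
        rna = self._rna([("G3", "V1", 2.0, 2.0)])
        out = compute_fc_pairs(self._matrix(), rna, self._ann(), "V1")
        # prenatal detected mean is 6 (the 0 excluded), postnatal 3
        assert out.iloc[0]["fc_protein"] == pytest.approx(0.5)

    def test_zero_prenatal_rna_excluded_with_warning(self):
        rna = self._rna([("G1", "V1", 0.0, 4.0)])
        with pytest.warns(UserWarning, match="dropped"):
            out = compute_fc_pairs(self._matrix(), rna, self._ann(), "V1")
        assert out.empty


class TestTypeEnrichment:
    def test_planted_set_tops_type6(self):
        pairs, ledger = simulate_rna_protein_pairs(400, seed=7)
        typed = classify_six_types(pairs)
        t6_genes = ledger.loc[ledger["true_type"] == "Type6", "gene"].tolist()
        rng = np.random.default_rng(0)
        other = ledger.loc[ledger["true_type"] != "Type6", "gene"]
        sets = GeneSetCollection({
            "PLANTED": frozenset(t6_genes),
            "RANDOM": frozenset(rng.choice(other, size=30, replace=False)),
        })
        res = type_enrichment(typed, sets)
        t6 = res["Type6"].set_index("set_name")
        assert t6.loc["PLANTED", "enriched"]
        assert t6.loc["PLANTED", "p"] < t6.loc["RANDOM", "p"]

    def test_empty_type_skipped(self):
        typed = pd.DataFrame({"gene": ["g1"], "fc_rna": [1.0], "fc_protein": [1.0],
                              "type": ["Type1"]})
        sets = GeneSetCollection({"S": frozenset({"g1"})})
        res = type_enrichment(typed, sets)
        assert set(res) == {"Type1"}
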