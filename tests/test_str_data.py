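"""Domain types, nomenclature and file formats."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skbio import DistanceMatrix

import strpop as sp
from strpop.str_data import AlleleLabel

allele_labels = st.builds(AlleleLabel,
                          repeats=st.integers(min_value=1, max_value=60),
                          partial=st.integers(min_value=0, max_value=3))


class TestAlleleLabel:
    @given(allele_labels)
    def test_render_parse_round_trip(self, a):
        assert AlleleLabel.parse(str(a)) == a

    @given(allele_labels, allele_labels)
    def test_ordering_matches_numeric_value(self, a, b):
        assert (a < b) == (a.value < b.value)

    def test_microvariant_rendering(self):
        assert str(AlleleLabel(9, 3)) == "9.3"
        assert str(AlleleLabel(29, 2)) == "29.2"
        assert str(AlleleLabel(10)) == "10"

    def test_trailing_zero_normalizes(self):
        assert AlleleLabel.parse("10.0") == AlleleLabel.parse("10")

    @pytest.mark.parametrize("bad", ["", "x", "9.5", "0", "-3", "9.3.1"])
    def test_invalid_tokens_rejected(self, bad):
        with pytest.raises(ValueError):
            AlleleLabel.parse(bad)


class TestGenotypeCSV:
    def test_round_trip_with_missing_and_homozygote_shorthand(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("sample,TH01,TPOX\nS1,8/9.3,11\nS2,,8/8\n")
        g = sp.read_genotypes(path)
        assert g.calls[("S1", "TH01")] == (AlleleLabel(8), AlleleLabel(9, 3))
        assert g.calls[("S1", "TPOX")] == (AlleleLabel(11), AlleleLabel(11))
        assert g.calls[("S2", "TH01")] is None
        out = tmp_path / "g2.csv"
        sp.write_genotypes(g, out)
        assert sp.read_genotypes(out).calls == g.calls

    def test_cell_order_canonicalized(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("sample,L\nS1,9.3/8\n")
        g = sp.read_genotypes(path)
        assert g.calls[("S1", "L")] == (AlleleLabel(8), AlleleLabel(9, 3))

    def test_duplicate_sample_error_names_id(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("sample,L\nS1,8/9\nS1,8/8\n")
        with pytest.raises(ValueError, match="S1"):
            sp.read_genotypes(path)

    def test_bad_token_error_names_location(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("sample,TH01\nS7,8/x\n")
        with pytest.raises(ValueError, match="S7.*TH01"):
            sp.read_genotypes(path)


class TestFrequencyTable:
    def test_packaged_panel_shape(self, gorkha):
        assert len(gorkha.loci) == 15
        assert gorkha.n["TPOX"] == 98
        assert sp.count_alleles(gorkha) == 138

    def test_tpox_column(self, gorkha):
        expected = {"8": 0.469, "9": 0.122, "10": 0.082, "11": 0.306, "12": 0.020}
        got = {str(a): f for a, f in gorkha.freqs["TPOX"].items()}
        assert got == pytest.approx(expected)

    def test_published_summary_rows_split_off(self, gorkha):
        assert gorkha.published is not None
        assert gorkha.published["pm"]["TPOX"] == pytest.approx(0.157)
        assert gorkha.published["pd"]["TPOX"] == pytest.approx(0.843)

    def test_single_locus_file(self, tmp_path):
        path = tmp_path / "f.csv"
        path.write_text("Allele,L\n10,0.5\n11,0.5\nn,40\n")
        t = sp.read_frequency_table(path)
        assert sum(t.freqs["L"].values()) == pytest.approx(1.0)
        assert sp.count_alleles(t) == 2

    def test_bad_column_sum_names_locus(self, tmp_path):
        path = tmp_path / "f.csv"
        path.write_text("Allele,GOOD,BAD\n10,0.5,0.5\n11,0.5,0.3\nn,40,40\n")
        with pytest.raises(ValueError, match="BAD"):
            sp.read_frequency_table(path)

    def test_from_genotypes_sums_exactly(self, tiny_table):
        t = sp.AlleleFrequencyTable.from_genotypes(tiny_table)
        for locus in t.loci:
            assert sum(t.freqs[locus].values()) == pytest.approx(1.0, abs=1e-12)
        # distinct labels seen: L1 has {8,9,10}, L2 has {11,12}
        assert sp.count_alleles(t) == 5
        assert t.n == {"L1": 3, "L2": 2}

    def test_write_read_round_trip(self, gorkha, tmp_path):
        out = tmp_path / "t.csv"
        sp.write_frequency_table(gorkha, out)
        back = sp.read_frequency_table(out)
        assert back.loci == gorkha.loci
        for locus in gorkha.loci:
            assert back.freqs[locus] == pytest.approx(gorkha.freqs[locus])


class TestDistanceMatrixIO:
    def test_packaged_nei_matrix(self):
        dm = sp.load_nei_da_matrix()
        assert dm.shape == (16, 16)
        assert "Gorkha" in dm.ids
        assert dm["Gorkha"][list(dm.ids).index("Nepalese")] == pytest.approx(0.015)

    def test_csv_round_trip_six_decimals(self, tmp_path):
        rng = np.random.default_rng(0)
        m = rng.uniform(0, 1, (5, 5))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        dm = DistanceMatrix(m, ids=list("ABCDE"))
        path = tmp_path / "d.csv"
        sp.write_distance_matrix(dm, path)
        back = sp.read_distance_matrix(path)
        np.testing.assert_allclose(back.data, dm.data, atol=5e-7)
        assert list(back.ids) == list(dm.ids)

    def test_phylip_round_trip(self, tmp_path):
        dm = sp.load_nei_da_matrix()
        path = tmp_path / "d.phy"
        sp.write_distance_matrix(dm, path, phylip=True)
        back = sp.read_distance_matrix(path)
        np.testing.assert_allclose(back.data, dm.data, atol=5e-7)

    def test_lower_triangle_mirrored(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text(",A,B,C\nA,0,,\nB,0.3,0,\nC,0.5,0.2,0\n")
        dm = sp.read_distance_matrix(path)
        assert dm["A"][1] == pytest.approx(0.3)
        assert dm["B"][2] == pytest.approx(0.2)

    def test_zero_matrix_valid(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text(",A,B\nA,0,0\nB,0,0\n")
        dm = sp.read_distance_matrix(path)
        assert np.all(dm.data == 0)

    def test_non_square_rejected(self, tmp_path):
        path = tmp_path / "d.phy"
        path.write_text("3\nA 0 1 2\nB 1 0 1\n")
        with pytest.raises((ValueError, IndexError)):
            sp.read_distance_matrix(path)

    def test_asymmetry_warns_then_averages(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text(",A,B\nA,0,0.30\nB,0.40,0\n")
        with pytest.warns(UserWarning, match="symmetrized"):
            dm = sp.read_distance_matrix(path)
        assert dm["A"][1] == pytest.approx(0.35)


class TestNewick:
    def test_three_leaf_star(self):
        dm = DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]], ids=list("ABC"))
        tree = sp.neighbor_joining(dm)
        assert sp.write_newick(tree) == "(A:1.0,B:2.0,C:3.0);"

    def test_round_trip_preserves_topology_and_lengths(self):
        dm = sp.load_nei_da_matrix()
        tree = sp.neighbor_joining(dm)
        back = sp.read_newick(sp.write_newick(tree))
        from strpop.phylogeny import bipartitions
        assert bipartitions(back) == bipartitions(tree)
        d1 = tree.tip_tip_distances()
        d2 = back.tip_tip_distances().filter(d1.ids)
        np.testing.assert_allclose(d1.data, d2.data, atol=1e-6)

    def test_support_serialized_as_internal_label(self):
        dm = DistanceMatrix([[0, 2, 9, 9], [2, 0, 9, 9],
                             [9, 9, 0, 2], [9, 9, 2, 0]], ids=list("ABCD"))
        tree = sp.neighbor_joining(dm)
        for node in tree.non_tips(include_self=False):
            node.name = "87"
        assert ")87:" in sp.write_newick(tree)
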