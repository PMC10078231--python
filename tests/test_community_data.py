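"""Abundance/metadata I/O, taxon filters and salinity binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cooxnet as cx
from cooxnet.community_data import CommunityDataError, min_occurrence_count


def write_tsv(path, text):
    path.write_text(text)
    return path


class TestReadAbundance:
    def test_counts_normalized_per_sample(self, tmp_path):
        p = write_tsv(tmp_path / "a.tsv",
                      "taxon\ts1\ts2\nt1\t10\t0\nt2\t30\t20\n")
        m = cx.read_abundance_table(p)
        np.testing.assert_allclose(m.rel_abundance,
                                   [[0.25, 0.0], [0.75, 1.0]])
        np.testing.assert_array_equal(m.presence, [[1, 0], [1, 1]])

    def test_relative_input_unchanged(self, tmp_path):
        p = write_tsv(tmp_path / "a.tsv",
                      "taxon\ts1\ts2\nt1\t0.25\t0.0\nt2\t0.75\t1.0\n")
        m = cx.read_abundance_table(p)
        np.testing.assert_allclose(m.rel_abundance,
                                   [[0.25, 0.0], [0.75, 1.0]], atol=1e-12)

    def test_zero_total_sample_rejected(self, tmp_path):
        p = write_tsv(tmp_path / "a.tsv",
                      "taxon\ts1\ts2\nt1\t10\t0\nt2\t30\t0\n")
        with pytest.raises(CommunityDataError, match="zero total"):
            cx.read_abundance_table(p)

    def test_non_numeric_cell_named(self, tmp_path):
        p = write_tsv(tmp_path / "a.tsv",
                      "taxon\ts1\ts2\nt1\t10\txx\nt2\t30\t20\n")
        with pytest.raises(CommunityDataError, match="t1.*s2"):
            cx.read_abundance_table(p)

    def test_duplicate_taxon_rejected(self, tmp_path):
        p = write_tsv(tmp_path / "a.tsv",
                      "taxon\ts1\nt1\t10\nt1\t30\n")
        with pytest.raises(CommunityDataError, match="duplicate"):
            cx.read_abundance_table(p)

    def test_transposed_orientation(self, tmp_path):
        p = write_tsv(tmp_path / "a.tsv",
                      "sample\tt1\tt2\ns1\t10\t30\ns2\t0\t20\n")
        m = cx.read_abundance_table(p, taxa_as_rows=False)
        assert m.taxa == ["t1", "t2"] and m.samples == ["s1", "s2"]
        np.testing.assert_allclose(m.rel_abundance,
                                   [[0.25, 0.0], [0.75, 1.0]])

    def test_round_trip(self, tmp_path, default_sim):
        matrix, _, _ = default_sim
        path = tmp_path / "round.tsv"
        cx.write_abundance_table(matrix, path)
        back = cx.read_abundance_table(path)
        assert back.taxa == matrix.taxa and back.samples == matrix.samples
        np.testing.assert_array_equal(back.presence, matrix.presence)
        np.testing.assert_allclose(back.rel_abundance, matrix.rel_abundance,
                                   atol=1e-9)


METADATA_HEADER = ("sample_id\tlake_id\tdate\tx\ty\tsalinity\ttemperature"
                   "\tph\tdissolved_oxygen\tredox\n")


class TestReadMetadata:
    def test_well_formed_row(self, tmp_path):
        p = write_tsv(tmp_path / "m.tsv", METADATA_HEADER +
                      "S1\tL3\t2015-06-01\t0.34\t41.70\t5.0\t22.1\t8.3"
                      "\t6.4\t120\n")
        (rec,) = cx.read_metadata(p)
        assert rec.sample_id == "S1" and rec.lake_id == "L3"
        assert rec.date.isoformat() == "2015-06-01"
        assert rec.salinity == 5.0 and rec.redox == 120.0

    def test_negative_salinity_rejected(self, tmp_path):
        p = write_tsv(tmp_path / "m.tsv", METADATA_HEADER +
                      "S1\tL3\t2015-06-01\t0\t0\t-1\t20\t8\t6\t120\n")
        with pytest.raises(CommunityDataError, match="salinity"):
            cx.read_metadata(p)

    def test_missing_column_named(self, tmp_path):
        p = write_tsv(tmp_path / "m.tsv",
                      "sample_id\tlake_id\tdate\tx\ty\tsalinity\n"
                      "S1\tL1\t2015-01-01\t0\t0\t1\n")
        with pytest.raises(CommunityDataError, match="temperature"):
            cx.read_metadata(p)

    def test_bad_date_rejected(self, tmp_path):
        p = write_tsv(tmp_path / "m.tsv", METADATA_HEADER +
                      "S1\tL3\t06/01/2015\t0\t0\t1\t20\t8\t6\t120\n")
        with pytest.raises(CommunityDataError, match="date"):
            cx.read_metadata(p)

    def test_count_preserved(self, tmp_path, default_sim):
        _, meta, _ = default_sim
        path = tmp_path / "m.tsv"
        cx.write_metadata(meta, path)
        assert len(cx.read_metadata(path)) == 116


class TestFilterTaxa:
    def test_minimum_occurrence_count_gloss(self):
        """> 5% of 116 samples means at least 6 samples."""
        assert min_occurrence_count(116, 0.05) == 6

    def test_exact_fraction_still_strict(self):
        # 5% of 120 is exactly 6; "more than 5%" needs 7
        assert min_occurrence_count(120, 0.05) == 7

    def test_abundance_threshold_strict(self):
        rel = np.array([[0.0009] * 10, [0.0011] * 10, [0.9] * 10])
        m = cx.CommunityMatrix(taxa=["lo", "mid", "hi"],
                               samples=[f"s{i}" for i in range(10)],
                               rel_abundance=rel)
        f = cx.filter_taxa(m, min_occ_frac=0.05, min_max_abund=0.001)
        assert f.taxa == ["mid", "hi"]

    def test_occurrence_rule_optional_for_subnetworks(self):
        rel = np.zeros((2, 40))
        rel[0, 0] = 0.01  # present in 1 of 40 samples: fails > 5%
        rel[1, :] = 0.05
        m = cx.CommunityMatrix(taxa=["rare", "common"],
                               samples=[f"s{i}" for i in range(40)],
                               rel_abundance=rel)
        assert cx.filter_taxa(m).taxa == ["common"]
        assert cx.filter_taxa(m, apply_occurrence=False).taxa == [
            "rare", "common"]

    def test_all_removed_warns_and_returns_empty(self):
        rel = np.full((2, 10), 1e-5)
        m = cx.CommunityMatrix(taxa=["a", "b"],
                               samples=[f"s{i}" for i in range(10)],
                               rel_abundance=rel)
        with pytest.warns(UserWarning):
            f = cx.filter_taxa(m)
        assert f.n_taxa == 0 and f.n_samples == 10

    @given(f1=st.floats(0.0, 0.5), f2=st.floats(0.0, 0.5),
           a1=st.floats(0.0, 0.5), a2=st.floats(0.0, 0.5))
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_thresholds(self, default_sim, f1, f2, a1, a2):
        """Raising either threshold never adds taxa."""
        matrix, _, _ = default_sim
        lo_f, hi_f = sorted((f1, f2))
        lo_a, hi_a = sorted((a1, a2))
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            loose = set(cx.filter_taxa(matrix, min_occ_frac=lo_f,
                                       min_max_abund=lo_a).taxa)
            tight = set(cx.filter_taxa(matrix, min_occ_frac=hi_f,
                                       min_max_abund=hi_a).taxa)
        assert tight <= loose


class TestSalinityBins:
    @pytest.mark.parametrize("salinity,expected", [
        (0.1, "low"), (2.4, "low"), (2.45, "low"),
        (2.5, "intermediate"), (4.9, "intermediate"),
        (5.0, "high"), (40.0, "high"),
    ])
    def test_printed_bounds(self, salinity, expected):
        assert cx.assign_salinity_bin(salinity) == expected

    def test_partition_of_one_decimal_grid(self):
        """Every one-decimal salinity in [0.1, 40] maps to exactly one bin
        matching the printed ranges."""
        for tenth in range(1, 401):
            s = tenth / 10
            b = cx.assign_salinity_bin(s)
            if s <= 2.4:
                assert b == "low"
            elif s <= 4.9:
                assert b == "intermediate"
            else:
                assert b == "high"

    def test_negative_rejected(self):
        with pytest.raises(CommunityDataError):
            cx.assign_salinity_bin(-0.5)
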