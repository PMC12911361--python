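"""Count-table ingest, rarefaction, persistence and region assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from planktonet import data_model as dm


# ---------------------------------------------------------------------------
# AsvTable and reading
# ---------------------------------------------------------------------------

class TestReadAsvTable:
    def test_well_formed_table(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text("sample\tASV1\tASV2\ns1\t3\t4\ns2\t1\t0\ns3\t2\t2\n")
        table = dm.read_asv_table(path, marker="16S")
        assert table.n_samples == 3 and table.n_asvs == 2
        assert table.data.loc["s2", "ASV1"] == 1

    def test_duplicate_sample_id_names_the_id(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("sample\tASV1\ns1\t3\ns1\t4\n")
        with pytest.raises(dm.ValidationError, match="s1"):
            dm.read_asv_table(path)

    def test_empty_file_reports_no_samples(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("sample\tASV1\n")
        with pytest.raises(dm.ValidationError, match="no samples"):
            dm.read_asv_table(path)

    def test_non_numeric_cell_is_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample\tASV1\ns1\tok\n")
        with pytest.raises(dm.ValidationError, match="ASV1"):
            dm.read_asv_table(path)

    def test_asv_rows_are_transposed(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("id\ts1\ts2\nASV1\t3\t1\nASV2\t4\t0\n")
        table = dm.read_asv_table(path)
        assert table.sample_ids == ["s1", "s2"]

    def test_negative_count_rejected(self):
        df = pd.DataFrame([[1, -2]], index=["s1"], columns=["a", "b"])
        with pytest.raises(dm.ValidationError, match="negative"):
            dm.AsvTable(df)


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

class TestRarefy:
    def test_row_totals_hit_depth_exactly(self, tiny_table):
        out = dm.rarefy(tiny_table, depth=5, seed=0)
        assert (out.sample_totals() == 5).all()

    def test_sample_at_depth_unchanged(self):
        table = dm.AsvTable(pd.DataFrame([[3, 2]], index=["s"], columns=["a", "b"]))
        out = dm.rarefy(table, depth=5, seed=0)
        assert out.data.loc["s"].tolist() == [3, 2]

    def test_single_taxon_sample(self):
        table = dm.AsvTable(pd.DataFrame([[10, 0]], index=["s"], columns=["a", "b"]))
        out = dm.rarefy(table, depth=5, seed=0)
        assert out.data.loc["s"].tolist() == [5, 0]

    def test_matches_hypergeometric_expectation(self):
        # counts (6, 4) at depth 5: first coordinate ~ Hypergeom(10, 6, 5)
        table = dm.AsvTable(pd.DataFrame([[6, 4]], index=["s"], columns=["a", "b"]))
        exact_mean = hypergeom(10, 6, 5).mean()
        draws = [dm.rarefy(table, depth=5, seed=s).data.iloc[0, 0] for s in range(4000)]
        se = hypergeom(10, 6, 5).std() / np.sqrt(len(draws))
        assert abs(np.mean(draws) - exact_mean) < 4 * se

    def test_shallow_samples_dropped_with_warning(self, tiny_table):
        with pytest.warns(UserWarning, match="dropped"):
            out = dm.rarefy(tiny_table, depth=11, seed=0)
        assert "s3" not in out.sample_ids  # total 10 < depth 11 drops
        assert set(out.sample_ids) == {"s1", "s2"}

    def test_depth_above_all_totals_errors(self, tiny_table):
        with pytest.raises(ValueError, match="depth"):
            dm.rarefy(tiny_table, depth=100, seed=0)

    def test_preserves_support(self, rng):
        counts = rng.integers(0, 30, size=(8, 12))
        counts[:, 3] = 0
        table = dm.AsvTable(pd.DataFrame(
            counts, index=[f"s{i}" for i in range(8)],
            columns=[f"a{j}" for j in range(12)]))
        out = dm.rarefy(table, seed=5)
        before = table.data.loc[out.sample_ids] > 0
        assert not ((out.data > 0) & ~before).any().any()


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_relative_abundance_rows_sum_to_one(seed):
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 100, size=(5, 7)) + np.eye(5, 7, dtype=int)
    table = dm.AsvTable(pd.DataFrame(
        counts, index=[f"s{i}" for i in range(5)], columns=[f"a{j}" for j in range(7)]))
    rel = dm.relative_abundance(table)
    np.testing.assert_allclose(rel.sum(axis=1), 1.0, atol=1e-12)


def test_relative_abundance_cases():
    table = dm.AsvTable(pd.DataFrame([[5, 5], [10, 0]], index=["s1", "s2"],
                                     columns=["a", "b"]))
    rel = dm.relative_abundance(table)
    assert rel.loc["s1"].tolist() == [0.5, 0.5]
    assert rel.loc["s2"].tolist() == [1.0, 0.0]
    zero = dm.AsvTable(pd.DataFrame([[1, 1], [0, 0]], index=["s1", "s2"],
                                    columns=["a", "b"]))
    with pytest.raises(ValueError, match="zero-total"):
        dm.relative_abundance(zero)


# ---------------------------------------------------------------------------
# Taxonomy groups
# ---------------------------------------------------------------------------

class TestAssignGroups:
    @pytest.mark.parametrize(
        "lineage,expected",
        [
            (["Eukaryota", "Stramenopiles", "Ochrophyta", "Pelagophyceae",
              "Pelagomonas"], "Stramenopiles_photosynthetic"),
            (["Bacteria", "Cyanobacteria", "Cyanobiaceae", "Prochlorococcus"],
             "Prochlorococcus"),
            (["Eukaryota", "Opisthokonta", "Metazoa"], "Other"),
            (["Eukaryota", "Stramenopiles", "Ochrophyta", "MAST-1"], "Other"),
            (["Eukaryota", "Archaeplastida", "Chlorophyta", "Bathycoccus"],
             "Archaeplastida"),
            (["Eukaryota", "Alveolata", "Dinoflagellata", "Dinophyceae"],
             "Dinoflagellata"),
            (["Eukaryota", "Haptophyta", "Phaeocystis"], "Haptophyta"),
            (["Bacteria", "Cyanobacteria", "Synechococcus"], "Synechococcus"),
        ],
    )
    def test_lineage_mapping(self, lineage, expected):
        tax = dm.TaxonomyMap(ranks={"x": lineage})
        assert dm.assign_groups(tax)["x"] == expected

    def test_qiime_style_file_roundtrip(self, tmp_path):
        path = tmp_path / "tax.tsv"
        path.write_text(
            "Feature ID\tTaxon\n"
            "ASV1\td__Bacteria;p__Cyanobacteria;g__Prochlorococcus\n"
            "ASV2\td__Eukaryota;p__Haptophyta;g__Phaeocystis\n"
        )
        tax = dm.read_taxonomy(path)
        assert tax.group_of("ASV1") == "Prochlorococcus"
        assert tax.group_of("ASV2") == "Haptophyta"
        assert tax.group_of("ASV_missing") == "Other"


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def _year_tables(counts_by_year):
    out = {}
    for year, rows in counts_by_year.items():
        out[year] = dm.AsvTable(pd.DataFrame(
            rows, index=[f"{year}s{i}" for i in range(len(rows))],
            columns=["a1", "a2", "a3"]))
    return out


class TestClassifyPersistence:
    def test_all_three_years_is_persistent(self):
        tables = _year_tables({
            2016: [[1, 1, 0]], 2017: [[2, 0, 0]], 2019: [[5, 3, 0]]})
        with pytest.warns(UserWarning, match="absent"):
            labels = dm.classify_persistence(tables)
        assert labels.labels["a1"] == "persistent"
        assert labels.labels["a2"] == "ephemeral"
        assert "a3" not in labels.labels.index
        assert labels.years_detected["a2"] == frozenset({2016, 2019})

    def test_fewer_than_three_years_errors(self):
        tables = _year_tables({2016: [[1, 1, 1]], 2017: [[1, 1, 1]]})
        with pytest.raises(ValueError, match="three years"):
            dm.classify_persistence(tables)

    def test_invariant_to_sample_order_and_duplication(self):
        tables = _year_tables({
            2016: [[1, 0, 2], [0, 1, 0]], 2017: [[2, 2, 0]], 2019: [[5, 0, 1]]})
        base = dm.classify_persistence(tables).labels
        shuffled = {y: dm.AsvTable(t.data.iloc[::-1]) for y, t in tables.items()}
        assert dm.classify_persistence(shuffled).labels.sort_index().equals(
            base.sort_index())
        doubled = {
            y: dm.AsvTable(pd.concat([t.data, t.data.set_axis(
                [f"{i}_dup" for i in t.data.index])]))
            for y, t in tables.items()
        }
        assert dm.classify_persistence(doubled).labels.sort_index().equals(
            base.sort_index())


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

class TestAssignRegion:
    @pytest.mark.parametrize(
        "salinity,chlorophyll,expected",
        [(35.1, 0.05, "NPSG"), (34.0, 0.30, "NTZ"), (34.0, 0.10, "STZ")],
    )
    def test_hydrography_rules(self, salinity, chlorophyll, expected):
        meta = pd.DataFrame({"salinity": [salinity], "chlorophyll": [chlorophyll]},
                            index=["s"])
        assert dm.assign_region(meta)["s"] == expected

    def test_front_latitude_fallback(self):
        meta = pd.DataFrame(
            {"year": [2016, 2016, 2016], "latitude": [30.0, 33.0, 38.0]},
            index=["s1", "s2", "s3"])
        regions = dm.assign_region(meta, front_latitudes={2016: (32.3, 35.0)})
        assert regions.tolist() == ["NPSG", "STZ", "NTZ"]

    def test_unassigned_with_warning(self):
        meta = pd.DataFrame({"latitude": [30.0]}, index=["s"])
        with pytest.warns(UserWarning, match="unassigned"):
            regions = dm.assign_region(meta)
        assert regions["s"] == "unassigned"

    def test_complete_hydrography_partitions(self, rng):
        meta = pd.DataFrame({
            "salinity": rng.uniform(33.5, 35.5, 50),
            "chlorophyll": rng.uniform(0.01, 0.5, 50),
        }, index=[f"s{i}" for i in range(50)])
        regions = dm.assign_region(meta)
        assert set(regions) <= {"NPSG", "STZ", "NTZ"}


def test_depth_bins_cover_strata():
    assert dm.depth_bin(10) == "0-15"
    assert dm.depth_bin(60) == "45-75"
    assert dm.depth_bin(100) == "90-125"
    assert dm.depth_bin(30) in dm.DEPTH_BIN_LABELS
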