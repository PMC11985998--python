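"""Reading, cleaning and reshaping of species-occurrence records."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aliendrivers.records import (
    SchemaError,
    SpeciesRecord,
    annual_first_records,
    build_occurrence_matrix,
    clean_records,
    composition_summary,
    normalize_species_name,
    read_species_records,
    records_to_frame,
)

EUROPE = {"Austria", "France", "Germany", "Spain"}


class TestReading:
    def test_three_valid_rows_give_three_records(self, records_csv):
        path = records_csv(
            [
                "Abies alba,Tracheophyta,Pinopsida,Austria,1900,ESTABLISHED,PRESENT",
                "Rattus rattus,Chordata,Mammalia,France,1850,ESTABLISHED,PRESENT",
                "Apis cerana,Arthropoda,Insecta,Spain,1990,ESTABLISHED,PRESENT",
            ]
        )
        records = read_species_records(path)
        assert len(records) == 3
        assert records[0].species_name == "abies alba"
        assert records[1].first_record_year == 1850

    def test_missing_status_column_names_it(self, records_csv):
        path = records_csv(
            ["Abies alba,Tracheophyta,Pinopsida,Austria,1900,ESTABLISHED"],
            header="scientificName,phylum,class,country,firstRecordYear,"
            "degreeOfEstablishment",
        )
        with pytest.raises(SchemaError, match="occurrenceStatus"):
            read_species_records(path)

    def test_fractional_year_kept_with_missing_year(self, records_csv, caplog):
        path = records_csv(
            ["Abies alba,Tracheophyta,Pinopsida,Austria,18.95,ESTABLISHED,PRESENT"]
        )
        with caplog.at_level("WARNING"):
            records = read_species_records(path)
        assert len(records) == 1
        assert records[0].first_record_year is None
        assert any("year" in m for m in caplog.messages)

    def test_out_of_range_year_becomes_missing(self, records_csv):
        path = records_csv(
            ["Abies alba,Tracheophyta,Pinopsida,Austria,999,ESTABLISHED,PRESENT"]
        )
        assert read_species_records(path)[0].first_record_year is None

    def test_synonym_map_replaces_normalized_name(self):
        assert (
            normalize_species_name("  Abies   ALBA ", {"abies alba": "abies nobilis"})
            == "abies nobilis"
        )

    def test_roundtrip_through_frame(self, record_factory, tmp_path):
        records = [record_factory(), record_factory(species="bison bonasus")]
        path = tmp_path / "out.csv"
        records_to_frame(records).to_csv(path, index=False)
        again = read_species_records(path)
        assert [r.species_name for r in again] == [r.species_name for r in records]


class TestCleaning:
    def test_absent_only_pair_removed_and_counted(self, record_factory):
        records = [
            record_factory(species="x y", degree="ABSENT", status="ABSENT"),
            record_factory(species="a b"),
        ]
        cleaned, report = clean_records(records, EUROPE)
        assert [r.species_name for r in cleaned] == ["a b"]
        assert report.n_removed_casual_absent == 1

    def test_casual_with_established_elsewhere_survives(self, record_factory):
        # same species-country pair listed CASUAL in one row, ESTABLISHED in
        # another: "listed only as" does not apply, both rows stay (one after
        # dedup)
        records = [
            record_factory(degree="CASUAL", status="CASUAL", year=1991),
            record_factory(degree="ESTABLISHED", status="PRESENT", year=1990),
        ]
        cleaned, report = clean_records(records, EUROPE)
        assert report.n_removed_casual_absent == 0
        assert len(cleaned) == 1
        assert cleaned[0].first_record_year == 1990  # earliest representative

    def test_non_european_removed(self, record_factory):
        records = [record_factory(country="Japan"), record_factory()]
        cleaned, report = clean_records(records, EUROPE)
        assert report.n_removed_non_european == 1
        assert len(cleaned) == 1

    def test_duplicate_pair_collapses(self, record_factory):
        records = [record_factory(), record_factory()]
        cleaned, report = clean_records(records, EUROPE)
        assert len(cleaned) == 1
        assert report.n_removed_duplicates == 1

    def test_idempotence(self, record_factory):
        records = [
            record_factory(),
            record_factory(),
            record_factory(species="x y", degree="CASUAL", status="CASUAL"),
            record_factory(country="Japan"),
        ]
        once, _ = clean_records(records, EUROPE)
        twice, report2 = clean_records(once, EUROPE)
        assert once == twice
        assert report2.n_input == report2.n_output

    def test_empty_input_is_not_an_error(self):
        cleaned, report = clean_records([], EUROPE)
        assert cleaned == [] and report.n_input == report.n_output == 0

    @given(perm=st.permutations(list(range(6))))
    @settings(max_examples=30, deadline=None)
    def test_order_independence(self, perm):
        records = [
            SpeciesRecord("a b", "P", "C", "Austria", 1990, "ESTABLISHED", "PRESENT"),
            SpeciesRecord("a b", "P", "C", "Austria", 1985, "ESTABLISHED", "PRESENT"),
            SpeciesRecord("c d", "P", "C", "France", None, "CASUAL", "CASUAL"),
            SpeciesRecord("e f", "P", "C", "Japan", 2000, "ESTABLISHED", "PRESENT"),
            SpeciesRecord("g h", "Q", "D", "Spain", 1970, "ESTABLISHED", "PRESENT"),
            SpeciesRecord("a b", "P", "C", "France", 1995, "ESTABLISHED", "PRESENT"),
        ]
        shuffled = [records[i] for i in perm]
        cleaned_a, _ = clean_records(records, EUROPE)
        cleaned_b, _ = clean_records(shuffled, EUROPE)
        assert cleaned_a == cleaned_b

    def test_every_removal_attributed_once(self, record_factory):
        records = [
            record_factory(),
            record_factory(),  # duplicate
            record_factory(species="x y", degree="ABSENT", status="ABSENT"),
            record_factory(species="z w", country="Japan"),
        ]
        _, report = clean_records(records, EUROPE)
        assert (
            report.n_removed_casual_absent
            + report.n_removed_non_european
            + report.n_removed_duplicates
            == report.n_input - report.n_output
        )


class TestOccurrenceMatrix:
    def test_shared_species_row_sums(self, record_factory):
        records = [
            record_factory(species="a b", country="Austria"),
            record_factory(species="c d", country="Austria"),
            record_factory(species="a b", country="France"),
            record_factory(species="e f", country="France"),
        ]
        m = build_occurrence_matrix(records)
        assert m.presence.shape == (2, 3)
        assert m.richness.tolist() == [2, 2]

    def test_richness_matches_distinct_species_counts(self, small_dataset):
        m = build_occurrence_matrix(small_dataset.records)
        for country in m.countries:
            distinct = len(
                {
                    r.species_name
                    for r in small_dataset.records
                    if r.country == country
                }
            )
            assert m.richness[country] == distinct

    def test_order_invariance(self, record_factory, rng):
        records = [
            record_factory(species=s, country=c)
            for s in ("a b", "c d", "e f")
            for c in ("Austria", "France")
        ]
        m1 = build_occurrence_matrix(records)
        m2 = build_occurrence_matrix(
            [records[i] for i in rng.permutation(len(records))]
        )
        assert np.array_equal(m1.presence, m2.presence)
        assert m1.countries == m2.countries and m1.species == m2.species

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            build_occurrence_matrix([])


class TestAnnualSeries:
    def test_gap_years_filled_with_zero(self, record_factory):
        records = [
            record_factory(species="a b", year=2000),
            record_factory(species="c d", year=2000),
            record_factory(species="e f", year=2003),
        ]
        s = annual_first_records(records, "Austria")
        assert s.years.tolist() == [2000, 2001, 2002, 2003]
        assert s.counts.tolist() == [2, 0, 0, 1]

    def test_single_record_gives_length_one(self, record_factory):
        s = annual_first_records([record_factory(year=1995)], "Austria")
        assert len(s.years) == 1 and s.counts.tolist() == [1]

    def test_counts_conserved_across_countries(self, small_dataset):
        records = small_dataset.records
        dated = sum(1 for r in records if r.first_record_year is not None)
        total = 0
        for country in {r.country for r in records}:
            total += annual_first_records(records, country).counts.sum()
        assert total == dated

    def test_no_dated_records_errors(self, record_factory):
        with pytest.raises(ValueError, match="no dated records"):
            annual_first_records([record_factory(year=None)], "Austria")


class TestComposition:
    def test_distinct_species_pooled_across_countries(self, record_factory):
        records = [
            record_factory(species="a b", phylum="Tracheophyta", country="Austria"),
            record_factory(species="a b", phylum="Tracheophyta", country="France"),
            record_factory(species="c d", phylum="Arthropoda"),
        ]
        table = composition_summary(records, "phylum")
        row = table.set_index("taxon")
        assert row.loc["Tracheophyta", "n_species"] == 1  # pooled, not 2
        assert row.loc["Arthropoda", "n_species"] == 1

    @pytest.mark.parametrize("level", ["phylum", "class"])
    def test_percentages_sum_to_100(self, small_dataset, level):
        table = composition_summary(small_dataset.records, level)
        assert table["percent"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_single_species_is_100_percent(self, record_factory):
        table = composition_summary([record_factory()], "class")
        assert len(table) == 1 and table["percent"].iloc[0] == 100.0

    def test_missing_taxonomy_bucketed_unassigned(self, record_factory):
        records = [record_factory(phylum=None), record_factory(species="c d")]
        table = composition_summary(records, "phylum")
        assert "Unassigned" in set(table["taxon"])
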