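from __future__ import annotations

import random

import pytest
from hypothesis import given, settings, strategies as st

from alienphylo import (
    Checklist,
    ChecklistError,
    SpeciesRecord,
    derive_assemblages,
    normalize_checklist,
    normalize_lifeform,
    read_checklist,
    tabulate_by,
    transition_rates,
    write_checklist,
)
from alienphylo.checklist import LIFEFORMS, PATHWAYS, STATUSES, TDWG_REGIONS


def make_record(name, status="casual", family="Asteraceae", lifeform="annual",
                origins=("america",), pathway="ornamental", genus="Genus"):
    return SpeciesRecord(
        species_name=name, family=family, genus=genus, lifeform=lifeform,
        origins=frozenset(origins), pathway=pathway, status=status,
    )


class TestReadChecklist:
    def test_round_trips_a_well_formed_file(self, checklist_csv):
        checklist = read_checklist(checklist_csv)
        assert len(checklist) == 6
        assert checklist.species_names[0] == "Eichhornia crassipes"
        # biennial survives reading; normalization is a separate step
        assert checklist.records[5].lifeform == "biennial"
        assert checklist.records[3].origins == {"europe", "temperate asia"}

    def test_duplicate_species_error_names_the_row(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "species,family,genus,lifeform,origin,pathway,status\n"
            "Eichhornia crassipes,Pontederiaceae,Eichhornia,perennial,america,ornamental,invasive\n"
            "Eichhornia crassipes,Pontederiaceae,Eichhornia,perennial,america,ornamental,invasive\n"
        )
        with pytest.raises(ChecklistError, match=r"row 2.*Eichhornia crassipes"):
            read_checklist(path)

    def test_unknown_status_error_lists_allowed_tokens(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "species,family,genus,lifeform,origin,pathway,status\n"
            "Avena sativa,Poaceae,Avena,annual,europe,food,weed\n"
        )
        with pytest.raises(ChecklistError, match="casual, naturalized, invasive"):
            read_checklist(path)

    def test_missing_column_is_an_error(self, tmp_path):
        path = tmp_path / "short.csv"
        path.write_text("species,family,genus,lifeform,origin,pathway\nx,f,g,annual,europe,food\n")
        with pytest.raises(ChecklistError, match="status"):
            read_checklist(path)

    def test_tokens_are_case_insensitive_and_extra_lifeforms_mapped(self, tmp_path):
        path = tmp_path / "mixed.csv"
        path.write_text(
            "species,family,genus,lifeform,origin,pathway,status\n"
            "Rosa sp,Rosaceae,Rosa,Shrub,Europe,Ornamental,Casual\n"
            "Lemna sp,Araceae,Lemna,AQUATIC,Temperate Asia,natural,naturalized\n"
        )
        checklist = read_checklist(path)
        assert checklist.records[0].lifeform == "woody"
        assert checklist.records[1].lifeform == "other"
        assert checklist.records[0].status == "casual"
        assert checklist.records[1].origins == {"temperate asia"}

    def test_write_read_round_trip_preserves_records(self, checklist_csv, tmp_path):
        checklist = read_checklist(checklist_csv)
        out = tmp_path / "rt.csv"
        write_checklist(checklist, out)
        assert read_checklist(out) == checklist


class TestNormalizeLifeform:
    @pytest.mark.parametrize(
        "given_lifeform,expected",
        [("biennial", "perennial"), ("annual", "annual"), ("perennial", "perennial"),
         ("woody", "woody"), ("other", "other")],
    )
    def test_folds_biennials_into_perennials_only(self, given_lifeform, expected):
        rec = make_record("X y", lifeform=given_lifeform)
        assert normalize_lifeform(rec).lifeform == expected

    def test_idempotent(self):
        rec = make_record("X y", lifeform="biennial")
        once = normalize_lifeform(rec)
        assert normalize_lifeform(once) == once


class TestDeriveAssemblages:
    def test_printed_casual_count_follows_from_totals(self):
        # 1686 alien of which 1198 naturalized of which 232 invasive
        records = tuple(
            make_record(
                f"sp{i:04d}",
                status="invasive" if i < 232 else "naturalized" if i < 1198 else "casual",
            )
            for i in range(1686)
        )
        sizes = derive_assemblages(Checklist(records)).sizes()
        assert sizes == {
            "alien": 1686, "casual": 488, "naturalized": 1198, "nni": 966, "invasive": 232,
        }

    def test_all_invasive_degenerates_to_empty_differences(self):
        records = tuple(make_record(f"s{i}", status="invasive") for i in range(5))
        assem = derive_assemblages(Checklist(records))
        assert assem.casual == frozenset() and assem.nni == frozenset()
        assert assem.alien == assem.naturalized == assem.invasive

    @given(statuses=st.lists(st.sampled_from(STATUSES), min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_nesting_and_partition_identities_always_hold(self, statuses):
        records = tuple(make_record(f"s{i}", status=s) for i, s in enumerate(statuses))
        a = derive_assemblages(Checklist(records))
        assert a.invasive <= a.naturalized <= a.alien
        assert a.casual == a.alien - a.naturalized
        assert a.nni == a.naturalized - a.invasive
        assert len(a.casual) + len(a.naturalized) == len(a.alien)
        assert len(a.nni) + len(a.invasive) == len(a.naturalized)


class TestTabulateBy:
    @pytest.fixture()
    def toy(self):
        records = (
            make_record("a 1", family="Asteraceae"),
            make_record("a 2", family="Asteraceae"),
            make_record("a 3", family="Asteraceae"),
            make_record("p 1", family="Poaceae"),
        )
        return Checklist(records)

    def test_family_proportions_are_direct_counts(self, toy):
        table = tabulate_by(toy, "family", toy.species_names)
        by_cat = dict(zip(table.category, table.proportion))
        assert by_cat == {"Asteraceae": 0.75, "Poaceae": 0.25}

    def test_multi_origin_species_counts_once_per_region(self):
        checklist = Checklist((make_record("m 1", origins=("america", "europe")),))
        table = tabulate_by(checklist, "origin", ["m 1"])
        assert dict(zip(table.category, table.proportion)) == {"america": 1.0, "europe": 1.0}

    def test_count_identities_per_field(self, toy):
        multi = Checklist(
            toy.records + (make_record("m 1", origins=("america", "europe", "africa")),)
        )
        members = multi.species_names
        for field_name in ("family", "lifeform", "pathway"):
            table = tabulate_by(multi, field_name, members)
            assert table["count"].sum() == len(members)
            assert abs(table.proportion.sum() - 1.0) < 1e-12
        origin = tabulate_by(multi, "origin", members)
        assert origin["count"].sum() >= len(members)

    def test_empty_assemblage_is_an_error(self, toy):
        with pytest.raises(ChecklistError, match="empty"):
            tabulate_by(toy, "family", [])


class TestTransitionRates:
    def test_direct_ratios(self):
        records = tuple(
            make_record(f"f{i}", family="Fabaceae",
                        status="invasive" if i < 4 else "naturalized")
            for i in range(10)
        )
        (rates,) = transition_rates(Checklist(records), ["Fabaceae"])
        assert rates.rate_nat == 1.0
        assert rates.rate_inv == 0.4

    def test_zero_naturalized_flags_invasion_rate_undefined(self):
        records = (make_record("c 1", family="Cactaceae", status="casual"),)
        (rates,) = transition_rates(Checklist(records), ["Cactaceae"])
        assert rates.rate_nat == 0.0
        assert rates.rate_inv is None

    def test_absent_family_is_an_error(self):
        records = (make_record("c 1"),)
        with pytest.raises(ChecklistError, match="Nothereaceae"):
            transition_rates(Checklist(records), ["Nothereaceae"])

    def test_matches_brute_force_row_filter_and_composition(self):
        rng = random.Random(7)
        families = ["Famae", "Fambe", "Famce"]
        records = tuple(
            make_record(f"s{i}", family=rng.choice(families), status=rng.choice(STATUSES))
            for i in range(120)
        )
        checklist = Checklist(records)
        for rates in transition_rates(checklist):
            rows = [r for r in records if r.family == rates.family]
            n_alien = len(rows)
            n_nat = sum(r.status in ("naturalized", "invasive") for r in rows)
            n_inv = sum(r.status == "invasive" for r in rows)
            assert (rates.n_alien, rates.n_naturalized, rates.n_invasive) == (
                n_alien, n_nat, n_inv,
            )
            if rates.rate_nat is not None and rates.rate_inv is not None:
                # composed rates recover the invasive count exactly
                assert round(rates.rate_nat * rates.rate_inv * n_alien) == n_inv


@given(
    data=st.lists(
        st.tuples(
            st.sampled_from(STATUSES),
            st.sampled_from(LIFEFORMS),
            st.sampled_from(PATHWAYS),
            st.sets(st.sampled_from(TDWG_REGIONS), min_size=1, max_size=3),
        ),
        min_size=1,
        max_size=40,
    )
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_normalized_checklists_survive_csv_round_trip(tmp_path_factory, data):
    records = tuple(
        make_record(f"Sp number{i}", status=s, lifeform=lf, pathway=pw, origins=og)
        for i, (s, lf, pw, og) in enumerate(data)
    )
    checklist = normalize_checklist(Checklist(records))
    path = tmp_path_factory.mktemp("rt") / "c.csv"
    write_checklist(checklist, path)
    assert read_checklist(path) == checklist
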