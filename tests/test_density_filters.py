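"""Group-size, singleton-species, genus-pruning and leading-gene filters."""

import itertools

import pytest

from phylopipe.density_filters import (
    Dataset,
    GeneGroup,
    drop_singleton_species,
    drop_small_groups,
    load_dataset,
    prune_genera,
    reduce_to_leading_gene,
    reinclude_families,
    save_dataset,
)

from conftest import make_entry, make_group


class TestDropSmallGroups:
    @pytest.mark.parametrize("n_species, kept", [(3, False), (4, True), (5, True)])
    def test_boundary_at_four_species(self, n_species, kept):
        g = make_group("COX1", {f"Sp_{i}": "ACGT" for i in range(n_species)})
        out = drop_small_groups(Dataset((g,)))
        assert bool(out.groups) is kept

    def test_empty_dataset_passes_through(self):
        out = drop_small_groups(Dataset(()))
        assert out.groups == ()

    def test_exclusion_log_matches_removed_entries(self):
        g3 = make_group("ND2", {f"Sp_{i}": "ACGT" for i in range(3)})
        g4 = make_group("COX1", {f"Sp_{i}": "ACGT" for i in range(4)})
        before = Dataset((g3, g4))
        out = drop_small_groups(before)
        assert len(out.exclusion_log) == before.n_entries - out.n_entries == 3


class TestDropSingletonSpecies:
    def _dataset(self):
        g1 = make_group("COX1", {"Sp_a": "A" * 8, "Sp_b": "A" * 8, "Sp_c": "A" * 8,
                                 "Sp_d": "A" * 8, "Lonely_sp": "A" * 8})
        g2 = make_group("RRNS", {"Sp_a": "C" * 8, "Sp_b": "C" * 8,
                                 "Sp_c": "C" * 8, "Sp_d": "C" * 8})
        return Dataset((g1, g2))

    def test_single_occurrence_species_removed(self):
        out = drop_singleton_species(self._dataset())
        assert "Lonely_sp" not in out.species
        assert {"Sp_a", "Sp_b", "Sp_c", "Sp_d"} <= set(out.species)

    def test_multi_occurrence_species_kept_everywhere(self):
        out = drop_singleton_species(self._dataset())
        for g in out.groups:
            assert "Sp_a" in g.species

    def test_removal_cascades_into_small_group_rule(self):
        # removing the singleton leaves COX1 with 3 species -> COX1 deleted too
        g1 = make_group("COX1", {"Sp_a": "A", "Sp_b": "A", "Sp_c": "A", "Lonely_sp": "A"})
        g2 = make_group("RRNS", {"Sp_a": "C", "Sp_b": "C", "Sp_c": "C", "Sp_d": "C",
                                 "Sp_e": "C"})
        g3 = make_group("RRNL", {"Sp_a": "G", "Sp_b": "G", "Sp_c": "G", "Sp_d": "G",
                                 "Sp_e": "G"})
        out = drop_singleton_species(Dataset((g1, g2, g3)))
        assert [g.gene_label for g in out.groups] == ["RRNS", "RRNL"]

    def test_log_cardinality_reconciles(self):
        before = self._dataset()
        out = drop_singleton_species(before)
        assert len(out.exclusion_log) == before.n_entries - out.n_entries

    def test_fixpoint_terminates_and_is_stable(self):
        ds = self._dataset()
        out = drop_singleton_species(ds, fixpoint=True)
        again = drop_singleton_species(out, fixpoint=True)
        assert again.n_entries == out.n_entries


def _ranking_oracle(ds, members, cap):
    """Brute-force oracle: best `cap` species under (count, length, name)."""
    def key(sp):
        entries = [e for g in ds.groups for e in g.entries if e.species == sp]
        return (-len(entries), -sum(len(e.residues) for e in entries), sp)
    return set(sorted(members, key=key)[:cap])


class TestPruneGenera:
    def _genus_dataset(self, n, lengths=None):
        # every species needs >= 2 sequences to be realistic post-singleton
        species = {f"Apis_sp{i:02d}": "A" * (lengths[i] if lengths else 10 + i)
                   for i in range(n)}
        g1 = make_group("COX1", species)
        g2 = make_group("RRNS", {sp: "C" * 5 for sp in list(species)[: max(4, n // 2)]})
        return Dataset((g1, g2))

    def test_rich_genus_pruned_to_cap_by_sequence_count(self):
        ds = self._genus_dataset(20)
        out = prune_genera(ds, max_species=15)
        kept = set(out.species)
        assert len(kept) == 15
        assert kept == _ranking_oracle(ds, ds.species, 15)

    def test_genus_at_cap_unchanged(self):
        ds = self._genus_dataset(15)
        out = prune_genera(ds, max_species=15)
        assert out.species == ds.species
        assert out.exclusion_log == ds.exclusion_log

    def test_length_breaks_count_ties(self):
        # 16 species all with one sequence; competition for the last slots
        # decided by total residue length, oracle-checked
        species = {f"Bombus_sp{i:02d}": "A" * (900 if i % 2 else 400) for i in range(16)}
        ds = Dataset((make_group("COX1", species),))
        out = prune_genera(ds, max_species=15)
        assert set(out.species) == _ranking_oracle(ds, ds.species, 15)
        dropped = set(ds.species) - set(out.species)
        (loser,) = dropped
        assert len(ds.groups[0].entry_for(loser).residues) == 400

    def test_species_without_epithet_is_its_own_genus(self):
        ds = Dataset((make_group("COX1", {"Weirdtaxon": "A" * 4,
                                          "Apis_sp1": "A" * 4}),))
        out = prune_genera(ds, max_species=1)
        assert set(out.species) == {"Weirdtaxon", "Apis_sp1"}


class TestReduceToLeadingGene:
    def test_species_outside_leading_group_removed_everywhere(self):
        a = make_group("COX1", {f"Sp_{i}": "A" for i in range(5)})
        b = make_group("RRNS", {"Sp_0": "C", "Sp_1": "C", "Other_sp": "C"})
        out = reduce_to_leading_gene(Dataset((a, b)))
        assert set(out.species) == {f"Sp_{i}" for i in range(5)}
        assert "Other_sp" not in out.species

    def test_identical_species_sets_unchanged(self):
        a = make_group("COX1", {f"Sp_{i}": "A" for i in range(4)})
        b = make_group("RRNS", {f"Sp_{i}": "C" for i in range(4)})
        ds = Dataset((a, b))
        out = reduce_to_leading_gene(ds)
        assert out.species == ds.species

    def test_tie_goes_to_alphabetical_gene_label(self):
        a = make_group("ZETA", {f"Sp_{i}": "A" for i in range(5)})
        b = make_group("ALPHA", {f"Qq_{i}": "C" for i in range(5)})
        out = reduce_to_leading_gene(Dataset((a, b)))
        assert set(out.species) == {f"Qq_{i}" for i in range(5)}

    def test_empty_dataset_is_an_error(self):
        with pytest.raises(ValueError):
            reduce_to_leading_gene(Dataset(()))


class TestReincludeFamilies:
    def _pool(self):
        entries = {}
        for i in range(5):
            entries[f"Rare_sp{i}"] = "A" * (10 * (i + 1))
        g1 = make_group("COX1", entries, family="Raridae")
        g2 = make_group("RRNS", {"Rare_sp4": "C" * 50, "Rare_sp3": "C" * 5},
                        family="Raridae")
        return Dataset((g1, g2))

    def _core(self):
        return Dataset((make_group("COX1", {f"Core_sp{i}": "A" * 20 for i in range(4)}),))

    def test_two_best_represented_species_added(self):
        out = reinclude_families(self._core(), self._pool(), ["Raridae"])
        added = set(out.species) - set(self._core().species)
        # sp4 and sp3 have two sequences each; others only one
        assert added == {"Rare_sp4", "Rare_sp3"}
        assert out.needs_composition_retest

    def test_single_candidate_family_adds_that_one(self):
        pool = Dataset((make_group("COX1", {"Solo_sp": "A" * 9}, family="Solidae"),))
        out = reinclude_families(self._core(), pool, ["Solidae"])
        assert "Solo_sp" in out.species

    def test_family_already_in_core_adds_nothing(self):
        core = self._core()
        pool = self._pool()
        # all Raridae species already in the core
        core_with = Dataset((make_group("COX1",
                                        {f"Rare_sp{i}": "A" for i in range(5)},
                                        family="Raridae"),))
        out = reinclude_families(core_with, pool, ["Raridae"])
        assert out.species == core_with.species

    def test_absent_family_skipped(self):
        out = reinclude_families(self._core(), self._pool(), ["Ghostidae"])
        assert out.species == self._core().species


class TestDatasetRoundTrip:
    def test_save_load_preserves_groups_and_log(self, tmp_path, simple_dataset):
        ds = drop_small_groups(simple_dataset)
        save_dataset(ds, tmp_path / "ds")
        back = load_dataset(tmp_path / "ds")
        assert {g.gene_label for g in back.groups} == {g.gene_label for g in ds.groups}
        assert back.exclusion_log == ds.exclusion_log
        for g in ds.groups:
            other = next(b for b in back.groups if b.gene_label == g.gene_label)
            assert {(e.species, e.residues) for e in other.entries} == {
                (e.species, e.residues) for e in g.entries
            }
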