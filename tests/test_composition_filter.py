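"""Chi-square base-composition homogeneity filtering against textbook oracles."""

import random

import numpy as np
import pytest
from scipy.stats import chisquare

from phylopipe.composition_filter import (
    base_composition,
    chi2_homogeneity,
    composition_partition,
    second_pass,
)
from phylopipe.density_filters import GeneGroup
from phylopipe.fixtures import make_composition_scenario

from conftest import make_entry, make_group


def oracle_stats(counts_by_species, included):
    """Independent textbook goodness-of-fit recomputation via scipy.chisquare."""
    freqs = [np.array(counts_by_species[s]) / sum(counts_by_species[s])
             for s in included if sum(counts_by_species[s]) > 0]
    mean = np.mean(freqs, axis=0)
    out = {}
    for s in included:
        counts = np.array(counts_by_species[s])
        expected = counts.sum() * mean
        stat, p = chisquare(counts, f_exp=expected, ddof=0)
        out[s] = (stat, p)
    return out


def oracle_filter(counts_by_species, alpha=0.05):
    """Full independent re-run of the iterative exclusion procedure."""
    included = sorted(s for s in counts_by_species if sum(counts_by_species[s]) > 0)
    excluded = []
    while True:
        stats = oracle_stats(counts_by_species, included)
        failing = [s for s in included if stats[s][1] < alpha]
        if not failing or len(included) <= 1:
            return set(included), set(excluded)
        worst = min(failing, key=lambda s: (stats[s][1], -stats[s][0], s))
        included.remove(worst)
        excluded.append(worst)
        if len(included) < 2:
            return set(included), set(excluded)


class TestBaseComposition:
    @pytest.mark.parametrize(
        "residues, expected",
        [("ACGT", (1, 1, 1, 1)), ("AAAA--NN", (4, 0, 0, 0)), ("NNN--?", (0, 0, 0, 0))],
    )
    def test_counts_ignore_gaps_and_ambiguity(self, residues, expected):
        assert base_composition(make_entry("Sp_a", residues)) == expected


class TestChi2Homogeneity:
    def test_identical_compositions_all_pass_with_zero_statistic(self):
        group = make_group("RRNS", {f"Sp_{i}": "ACGT" * 25 for i in range(6)})
        report = chi2_homogeneity(group)
        assert report.excluded == frozenset()
        assert report.iterations == 1
        assert all(r.chi2 == 0.0 for r in report.per_sequence)

    def test_all_g_sequence_excluded_from_uniform_group(self):
        rows = {f"Sp_{i:02d}": "ACGT" * 100 for i in range(10)}
        rows["Deviant_sp"] = "G" * 400
        report = chi2_homogeneity(make_group("RRNS", rows))
        assert report.excluded == {"Deviant_sp"}
        assert report.homogeneous == frozenset(rows) - {"Deviant_sp"}
        deviant = next(r for r in report.per_sequence if r.species == "Deviant_sp")
        assert deviant.chi2 > 7.815  # chi2 critical value at df=3, alpha=0.05

    def test_statistic_matches_scipy_oracle_to_1e9(self):
        rng = random.Random(12)
        rows = {
            f"Sp_{i:02d}": "".join(rng.choice("ACGT") for _ in range(300))
            for i in range(8)
        }
        report = chi2_homogeneity(make_group("RRNS", rows))
        counts = {r.species: r.counts for r in report.per_sequence}
        oracle = oracle_stats(counts, sorted(report.homogeneous))
        for r in report.per_sequence:
            if r.species in report.homogeneous:
                stat, p = oracle[r.species]
                assert r.chi2 == pytest.approx(stat, rel=1e-9)
                assert r.p_value == pytest.approx(p, rel=1e-9)

    def test_symmetric_pair_passes_or_fails_together(self):
        # compositions mirror-symmetric about the mean -> identical statistics
        a = "A" * 60 + "C" * 40 + "G" * 50 + "T" * 50
        b = "A" * 40 + "C" * 60 + "G" * 50 + "T" * 50
        report = chi2_homogeneity(make_group("RRNS", {"Sp_a": a, "Sp_b": b}))
        rows = {r.species: r for r in report.per_sequence}
        assert rows["Sp_a"].chi2 == pytest.approx(rows["Sp_b"].chi2, rel=1e-12)
        assert report.homogeneous == {"Sp_a", "Sp_b"} or report.excluded

    def test_homogeneous_output_is_a_fixed_point(self):
        group, _ = make_composition_scenario(4)
        report = chi2_homogeneity(group)
        survivors = group.subset(set(report.homogeneous))
        again = chi2_homogeneity(survivors)
        assert again.excluded == frozenset()
        assert again.homogeneous == report.homogeneous

    def test_exclusion_set_matches_full_oracle_rerun(self):
        for seed in range(10):
            group, _ = make_composition_scenario(seed, n_homogeneous=12, n_outliers=2)
            counts = {e.species: base_composition(e) for e in group.entries}
            oracle_in, oracle_out = oracle_filter(counts)
            report = chi2_homogeneity(group)
            assert set(report.homogeneous) == oracle_in
            assert set(report.excluded) == oracle_out

    def test_order_permutation_does_not_change_result(self):
        group, _ = make_composition_scenario(9, n_homogeneous=10, n_outliers=2)
        base = chi2_homogeneity(group)
        rng = random.Random(0)
        entries = list(group.entries)
        for _ in range(3):
            rng.shuffle(entries)
            shuffled = GeneGroup(group.gene_label, tuple(entries), alphabet="nucleotide")
            report = chi2_homogeneity(shuffled)
            assert report.homogeneous == base.homogeneous
            assert report.excluded == base.excluded

    def test_termination_bounded_by_group_size(self):
        group, _ = make_composition_scenario(2, n_homogeneous=8, n_outliers=4,
                                             outlier_gc_shift=0.4)
        report = chi2_homogeneity(group)
        assert report.iterations <= len(group.entries) + 1

    def test_untestable_group_passes_with_flag(self):
        group = make_group("RRNS", {"Sp_a": "ACGT" * 10})
        report = chi2_homogeneity(group)
        assert report.homogeneous == {"Sp_a"}
        assert "untestable_set" in report.flags


class TestSecondPass:
    def test_mutually_homogeneous_gc_rich_family_retained(self):
        # strong outliers relative to a uniform group, but consistent among
        # themselves: second pass keeps them as their own group
        group, outliers = make_composition_scenario(
            6, n_homogeneous=15, n_outliers=5, outlier_gc_shift=0.30,
            exact_frequencies=True,
        )
        g1, g2, discarded, (rep1, rep2) = composition_partition(group)
        assert set(rep1.excluded) == outliers
        assert g2.species == outliers
        assert discarded == frozenset()

    def test_all_outlier_group_forms_its_own_homogeneous_group(self):
        group, outliers = make_composition_scenario(
            8, n_homogeneous=0, n_outliers=6, outlier_gc_shift=0.30,
            exact_frequencies=True,
        )
        report = chi2_homogeneity(group)
        assert report.homogeneous == outliers
        assert report.excluded == frozenset()

    def test_single_excluded_sequence_retained_with_flag(self):
        group = make_group("RRNS", {"Sp_x": "G" * 100})
        report = second_pass(group)
        assert report.homogeneous == {"Sp_x"}
        assert "untestable_set" in report.flags

    def test_empty_excluded_set_gives_empty_report(self):
        empty = GeneGroup("RRNS", (), alphabet="nucleotide")
        report = second_pass(empty)
        assert report.homogeneous == frozenset()
        assert report.per_sequence == ()


class TestCalibration:
    def test_null_false_exclusion_rate_near_nominal_alpha(self):
        # under compositional homogeneity the per-sequence exclusion rate
        # stays at or below the nominal 5% level (slightly conservative
        # because each sequence contributes to the mean frequencies)
        total = excluded = 0
        for seed in range(60):
            group, _ = make_composition_scenario(
                seed, n_homogeneous=20, n_outliers=0, outlier_gc_shift=0.0
            )
            report = chi2_homogeneity(group)
            total += 20
            excluded += len(report.excluded)
        assert excluded / total < 0.07

    @pytest.mark.parametrize("seed", range(8))
    def test_planted_strong_outliers_always_excluded(self, seed):
        group, outliers = make_composition_scenario(seed)
        report = chi2_homogeneity(group)
        assert outliers <= report.excluded
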