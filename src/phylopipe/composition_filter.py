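"""Base-composition homogeneity filtering by iterated chi-square testing.

Sequences whose base composition deviates from the group mean violate the
stationarity assumed by standard substitution models and bias tree
inference.  Following the classic TREE-PUZZLE diagnostic, each sequence is
tested against the mean relative base frequencies of the currently included
sequences with a goodness-of-fit chi-square statistic (df = 3).  The most
deviant sequence is removed and the test repeated until the remaining group
is homogeneous.  Because the removed sequences may themselves form a second
homogeneous group (e.g. a consistently GC-rich clade), they are re-tested
with the same procedure; sequences failing both passes are discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import chi2 as chi2_dist

from phylopipe.density_filters import GeneGroup
from phylopipe.genbank_io import SeqEntry

ALPHA = 0.05
BASES = "ACGT"
_DF = 3  # four bases, frequencies constrained to sum to one


def base_composition(entry: SeqEntry) -> tuple[int, int, int, int]:
    """Counts of unambiguous A, C, G, T; gaps and ambiguity codes ignored."""
    if entry.alphabet != "nucleotide":
        raise TypeError("base composition is defined for nucleotide entries")
    up = entry.residues.upper()
    return tuple(up.count(b) for b in BASES)


@dataclass(frozen=True)
class CompositionRow:
    species: str
    counts: tuple[int, int, int, int]
    chi2: float
    p_value: float


@dataclass(frozen=True)
class CompositionReport:
    gene_label: str
    per_sequence: tuple[CompositionRow, ...]
    homogeneous: frozenset[str]
    excluded: frozenset[str]
    alpha: float
    iterations: int
    flags: tuple[str, ...] = ()


def _chi2_stat(counts: np.ndarray, mean_freq: np.ndarray) -> tuple[float, float]:
    n = counts.sum()
    if n == 0:
        return 0.0, 1.0
    expected = n * mean_freq
    stat = 0.0
    for o, e in zip(counts, expected):
        if e == 0.0:
            if o > 0:  # base absent from the group mean but present here
                return math.inf, 0.0
            continue
        stat += (o - e) ** 2 / e
    return float(stat), float(chi2_dist.sf(stat, _DF))


def _mean_frequencies(count_rows: list[np.ndarray]) -> np.ndarray:
    freqs = [c / c.sum() for c in count_rows if c.sum() > 0]
    if not freqs:
        return np.zeros(4)
    return np.mean(freqs, axis=0)


def chi2_homogeneity(group: GeneGroup, alpha: float = ALPHA) -> CompositionReport:
    """Iteratively exclude compositionally deviant sequences.

    Each round recomputes the mean relative base frequencies of the
    included sequences, tests every included sequence against them, and —
    if any fails at ``alpha`` — removes the single most deviant one
    (smallest p, ties to larger chi-square, then to the alphabetically
    first species).  Terminates when all included sequences pass.
    """
    if group.alphabet != "nucleotide":
        raise TypeError("composition homogeneity is tested on nucleotide groups")
    counts = {e.species: np.array(base_composition(e)) for e in group.entries}
    flags = tuple(
        f"untestable:{s}" for s in sorted(counts) if counts[s].sum() == 0
    )
    testable = [s for s in sorted(counts) if counts[s].sum() > 0]
    if len(testable) < 2:
        rows = tuple(
            CompositionRow(s, tuple(int(x) for x in counts[s]), 0.0, 1.0)
            for s in sorted(counts)
        )
        return CompositionReport(
            gene_label=group.gene_label,
            per_sequence=rows,
            homogeneous=frozenset(counts),
            excluded=frozenset(),
            alpha=alpha,
            iterations=0,
            flags=flags + ("untestable_set",),
        )

    included = list(testable)
    removed_rows: dict[str, CompositionRow] = {}
    iterations = 0
    while True:
        iterations += 1
        mean_freq = _mean_frequencies([counts[s] for s in included])
        stats = {s: _chi2_stat(counts[s], mean_freq) for s in included}
        failing = [s for s in included if stats[s][1] < alpha]
        if not failing:
            final_rows = {
                s: CompositionRow(s, tuple(int(x) for x in counts[s]), *stats[s])
                for s in included
            }
            break
        worst = min(failing, key=lambda s: (stats[s][1], -stats[s][0], s))
        removed_rows[worst] = CompositionRow(
            worst, tuple(int(x) for x in counts[worst]), *stats[worst]
        )
        included.remove(worst)
        if len(included) < 2:
            # the survivors trivially pass against their own mean
            mean_freq = _mean_frequencies([counts[s] for s in included])
            final_rows = {
                s: CompositionRow(
                    s, tuple(int(x) for x in counts[s]), *_chi2_stat(counts[s], mean_freq)
                )
                for s in included
            }
            break
    untestable_rows = {
        s: CompositionRow(s, tuple(int(x) for x in counts[s]), 0.0, 1.0)
        for s in counts
        if counts[s].sum() == 0
    }
    rows = {**final_rows, **removed_rows, **untestable_rows}
    homogeneous = frozenset(included) | frozenset(untestable_rows)
    return CompositionReport(
        gene_label=group.gene_label,
        per_sequence=tuple(rows[s] for s in sorted(rows)),
        homogeneous=homogeneous,
        excluded=frozenset(removed_rows),
        alpha=alpha,
        iterations=iterations,
        flags=flags,
    )


def second_pass(excluded: GeneGroup, alpha: float = ALPHA) -> CompositionReport:
    """Re-test the excluded sequences among themselves.

    Deviant clades (GC-rich families, for instance) can be internally
    homogeneous even though they fail against the full group; they are
    retained as a second homogeneous group.  Sequences failing again are
    the ones finally discarded.  A single leftover sequence is untestable
    and retained by convention, flagged.
    """
    if not excluded.entries:
        return CompositionReport(
            gene_label=excluded.gene_label,
            per_sequence=(),
            homogeneous=frozenset(),
            excluded=frozenset(),
            alpha=alpha,
            iterations=0,
            flags=("empty_set",),
        )
    return chi2_homogeneity(excluded, alpha)


def composition_partition(
    group: GeneGroup, alpha: float = ALPHA
) -> tuple[GeneGroup, GeneGroup, frozenset[str], tuple[CompositionReport, CompositionReport]]:
    """Full two-pass partition of a group.

    Returns (first homogeneous group, second homogeneous group, finally
    discarded species, the two reports).
    """
    report1 = chi2_homogeneity(group, alpha)
    group1 = group.subset(set(report1.homogeneous))
    excluded_group = group.subset(set(report1.excluded))
    report2 = second_pass(excluded_group, alpha)
    group2 = excluded_group.subset(set(report2.homogeneous))
    discarded = frozenset(report2.excluded)
    return group1, group2, discarded, (report1, report2)


def write_report(
    reports: tuple[CompositionReport, CompositionReport], path: str | Path
) -> None:
    """Tab-separated per-sequence report with the group-1/2/discarded verdict."""
    report1, report2 = reports
    verdict = {s: "group1" for s in report1.homogeneous}
    verdict.update({s: "group2" for s in report2.homogeneous})
    verdict.update({s: "discarded" for s in report2.excluded})
    rows = {r.species: r for r in report1.per_sequence}
    rows.update({r.species: r for r in report2.per_sequence if r.species not in report1.homogeneous})
    with open(path, "w") as fh:
        fh.write("species\tA\tC\tG\tT\tchi2\tp\tverdict\n")
        for s in sorted(rows):
            r = rows[s]
            a, c, g, t = r.counts
            fh.write(
                f"{s}\t{a}\t{c}\t{g}\t{t}\t{r.chi2:.6g}\t{r.p_value:.6g}\t{verdict.get(s, '?')}\n"
            )
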