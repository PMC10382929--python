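"""Pairwise karyotype comparison.

Detects minichromosomes that are identical between two karyotypes,
matches each minichromosome to its best counterpart by shared full-gene
content, and flags merger candidates (two ancestral minichromosomes
whose surviving genes are co-resident on one derived minichromosome).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .model import Karyotype, Minichromosome

__all__ = [
    "ComparisonReport",
    "ChromosomeMatching",
    "chromosomes_equal",
    "shared_gene_count",
    "match_chromosomes",
    "compare_karyotypes",
]


@dataclass(frozen=True)
class ComparisonReport:
    """Outcome of comparing two karyotypes minichromosome-by-minichromosome."""

    shared: list[tuple[str, str]]
    differing: list[tuple[str, str, list[str]]]
    unmatched_left: list[str]
    unmatched_right: list[str]

    @property
    def n_shared(self) -> int:
        return len(self.shared)

    def to_tsv(self) -> str:
        rows = ["left\tright\tcategory\tdiff"]
        for a, b in self.shared:
            rows.append(f"{a}\t{b}\tshared\t")
        for a, b, diffs in self.differing:
            rows.append(f"{a}\t{b}\tdiffering\t{'; '.join(diffs)}")
        for a in self.unmatched_left:
            rows.append(f"{a}\t\tunmatched\t")
        for b in self.unmatched_right:
            rows.append(f"\t{b}\tunmatched\t")
        return "\n".join(rows) + "\n"


@dataclass(frozen=True)
class ChromosomeMatching:
    """Ancestral-to-derived minichromosome correspondence."""

    pairs: list[tuple[str, str, int]]  # (ancestral label, derived label, shared genes)
    unmatched_ancestral: list[str]
    unmatched_derived: list[str]
    mergers: list[tuple[str, str]] = field(default_factory=list)  # (absorbed ancestral, derived)

    def derived_for(self, ancestral_label: str) -> str | None:
        for a, d, _ in self.pairs:
            if a == ancestral_label:
                return d
        return None

    def ancestral_for(self, derived_label: str) -> str | None:
        for a, d, _ in self.pairs:
            if d == derived_label:
                return a
        return None


def chromosomes_equal(m1: Minichromosome, m2: Minichromosome, include_pseudo: bool = False) -> bool:
    """True iff two minichromosomes carry the same genes in the same order.

    Comparison is on (name, orientation) of full genes; duplicate copies
    compare equal by name.  By default pseudo genes are ignored: the
    published shared-minichromosome count treats a minichromosome pair
    as "the same gene content and gene arrangement" even when one side
    carries an extra pseudo gene.  Set ``include_pseudo=True`` for a
    strict comparison that also requires pseudo genes to agree in name,
    status and position.
    """

    def signature(m: Minichromosome) -> list[tuple[str, str, str]]:
        return [
            (f.name, f.status.value, f.orientation.value)
            for f in m.genes
            if include_pseudo or f.is_full
        ]

    return signature(m1) == signature(m2)


def shared_gene_count(m1: Minichromosome, m2: Minichromosome) -> int:
    """Number of distinct full-gene names shared by two minichromosomes.

    Pseudo genes are excluded and duplicate copies contribute at most one
    unit of overlap per gene name.
    """
    return len(set(m1.full_gene_names()) & set(m2.full_gene_names()))


def _optimal_pairs(
    left: list[Minichromosome],
    right: list[Minichromosome],
    prefer_equal: bool = False,
) -> list[tuple[str, str, int]]:
    """Maximum-total-shared-gene assignment between two minichromosome lists.

    Sides are label-sorted first so the result is deterministic; pairs
    with zero overlap are discarded (those minichromosomes stay
    unmatched).  An exact assignment is used rather than a greedy sweep
    because greedy pairing is provably suboptimal on valid inputs.  With
    ``prefer_equal`` a sub-unit bonus steers ties toward pairs that are
    outright equal, which keeps the shared count symmetric.
    """
    left = sorted(left, key=lambda m: m.label)
    right = sorted(right, key=lambda m: m.label)
    if not left or not right:
        return []
    overlap = np.array(
        [[shared_gene_count(a, b) for b in right] for a in left], dtype=float
    )
    weight = overlap.copy()
    if prefer_equal:
        bonus = 0.5 / max(len(left), len(right))
        for i, a in enumerate(left):
            for j, b in enumerate(right):
                if overlap[i, j] > 0 and chromosomes_equal(a, b):
                    weight[i, j] += bonus
    rows, cols = linear_sum_assignment(weight, maximize=True)
    pairs = [
        (left[i].label, right[j].label, int(overlap[i, j]))
        for i, j in zip(rows, cols)
        if overlap[i, j] > 0
    ]
    pairs.sort()
    return pairs


def match_chromosomes(ancestral: Karyotype, derived: Karyotype) -> ChromosomeMatching:
    """Match ancestral to derived minichromosomes by shared full genes.

    One-to-at-most-one on each side.  An unmatched ancestral
    minichromosome whose surviving full genes all sit on a single derived
    minichromosome already matched to a different ancestor is flagged as
    a merger candidate (two ancestral chromosomes merged as one).
    """
    pairs = _optimal_pairs(ancestral.minichromosomes, derived.minichromosomes)
    matched_a = {a for a, _, _ in pairs}
    matched_d = {d for _, d, _ in pairs}
    unmatched_a = sorted(m.label for m in ancestral if m.label not in matched_a)
    unmatched_d = sorted(m.label for m in derived if m.label not in matched_d)

    mergers = []
    for a_label in unmatched_a:
        a = ancestral.chromosome(a_label)
        hosts = {
            d.label
            for d in derived
            if shared_gene_count(a, d) > 0
        }
        survivors = [
            name
            for name in a.full_gene_names()
            if any(name in d.full_gene_names() for d in derived)
        ]
        if len(hosts) == 1 and survivors:
            host = next(iter(hosts))
            host_chr = derived.chromosome(host)
            if host in matched_d and all(name in host_chr.full_gene_names() for name in survivors):
                mergers.append((a_label, host))
    return ChromosomeMatching(
        pairs=pairs,
        unmatched_ancestral=unmatched_a,
        unmatched_derived=unmatched_d,
        mergers=sorted(mergers),
    )


def compare_karyotypes(k1: Karyotype, k2: Karyotype, include_pseudo: bool = False) -> ComparisonReport:
    """Category report: shared, differing (matched but unequal), unmatched."""
    pairs = _optimal_pairs(k1.minichromosomes, k2.minichromosomes, prefer_equal=True)
    shared: list[tuple[str, str]] = []
    differing: list[tuple[str, str, list[str]]] = []
    for a_label, b_label, _ in pairs:
        a = k1.chromosome(a_label)
        b = k2.chromosome(b_label)
        if chromosomes_equal(a, b, include_pseudo=include_pseudo):
            shared.append((a_label, b_label))
        else:
            differing.append((a_label, b_label, _describe_diffs(a, b)))
    matched_1 = {a for a, _, _ in pairs}
    matched_2 = {b for _, b, _ in pairs}
    return ComparisonReport(
        shared=shared,
        differing=differing,
        unmatched_left=sorted(m.label for m in k1 if m.label not in matched_1),
        unmatched_right=sorted(m.label for m in k2 if m.label not in matched_2),
    )


def _describe_diffs(a: Minichromosome, b: Minichromosome) -> list[str]:
    """Human-readable per-position differences between two gene lists."""
    ta = [f.token for f in a.genes]
    tb = [f.token for f in b.genes]
    diffs = []
    for i in range(max(len(ta), len(tb))):
        xa = ta[i] if i < len(ta) else "-"
        xb = tb[i] if i < len(tb) else "-"
        if xa != xb:
            diffs.append(f"pos {i}: {xa} vs {xb}")
    return diffs
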