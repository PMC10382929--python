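"""Parsimony inference of inter-minichromosomal recombination events.

Given an ancestral and a derived karyotype, every gene occurrence is
classified as retained, translocated, duplicated, partially duplicated
(pseudo copy), degenerated in place, deleted, or part of a
minichromosome merger.  Each classified change is an :class:`EventRecord`
anchored to the nearest downstream full, non-duplicate gene; anchors are
tallied across branches to locate recombination hotspots, and the number
of distinct ancestral donor minichromosomes at an anchor is the
parsimony lower bound on recombination events there.

Counting convention: one recombination event is one donor-to-recipient
transfer of material; a merger counts as one event, and a maximal
adjacent run of genes from a single donor (for example a three-gene
block translocated together) counts as one event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .compare import ChromosomeMatching, match_chromosomes
from .model import Karyotype, gene_kind

__all__ = [
    "EVENT_TYPES",
    "EventRecord",
    "HotspotTally",
    "InferenceError",
    "infer_events",
    "classify_occurrences",
    "min_recombination_events",
    "anchor_ambiguity",
    "hotspot_tally",
]

EVENT_TYPES = (
    "merger",
    "translocation",
    "duplication_insert",
    "partial_duplication",
    "degeneration_in_place",
    "deletion",
)

NO_ANCHOR = "none"


class InferenceError(ValueError):
    pass


@dataclass(frozen=True)
class EventRecord:
    """One inferred recombination-derived change."""

    type: str
    genes: tuple[str, ...]
    donor: str | None = None
    recipient: str | None = None
    anchor: str = NO_ANCHOR
    details: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise InferenceError(f"unknown event type {self.type!r}")

    @property
    def key(self) -> tuple:
        """Identity used when comparing inferred events with a truth log."""
        return (self.type, self.genes, self.donor)

    def to_dict(self) -> dict:
        return {
            "type": self.type,
            "genes": list(self.genes),
            "donor": self.donor,
            "recipient": self.recipient,
            "anchor": self.anchor,
            "details": self.details,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EventRecord":
        return cls(
            type=d["type"],
            genes=tuple(d["genes"]),
            donor=d.get("donor"),
            recipient=d.get("recipient"),
            anchor=d.get("anchor", NO_ANCHOR),
            details=d.get("details", {}),
        )


@dataclass(frozen=True)
class HotspotTally:
    per_branch: dict[str, dict[str, int]]
    totals: dict[str, int]
    ranking: list[tuple[str, int]]
    n_unlocated: int

    def to_tsv(self) -> str:
        rows = ["anchor\ttotal\trank\t" + "\t".join(sorted(self.per_branch))]
        branches = sorted(self.per_branch)
        for rank, (anchor, total) in enumerate(self.ranking, start=1):
            per = "\t".join(str(self.per_branch[b].get(anchor, 0)) for b in branches)
            rows.append(f"{anchor}\t{total}\t{rank}\t{per}")
        return "\n".join(rows) + "\n"


def classify_occurrences(
    ancestral: Karyotype,
    derived: Karyotype,
    matching: ChromosomeMatching | None = None,
) -> tuple[dict, dict, ChromosomeMatching]:
    """Per-occurrence classification underlying :func:`infer_events`.

    Returns ``(derived_class, ancestral_class, matching)`` where the
    dicts map ``(chromosome label, position)`` to ``(kind, partner)``.
    Every ancestral occurrence ends up retained / translocated /
    degenerated / merged / deleted exactly once, and every derived
    occurrence gets exactly one classification (conservation).
    """
    if matching is None:
        matching = match_chromosomes(ancestral, derived)
    a_for_d = {d: a for a, d, _ in matching.pairs}
    merger_sources: dict[str, list[str]] = {}
    for src, host in matching.mergers:
        merger_sources.setdefault(host, []).append(src)

    anc_class: dict[tuple[str, int], tuple[str, str | None]] = {}
    der_class: dict[tuple[str, int], tuple[str, str | None]] = {}

    vocab = {name for name, _ in _vocab_pairs()}
    for d_chr in derived:
        for f in d_chr.genes:
            if f.name not in vocab:
                raise InferenceError(f"gene {f.name!r} not in the canonical vocabulary")

    def avail_positions(a_label: str, name: str, full: bool) -> list[int]:
        a_chr = ancestral.chromosome(a_label)
        return [
            pos
            for pos, f in enumerate(a_chr.genes)
            if f.name == name
            and f.is_full == full
            and (a_label, pos) not in anc_class
        ]

    # Pass 1: retained occurrences and in-place degenerations, per matched pair.
    for d_chr in derived:
        a_label = a_for_d.get(d_chr.label)
        if a_label is None:
            continue
        for pos, f in enumerate(d_chr.genes):
            cands = avail_positions(a_label, f.name, full=f.is_full)
            if cands:
                anc_class[(a_label, cands[0])] = ("retained", d_chr.label)
                der_class[(d_chr.label, pos)] = ("retained", a_label)
        for pos, f in enumerate(d_chr.genes):
            if (d_chr.label, pos) in der_class or f.is_full:
                continue
            cands = avail_positions(a_label, f.name, full=True)
            if cands:  # pseudo at the gene's ancestral location
                anc_class[(a_label, cands[0])] = ("degenerated", d_chr.label)
                der_class[(d_chr.label, pos)] = ("degeneration_in_place", a_label)

    # Pass 2: mergers — survivors of an absorbed ancestral chromosome that
    # are co-resident on the host derived chromosome.
    for host in sorted(merger_sources):
        d_chr = derived.chromosome(host)
        for src in sorted(merger_sources[host]):
            for pos, f in enumerate(d_chr.genes):
                if (host, pos) in der_class or not f.is_full:
                    continue
                cands = avail_positions(src, f.name, full=True)
                if cands:
                    anc_class[(src, cands[0])] = ("merged", host)
                    der_class[(host, pos)] = ("merged", src)

    # Pass 3: remaining derived full occurrences -> translocation if an
    # unconsumed ancestral copy exists (it moved), else duplication_insert.
    for d_chr in derived:
        for pos, f in enumerate(d_chr.genes):
            if (d_chr.label, pos) in der_class or not f.is_full:
                continue
            sources = [
                (a.label, apos)
                for a in ancestral
                for apos in avail_positions(a.label, f.name, full=True)
            ]
            if sources:
                src_label, src_pos = sources[0]
                anc_class[(src_label, src_pos)] = ("translocated", d_chr.label)
                der_class[(d_chr.label, pos)] = ("translocation", src_label)
            else:
                donor = _original_full_home(ancestral, f.name)
                if donor is None:
                    raise InferenceError(
                        f"full gene {f.name!r} on {d_chr.label} has no ancestral source"
                    )
                der_class[(d_chr.label, pos)] = ("duplication_insert", donor)

    # Pass 4: remaining derived pseudo occurrences -> partial duplication of
    # the full-length namesake on another minichromosome.
    for d_chr in derived:
        for pos, f in enumerate(d_chr.genes):
            if (d_chr.label, pos) in der_class:
                continue
            donor = _original_full_home(ancestral, f.name)
            if donor is None:
                raise InferenceError(
                    f"pseudo gene {f.name!r} on {d_chr.label} has no full-length "
                    f"ancestral namesake"
                )
            der_class[(d_chr.label, pos)] = ("partial_duplication", donor)

    # Pass 5: unaccounted ancestral occurrences are deletions.
    for a_chr in ancestral:
        for pos, f in enumerate(a_chr.genes):
            if (a_chr.label, pos) not in anc_class:
                anc_class[(a_chr.label, pos)] = ("deleted", None)

    return der_class, anc_class, matching


def _vocab_pairs():
    from .model import canonical_vocabulary

    return canonical_vocabulary()


def _original_full_home(ancestral: Karyotype, name: str) -> str | None:
    """Label of the ancestral minichromosome carrying the original full copy."""
    best: tuple[int, int, str] | None = None
    for order, a_chr in enumerate(ancestral):
        for f in a_chr.genes:
            if f.name == name and f.is_full:
                cand = (f.copy, order, a_chr.label)
                if best is None or cand < best:
                    best = cand
    return best[2] if best else None


def _anchor_after(chromosome, last_pos: int) -> str:
    """Nearest downstream full non-duplicate gene, or ``none`` at cluster end.

    Pseudo genes and later duplicate copies are themselves products of
    insertion and are skipped; this reproduces the published convention
    of tallying stacked insertions at the location of the original
    downstream gene.
    """
    for f in chromosome.genes[last_pos + 1 :]:
        if f.is_full and f.copy == 1:
            return f.name
    return NO_ANCHOR


def infer_events(
    ancestral: Karyotype,
    derived: Karyotype,
    matching: ChromosomeMatching | None = None,
) -> list[EventRecord]:
    """Deterministic branch-wise event inference (ancestor vs descendant)."""
    der_class, anc_class, matching = classify_occurrences(ancestral, derived, matching)
    events: list[EventRecord] = []

    # Derived-side events, with maximal adjacent same-donor runs fused.
    run_kinds = {"translocation", "duplication_insert", "partial_duplication"}
    for d_chr in derived:
        pos = 0
        n = len(d_chr.genes)
        while pos < n:
            kind, partner = der_class[(d_chr.label, pos)]
            if kind in ("retained", "merged"):
                pos += 1
                continue
            if kind == "degeneration_in_place":
                events.append(
                    EventRecord(
                        type="degeneration_in_place",
                        genes=(d_chr.genes[pos].name,),
                        recipient=d_chr.label,
                        anchor=_anchor_after(d_chr, pos),
                    )
                )
                pos += 1
                continue
            if kind in run_kinds:
                end = pos
                while (
                    end + 1 < n
                    and der_class[(d_chr.label, end + 1)] == (kind, partner)
                ):
                    end += 1
                events.append(
                    EventRecord(
                        type=kind,
                        genes=tuple(f.name for f in d_chr.genes[pos : end + 1]),
                        donor=partner,
                        recipient=d_chr.label,
                        anchor=_anchor_after(d_chr, end),
                    )
                )
                pos = end + 1
                continue
            raise AssertionError(f"unhandled classification {kind}")

    # One merger event per absorbed ancestral chromosome.
    for src, host in matching.mergers:
        d_chr = derived.chromosome(host)
        positions = [
            pos
            for pos in range(len(d_chr.genes))
            if der_class[(d_chr.label, pos)] == ("merged", src)
        ]
        if not positions:
            continue
        events.append(
            EventRecord(
                type="merger",
                genes=tuple(d_chr.genes[p].name for p in positions),
                donor=src,
                recipient=host,
                anchor=_anchor_after(d_chr, max(positions)),
            )
        )

    # Ancestral-side deletions, adjacent positions fused into one run.
    for a_chr in ancestral:
        deleted = [
            pos
            for pos in range(len(a_chr.genes))
            if anc_class[(a_chr.label, pos)][0] == "deleted"
        ]
        for run in _adjacent_runs(deleted):
            events.append(
                EventRecord(
                    type="deletion",
                    genes=tuple(a_chr.genes[p].name for p in run),
                    donor=a_chr.label,
                    anchor=_anchor_after(a_chr, run[-1]),
                )
            )
    return events


def _adjacent_runs(positions: list[int]) -> list[list[int]]:
    runs: list[list[int]] = []
    for p in positions:
        if runs and p == runs[-1][-1] + 1:
            runs[-1].append(p)
        else:
            runs.append([p])
    return runs


def min_recombination_events(
    events: list[EventRecord], location_anchor: str, ancestral: Karyotype
) -> int:
    """Parsimony lower bound on recombination events at one anchor.

    Counts the distinct ancestral donor minichromosomes among the events
    anchored there: material arriving from n different donors requires at
    least n donor-to-recipient transfers, while several pieces from one
    donor could have arrived in a single transfer.
    """
    gene_kind(location_anchor)  # raises on a non-canonical anchor
    donors = {
        e.donor for e in events if e.anchor == location_anchor and e.donor is not None
    }
    return len(donors)


def anchor_ambiguity(events: list[EventRecord], location_anchor: str) -> bool:
    """True when the lower bound at an anchor is not tight.

    If two events at the anchor share one donor they may or may not have
    arrived in a single transfer, so the true count could exceed the
    bound ("at least n, possibly more").
    """
    donors = [
        e.donor for e in events if e.anchor == location_anchor and e.donor is not None
    ]
    return len(donors) > len(set(donors))


def hotspot_tally(branch_events: list[tuple[str, list[EventRecord]]]) -> HotspotTally:
    """Per-anchor event counts per branch, ranked by total.

    Events without a location (anchor ``none``) are excluded from totals
    and ranking; ties rank lexicographically.
    """
    per_branch: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {}
    n_unlocated = 0
    for branch, events in branch_events:
        counts = per_branch.setdefault(branch, {})
        for e in events:
            if e.anchor == NO_ANCHOR:
                n_unlocated += 1
                continue
            counts[e.anchor] = counts.get(e.anchor, 0) + 1
            totals[e.anchor] = totals.get(e.anchor, 0) + 1
    ranking = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    return HotspotTally(
        per_branch=per_branch, totals=totals, ranking=ranking, n_unlocated=n_unlocated
    )
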