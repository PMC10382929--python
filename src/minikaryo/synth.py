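"""Synthetic fragmented-genome generator with ground-truth event logs.

Builds an ancestral minichromosomal genome (one gene cluster plus one
large NCR per circular minichromosome, shared AT-rich and GC-rich motifs
planted in every NCR, one reverse-orientation gene run), applies
recombination events while recording a replayable truth log, and
simulates paired-end reads.  Everything is deterministic under the seed.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import (
    GeneFeature,
    Karyotype,
    KaryotypeError,
    Minichromosome,
    Orientation,
    Status,
    canonical_vocabulary,
    revcomp,
)
from .recomb import EventRecord

__all__ = [
    "MotifSpec",
    "SyntheticGenome",
    "TruthLog",
    "ReadPair",
    "DEFAULT_PARTITION",
    "DEFAULT_GENE_LENGTHS",
    "generate_ancestral_genome",
    "apply_events",
    "simulate_reads",
    "write_fastq_pairs",
    "write_genome_fasta",
]

# Ten clusters of 2-8 genes covering the 37-gene vocabulary exactly once,
# mirroring the architecture of the published species tables.
DEFAULT_PARTITION: tuple[tuple[str, ...], ...] = (
    ("E", "cytb", "S1", "S2", "R", "nad4L", "P", "atp8"),
    ("rrnS", "C", "atp6", "N"),
    ("I", "cox1"),
    ("D", "Y", "cox2", "nad6"),
    ("cox3", "W", "A"),
    ("Q", "nad1", "T", "G", "nad3"),
    ("K", "nad4"),
    ("L1", "nad2"),
    ("H", "nad5", "F", "L2"),
    ("M", "rrnL", "V"),
)

DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "atp6": 670, "atp8": 160, "cox1": 1530, "cox2": 680, "cox3": 780,
    "cytb": 1130, "nad1": 940, "nad2": 1010, "nad3": 350, "nad4": 1330,
    "nad4L": 270, "nad5": 1720, "nad6": 520, "rrnS": 750, "rrnL": 1200,
}
_TRNA_LEN = 65

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class MotifSpec:
    """Planted NCR motifs: AT-rich upstream, GC-rich downstream of cluster."""

    at_len: int = 45
    at_fraction: float = 1.0
    gc_len: int = 38
    gc_fraction: float = 0.763


@dataclass
class SyntheticGenome:
    karyotype: Karyotype
    at_motif: str
    gc_motif: str
    seed: int
    params: dict = field(default_factory=dict)

    def ncrs(self) -> list[str]:
        return [m.ncr_sequence for m in self.karyotype]

    def circle(self, label: str) -> str:
        return self.karyotype.chromosome(label).sequence()


@dataclass
class TruthLog:
    """Ordered applied events; replaying them reproduces the derived genome."""

    events: list[EventRecord]
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "params": self.params,
                "events": [e.to_dict() for e in self.events],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthLog":
        doc = json.loads(text)
        return cls(
            events=[EventRecord.from_dict(d) for d in doc["events"]],
            seed=doc["seed"],
            params=doc.get("params", {}),
        )


@dataclass(frozen=True)
class ReadPair:
    name: str
    mate1: str
    qual1: str
    mate2: str
    qual2: str
    origin_label: str
    origin_start: int
    origin_strand: str = "+"


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return _BASES[rng.choice(4, size=length, p=probs)].tobytes().decode()


def generate_ancestral_genome(
    n_minichromosomes: int = 10,
    partition: Optional[Sequence[Sequence[str]]] = None,
    ncr_len_range: tuple[int, int] = (686, 1296),
    motif_spec: Optional[MotifSpec] = None,
    gc: float = 0.30,
    gene_lengths: Optional[dict[str, int]] = None,
    length_scale: float = 1.0,
    reverse_run: bool = True,
    seed: int = 0,
) -> SyntheticGenome:
    """Generate an ancestral genome: one gene cluster + one NCR per circle.

    ``partition`` must cover the 37-gene vocabulary exactly once and have
    ``n_minichromosomes`` parts.  Gene sequences are iid at the given GC
    content; every NCR carries the genome's AT-rich motif near its
    upstream (cluster-facing) end and the GC-rich motif near its
    downstream end.  One reverse-orientation gene run is placed per
    genome by default.  ``length_scale`` shrinks gene lengths for
    desk-scale assembly toys.
    """
    partition = tuple(tuple(p) for p in (partition or DEFAULT_PARTITION))
    if len(partition) != n_minichromosomes:
        raise KaryotypeError(
            f"partition has {len(partition)} parts, expected {n_minichromosomes}"
        )
    flat = [g for part in partition for g in part]
    vocab = [name for name, _ in canonical_vocabulary()]
    if sorted(flat) != sorted(vocab):
        missing = set(vocab) - set(flat)
        extra = [g for g in flat if flat.count(g) > 1 or g not in vocab]
        raise KaryotypeError(
            f"partition must cover the vocabulary exactly once "
            f"(missing={sorted(missing)}, duplicated/unknown={sorted(set(extra))})"
        )
    motif_spec = motif_spec or MotifSpec()
    lengths = dict(gene_lengths or DEFAULT_GENE_LENGTHS)

    rng = np.random.default_rng(seed)
    at_motif = _random_seq(rng, motif_spec.at_len, gc=1.0 - motif_spec.at_fraction)
    gc_motif = _random_seq(rng, motif_spec.gc_len, gc=motif_spec.gc_fraction)
    pad = motif_spec.at_len + motif_spec.gc_len + 80
    lo, hi = ncr_len_range
    if lo < pad:
        raise KaryotypeError(f"ncr_len_range minimum {lo} too small for motifs (need >= {pad})")

    minis = []
    for idx, part in enumerate(partition):
        genes = []
        for name in part:
            base_len = lengths.get(name, _TRNA_LEN)
            glen = max(30, int(round(base_len * length_scale)))
            orientation = Orientation.forward
            if reverse_run and name in ("Q", "nad1", "T") and "nad1" in part:
                orientation = Orientation.reverse
            genes.append(
                GeneFeature(
                    name=name,
                    orientation=orientation,
                    length_bp=glen,
                    sequence=_random_seq(rng, glen, gc),
                )
            )
        ncr_len = int(rng.integers(lo, hi + 1))
        ncr = list(_random_seq(rng, ncr_len, gc))
        gc_off = int(rng.integers(10, 31))
        ncr[gc_off : gc_off + len(gc_motif)] = gc_motif
        at_end = ncr_len - int(rng.integers(10, 31))
        ncr[at_end - len(at_motif) : at_end] = at_motif
        ncr = "".join(ncr)
        m = Minichromosome(genes=genes, label=f"mc{idx + 1:02d}", ncr_sequence=ncr)
        _refresh_sizes(m)
        minis.append(m)

    k = Karyotype(species=f"synthetic-{seed}", minichromosomes=minis)
    for m in k:
        m.check_size_additivity()
    return SyntheticGenome(
        karyotype=k,
        at_motif=at_motif,
        gc_motif=gc_motif,
        seed=seed,
        params={
            "n_minichromosomes": n_minichromosomes,
            "ncr_len_range": list(ncr_len_range),
            "gc": gc,
            "length_scale": length_scale,
        },
    )


def _refresh_sizes(m: Minichromosome) -> None:
    m.cluster_sequence = "".join(f.sequence for f in m.genes)
    m.cluster_len_bp = len(m.cluster_sequence)
    m.ncr_len_bp = len(m.ncr_sequence)
    m.total_len_bp = m.cluster_len_bp + m.ncr_len_bp
    m.pseudo_len_bp = sum(f.length_bp for f in m.genes if f.status is Status.pseudo)


RANDOM_EVENT_TYPES = (
    "translocation",
    "duplication_insert",
    "partial_duplication",
    "degeneration_in_place",
    "deletion",
)


def apply_events(
    genome: SyntheticGenome,
    events: Optional[list[EventRecord]] = None,
    n_events: int = 0,
    event_types: Sequence[str] = RANDOM_EVENT_TYPES,
    seed: int = 0,
) -> tuple[SyntheticGenome, TruthLog]:
    """Apply recombination events, returning the derived genome + truth log.

    Pass explicit ``events`` (with resolved operand details, e.g. from a
    truth log) for byte-identical replay, or ``n_events`` to draw random
    events.  Random draws pick a type, then operands, uniformly, under
    constraints that keep each event recoverable by branch-wise
    inference: affected genes are distinct single-copy genes, donor
    chromosomes are distinct, and no chromosome is left without at least
    two full genes.
    """
    derived = SyntheticGenome(
        karyotype=copy.deepcopy(genome.karyotype),
        at_motif=genome.at_motif,
        gc_motif=genome.gc_motif,
        seed=genome.seed,
        params=dict(genome.params),
    )
    k = derived.karyotype
    rng = np.random.default_rng(seed)

    if events is None:
        events = _draw_random_events(k, n_events, tuple(event_types), rng)
    applied = []
    for e in events:
        applied.append(_apply_one(k, e))
    for m in k:
        m.check_size_additivity()
    return derived, TruthLog(events=applied, seed=seed, params={"n_events": len(applied)})


def _find_full(m: Minichromosome, name: str) -> int:
    for pos, f in enumerate(m.genes):
        if f.name == name and f.is_full:
            return pos
    raise KaryotypeError(f"gene {name} not full on {m.label}")


def _resolve_insert_pos(recipient: Minichromosome, d: dict, anchor: str) -> int:
    """Insertion index; falls back to 'immediately upstream of the anchor gene'."""
    if "insert_pos" in d:
        return d["insert_pos"]
    if anchor != "none":
        for pos, f in enumerate(recipient.genes):
            if f.name == anchor and f.is_full:
                d["insert_pos"] = pos
                return pos
        raise KaryotypeError(f"anchor {anchor!r} not found on {recipient.label}")
    d["insert_pos"] = len(recipient.genes)
    return d["insert_pos"]


def _apply_one(k: Karyotype, e: EventRecord) -> EventRecord:
    """Apply one event; returns the record with resolved details filled in."""
    d = dict(e.details)
    if e.type == "translocation":
        donor = k.chromosome(e.donor)
        recipient = k.chromosome(e.recipient)
        positions = [_find_full(donor, g) for g in e.genes]
        if positions != list(range(positions[0], positions[0] + len(positions))):
            raise KaryotypeError(f"translocation genes {e.genes} not adjacent on {e.donor}")
        moved = donor.genes[positions[0] : positions[-1] + 1]
        del donor.genes[positions[0] : positions[-1] + 1]
        if not any(f.is_full for f in donor.genes):
            raise KaryotypeError(f"translocation would empty {e.donor}")
        ins = _resolve_insert_pos(recipient, d, e.anchor)
        recipient.genes[ins:ins] = moved
        _refresh_sizes(donor)
        _refresh_sizes(recipient)
    elif e.type == "duplication_insert":
        donor = k.chromosome(e.donor)
        recipient = k.chromosome(e.recipient)
        (gene,) = e.genes
        src = donor.genes[_find_full(donor, gene)]
        n_copies = sum(1 for m in k for f in m.genes if f.name == gene and f.is_full)
        dup = GeneFeature(
            name=src.name,
            status=Status.full,
            orientation=src.orientation,
            copy=n_copies + 1,
            length_bp=src.length_bp,
            sequence=src.sequence,  # copied verbatim: duplicate copies are sequence-identical
        )
        ins = _resolve_insert_pos(recipient, d, e.anchor)
        recipient.genes[ins:ins] = [dup]
        _refresh_sizes(recipient)
    elif e.type == "partial_duplication":
        donor = k.chromosome(e.donor)
        recipient = k.chromosome(e.recipient)
        (gene,) = e.genes
        src = donor.genes[_find_full(donor, gene)]
        start, length = d["window_start"], d["window_len"]
        window = src.sequence[start : start + length]
        n_pseudo = sum(
            1 for m in k for f in m.genes if f.name == gene and f.status is Status.pseudo
        )
        pseudo = GeneFeature(
            name=gene,
            status=Status.pseudo,
            orientation=src.orientation,
            copy=n_pseudo + 1,
            length_bp=len(window),
            sequence=window,
        )
        ins = _resolve_insert_pos(recipient, d, e.anchor)
        recipient.genes[ins:ins] = [pseudo]
        _refresh_sizes(recipient)
    elif e.type == "degeneration_in_place":
        target = k.chromosome(e.recipient)
        (gene,) = e.genes
        pos = _find_full(target, gene)
        f = target.genes[pos]
        target.genes[pos] = GeneFeature(
            name=f.name,
            status=Status.pseudo,
            orientation=f.orientation,
            copy=f.copy,
            length_bp=f.length_bp,
            sequence=f.sequence,
        )
        _refresh_sizes(target)
    elif e.type == "deletion":
        donor = k.chromosome(e.donor)
        (gene,) = e.genes
        pos = _find_full(donor, gene)
        del donor.genes[pos]
        if sum(1 for f in donor.genes if f.is_full) < 1:
            raise KaryotypeError(f"deletion would empty {e.donor}")
        _refresh_sizes(donor)
    elif e.type == "merger":
        donor = k.chromosome(e.donor)
        recipient = k.chromosome(e.recipient)
        recipient.genes[0:0] = donor.genes
        k.minichromosomes.remove(donor)
        _refresh_sizes(recipient)
    else:
        raise KaryotypeError(f"inapplicable event type {e.type!r}")
    return EventRecord(
        type=e.type,
        genes=e.genes,
        donor=e.donor,
        recipient=e.recipient,
        anchor=e.anchor,
        details=d,
    )


def _draw_random_events(
    k: Karyotype,
    n_events: int,
    event_types: tuple[str, ...],
    rng: np.random.Generator,
) -> list[EventRecord]:
    labels = [m.label for m in k.minichromosomes]
    index = k.gene_index()
    single_copy = sorted(
        name
        for name, occ in index.items()
        if len(occ) == 1 and occ[0][2] is Status.full
    )
    used_genes: set[str] = set()
    used_sources: set[str] = set()
    events = []
    for _ in range(n_events):
        for _attempt in range(200):
            etype = event_types[int(rng.integers(len(event_types)))]
            gene = single_copy[int(rng.integers(len(single_copy)))]
            if gene in used_genes:
                continue
            src_label = index[gene][0][0]
            if src_label in used_sources:
                continue
            src = k.chromosome(src_label)
            others = [x for x in labels if x != src_label]
            recipient = others[int(rng.integers(len(others)))]
            rec_chr = k.chromosome(recipient)
            ins = int(rng.integers(0, len(rec_chr.genes) + 1))
            if etype == "translocation":
                if src.n_full_genes() < 3:
                    continue
                e = EventRecord(
                    type=etype, genes=(gene,), donor=src_label,
                    recipient=recipient, details={"insert_pos": ins},
                )
            elif etype == "duplication_insert":
                e = EventRecord(
                    type=etype, genes=(gene,), donor=src_label,
                    recipient=recipient, details={"insert_pos": ins},
                )
            elif etype == "partial_duplication":
                src_feature = src.genes[_find_full(src, gene)]
                wlen = int(rng.integers(150, 451))
                wlen = min(wlen, src_feature.length_bp)
                wstart = int(rng.integers(0, src_feature.length_bp - wlen + 1))
                e = EventRecord(
                    type=etype, genes=(gene,), donor=src_label, recipient=recipient,
                    details={"window_start": wstart, "window_len": wlen, "insert_pos": ins},
                )
            elif etype == "degeneration_in_place":
                if src.n_full_genes() < 3:
                    continue
                e = EventRecord(type=etype, genes=(gene,), recipient=src_label)
            elif etype == "deletion":
                if src.n_full_genes() < 3:
                    continue
                e = EventRecord(type=etype, genes=(gene,), donor=src_label)
            else:
                raise KaryotypeError(f"cannot draw event of type {etype!r}")
            used_genes.add(gene)
            used_sources.add(src_label)
            events.append(e)
            break
        else:
            raise KaryotypeError("could not draw an applicable random event")
    return events


def simulate_reads(
    genome: SyntheticGenome,
    coverage: float,
    read_len: int = 300,
    insert_len: int = 530,
    error_rate: float = 0.0,
    seed: int = 0,
    degrade_tail: bool = False,
) -> list[ReadPair]:
    """Uniform circular paired-end sampling per minichromosome.

    Fragments of ``insert_len`` are drawn uniformly around each circle;
    mate 1 is the fragment start, mate 2 the reverse complement of the
    fragment end.  Substitution errors are iid at ``error_rate``; no
    indel errors.  Qualities are constant Q37, except in
    ``degrade_tail`` mode where the tail 55% of every read drops to Q2
    (exists solely to exercise the read filter).
    """
    if insert_len < read_len:
        raise ValueError("insert_len must be >= read_len")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    pairs = []
    q_hi = chr(37 + 33)
    for m in genome.karyotype:
        circle = m.sequence()
        L = len(circle)
        if insert_len > L:
            raise ValueError(f"insert_len {insert_len} exceeds circle {m.label} ({L} bp)")
        doubled = circle + circle
        n_pairs = max(1, int(round(coverage * L / (2 * read_len))))
        starts = rng.integers(0, L, size=n_pairs)
        for i, start in enumerate(starts):
            frag = doubled[start : start + insert_len]
            mate1 = _with_errors(frag[:read_len], error_rate, rng)
            mate2 = _with_errors(revcomp(frag[-read_len:]), error_rate, rng)
            if degrade_tail:
                keep = int(read_len * 0.45)
                qual = q_hi * keep + "#" * (read_len - keep)
            else:
                qual = q_hi * read_len
            pairs.append(
                ReadPair(
                    name=f"sim:{m.label}:{i}",
                    mate1=mate1,
                    qual1=qual,
                    mate2=mate2,
                    qual2=qual,
                    origin_label=m.label,
                    origin_start=int(start),
                )
            )
    return pairs


def _with_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[int(rng.integers(len(choices)))]
    return arr.tobytes().decode()


def write_fastq_pairs(pairs: Sequence[ReadPair], path1, path2) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.name}/1\n{p.mate1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.name}/2\n{p.mate2}\n+\n{p.qual2}\n")


def write_genome_fasta(genome: SyntheticGenome, path) -> None:
    """One record per minichromosome, linearized at the NCR cut."""
    with open(path, "w") as fh:
        for m in genome.karyotype:
            fh.write(f">{m.label} {m.gene_string()}\n")
            seq = m.sequence()
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
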