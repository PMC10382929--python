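"""Core data model for fragmented mitochondrial genomes.

A *minichromosome* is a small circular chromosome carrying an ordered
cluster of genes plus one large non-coding region (NCR).  A *karyotype*
is the full set of minichromosomes of one species.  This module defines
the domain types, the compact karyotype-string grammar, a parser and
serializer that round-trip byte-identically, packaged karyotype fixtures,
and summary statistics.

Grammar
-------
One minichromosome per line.  Genes are joined by ``-`` and read in the
majority transcription direction starting immediately after the large
NCR.  Each token is::

    [~][p]<name>[#<copy>]

where ``~`` marks reverse orientation, ``p`` marks a pseudo gene,
``<name>`` is one of the canonical 37 mitochondrial gene names, and
``#2``, ``#3``... tag second and later copies of a duplicated gene.
Optional tab-separated integer columns give total, gene-cluster, NCR and
pseudo-gene sizes in bp.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

__all__ = [
    "GeneKind",
    "Status",
    "Orientation",
    "GeneFeature",
    "Minichromosome",
    "Karyotype",
    "KaryotypeSummary",
    "KaryotypeError",
    "canonical_vocabulary",
    "gene_kind",
    "parse_token",
    "parse_minichromosome",
    "parse_karyotype",
    "serialize_karyotype",
    "summarize_karyotype",
    "load_fixture",
    "FIXTURE_NAMES",
]


class KaryotypeError(ValueError):
    """Raised on malformed karyotype documents or inconsistent models."""


class GeneKind(str, enum.Enum):
    PCG = "PCG"
    tRNA = "tRNA"
    rRNA = "rRNA"


class Status(str, enum.Enum):
    full = "full"
    pseudo = "pseudo"


class Orientation(str, enum.Enum):
    forward = "forward"
    reverse = "reverse"


_PCG = (
    "atp6", "atp8", "cox1", "cox2", "cox3", "cytb",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
)
_TRNA = (
    "A", "C", "D", "E", "F", "G", "H", "I", "K", "L1", "L2",
    "M", "N", "P", "Q", "R", "S1", "S2", "T", "V", "W", "Y",
)
_RRNA = ("rrnS", "rrnL")

_KIND_OF = {name: GeneKind.PCG for name in _PCG}
_KIND_OF.update({name: GeneKind.tRNA for name in _TRNA})
_KIND_OF.update({name: GeneKind.rRNA for name in _RRNA})

FIXTURE_NAMES = ("L_vituli", "L_africanus", "MRCA_Anoplura", "MRCA_Linognathus")

_TOKEN_RE = re.compile(r"^(?P<rev>~)?(?P<pseudo>p)?(?P<name>[A-Za-z0-9]+?)(?:#(?P<copy>[0-9]+))?$")


def canonical_vocabulary() -> list[tuple[str, GeneKind]]:
    """The 37-gene mitochondrial vocabulary as ``(name, kind)`` pairs.

    13 protein-coding genes, 22 tRNA genes (single-letter names, numbered
    isoacceptors L1/L2 and S1/S2) and 2 rRNA genes.
    """
    return [(name, _KIND_OF[name]) for name in _PCG + _TRNA + _RRNA]


def gene_kind(name: str) -> GeneKind:
    try:
        return _KIND_OF[name]
    except KeyError:
        raise KaryotypeError(f"unknown gene name: {name!r}") from None


@dataclass(frozen=True)
class GeneFeature:
    """One gene occurrence on a minichromosome."""

    name: str
    status: Status = Status.full
    orientation: Orientation = Orientation.forward
    copy: int = 1
    length_bp: Optional[int] = None
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        gene_kind(self.name)  # validates the name
        if self.copy < 1:
            raise KaryotypeError(f"copy index must be >= 1, got {self.copy}")
        if self.length_bp is not None and self.length_bp < 0:
            raise KaryotypeError("length_bp must be non-negative")
        if self.sequence is not None:
            if not set(self.sequence) <= set("ACGTN"):
                raise KaryotypeError(f"sequence of {self.name} contains non-ACGTN characters")
            if self.length_bp is not None and len(self.sequence) != self.length_bp:
                raise KaryotypeError(
                    f"sequence length {len(self.sequence)} != length_bp {self.length_bp} for {self.name}"
                )

    @property
    def kind(self) -> GeneKind:
        return gene_kind(self.name)

    @property
    def is_full(self) -> bool:
        return self.status is Status.full

    @property
    def token(self) -> str:
        tok = self.name
        if self.copy > 1:
            tok += f"#{self.copy}"
        if self.status is Status.pseudo:
            tok = "p" + tok
        if self.orientation is Orientation.reverse:
            tok = "~" + tok
        return tok


@dataclass
class Minichromosome:
    """A circular minichromosome: NCR-anchored ordered gene list plus sizes.

    ``genes`` are read in the majority transcription direction starting
    immediately after the large NCR.  Coordinates on attached sequences
    are 0-based half-open on the circle linearized at the NCR cut.
    """

    genes: list[GeneFeature]
    label: Optional[str] = None
    total_len_bp: Optional[int] = None
    cluster_len_bp: Optional[int] = None
    ncr_len_bp: Optional[int] = None
    pseudo_len_bp: Optional[int] = None
    cluster_sequence: Optional[str] = None
    ncr_sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise KaryotypeError("a minichromosome must carry at least one gene")
        if self.label is None:
            self.label = self.gene_string()

    def gene_string(self) -> str:
        return "-".join(f.token for f in self.genes)

    def full_gene_names(self) -> list[str]:
        """Distinct names with at least one full occurrence, in cluster order."""
        seen: list[str] = []
        for f in self.genes:
            if f.is_full and f.name not in seen:
                seen.append(f.name)
        return seen

    def n_full_genes(self) -> int:
        return sum(1 for f in self.genes if f.is_full)

    def check_size_additivity(self) -> None:
        """Assert total = cluster + NCR (synthetic-genome invariant only).

        Published size tables carry small unexplained discrepancies, so
        this is never enforced at parse time.
        """
        if None in (self.total_len_bp, self.cluster_len_bp, self.ncr_len_bp):
            return
        if self.total_len_bp != self.cluster_len_bp + self.ncr_len_bp:
            raise KaryotypeError(
                f"{self.label}: total {self.total_len_bp} != "
                f"cluster {self.cluster_len_bp} + NCR {self.ncr_len_bp}"
            )

    def sequence(self) -> Optional[str]:
        """Full circle sequence linearized at the NCR cut (cluster first)."""
        if self.cluster_sequence is None or self.ncr_sequence is None:
            return None
        return self.cluster_sequence + self.ncr_sequence


@dataclass
class Karyotype:
    """A species' set of minichromosomes, with a gene-occurrence index."""

    species: str
    minichromosomes: list[Minichromosome] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [m.label for m in self.minichromosomes]
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise KaryotypeError(f"duplicate minichromosome labels: {sorted(dupes)}")

    def __iter__(self):
        return iter(self.minichromosomes)

    def __len__(self) -> int:
        return len(self.minichromosomes)

    def chromosome(self, label: str) -> Minichromosome:
        for m in self.minichromosomes:
            if m.label == label:
                return m
        raise KeyError(label)

    def gene_index(self) -> dict[str, list[tuple[str, int, Status]]]:
        """name -> list of (minichromosome label, position, status)."""
        index: dict[str, list[tuple[str, int, Status]]] = {}
        for m in self.minichromosomes:
            for pos, f in enumerate(m.genes):
                index.setdefault(f.name, []).append((m.label, pos, f.status))
        return index

    def full_occurrences(self, name: str) -> list[tuple[str, int]]:
        return [
            (label, pos)
            for label, pos, status in self.gene_index().get(name, [])
            if status is Status.full
        ]

    def to_json(self) -> str:
        doc = {
            "species": self.species,
            "minichromosomes": [
                {
                    "label": m.label,
                    "genes": [
                        {
                            "name": f.name,
                            "status": f.status.value,
                            "orientation": f.orientation.value,
                            "copy": f.copy,
                            "length_bp": f.length_bp,
                        }
                        for f in m.genes
                    ],
                    "total_len_bp": m.total_len_bp,
                    "cluster_len_bp": m.cluster_len_bp,
                    "ncr_len_bp": m.ncr_len_bp,
                    "pseudo_len_bp": m.pseudo_len_bp,
                }
                for m in self.minichromosomes
            ],
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "Karyotype":
        doc = json.loads(text)
        minis = []
        for md in doc["minichromosomes"]:
            genes = [
                GeneFeature(
                    name=g["name"],
                    status=Status(g["status"]),
                    orientation=Orientation(g["orientation"]),
                    copy=g.get("copy", 1),
                    length_bp=g.get("length_bp"),
                )
                for g in md["genes"]
            ]
            minis.append(
                Minichromosome(
                    genes=genes,
                    label=md.get("label"),
                    total_len_bp=md.get("total_len_bp"),
                    cluster_len_bp=md.get("cluster_len_bp"),
                    ncr_len_bp=md.get("ncr_len_bp"),
                    pseudo_len_bp=md.get("pseudo_len_bp"),
                )
            )
        return cls(species=doc["species"], minichromosomes=minis)


@dataclass(frozen=True)
class KaryotypeSummary:
    n_minichromosomes: int
    n_distinct_full_genes: int
    n_duplicate_genes: int
    n_pseudo_genes: int
    total_len_bp: Optional[int]
    cluster_len_bp: Optional[int]
    ncr_len_bp: Optional[int]
    pseudo_len_bp: Optional[int]
    min_genes_per_minichromosome: int
    max_genes_per_minichromosome: int
    max_ncr_len_bp: Optional[int] = None


def parse_token(token: str, line_no: int = 0) -> GeneFeature:
    m = _TOKEN_RE.match(token)
    if m and m.group("name") in _KIND_OF:
        return GeneFeature(
            name=m.group("name"),
            status=Status.pseudo if m.group("pseudo") else Status.full,
            orientation=Orientation.reverse if m.group("rev") else Orientation.forward,
            copy=int(m.group("copy")) if m.group("copy") else 1,
        )
    raise KaryotypeError(f"line {line_no}: unknown gene token {token!r}")


def parse_minichromosome(line: str, line_no: int = 0) -> Minichromosome:
    cols = line.rstrip("\n").split("\t")
    gene_part = cols[0].strip()
    if not gene_part:
        raise KaryotypeError(f"line {line_no}: empty minichromosome")
    genes = [parse_token(tok, line_no) for tok in gene_part.split("-")]
    sizes: list[Optional[int]] = [None, None, None, None]
    for i, col in enumerate(cols[1:5]):
        col = col.strip()
        if col:
            try:
                sizes[i] = int(col.replace(",", ""))
            except ValueError:
                raise KaryotypeError(f"line {line_no}: bad size column {col!r}") from None
    return Minichromosome(
        genes=genes,
        total_len_bp=sizes[0],
        cluster_len_bp=sizes[1],
        ncr_len_bp=sizes[2],
        pseudo_len_bp=sizes[3],
    )


def parse_karyotype(text: str, species: str = "unnamed") -> Karyotype:
    """Parse a karyotype grammar document (one minichromosome per line)."""
    minis = []
    for line_no, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        minis.append(parse_minichromosome(line, line_no))
    if not minis:
        raise KaryotypeError("empty karyotype document")
    return Karyotype(species=species, minichromosomes=minis)


def serialize_karyotype(k: Karyotype) -> str:
    """Serialize to the grammar; ``parse(serialize(k))`` round-trips."""
    lines = []
    for m in k.minichromosomes:
        cols = [m.gene_string()]
        sizes = (m.total_len_bp, m.cluster_len_bp, m.ncr_len_bp, m.pseudo_len_bp)
        if any(s is not None for s in sizes):
            cols.extend("" if s is None else str(s) for s in sizes)
        lines.append("\t".join(cols).rstrip("\t"))
    return "\n".join(lines) + "\n"


def summarize_karyotype(k: Karyotype) -> KaryotypeSummary:
    """Roll-up counts and size totals.

    Duplicates are full-status occurrences beyond the first per gene
    name; pseudo genes are tallied separately and never count toward the
    37-gene vocabulary.  Size totals are reported as absent (``None``)
    whenever any minichromosome lacks that column — never as zero.
    """
    full_counts: dict[str, int] = {}
    n_pseudo = 0
    for m in k.minichromosomes:
        for f in m.genes:
            if f.is_full:
                full_counts[f.name] = full_counts.get(f.name, 0) + 1
            else:
                n_pseudo += 1

    def _total(values: Iterable[Optional[int]]) -> Optional[int]:
        values = list(values)
        if any(v is None for v in values):
            return None
        return sum(values)  # type: ignore[arg-type]

    ncr_sizes = [m.ncr_len_bp for m in k.minichromosomes]
    per_chrom = [m.n_full_genes() for m in k.minichromosomes]
    return KaryotypeSummary(
        n_minichromosomes=len(k.minichromosomes),
        n_distinct_full_genes=len(full_counts),
        n_duplicate_genes=sum(c - 1 for c in full_counts.values()),
        n_pseudo_genes=n_pseudo,
        total_len_bp=_total(m.total_len_bp for m in k.minichromosomes),
        cluster_len_bp=_total(m.cluster_len_bp for m in k.minichromosomes),
        ncr_len_bp=_total(ncr_sizes),
        pseudo_len_bp=_total(m.pseudo_len_bp for m in k.minichromosomes),
        min_genes_per_minichromosome=min(per_chrom),
        max_genes_per_minichromosome=max(per_chrom),
        max_ncr_len_bp=None if any(s is None for s in ncr_sizes) else max(ncr_sizes),
    )


def load_fixture(name: str) -> Karyotype:
    """Load one of the packaged karyotypes.

    ``L_vituli`` and ``L_africanus`` are transcribed verbatim from the
    published per-species minichromosome tables (with figure-legend
    orientations); the two MRCA karyotypes are ancestral reconstructions
    transcribed from the cited ancestral-karyotype figure.  All
    downstream algorithms treat these as swappable inputs, not constants.
    """
    if name not in FIXTURE_NAMES:
        raise KaryotypeError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    text = resources.files("minikaryo.data").joinpath(f"{name}.tsv").read_text()
    return parse_karyotype(text, species=name)


def revcomp(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return seq.translate(_RC_TABLE)[::-1]


_RC_TABLE = str.maketrans("ACGTN", "TGCAN")
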