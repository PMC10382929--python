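"""Toy iterative map-to-reference assembler for minichromosomal genomes.

Mirrors the published strategy at desk scale: quality/N read filtering,
seed-and-extend assembly of one minichromosome from a gene seed,
circularization, derivation of the conserved large-NCR consensus shared
by two seed assemblies, and NCR-bait recovery of the remaining
minichromosomes.  Overlaps are ungapped (substitution-only error model);
identity over an overlap is exact matches / overlap length.

Not a general-purpose assembler: no de Bruijn graph, no scaffolding, no
polishing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .model import revcomp
from .stretch import longest_shared_stretch
from .synth import ReadPair

__all__ = [
    "AssemblyError",
    "Contig",
    "filter_reads",
    "iterative_extend",
    "derive_ncr_consensus",
    "bait_assemble",
    "canonical_rotation",
    "rotation_equal",
    "read_fastq_pairs",
]

DEFAULT_MIN_OVERLAP = 200  # published assembly parameters
DEFAULT_MIN_IDENTITY = 0.99


class AssemblyError(RuntimeError):
    pass


@dataclass
class Contig:
    sequence: str
    circular: bool = False
    depth: list[int] = field(default_factory=list)
    provenance: str = "seed"

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mean_depth(self) -> float:
        return sum(self.depth) / len(self.depth) if self.depth else 0.0


def _phred(qual: str) -> list[int]:
    return [ord(c) - 33 for c in qual]


def _mate_ok(seq: str, qual: str, max_n_frac: float, q_thresh: int, max_lowq_frac: float) -> bool:
    if len(seq) != len(qual) or not seq:
        raise AssemblyError("malformed read: sequence/quality length mismatch")
    if seq.count("N") / len(seq) > max_n_frac:
        return False
    low = sum(1 for q in _phred(qual) if q <= q_thresh)
    return low / len(qual) <= max_lowq_frac


def filter_reads(
    pairs: Iterable[ReadPair],
    max_n_frac: float = 0.10,
    q_thresh: int = 20,
    max_lowq_frac: float = 0.50,
) -> list[ReadPair]:
    """Drop read pairs where either mate has >10% N or >50% bases at Q<=20.

    Order of the surviving pairs is preserved; the operation is
    idempotent.
    """
    kept = []
    for idx, p in enumerate(pairs):
        try:
            ok = _mate_ok(p.mate1, p.qual1, max_n_frac, q_thresh, max_lowq_frac) and _mate_ok(
                p.mate2, p.qual2, max_n_frac, q_thresh, max_lowq_frac
            )
        except AssemblyError as err:
            raise AssemblyError(f"record {idx}: {err}") from None
        if ok:
            kept.append(p)
    return kept


def read_fastq_pairs(path1, path2) -> list[ReadPair]:
    """Load paired FASTQ files (plain text, 4 lines per record)."""

    def _records(path):
        out = []
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh]
        if len(lines) % 4:
            raise AssemblyError(f"{path}: truncated FASTQ (record {len(lines) // 4})")
        for i in range(0, len(lines), 4):
            if not lines[i].startswith("@") or not lines[i + 2].startswith("+"):
                raise AssemblyError(f"{path}: malformed FASTQ at record {i // 4}")
            out.append((lines[i][1:].split()[0], lines[i + 1], lines[i + 3]))
        return out

    r1, r2 = _records(path1), _records(path2)
    if len(r1) != len(r2):
        raise AssemblyError("mate files differ in record count")
    return [
        ReadPair(
            name=n1.removesuffix("/1"),
            mate1=s1, qual1=q1, mate2=s2, qual2=q2,
            origin_label="", origin_start=-1,
        )
        for (n1, s1, q1), (_, s2, q2) in zip(r1, r2)
    ]


def _read_pool(pairs: Sequence[ReadPair]) -> list[str]:
    """All mate sequences plus reverse complements."""
    pool = []
    for p in pairs:
        pool.append(p.mate1)
        pool.append(p.mate2)
    pool += [revcomp(s) for s in pool]
    return pool


class _KmerIndex:
    """Exact k-mer positions over a read pool, for overlap candidate lookup."""

    def __init__(self, reads: list[str], k: int):
        self.reads = reads
        self.k = k
        self.index: dict[str, list[tuple[int, int]]] = {}
        for ridx, seq in enumerate(reads):
            for pos in range(0, len(seq) - k + 1):
                self.index.setdefault(seq[pos : pos + k], []).append((ridx, pos))

    def candidates(self, kmer: str) -> list[tuple[int, int]]:
        return self.index.get(kmer, [])


def _identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    if not a:
        return 0.0
    return sum(1 for x, y in zip(a, b) if x == y) / len(a)


def _consensus(columns: list[list[str]]) -> str:
    """Majority base per column; ties resolve to the earliest-observed base."""
    out = []
    for col in columns:
        counts: dict[str, int] = {}
        for base in col:
            counts[base] = counts.get(base, 0) + 1
        out.append(max(counts, key=lambda b: (counts[b], -col.index(b))))
    return "".join(out)


def _try_circularize(contig: str, min_overlap: int, min_identity: float) -> str | None:
    """If the contig end matches its own start, close the circle (trim overlap)."""
    best = None
    max_ov = min(len(contig) - min_overlap, 2 * min_overlap + len(contig) // 2)
    for ov in range(min_overlap, max_ov + 1):
        if _identity(contig[-ov:], contig[:ov]) >= min_identity:
            best = ov
    if best is None:
        return None
    return contig[: len(contig) - best]


def iterative_extend(
    pairs: Sequence[ReadPair],
    seed_sequence: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_length: int | None = None,
    _index: "_KmerIndex | None" = None,
) -> Contig:
    """Seed-and-extend one minichromosome from reads, to a fixpoint.

    Each round gathers reads whose prefix overlaps the contig end by at
    least ``min_overlap`` bases at ``min_identity`` (ungapped), extends
    by the majority consensus of their overhangs, and stops when no read
    extends the contig or when the two contig ends mutually overlap under
    the same thresholds (the contig is then circular and the duplicated
    overlap is trimmed).
    """
    if len(seed_sequence) < min_overlap:
        raise AssemblyError(
            f"seed ({len(seed_sequence)} bp) shorter than min_overlap {min_overlap}"
        )
    index = _index if _index is not None else _KmerIndex(_read_pool(pairs), k=min(21, min_overlap))
    k = index.k
    reads = index.reads
    contig = seed_sequence
    max_length = max_length or 100 * len(seed_sequence)

    seeded = any(contig[i : i + k] in index.index for i in range(0, len(contig) - k + 1, k))
    if not seeded:
        raise AssemblyError("seed not covered")

    depth = [0] * len(contig)
    while len(contig) < max_length:
        closed = _try_circularize(contig, min_overlap, min_identity)
        if closed is not None and len(closed) >= min_overlap:
            return Contig(
                sequence=closed, circular=True, depth=depth[: len(closed)], provenance="seed"
            )
        terminal = contig[-k:]
        overhang_cols: list[list[str]] = []
        for ridx, pos in index.candidates(terminal):
            read = reads[ridx]
            # read aligned so read[pos:pos+k] sits on the contig's terminal k-mer
            ov = min(pos + k, len(contig))
            if ov < min_overlap:
                continue
            if _identity(read[pos + k - ov : pos + k], contig[-ov:]) < min_identity:
                continue
            overhang = read[pos + k :]
            for col, base in enumerate(overhang):
                if col >= len(overhang_cols):
                    overhang_cols.append([])
                overhang_cols[col].append(base)
        if not overhang_cols:
            break
        contig += _consensus(overhang_cols)
        depth += [len(col) for col in overhang_cols]
    return Contig(sequence=contig, circular=False, depth=depth, provenance="seed")


def derive_ncr_consensus(
    contig_a: Contig,
    contig_b: Contig,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> str:
    """Longest high-identity region shared by two circular contigs.

    Finds the longest exact shared core on the doubled circles, then
    extends it outward while the running identity stays at or above
    ``min_identity`` (trimming back to the last matching position).  The
    consensus is reported on contig_a's strand and coordinates, i.e. in
    the upstream-to-downstream orientation of contig_a's gene cluster.
    """
    if not (contig_a.circular and contig_b.circular):
        raise AssemblyError("both contigs must be circular")
    a, b = contig_a.sequence, contig_b.sequence
    cap = min(len(a), len(b))
    hit = longest_shared_stretch(a + a, b + b)
    if hit.length_bp == 0 or min(hit.length_bp, cap) < min_overlap:
        raise AssemblyError(f"no shared region of >= {min_overlap} bp")
    length = min(hit.length_bp, cap)
    start_a, start_b = hit.pos_a, hit.pos_b
    # extend across isolated substitutions while running identity holds,
    # rolling back to the last exactly-matching position on each side
    aa, bb = a + a, b + b
    end_a, end_b = start_a + length, start_b + length
    matches = total = length
    checkpoint = (end_a, end_b, matches, total)
    while end_a < 2 * len(a) and end_b < 2 * len(b) and total < cap:
        same = aa[end_a] == bb[end_b]
        matches += same
        total += 1
        end_a += 1
        end_b += 1
        if matches / total < min_identity:
            break
        if same:
            checkpoint = (end_a, end_b, matches, total)
    end_a, end_b, matches, total = checkpoint
    checkpoint = (start_a, start_b, matches, total)
    while start_a > 0 and start_b > 0 and total < cap:
        same = aa[start_a - 1] == bb[start_b - 1]
        matches += same
        total += 1
        start_a -= 1
        start_b -= 1
        if matches / total < min_identity:
            break
        if same:
            checkpoint = (start_a, start_b, matches, total)
    start_a, start_b, _, _ = checkpoint
    return aa[start_a:end_a][:cap]


def bait_assemble(
    pairs: Sequence[ReadPair],
    ncr_consensus: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    flank_group_len: int = 15,
    end_trim: int = 4,
) -> list[Contig]:
    """Recover minichromosomes by baiting reads with the shared NCR.

    Reads matching the downstream end of the NCR consensus and running
    past it into a gene cluster are grouped by their cluster-facing
    flanking sequence; each distinct flank seeds one extension.  The
    number of distinct circles recovered is the assembler's
    minichromosome-count estimate.  ``end_trim`` discards a few consensus
    bases at both ends before matching: a pairwise-derived consensus can
    overrun the genuinely conserved region by a couple of chance-matched
    bases, which would otherwise hide the junctions of other
    minichromosomes.
    """
    if not ncr_consensus:
        raise AssemblyError("empty NCR consensus")
    if len(ncr_consensus) > 3 * end_trim:
        ncr_consensus = ncr_consensus[end_trim : len(ncr_consensus) - end_trim]
    window_len = min(min_overlap, len(ncr_consensus))
    if window_len < flank_group_len:
        raise AssemblyError("NCR consensus too short to bait reads")
    index = _KmerIndex(_read_pool(pairs), k=min(21, min_overlap))
    end_window = ncr_consensus[-window_len:]
    flanks: dict[str, str] = {}
    for read in index.reads:
        p = read.find(end_window)
        if p < 0:
            continue
        overhang = read[p + len(end_window) :]
        if len(overhang) < flank_group_len:
            continue
        key = overhang[:flank_group_len]
        if key not in flanks or len(overhang) > len(flanks[key]):
            flanks[key] = overhang
    contigs: list[Contig] = []
    seen: set[str] = set()
    for key in sorted(flanks):
        seed = ncr_consensus + flanks[key]
        try:
            contig = iterative_extend(
                pairs, seed, min_overlap=min_overlap, min_identity=min_identity, _index=index
            )
        except AssemblyError:
            continue
        contig.provenance = "baited"
        canon = canonical_rotation(contig.sequence) if contig.circular else contig.sequence
        if canon in seen:
            continue
        seen.add(canon)
        contigs.append(contig)
    return contigs


def canonical_rotation(seq: str) -> str:
    """Lexicographically minimal rotation (Booth's algorithm)."""
    s = seq + seq
    n = len(seq)
    i, j, k = 0, 1, 0
    while i < n and j < n and k < n:
        a, b = s[i + k], s[j + k]
        if a == b:
            k += 1
            continue
        if a > b:
            i = max(i + k + 1, j)
        else:
            j = max(j + k + 1, i)
        if i == j:
            j += 1
        k = 0
    start = min(i, j)
    return s[start : start + n]


def rotation_equal(a: str, b: str) -> bool:
    return len(a) == len(b) and canonical_rotation(a) == canonical_rotation(b)
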