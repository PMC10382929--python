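"""Sequence-level evidence of recombination.

Three primitives: global-alignment percent difference between gene
copies, longest shared identical stretch between two sequences (with an
optional reverse-complement search and a Monte-Carlo null for the length
expected by chance), and discovery of motifs exactly conserved across
all large non-coding regions (NCRs) of a genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import revcomp

__all__ = [
    "StretchHit",
    "MotifHit",
    "percent_difference",
    "longest_shared_stretch",
    "stretch_null_quantile",
    "find_conserved_motifs",
]

_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class StretchHit:
    """A maximal exact match between two sequences."""

    length_bp: int
    pos_a: int
    pos_b: int
    strand: str = "same"  # or "revcomp"

    def __post_init__(self) -> None:
        if self.strand not in ("same", "revcomp"):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class MotifHit:
    """A substring conserved exactly across every supplied NCR."""

    consensus: str
    length_bp: int
    at_fraction: float
    position_class: str  # upstream_of_cluster | downstream_of_cluster
    offsets: tuple[int, ...]


def _check_seq(seq: str, argname: str) -> str:
    if not seq:
        raise ValueError(f"{argname} must be non-empty")
    if not set(seq) <= _ALPHABET:
        raise ValueError(f"{argname} contains characters outside ACGTN")
    return seq


def percent_difference(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> float:
    """Percent difference of two sequences under global end-to-end alignment.

    The difference is (mismatch columns + gap columns) / alignment length
    x 100.  Gap columns count as differences and end gaps are penalized,
    so identical sequences score 0 and the measure is symmetric (operands
    are ordered canonically before aligning).  The published per-gene
    percentages were computed with unstated parameters, so values from
    this function are reported alongside the scoring scheme rather than
    asserted against the paper.
    """
    _check_seq(a, "a")
    _check_seq(b, "b")
    if b < a:
        a, b = b, a
    n_mis, n_gap, length = _global_alignment_columns(a, b, match, mismatch, gap)
    return 100.0 * (n_mis + n_gap) / length


def _global_alignment_columns(
    a: str, b: str, match: int, mismatch: int, gap: int
) -> tuple[int, int, int]:
    """Needleman-Wunsch with linear gaps; deterministic traceback.

    Ties prefer diagonal, then the up (gap in b) move, then left.
    Returns (mismatch columns, gap columns, alignment length).
    """
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1), dtype=np.int64)
    score[0, :] = gap * np.arange(m + 1)
    score[:, 0] = gap * np.arange(n + 1)
    eq = np.frombuffer(a.encode(), dtype=np.uint8)[:, None] == np.frombuffer(
        b.encode(), dtype=np.uint8
    )[None, :]
    sub = np.where(eq, match, mismatch)
    for i in range(1, n + 1):
        diag = score[i - 1, :-1] + sub[i - 1]
        up = score[i - 1, 1:] + gap
        best = np.maximum(diag, up)
        row = score[i]
        prev = score[i, 0]
        for j in range(1, m + 1):
            prev = max(best[j - 1], prev + gap)
            row[j] = prev
    i, j = n, m
    n_mis = n_gap = length = 0
    while i > 0 or j > 0:
        s = score[i, j]
        if i > 0 and j > 0 and s == score[i - 1, j - 1] + sub[i - 1, j - 1]:
            if a[i - 1] != b[j - 1]:
                n_mis += 1
            i, j = i - 1, j - 1
        elif i > 0 and s == score[i - 1, j] + gap:
            n_gap += 1
            i -= 1
        else:
            n_gap += 1
            j -= 1
        length += 1
    return n_mis, n_gap, length


def _lcs_arrays(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """Longest common substring of two uint8 arrays.

    Returns (length, start in a, start in b); ties resolve to the
    smallest start in a, then in b.  O(n*m) time, O(m) memory.
    """
    n, m = len(a), len(b)
    prev = np.zeros(m, dtype=np.int32)
    best_len, best_end_a, best_end_b = 0, 0, 0
    for i in range(n):
        eq = a[i] == b
        cur = np.where(eq, 1, 0).astype(np.int32)
        cur[1:] += np.where(eq[1:], prev[:-1], 0)
        row_max = int(cur.max()) if m else 0
        if row_max > best_len:
            best_len = row_max
            best_end_a = i
            best_end_b = int(np.argmax(cur))
        prev = cur
    if best_len == 0:
        return 0, 0, 0
    return best_len, best_end_a - best_len + 1, best_end_b - best_len + 1


def _as_u8(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def longest_shared_stretch(a: str, b: str, include_revcomp: bool = False) -> StretchHit:
    """Maximal-length exact substring shared by two sequences.

    With ``include_revcomp`` the reverse complement of ``b`` is searched
    as well; a same-strand hit wins over an equally long reverse hit.
    Positions refer to the original orientations of both inputs.  A
    zero-length sentinel hit is returned when nothing is shared.
    """
    _check_seq(a, "a")
    _check_seq(b, "b")
    length, pa, pb = _lcs_arrays(_as_u8(a), _as_u8(b))
    hit = StretchHit(length_bp=length, pos_a=pa, pos_b=pb, strand="same")
    if include_revcomp:
        rlength, rpa, rpb = _lcs_arrays(_as_u8(a), _as_u8(revcomp(b)))
        if rlength > hit.length_bp:
            hit = StretchHit(
                length_bp=rlength,
                pos_a=rpa,
                pos_b=len(b) - rpb - rlength,
                strand="revcomp",
            )
    if hit.length_bp == 0:
        return StretchHit(length_bp=0, pos_a=0, pos_b=0, strand="same")
    return hit


def stretch_null_quantile(
    len_a: int,
    len_b: int,
    gc: float,
    reps: int,
    q: float,
    seed: int,
) -> float:
    """Monte-Carlo null for the longest shared stretch expected by chance.

    Simulates ``reps`` iid sequence pairs with the given lengths and GC
    content (iid multinomial model, no Markov correction) and returns the
    empirical ``q``-quantile of the maximal shared stretch length.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100 for a usable quantile")
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc must be in [0, 1], got {gc}")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must be in [0, 1], got {q}")
    if len_a < 1 or len_b < 1:
        raise ValueError("sequence lengths must be positive")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    lengths = np.empty(reps, dtype=np.int32)
    for r in range(reps):
        sa = bases[rng.choice(4, size=len_a, p=probs)]
        sb = bases[rng.choice(4, size=len_b, p=probs)]
        lengths[r], _, _ = _lcs_arrays(sa, sb)
    return float(np.quantile(lengths, q))


def find_conserved_motifs(ncrs: list[str], min_len: int = 20) -> list[MotifHit]:
    """Longest substrings exactly conserved across all supplied NCRs.

    Every maximal common substring of length >= ``min_len`` is reported
    (candidates contained in a longer hit are pruned), ordered by length
    descending then sequence.  NCR coordinates are cluster-relative: the
    NCR runs from the downstream end of the gene cluster around the
    circle to its upstream start, so a motif sitting in the second half
    of the NCRs is classed ``upstream_of_cluster`` (by majority vote of
    per-NCR offsets) and one in the first half ``downstream_of_cluster``.
    """
    if len(ncrs) < 2:
        raise ValueError("need at least two NCRs")
    for i, s in enumerate(ncrs):
        _check_seq(s, f"ncrs[{i}]")
    pivot = min(ncrs, key=len)
    others = [s for s in ncrs if s is not pivot]

    def common_len_from(i: int) -> int:
        lo, hi = 0, len(pivot) - i
        while lo < hi:
            mid = (lo + hi + 1) // 2
            sub = pivot[i : i + mid]
            if all(sub in s for s in others):
                lo = mid
            else:
                hi = mid - 1
        return lo

    candidates: dict[str, None] = {}
    for i in range(len(pivot)):
        length = common_len_from(i)
        if length >= min_len:
            candidates[pivot[i : i + length]] = None
    motifs = [
        s
        for s in candidates
        if not any(s != other and s in other for other in candidates)
    ]
    motifs.sort(key=lambda s: (-len(s), s))

    hits = []
    for motif in motifs:
        offsets = tuple(s.find(motif) for s in ncrs)
        upstream_votes = sum(
            1 for off, s in zip(offsets, ncrs) if off + len(motif) / 2 >= len(s) / 2
        )
        at = sum(1 for c in motif if c in "AT") / len(motif)
        hits.append(
            MotifHit(
                consensus=motif,
                length_bp=len(motif),
                at_fraction=at,
                position_class=(
                    "upstream_of_cluster"
                    if upstream_votes * 2 >= len(ncrs)
                    else "downstream_of_cluster"
                ),
                offsets=offsets,
            )
        )
    return hits
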