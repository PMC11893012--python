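"""Pairwise alignment primitives.

Two tools only: an ungapped seed-and-extend nucleotide block aligner used for
intergenomic similarity (substitution-dominated phage genome pairs), and a
global protein percent-identity based on Needleman-Wunsch alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align

from .genome_io import reverse_complement

__all__ = ["AlignedBlock", "anchor_block_align", "protein_identity", "protein_alignment_stats"]


@dataclass(frozen=True)
class AlignedBlock:
    """An ungapped aligned block between two sequences.

    Coordinates are 0-based half-open on each sequence's forward strand; for
    strand "-" the block pairs A[a_start:a_end] with the reverse complement of
    B[b_start:b_end].
    """

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    strand: str
    matches: int
    length: int


def _extend_ungapped(
    a: str,
    b: str,
    a0: int,
    b0: int,
    k: int,
    min_identity: float,
    window: int = 16,
    window_min: int = 8,
) -> tuple[int, int, int]:
    """Extend an exact k-mer seed at (a0, b0) in both directions.

    Extension stops when a sliding window of recent columns drops below 50%
    matches (the block has run off the homologous region) and the block is
    trimmed back to the last match keeping cumulative identity >= min_identity.
    Returns (start offset <= 0, end offset >= k, matches) relative to a0.
    """
    la, lb = len(a), len(b)

    def walk(direction: int) -> tuple[int, int]:
        # direction +1 extends right from the seed end, -1 extends left.
        matches = 0
        length = 0
        best_len = 0
        best_matches = 0
        recent = 0  # match count in the last `window` columns
        hist = []
        if direction > 0:
            ai, bi = a0 + k, b0 + k
        else:
            ai, bi = a0 - 1, b0 - 1
        base_m = k  # seed matches included in cumulative identity
        while 0 <= ai < la and 0 <= bi < lb:
            m = 1 if a[ai] == b[bi] else 0
            matches += m
            length += 1
            hist.append(m)
            recent += m
            if length > window:
                recent -= hist[length - window - 1]
            if m and (base_m + matches) / (k + length) >= min_identity:
                best_len, best_matches = length, matches
            if length >= window and recent < window_min:
                break
            ai += direction
            bi += direction
        return best_len, best_matches

    right_len, right_m = walk(+1)
    left_len, left_m = walk(-1)
    return -left_len, k + right_len, k + left_m + right_m


def _scan_strand(a: str, b: str, k: int, min_identity: float) -> list[tuple[int, int, int]]:
    """Seed-and-extend a against b (forward orientation).

    Returns blocks as (a_start, b_start, length, ...) tuples with match counts:
    (a_start, a_end, b_start, matches).
    """
    index: dict[str, list[int]] = {}
    for j in range(len(b) - k + 1):
        index.setdefault(b[j : j + k], []).append(j)
    # diagonal -> rightmost a-coordinate already covered by an extended block
    covered: dict[int, int] = {}
    blocks: list[tuple[int, int, int, int]] = []
    for i in range(len(a) - k + 1):
        hits = index.get(a[i : i + k])
        if not hits:
            continue
        for j in hits:
            d = i - j
            if covered.get(d, -1) >= i + k:
                continue
            lo, hi, m = _extend_ungapped(a, b, i, j, k, min_identity)
            blocks.append((i + lo, i + hi, j + lo, m))
            covered[d] = max(covered.get(d, -1), i + hi)
    return blocks


def _overlaps(s: int, e: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s < ie and e > is_ for is_, ie in intervals)


def _clip_block(
    c: AlignedBlock,
    a_iv: list[tuple[int, int]],
    b_iv: list[tuple[int, int]],
    seq_a: str,
    seq_b: str,
    min_block: int,
) -> AlignedBlock | None:
    """Clip a candidate block against already-selected intervals.

    Overlaps on B are mapped onto A through the block's diagonal; the
    surviving sub-block keeps the left part when a selected interval splits
    it.  Matches are recounted on the clipped range."""
    s, e = c.a_start, c.a_end

    def b_to_a(is_: int, ie: int) -> tuple[int, int]:
        if c.strand == "+":
            d = c.a_start - c.b_start
            return is_ + d, ie + d
        return c.a_start + (c.b_end - ie), c.a_start + (c.b_end - is_)

    mapped = a_iv + [b_to_a(is_, ie) for is_, ie in b_iv]
    changed = True
    while changed and s < e:
        changed = False
        for is_, ie in mapped:
            if s < ie and e > is_:
                if is_ <= s:
                    s = ie
                else:  # right or middle overlap: keep the left part
                    e = is_
                changed = True
                break
    if e - s < min_block:
        return None
    if c.strand == "+":
        b_s = c.b_start + (s - c.a_start)
        b_e = b_s + (e - s)
        sub_b = seq_b[b_s:b_e]
    else:
        b_e = c.b_end - (s - c.a_start)
        b_s = c.b_end - (e - c.a_start)
        sub_b = reverse_complement(seq_b[b_s:b_e])
    sub_a = seq_a[s:e]
    matches = sum(1 for x, y in zip(sub_a, sub_b) if x == y)
    return AlignedBlock(s, e, b_s, b_e, c.strand, matches, e - s)


def anchor_block_align(
    seq_a: str,
    seq_b: str,
    k: int = 13,
    min_block: int = 30,
    min_identity: float = 0.70,
) -> list[AlignedBlock]:
    """Shared-k-mer seeded, ungapped block alignment of two genomes.

    Both strands of B are scanned; candidate blocks are resolved greedily by
    descending match count (ties by ascending coordinates) so the selected
    blocks are mutually non-overlapping on each sequence; blocks shorter than
    ``min_block`` are dropped.  No shared k-mers yields an empty list.
    """
    if len(seq_a) < k or len(seq_b) < k:
        return []
    seq_a = seq_a.upper()
    seq_b = seq_b.upper()
    candidates: list[AlignedBlock] = []
    for a_s, a_e, b_s, m in _scan_strand(seq_a, seq_b, k, min_identity):
        candidates.append(AlignedBlock(a_s, a_e, b_s, b_s + (a_e - a_s), "+", m, a_e - a_s))
    rc = reverse_complement(seq_b)
    lb = len(seq_b)
    for a_s, a_e, b_s, m in _scan_strand(seq_a, rc, k, min_identity):
        length = a_e - a_s
        candidates.append(
            AlignedBlock(a_s, a_e, lb - (b_s + length), lb - b_s, "-", m, length)
        )
    candidates = [c for c in candidates if c.length >= min_block]
    # dedupe identical blocks produced by multiple seeds on one diagonal
    candidates = sorted(set(candidates), key=lambda c: (-c.matches, c.a_start, c.b_start))
    chosen: list[AlignedBlock] = []
    a_iv: list[tuple[int, int]] = []
    b_iv: list[tuple[int, int]] = []
    for c in candidates:
        if _overlaps(c.a_start, c.a_end, a_iv) or _overlaps(c.b_start, c.b_end, b_iv):
            clipped = _clip_block(c, a_iv, b_iv, seq_a, seq_b, min_block)
            if clipped is None:
                continue
            c = clipped
        chosen.append(c)
        a_iv.append((c.a_start, c.a_end))
        b_iv.append((c.b_start, c.b_end))
    chosen.sort(key=lambda c: c.a_start)
    return chosen


# ---------------------------------------------------------------------------
# Protein identity

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()


@lru_cache(maxsize=200_000)
def _align_cached(p1: str, p2: str) -> tuple[float, float, int]:
    aln = _ALIGNER.align(p1, p2)[0]
    counts = aln.counts()
    identity = 100.0 * counts.identities / aln.length
    coverage = (counts.identities + counts.mismatches) / max(len(p1), len(p2))
    return identity, coverage, aln.length


def protein_identity(p1: str, p2: str) -> float:
    """Global-alignment percent identity: 100 x identical columns / columns.

    Scoring is match +1, mismatch 0, gap open -10, gap extend -0.5; gap
    columns count in the denominator.
    """
    if not p1 or not p2:
        raise ValueError("protein_identity requires non-empty sequences")
    return _align_cached(p1, p2)[0]


def protein_alignment_stats(p1: str, p2: str) -> tuple[float, float]:
    """(percent identity, aligned-pair coverage of the longer sequence)."""
    if not p1 or not p2:
        raise ValueError("protein alignment requires non-empty sequences")
    identity, coverage, _ = _align_cached(p1, p2)
    return identity, coverage
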