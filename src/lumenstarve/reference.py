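"""Exhaustive brute-force reference scanners.

Straight-line implementations that try every (k, position, spacer)
combination by direct string comparison.  They are deliberately written
without the k-mer indexes used by :mod:`lumenstarve.motif_scan` so the
two code paths can cross-validate each other; the synthetic promoter
generator also uses them as its rejection screen.
"""

from __future__ import annotations

from .genome_io import reverse_complement
from .motif_scan import (
    InvertedRepeat,
    OverlappingIRPair,
    TandemInvertedRepeat,
    _check_sequence,
)

__all__ = [
    "brute_inverted_repeats",
    "brute_filter_subsumed",
    "brute_overlapping_pairs",
    "brute_tandem_inverted",
]


def brute_inverted_repeats(
    seq: str, kmin: int = 6, kmax: int = 15, seq_id: str = ""
) -> list[InvertedRepeat]:
    """Try every (k, left_start, spacer) triple explicitly."""
    s = _check_sequence(seq)
    n = len(s)
    hits: list[InvertedRepeat] = []
    for left in range(n):
        for k in range(kmin, kmax + 1):
            if left + 2 * k > n:
                break
            arm = s[left : left + k]
            if "N" in arm:
                continue
            rc = reverse_complement(arm)
            for spacer in range(0, k + 1):
                right = left + k + spacer
                if right + k > n:
                    break
                window = s[right : right + k]
                if "N" not in window and window == rc:
                    hits.append(InvertedRepeat(arm, k, left, right, seq_id))
    hits.sort(key=InvertedRepeat.sort_key)
    return hits


def brute_filter_subsumed(hits: list[InvertedRepeat]) -> list[InvertedRepeat]:
    """Longest-first subsumption sweep, re-derived from the rule text.

    Walk arm lengths from the largest present down to the smallest; at
    each level delete every hit of that length whose two arm intervals
    both lie inside the corresponding arms of a surviving longer hit.
    """
    survivors = list(hits)
    for k in sorted({h.k for h in hits}, reverse=True):
        keep = []
        for h in survivors:
            if h.k != k:
                keep.append(h)
                continue
            swallowed = False
            for other in survivors:
                if other.k <= h.k:
                    continue
                left_inside = (
                    other.left_start <= h.left_start
                    and h.left_start + h.k <= other.left_start + other.k
                )
                right_inside = (
                    other.right_start <= h.right_start
                    and h.right_start + h.k <= other.right_start + other.k
                )
                if left_inside and right_inside:
                    swallowed = True
                    break
            if not swallowed:
                keep.append(h)
        survivors = keep
    survivors.sort(key=InvertedRepeat.sort_key)
    return survivors


def brute_overlapping_pairs(hits: list[InvertedRepeat]) -> list[OverlappingIRPair]:
    """All-pairs footprint intersection check."""
    ordered = sorted(hits, key=InvertedRepeat.sort_key)
    pairs: list[OverlappingIRPair] = []
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            a, b = ordered[i], ordered[j]
            a_lo, a_hi = a.footprint
            b_lo, b_hi = b.footprint
            overlap = min(a_hi, b_hi) - max(a_lo, b_lo) + 1
            if overlap >= 1:
                pairs.append(OverlappingIRPair(a, b, overlap))
    return pairs


def brute_tandem_inverted(
    seq: str, kmin: int = 6, kmax: int = 15, seq_id: str = ""
) -> list[TandemInvertedRepeat]:
    """Try every (k, p1, gap1, gap2) combination explicitly."""
    s = _check_sequence(seq)
    n = len(s)
    hits: list[TandemInvertedRepeat] = []
    for k in range(kmin, kmax + 1):
        for p1 in range(n - 3 * k + 1):
            w1 = s[p1 : p1 + k]
            if "N" in w1 or ("C" not in w1 and "G" not in w1):
                continue
            rc1 = reverse_complement(w1)
            if rc1 == w1:
                continue
            for g1 in range(0, k + 1):
                p2 = p1 + k + g1
                if p2 + k > n:
                    break
                w2 = s[p2 : p2 + k]
                if "N" in w2:
                    continue
                for g2 in range(0, k + 1):
                    p3 = p2 + k + g2
                    if p3 + k > n:
                        break
                    w3 = s[p3 : p3 + k]
                    if "N" in w3:
                        continue
                    # (F, F, RC): copies of w1 then its reverse complement
                    if w2 == w1 and w3 == rc1:
                        hits.append(
                            TandemInvertedRepeat(
                                w1, k, (p1, p2, p3),
                                ("forward", "forward", "revcomp"), seq_id,
                            )
                        )
                    # (RC, F, F): w1 is the reverse complement of the oligo
                    if w2 == rc1 and w3 == rc1:
                        hits.append(
                            TandemInvertedRepeat(
                                rc1, k, (p1, p2, p3),
                                ("revcomp", "forward", "forward"), seq_id,
                            )
                        )
    hits.sort(key=lambda t: (t.starts[0], t.k, t.starts[1], t.starts[2]))
    return hits
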