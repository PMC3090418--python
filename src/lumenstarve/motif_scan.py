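"""Repeat-motif discovery in promoter sequences.

Two structured motif classes are searched:

* **Overlapping inverted repeats** — first every individual inverted
  repeat (IR) is enumerated: a repeating oligo of ``kmin``..``kmax``
  nucleotides followed, after a spacer no longer than the oligo, by its
  reverse complement.  Low-complexity oligos (no C or G) are discarded,
  as are IRs better represented by a longer retained IR (both arms
  nested inside the longer IR's arms).  Surviving IRs whose footprints
  intersect form overlapping pairs.
* **Tandem + inverted repeats** — an oligo of the same length range
  occurring three times in close proximity (gaps of 0..k nucleotides)
  with exactly one *terminal* occurrence reverse complemented relative
  to the other two, and at least one C or G in the oligo.

A degenerate-consensus scanner covers operator-box models (e.g. the
three Fur-box structures: a 19-bp inverted repeat, a hexamer
head-to-head-to-tail triplet, and two overlapping heptamer inverted
repeats (7-1-7)x2) with a configurable mismatch allowance; a strict scan
uses 0 mismatches, "relaxed" scans any larger value.

The production scanner uses a k-mer position index; the exhaustive
reference implementation used for cross-validation lives in
:mod:`lumenstarve.reference`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .genome_io import PromoterRegion, ValidationError, reverse_complement

__all__ = [
    "InvertedRepeat",
    "OverlappingIRPair",
    "TandemInvertedRepeat",
    "ConsensusModel",
    "ConsensusHit",
    "MotifReport",
    "SequenceScan",
    "enumerate_inverted_repeats",
    "filter_low_complexity",
    "filter_subsumed",
    "find_overlapping_ir_pairs",
    "find_tandem_inverted",
    "scan_consensus",
    "scan_promoter_set",
    "DEFAULT_CONSENSUS_MODELS",
]

_VALID = frozenset("ACGTN")

IUPAC_CLASSES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


def _check_sequence(seq: str) -> str:
    s = seq.upper()
    bad = set(s) - _VALID
    if bad:
        raise ValidationError(f"illegal nucleotide(s) {sorted(bad)} in sequence")
    return s


@dataclass(frozen=True)
class InvertedRepeat:
    """One inverted repeat: ``oligo`` (left arm) ... spacer ... revcomp(oligo)."""

    oligo: str
    k: int
    left_start: int
    right_start: int
    seq_id: str = ""

    @property
    def spacer(self) -> int:
        return self.right_start - (self.left_start + self.k)

    @property
    def footprint(self) -> tuple[int, int]:
        """0-based inclusive (start, end) of the full motif."""
        return (self.left_start, self.right_start + self.k - 1)

    def sort_key(self) -> tuple[int, int, int]:
        return (self.left_start, self.k, self.spacer)


@dataclass(frozen=True)
class OverlappingIRPair:
    """Unordered pair of distinct IRs with intersecting footprints."""

    first: InvertedRepeat
    second: InvertedRepeat
    overlap_len: int


@dataclass(frozen=True)
class TandemInvertedRepeat:
    """Three close occurrences of an oligo, one terminal copy reverse complemented."""

    oligo: str
    k: int
    starts: tuple[int, int, int]
    orientations: tuple[str, str, str]  # each 'forward' or 'revcomp'
    seq_id: str = ""

    @property
    def gaps(self) -> tuple[int, int]:
        p1, p2, p3 = self.starts
        return (p2 - p1 - self.k, p3 - p2 - self.k)


@dataclass(frozen=True)
class ConsensusModel:
    """A degenerate IUPAC pattern with a mismatch budget."""

    name: str
    pattern: str
    max_mismatches: int = 0
    structure_tag: str = ""

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        object.__setattr__(self, "pattern", pat)
        bad = set(pat) - set(IUPAC_CLASSES)
        if bad:
            raise ValidationError(f"model {self.name!r}: invalid IUPAC code(s) {sorted(bad)}")
        if len(pat) < 6:
            raise ValidationError(f"model {self.name!r}: pattern shorter than 6")
        if not (0 <= self.max_mismatches < len(pat)):
            raise ValidationError(f"model {self.name!r}: max_mismatches out of range")


@dataclass(frozen=True)
class ConsensusHit:
    model: str
    position: int  # 0-based start of the window on the input (forward) sequence
    strand: str    # '+' or '-'
    mismatches: int
    seq_id: str = ""


# Editable default operator-box models.  The three Fur-box *structures*
# are documented in the literature but their HTCC1062 sequences are not;
# these generic patterns are placeholders meant to be overridden from
# configuration for any real search.
DEFAULT_CONSENSUS_MODELS: tuple[ConsensusModel, ...] = (
    ConsensusModel("furbox_19bp_ir", "GATAATGATAATCATTATC", 0, "ir_19bp"),
    ConsensusModel("furbox_hexamer_x3", "GATAATGATAATTATTAT", 0, "hexamer_x3"),
    ConsensusModel("furbox_heptamer_7_1_7_sq", "TGATAATNATTATCANTATCA", 0, "heptamer_7_1_7_sq"),
)


def enumerate_inverted_repeats(
    seq: str, kmin: int = 6, kmax: int = 15, seq_id: str = ""
) -> list[InvertedRepeat]:
    """Exhaustively enumerate individual inverted repeats (pre-filter).

    Reports every (k, left_start, spacer) with ``kmin <= k <= kmax`` and
    ``0 <= spacer <= k`` whose right arm equals the reverse complement of
    the left arm, with no N inside either arm.  Ordering is
    deterministic: (left_start, k, spacer).
    """
    if kmin < 1 or kmin > kmax:
        raise ValueError("need 1 <= kmin <= kmax")
    s = _check_sequence(seq)
    n = len(s)
    hits: list[InvertedRepeat] = []
    for k in range(kmin, kmax + 1):
        if 2 * k > n:
            break
        # index of all N-free k-mers by sequence
        index: dict[str, list[int]] = {}
        for i in range(n - k + 1):
            w = s[i : i + k]
            if "N" not in w:
                index.setdefault(w, []).append(i)
        for arm, positions in index.items():
            targets = index.get(reverse_complement(arm))
            if not targets:
                continue
            for i in positions:
                lo, hi = i + k, i + 2 * k  # right_start range for spacer in [0, k]
                for j in targets:
                    if lo <= j <= hi:
                        hits.append(InvertedRepeat(arm, k, i, j, seq_id))
    hits.sort(key=InvertedRepeat.sort_key)
    return hits


def filter_low_complexity(hits: Iterable[InvertedRepeat]) -> list[InvertedRepeat]:
    """Discard IRs whose repeating oligo lacks both C and G."""
    return [h for h in hits if ("C" in h.oligo or "G" in h.oligo)]


def _contains(outer: InvertedRepeat, inner: InvertedRepeat) -> bool:
    return (
        outer.k > inner.k
        and outer.left_start <= inner.left_start
        and inner.left_start + inner.k <= outer.left_start + outer.k
        and outer.right_start <= inner.right_start
        and inner.right_start + inner.k <= outer.right_start + outer.k
    )


def filter_subsumed(hits: Sequence[InvertedRepeat]) -> list[InvertedRepeat]:
    """Drop IRs better represented by a longer retained IR.

    An IR is removed when a retained IR of larger k contains both of its
    arms inside the corresponding longer arms.  Processing runs from the
    longest k downward, so containment is always judged against
    survivors (fixpoint of the longest-first sweep).
    """
    retained: list[InvertedRepeat] = []
    for h in sorted(hits, key=lambda h: (-h.k,) + h.sort_key()):
        if not any(_contains(b, h) for b in retained):
            retained.append(h)
    retained.sort(key=InvertedRepeat.sort_key)
    return retained


def find_overlapping_ir_pairs(hits: Sequence[InvertedRepeat]) -> list[OverlappingIRPair]:
    """All unordered pairs of distinct IRs whose footprints intersect (>= 1 bp)."""
    ordered = sorted(hits, key=InvertedRepeat.sort_key)
    pairs: list[OverlappingIRPair] = []
    for a_idx in range(len(ordered)):
        a = ordered[a_idx]
        a_lo, a_hi = a.footprint
        for b in ordered[a_idx + 1 :]:
            b_lo, b_hi = b.footprint
            overlap = min(a_hi, b_hi) - max(a_lo, b_lo) + 1
            if overlap >= 1:
                pairs.append(OverlappingIRPair(a, b, overlap))
    return pairs


def find_tandem_inverted(
    seq: str, kmin: int = 6, kmax: int = 15, seq_id: str = ""
) -> list[TandemInvertedRepeat]:
    """Find tandem + inverted repeats.

    A hit is an oligo of length k occurring at p1 < p2 < p3 with both
    gaps in [0, k], exactly one of the first/last occurrences reverse
    complemented relative to the other two, and at least one C or G in
    the oligo.  Oligos equal to their own reverse complement are
    rejected (the orientation rule is undecidable for them).  Ordering
    is deterministic: (p1, k, p2, p3).
    """
    if kmin < 1 or kmin > kmax:
        raise ValueError("need 1 <= kmin <= kmax")
    s = _check_sequence(seq)
    n = len(s)
    hits: list[TandemInvertedRepeat] = []
    for k in range(kmin, kmax + 1):
        if 3 * k > n:
            break
        index: dict[str, list[int]] = {}
        for i in range(n - k + 1):
            w = s[i : i + k]
            if "N" not in w:
                index.setdefault(w, []).append(i)
        for p1 in range(n - 3 * k + 1):
            w1 = s[p1 : p1 + k]
            if "N" in w1 or ("C" not in w1 and "G" not in w1):
                continue
            rc1 = reverse_complement(w1)
            if rc1 == w1:
                continue
            # pattern A: orientations (F, F, RC), oligo = w1
            # pattern B: orientations (RC, F, F), oligo = rc(w1)
            for pattern, mid_word, last_word in (
                ("A", w1, rc1),
                ("B", rc1, rc1),
            ):
                for p2 in index.get(mid_word, ()):
                    if not (p1 + k <= p2 <= p1 + 2 * k):
                        continue
                    for p3 in index.get(last_word, ()):
                        if not (p2 + k <= p3 <= p2 + 2 * k):
                            continue
                        if pattern == "A":
                            hits.append(
                                TandemInvertedRepeat(
                                    w1, k, (p1, p2, p3),
                                    ("forward", "forward", "revcomp"), seq_id,
                                )
                            )
                        else:
                            hits.append(
                                TandemInvertedRepeat(
                                    rc1, k, (p1, p2, p3),
                                    ("revcomp", "forward", "forward"), seq_id,
                                )
                            )
    hits.sort(key=lambda t: (t.starts[0], t.k, t.starts[1], t.starts[2]))
    return hits


def scan_consensus(seq: str, model: ConsensusModel, seq_id: str = "") -> list[ConsensusHit]:
    """Scan both strands for windows matching a degenerate pattern.

    A window matches when the number of positions whose base falls
    outside the pattern's IUPAC class is at most ``max_mismatches``.
    An N in the *sequence* never matches any class.  Minus-strand hit
    positions refer to the window start on the forward sequence.
    """
    s = _check_sequence(seq)
    m = len(model.pattern)
    n = len(s)
    if m > n:
        return []
    classes = [IUPAC_CLASSES[c] for c in model.pattern]
    hits: list[ConsensusHit] = []
    for strand, scanned in (("+", s), ("-", reverse_complement(s))):
        for i in range(n - m + 1):
            mism = 0
            window = scanned[i : i + m]
            for base, cls in zip(window, classes):
                if base not in cls:
                    mism += 1
                    if mism > model.max_mismatches:
                        break
            else:
                pos = i if strand == "+" else n - m - i
                hits.append(ConsensusHit(model.name, pos, strand, mism, seq_id))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


@dataclass
class SequenceScan:
    """All motif hits for one sequence."""

    seq_id: str
    inverted_repeats: list[InvertedRepeat]
    overlapping_pairs: list[OverlappingIRPair]
    tandem_inverted: list[TandemInvertedRepeat]
    consensus_hits: list[ConsensusHit] = field(default_factory=list)


@dataclass
class MotifReport:
    """Per-sequence scan results plus the parameters that produced them."""

    params: dict
    sequences: list[SequenceScan]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "inverted_repeats": sum(len(s.inverted_repeats) for s in self.sequences),
            "overlapping_pairs": sum(len(s.overlapping_pairs) for s in self.sequences),
            "tandem_inverted": sum(len(s.tandem_inverted) for s in self.sequences),
            "consensus_hits": sum(len(s.consensus_hits) for s in self.sequences),
        }


def scan_promoter_set(
    promoters: Sequence[PromoterRegion],
    kmin: int = 6,
    kmax: int = 15,
    consensus_models: Sequence[ConsensusModel] = (),
) -> MotifReport:
    """Run the full scan over a promoter set.

    Per sequence: enumerate IRs, apply the low-complexity and
    longer-oligo filters, collect overlapping IR pairs and tandem +
    inverted repeats, and optionally scan consensus models.  Fully
    deterministic.
    """
    scans: list[SequenceScan] = []
    for p in promoters:
        irs = enumerate_inverted_repeats(p.sequence, kmin, kmax, seq_id=p.gene_id) \
            if len(p.sequence) >= 2 * kmin else []
        survivors = filter_subsumed(filter_low_complexity(irs))
        pairs = find_overlapping_ir_pairs(survivors)
        tandems = (
            find_tandem_inverted(p.sequence, kmin, kmax, seq_id=p.gene_id)
            if len(p.sequence) >= 3 * kmin
            else []
        )
        chits: list[ConsensusHit] = []
        for model in consensus_models:
            chits.extend(scan_consensus(p.sequence, model, seq_id=p.gene_id))
        scans.append(SequenceScan(p.gene_id, survivors, pairs, tandems, chits))
    params = {
        "kmin": kmin,
        "kmax": kmax,
        "consensus_models": [
            {"name": m.name, "pattern": m.pattern, "max_mismatches": m.max_mismatches}
            for m in consensus_models
        ],
    }
    return MotifReport(params=params, sequences=scans)
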