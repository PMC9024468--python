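"""Internal-symmetry analysis of stwintron RNA.

A single-stranded intron that folds back on itself into a hairpin pairs its
5' half against its 3' half.  Aligning the sequence globally against its own
reverse complement makes that symmetry visible: a column in which the two
letters agree corresponds to a Watson-Crick base pair in the implied fold,
and a column pairing G against A (or T against C) corresponds to a
noncanonical G·U / U·G wobble pair (the reverse-complement operation maps
the wobble partner U to A, and G to C, respectively).

The aligner is a standard global affine-gap pairwise aligner; terminal
overhangs (common in asymmetric stwintrons) appear as terminal gap runs
when they genuinely pay, and are reported separately from internal gaps.
When no scoring is given, a small grid of scoring parameters is run and
the most parsimonious profile kept: fewest internal gap openings, then
smallest total gap extent, then fewest unpaired columns, then the mildest
gap-open penalty.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import Align

__all__ = [
    "MATCH",
    "WOBBLE",
    "NONE",
    "GAP",
    "SymmetryProfile",
    "InvertedRepeatCall",
    "reverse_complement",
    "self_align",
    "palindrome_scan",
    "call_terminal_inverted_repeat",
]

MATCH = "M"
WOBBLE = "W"
NONE = "."
GAP = "-"

_CLASS_RANK = {MATCH: 3, WOBBLE: 2, NONE: 1, GAP: 0}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)

#: Aligned-column letter pairs that imply a G·U or U·G wobble in the fold.
_WOBBLE_PAIRS = {("G", "A"), ("T", "C")}

#: Scoring grid used when ``self_align`` is called without explicit scoring,
#: emulating alignments under progressively gap-averse matrices.
DEFAULT_SCORING_GRID: tuple[dict[str, float], ...] = (
    {"match": 2, "mismatch": -1, "gap_open": -6, "gap_extend": -1},
    {"match": 2, "mismatch": -1, "gap_open": -10, "gap_extend": -1},
    {"match": 2, "mismatch": -2, "gap_open": -16, "gap_extend": -2},
)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SymmetryProfile:
    """Positionwise classification of a sequence against its reverse complement.

    ``classes`` is a string over {M, W, ., -} (match / GU-wobble / unpaired
    / gap), one character per alignment column, symmetrised so that
    ``classes[i]`` and ``classes[-1 - i]`` agree.  ``midpoint`` indexes the
    centre of the self-mirror axis.  Overhang lengths count the terminal
    one-sided-gap columns of the raw (pre-symmetrisation) alignment.
    """

    classes: str
    midpoint: int
    gap_count: int
    gap_extent: int
    overhang5: int
    overhang3: int
    scoring: tuple[tuple[str, float], ...]

    @property
    def aligned_length(self) -> int:
        return len(self.classes)

    @property
    def match_fraction(self) -> float:
        """MATCH columns over non-gap columns."""
        ungapped = sum(1 for c in self.classes if c != GAP)
        if ungapped == 0:
            return 0.0
        return sum(1 for c in self.classes if c == MATCH) / ungapped

    @property
    def wobble_count(self) -> int:
        return self.classes.count(WOBBLE)


@dataclass(frozen=True)
class InvertedRepeatCall:
    """A terminal inverted repeat: near-reverse-complementary arms at both ends."""

    arm_length: int
    identity: float  # percent, 0..100
    arm5: tuple[int, int]
    arm3: tuple[int, int]

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity must be a percentage in [0, 100]")
        if self.arm5[1] > self.arm3[0]:
            raise ValueError("inverted-repeat arms must not overlap")


def _make_aligner(scoring: dict[str, float]) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring["match"]
    aligner.mismatch_score = scoring["mismatch"]
    aligner.open_gap_score = scoring["gap_open"]
    aligner.extend_gap_score = scoring["gap_extend"]
    return aligner


def _classify_columns(a: str, b: str) -> list[str]:
    out = []
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            out.append(GAP)
        elif x == y:
            out.append(MATCH)
        elif (x, y) in _WOBBLE_PAIRS:
            out.append(WOBBLE)
        else:
            out.append(NONE)
    return out


def _symmetrise(classes: Sequence[str]) -> str:
    """Columnwise consensus of the profile and its mirror.

    Aligning s against reverse_complement(s) is a self-mirror problem: the
    mirror image of any optimal path is itself optimal, so an asymmetric
    profile reflects pure tie-breaking.  Where profile and mirror disagree
    the conservative (lower-rank) class is kept.
    """
    n = len(classes)
    out = []
    for i in range(n):
        a, b = classes[i], classes[n - 1 - i]
        out.append(a if _CLASS_RANK[a] <= _CLASS_RANK[b] else b)
    return "".join(out)


def _align_once(seq: str, scoring: dict[str, float]) -> SymmetryProfile:
    rc = reverse_complement(seq)
    aligner = _make_aligner(scoring)
    alignment = aligner.align(seq, rc)[0]
    a, b = str(alignment[0]), str(alignment[1])
    raw = _classify_columns(a, b)

    over5 = 0
    while over5 < len(raw) and raw[over5] == GAP:
        over5 += 1
    over3 = 0
    while over3 < len(raw) - over5 and raw[len(raw) - 1 - over3] == GAP:
        over3 += 1

    interior = raw[over5 : len(raw) - over3]
    gap_runs = 0
    gap_cols = 0
    in_gap = False
    for c in interior:
        if c == GAP:
            gap_cols += 1
            if not in_gap:
                gap_runs += 1
                in_gap = True
        else:
            in_gap = False

    classes = _symmetrise(raw)
    return SymmetryProfile(
        classes=classes,
        midpoint=len(classes) // 2,
        gap_count=gap_runs,
        gap_extent=gap_cols,
        overhang5=over5,
        overhang3=over3,
        scoring=tuple(sorted(scoring.items())),
    )


def self_align(seq: str, scoring: dict[str, float] | None = None) -> SymmetryProfile:
    """Globally align ``seq`` to its own reverse complement and classify columns.

    With ``scoring=None`` a small parameter grid is run and the most
    parsimonious profile kept (fewest gap openings, smallest gap extent,
    fewest unpaired columns, mildest gap-open), standing in for a
    per-sequence choice among alignment matrices.
    """
    seq = seq.upper()
    if len(seq) < 10:
        raise ValueError(f"sequence too short for symmetry profiling ({len(seq)} < 10 nt)")
    if scoring is not None:
        return _align_once(seq, scoring)
    profiles = [_align_once(seq, sc) for sc in DEFAULT_SCORING_GRID]
    return min(
        profiles,
        key=lambda p: (
            p.gap_count,
            p.gap_extent,
            p.classes.count(NONE),
            -dict(p.scoring)["gap_open"],
        ),
    )


def palindrome_scan(seq: str, min_len: int = 10) -> list[tuple[int, int]]:
    """All maximal windows equal to their own reverse complement.

    Reverse-complement palindromes have even length; the scan expands around
    every inter-base centre and reports the maximal palindrome per centre
    with length >= ``min_len`` as half-open (start, end) intervals.
    """
    if min_len % 2 != 0 or min_len < 4:
        raise ValueError("min_len must be even and >= 4")
    seq = seq.upper()
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    n = len(seq)
    out: list[tuple[int, int]] = []
    for centre in range(1, n):
        k = 0
        while (
            centre - k - 1 >= 0
            and centre + k < n
            and comp.get(seq[centre - k - 1]) == seq[centre + k]
        ):
            k += 1
        if 2 * k >= min_len:
            out.append((centre - k, centre + k))
    return out


def call_terminal_inverted_repeat(
    seq: str,
    window_range: tuple[int, int] = (45, 55),
    min_identity: float = 65.0,
) -> InvertedRepeatCall | None:
    """Detect a terminal inverted repeat by ungapped arm comparison.

    For every arm length in ``window_range`` the 5' arm is compared
    position-by-position with the reverse complement of the 3' arm; the
    call maximises the match-minus-mismatch score (ties: higher identity).
    Returns ``None`` when no arm length reaches ``min_identity`` percent.
    """
    seq = seq.upper()
    lo, hi = window_range
    if lo < 1 or lo > hi:
        raise ValueError("window_range must satisfy 1 <= min <= max")
    best: tuple[float, float, int] | None = None  # (score, identity, L)
    for L in range(lo, min(hi, len(seq) // 2) + 1):
        arm5 = seq[:L]
        arm3_rc = reverse_complement(seq[-L:])
        matches = sum(1 for x, y in zip(arm5, arm3_rc) if x == y)
        identity = 100.0 * matches / L
        if identity < min_identity:
            continue
        score = matches - (L - matches)
        if best is None or (score, identity) > (best[0], best[1]):
            best = (score, identity, L)
    if best is None:
        return None
    _, identity, L = best
    return InvertedRepeatCall(
        arm_length=L,
        identity=identity,
        arm5=(0, L),
        arm3=(len(seq) - L, len(seq)),
    )
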