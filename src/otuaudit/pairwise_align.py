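"""Optimal global pairwise alignment and the PSD metric.

PSD (pairwise-alignment sequence dissimilarity) is the fraction of
disagreeing columns in an optimal global (Needleman–Wunsch) alignment of
two ungapped sequences. It is the p-distance that conventional
similarity-threshold OTU clustering is built on: a 97% identity threshold
corresponds to a maximum PSD of 0.03.

Scoring is linear-gap (one penalty per gap column). Under the default
``GAPS_COUNT`` policy every gap column counts as a disagreeing site;
``GAPS_EXCLUDED`` drops gap columns from both numerator and denominator.
Columns containing ``N`` in either row never count under either policy.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .errors import InputError, UndefinedDistanceError
from .io_formats import Sequence


class GapPolicy(enum.Enum):
    GAPS_COUNT = "count"
    GAPS_EXCLUDED = "exclude"


@dataclass(frozen=True)
class ScoringScheme:
    """Linear-gap scoring for global alignment.

    The default (match=1, mismatch=-1, gap=-2) is a plain textbook scheme;
    the upstream clustering tools do not publish their internal parameters,
    so all three are user-settable.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0

    def __post_init__(self) -> None:
        if not self.match > self.mismatch:
            raise InputError("scoring scheme requires match > mismatch")
        if not self.gap < 0:
            raise InputError("scoring scheme requires gap < 0")


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two equal-length gapped rows plus the alignment score."""

    row_a: str
    row_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise InputError("alignment rows must have equal length")
        if any(x == "-" and y == "-" for x, y in zip(self.row_a, self.row_b)):
            raise InputError("alignment contains an all-gap column")


def global_align(a: Sequence | str, b: Sequence | str,
                 scheme: ScoringScheme = ScoringScheme()) -> PairwiseAlignment:
    """Needleman–Wunsch global alignment with linear gap costs.

    Traceback is deterministic with tie-break diagonal > up > left
    (up consumes a residue of ``a``, left a residue of ``b``).
    """
    sa = a.residues if isinstance(a, Sequence) else a
    sb = b.residues if isinstance(b, Sequence) else b
    if "-" in sa or "-" in sb:
        raise InputError("global_align requires ungapped input sequences")
    if not sa or not sb:
        raise InputError("global_align requires non-empty sequences")

    m, n = len(sa), len(sb)
    match, mismatch, gap = scheme.match, scheme.mismatch, scheme.gap

    # H[i][j] = best score aligning sa[:i] with sb[:j]
    prev = [j * gap for j in range(n + 1)]
    H = [prev]
    for i in range(1, m + 1):
        ai = sa[i - 1]
        cur = [i * gap] + [0.0] * n
        for j in range(1, n + 1):
            s = match if ai == sb[j - 1] else mismatch
            diag = prev[j - 1] + s
            up = prev[j] + gap
            left = cur[j - 1] + gap
            cur[j] = diag if diag >= up and diag >= left else (up if up >= left else left)
        H.append(cur)
        prev = cur

    # traceback, diagonal > up > left
    ra: list[str] = []
    rb: list[str] = []
    i, j = m, n
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = match if sa[i - 1] == sb[j - 1] else mismatch
            if H[i][j] == H[i - 1][j - 1] + s:
                ra.append(sa[i - 1]); rb.append(sb[j - 1])
                i -= 1; j -= 1
                continue
        if i > 0 and H[i][j] == H[i - 1][j] + gap:
            ra.append(sa[i - 1]); rb.append("-")
            i -= 1
            continue
        ra.append("-"); rb.append(sb[j - 1])
        j -= 1

    return PairwiseAlignment("".join(reversed(ra)), "".join(reversed(rb)), H[m][n])


def psd_from_alignment(row_a: str, row_b: str,
                       gap_policy: GapPolicy = GapPolicy.GAPS_COUNT) -> float:
    """PSD computed on pre-aligned rows. N-columns never count."""
    counted = 0
    disagree = 0
    for x, y in zip(row_a, row_b):
        if x == "N" or y == "N":
            continue
        is_gap = (x == "-") or (y == "-")
        if is_gap:
            if gap_policy is GapPolicy.GAPS_COUNT:
                counted += 1
                disagree += 1
            continue
        counted += 1
        if x != y:
            disagree += 1
    if counted == 0:
        raise UndefinedDistanceError("no countable columns in pairwise alignment")
    return disagree / counted


def psd(a: Sequence | str, b: Sequence | str,
        scheme: ScoringScheme = ScoringScheme(),
        gap_policy: GapPolicy = GapPolicy.GAPS_COUNT) -> float:
    """Pairwise-alignment sequence dissimilarity in [0, 1]."""
    aln = global_align(a, b, scheme)
    return psd_from_alignment(aln.row_a, aln.row_b, gap_policy)
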