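"""MSD: sequence dissimilarity read out of a shared multiple alignment.

For a pair of rows induced from one MSA, the MSD is the fraction of
disagreeing columns among columns that are non-gapped in both rows.
Columns containing ``N`` in either row are excluded from numerator and
denominator — an N carries no evidence of substitution. This makes MSD a
proper p-distance on the induced pairwise alignment.

Because a p-distance ignores multiple substitutions at a site, it
saturates: under the Jukes–Cantor model the expected p-distance at true
distance d is (3/4)(1 - exp(-4d/3)) < 3/4. :func:`jc_correct` inverts
that relation to recover an expected-substitutions-per-site distance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import SaturationError, UndefinedDistanceError
from .io_formats import MultipleAlignment, OTUCluster
from .records import DistanceRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InducedPair:
    """Column tally for a pair of rows induced from one MSA."""

    counted: int
    disagreeing: int

    def __post_init__(self) -> None:
        if not (0 <= self.disagreeing <= self.counted):
            raise ValueError("disagreeing must lie in [0, counted]")


def induce_pair(msa: MultipleAlignment, id_a: str, id_b: str,
                one_gapped_is_mismatch: bool = False) -> InducedPair:
    """Tally countable and disagreeing columns for a pair of MSA rows.

    A column counts when both rows are non-gap and neither is ``N``.  With
    ``one_gapped_is_mismatch`` set, columns gapped in exactly one row are
    additionally counted as disagreements (a sensitivity-analysis variant;
    the default excludes them).
    """
    a = np.frombuffer(msa.row(id_a).encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(msa.row(id_b).encode("ascii"), dtype=np.uint8)
    n_code, gap_code = ord("N"), ord("-")
    usable = (a != n_code) & (b != n_code)
    gap_a = a == gap_code
    gap_b = b == gap_code
    both = usable & ~gap_a & ~gap_b
    counted = int(both.sum())
    disagreeing = int((both & (a != b)).sum())
    if one_gapped_is_mismatch:
        one_gapped = usable & (gap_a ^ gap_b)
        extra = int(one_gapped.sum())
        counted += extra
        disagreeing += extra
    return InducedPair(counted, disagreeing)


def msd(msa: MultipleAlignment, id_a: str, id_b: str,
        one_gapped_is_mismatch: bool = False) -> float:
    """MSA-based sequence dissimilarity in [0, 1]."""
    pair = induce_pair(msa, id_a, id_b, one_gapped_is_mismatch)
    if pair.counted == 0:
        raise UndefinedDistanceError(
            f"pair ({id_a!r}, {id_b!r}): no countable columns in induced alignment"
        )
    return pair.disagreeing / pair.counted


def msd_rep_vs_all(msa: MultipleAlignment, cluster: OTUCluster,
                   one_gapped_is_mismatch: bool = False) -> list[DistanceRecord]:
    """MSD from the representative to every member of the cluster.

    Pairs with zero countable columns are dropped with a logged warning
    rather than failing the whole OTU (fragmentary reads can have disjoint
    footprints in a reference-based MSA).
    """
    rep = cluster.representative_id
    if rep not in msa:
        from .errors import UnknownIdError
        raise UnknownIdError(f"representative {rep!r} of OTU {cluster.otu_id!r} not in alignment")
    records: list[DistanceRecord] = []
    dropped = 0
    for member in sorted(cluster.member_ids):
        try:
            value = msd(msa, rep, member, one_gapped_is_mismatch)
        except UndefinedDistanceError:
            dropped += 1
            logger.warning(
                "OTU %s: pair (%s, %s) has no countable columns; dropped",
                cluster.otu_id, rep, member,
            )
            continue
        records.append(DistanceRecord(cluster.otu_id, member, msd=value))
    if dropped:
        logger.warning("OTU %s: dropped %d member pair(s) with undefined MSD",
                       cluster.otu_id, dropped)
    return records


def jc_correct(p: float) -> float:
    """Jukes–Cantor correction d = -(3/4) ln(1 - 4p/3).

    Converts a p-distance into expected substitutions per site under the
    simplest substitution model. Monotone increasing with jc_correct(0)=0
    and jc_correct(p) >= p; saturates as p -> 3/4.
    """
    if p < 0:
        raise UndefinedDistanceError(f"p-distance must be >= 0, got {p}")
    if p >= 0.75:
        raise SaturationError(f"p-distance {p} is saturated (>= 3/4); correction undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)
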