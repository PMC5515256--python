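"""Annotation concordance between OTU members and their representative.

An OTU inherits its representative's taxonomic annotation, so a member
whose own classification differs marks an annotation inconsistency. A
member is UNDER-classified when its lineage is a strict prefix of the
representative's (shallower, no disagreement), OVER-classified when the
representative's is a strict prefix of the member's, and CONFLICTING when
any rank assigned in both lineages disagrees. A conflict takes precedence
over a depth difference: it is the stronger discordance.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping

from .errors import UnknownIdError
from .io_formats import Lineage, OTUCluster


class ConcordanceClass(enum.Enum):
    CONCORDANT = "concordant"
    UNDER = "under"
    OVER = "over"
    CONFLICTING = "conflicting"


@dataclass(frozen=True)
class ConcordanceSummary:
    otu_id: str
    n_concordant: int
    n_under: int
    n_over: int
    n_conflicting: int

    @property
    def n_members(self) -> int:
        return self.n_concordant + self.n_under + self.n_over + self.n_conflicting

    @property
    def flag_differing(self) -> bool:
        """Any member classified differently from the representative."""
        return (self.n_under + self.n_over + self.n_conflicting) > 0


def classify_pair(rep: Lineage, member: Lineage) -> ConcordanceClass:
    """Classify a member's lineage against the representative's."""
    for a, b in zip(rep.ranks, member.ranks):
        if a is not None and b is not None and a != b:
            return ConcordanceClass.CONFLICTING
    if member.depth < rep.depth:
        return ConcordanceClass.UNDER
    if member.depth > rep.depth:
        return ConcordanceClass.OVER
    return ConcordanceClass.CONCORDANT


def summarize_concordance(cluster: OTUCluster,
                          taxonomy: Mapping[str, Lineage]) -> ConcordanceSummary:
    """Per-class member counts for one OTU."""
    rep_id = cluster.representative_id
    if rep_id not in taxonomy:
        raise UnknownIdError(
            f"representative {rep_id!r} of OTU {cluster.otu_id!r} missing from taxonomy"
        )
    rep = taxonomy[rep_id]
    counts = {cls: 0 for cls in ConcordanceClass}
    for member in sorted(cluster.member_ids):
        if member not in taxonomy:
            raise UnknownIdError(
                f"member {member!r} of OTU {cluster.otu_id!r} missing from taxonomy"
            )
        counts[classify_pair(rep, taxonomy[member])] += 1
    return ConcordanceSummary(
        otu_id=cluster.otu_id,
        n_concordant=counts[ConcordanceClass.CONCORDANT],
        n_under=counts[ConcordanceClass.UNDER],
        n_over=counts[ConcordanceClass.OVER],
        n_conflicting=counts[ConcordanceClass.CONFLICTING],
    )


@dataclass(frozen=True)
class DivergenceStratification:
    """Fractions of annotation-discordant OTUs, overall and among divergent OTUs."""

    frac_differing_overall: float
    frac_differing_high_msd: float | None  # None when the stratum is empty
    n_otus: int
    n_otus_high_msd: int


def concordance_by_divergence(summaries: Iterable[ConcordanceSummary],
                              otu_mean_msd: Mapping[str, float | None],
                              threshold: float = 0.03) -> DivergenceStratification:
    """Fraction of flagged OTUs overall and within the mean-MSD >= threshold stratum.

    Note the stratum boundary is inclusive (mean MSD of ``threshold`` or
    greater), unlike the strict per-member exceedance used elsewhere.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no concordance summaries given")
    n = len(summaries)
    n_diff = sum(1 for s in summaries if s.flag_differing)
    high = [s for s in summaries
            if otu_mean_msd.get(s.otu_id) is not None
            and otu_mean_msd[s.otu_id] >= threshold]
    frac_high = (sum(1 for s in high if s.flag_differing) / len(high)) if high else None
    return DivergenceStratification(
        frac_differing_overall=n_diff / n,
        frac_differing_high_msd=frac_high,
        n_otus=n,
        n_otus_high_msd=len(high),
    )
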