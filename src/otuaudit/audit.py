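"""Per-OTU and dataset-level compactness statistics.

By construction, every member of a 97%-similarity OTU should be at most 3%
dissimilar from the representative (PSD < 0.03). The audit re-measures
members against the representative with MSD and BLD, thresholds at 0.03
(strictly greater than), and aggregates: fractions of OTUs with at least
one exceeding member, fractions of sequences exceeding, per-OTU and
dataset means, the BLD/MSD underestimation ratio, and Pearson correlation
between the two metrics per read and per OTU mean.

Dataset means are pooled over per-read records (headline) and also
reported as means of per-OTU means, since both conventions are in use.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence as TSequence

import numpy as np
from scipy import stats

from .errors import InputError
from .io_formats import Lineage, OTUCluster, RANKS
from .records import DistanceRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AuditConfig:
    threshold: float = 0.03
    min_otu_size: int = 100
    rank: str = "phylum"

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise InputError(f"threshold must lie in (0,1), got {self.threshold}")
        if self.min_otu_size < 1:
            raise InputError(f"min_otu_size must be >= 1, got {self.min_otu_size}")
        if self.rank not in RANKS:
            raise InputError(f"unknown rank {self.rank!r}")


@dataclass(frozen=True)
class OTUSummary:
    otu_id: str
    n_members: int
    mean_msd: float | None
    max_msd: float | None
    mean_bld: float | None
    max_bld: float | None
    frac_members_msd_gt: float
    frac_members_bld_gt: float

    @property
    def flag_any_msd_gt(self) -> bool:
        return self.frac_members_msd_gt > 0

    @property
    def flag_mean_msd_gt(self) -> bool:
        return self.mean_msd is not None and self.mean_msd > self._threshold

    # threshold the flags refer to, captured at construction time
    _threshold: float = 0.03


@dataclass(frozen=True)
class DatasetSummary:
    n_otus: int
    n_records: int
    frac_otus_any_msd_gt: float
    frac_otus_mean_msd_gt: float
    frac_sequences_msd_gt: float
    frac_sequences_bld_gt: float
    mean_msd: float | None
    mean_bld: float | None
    mean_msd_of_otu_means: float | None
    mean_bld_of_otu_means: float | None
    bld_msd_ratio: float | None
    pearson_per_read: float | None
    pearson_per_otu_mean: float | None


def filter_otus(clusters: Iterable[OTUCluster], min_otu_size: int = 100) -> list[OTUCluster]:
    """Keep clusters whose total size (members + representative) >= min_otu_size."""
    clusters = list(clusters)
    kept = [c for c in clusters if c.size >= min_otu_size]
    logger.info("filter_otus: kept %d of %d OTUs (min size %d)",
                len(kept), len(clusters), min_otu_size)
    return kept


def _agg(values: list[float]) -> tuple[float | None, float | None]:
    if not values:
        return None, None
    return float(np.mean(values)), float(max(values))


def summarize_otu(records: TSequence[DistanceRecord],
                  config: AuditConfig = AuditConfig()) -> OTUSummary:
    """Aggregate one OTU's per-member records.

    Exceedance fractions use strict inequality (> threshold). Records
    missing a metric are excluded from that metric's aggregates only.
    """
    if not records:
        raise InputError("summarize_otu requires at least one record")
    otu_ids = {r.otu_id for r in records}
    if len(otu_ids) != 1:
        raise InputError(f"records span multiple OTUs: {sorted(otu_ids)}")
    t = config.threshold
    msds = [r.msd for r in records if r.msd is not None]
    blds = [r.bld for r in records if r.bld is not None]
    mean_msd, max_msd = _agg(msds)
    mean_bld, max_bld = _agg(blds)
    return OTUSummary(
        otu_id=next(iter(otu_ids)),
        n_members=len(records),
        mean_msd=mean_msd, max_msd=max_msd,
        mean_bld=mean_bld, max_bld=max_bld,
        frac_members_msd_gt=(sum(1 for v in msds if v > t) / len(msds)) if msds else 0.0,
        frac_members_bld_gt=(sum(1 for v in blds if v > t) / len(blds)) if blds else 0.0,
        _threshold=t,
    )


def pearson(pairs: Iterable[tuple[float | None, float | None]]) -> float | None:
    """Sample Pearson correlation over complete pairs.

    Incomplete pairs are dropped with a logged count. With fewer than two
    complete pairs, or zero variance in either coordinate, the correlation
    is undefined and reported as ``None`` (never coerced to 0).
    """
    pairs = list(pairs)
    complete = [(x, y) for x, y in pairs if x is not None and y is not None]
    dropped = len(pairs) - len(complete)
    if dropped:
        logger.info("pearson: dropped %d incomplete pair(s)", dropped)
    if len(complete) < 2:
        return None
    xs = np.array([p[0] for p in complete])
    ys = np.array([p[1] for p in complete])
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return None
    r = stats.pearsonr(xs, ys).statistic
    return float(r)


def summarize_dataset(records: TSequence[DistanceRecord],
                      summaries: TSequence[OTUSummary],
                      config: AuditConfig = AuditConfig()) -> DatasetSummary:
    """Dataset-level audit statistics.

    Sequence-level fractions are computed over per-member records,
    OTU-level fractions over per-OTU summaries. OTUs with no usable
    records for a metric are excluded from that metric's OTU fractions
    with a logged count.
    """
    if not summaries:
        raise InputError("summarize_dataset requires at least one OTU summary")
    t = config.threshold

    msds = [r.msd for r in records if r.msd is not None]
    blds = [r.bld for r in records if r.bld is not None]

    with_msd = [s for s in summaries if s.mean_msd is not None]
    with_bld = [s for s in summaries if s.mean_bld is not None]
    excluded = len(summaries) - len(with_msd)
    if excluded:
        logger.info("summarize_dataset: %d OTU(s) have no usable MSD records", excluded)

    mean_msd = float(np.mean(msds)) if msds else None
    mean_bld = float(np.mean(blds)) if blds else None
    ratio = (mean_bld / mean_msd) if (mean_msd and mean_bld is not None) else None

    per_read_pairs = [(r.msd, r.bld) for r in records]
    per_otu_pairs = [(s.mean_msd, s.mean_bld) for s in summaries]

    return DatasetSummary(
        n_otus=len(summaries),
        n_records=len(records),
        frac_otus_any_msd_gt=(
            sum(1 for s in with_msd if s.flag_any_msd_gt) / len(with_msd) if with_msd else 0.0
        ),
        frac_otus_mean_msd_gt=(
            sum(1 for s in with_msd if s.mean_msd > t) / len(with_msd) if with_msd else 0.0
        ),
        frac_sequences_msd_gt=(sum(1 for v in msds if v > t) / len(msds)) if msds else 0.0,
        frac_sequences_bld_gt=(sum(1 for v in blds if v > t) / len(blds)) if blds else 0.0,
        mean_msd=mean_msd,
        mean_bld=mean_bld,
        mean_msd_of_otu_means=(
            float(np.mean([s.mean_msd for s in with_msd])) if with_msd else None
        ),
        mean_bld_of_otu_means=(
            float(np.mean([s.mean_bld for s in with_bld])) if with_bld else None
        ),
        bld_msd_ratio=ratio,
        pearson_per_read=pearson(per_read_pairs),
        pearson_per_otu_mean=pearson(per_otu_pairs),
    )


@dataclass(frozen=True)
class TaxonGroup:
    """Box-plot-ready summary of per-OTU mean distances for one taxon."""

    taxon: str
    n_otus: int
    mean_of_mean_msd: float | None
    mean_of_mean_bld: float | None
    q1_msd: float | None
    median_msd: float | None
    q3_msd: float | None
    q1_bld: float | None
    median_bld: float | None
    q3_bld: float | None


def _quartiles(values: list[float]) -> tuple[float | None, float | None, float | None]:
    if not values:
        return None, None, None
    q1, q2, q3 = np.percentile(values, [25, 50, 75])
    return float(q1), float(q2), float(q3)


def group_by_rank(summaries: Iterable[OTUSummary],
                  clusters: Iterable[OTUCluster],
                  taxonomy: Mapping[str, Lineage],
                  rank: str = "phylum") -> list[TaxonGroup]:
    """Group per-OTU summaries by the representative's taxon at ``rank``.

    OTUs whose representative is unassigned at that rank (or missing from
    the taxonomy) are grouped under ``UNASSIGNED``.
    """
    if rank not in RANKS:
        raise InputError(f"unknown rank {rank!r}")
    rep_of = {c.otu_id: c.representative_id for c in clusters}
    groups: dict[str, list[OTUSummary]] = {}
    for s in summaries:
        rep = rep_of.get(s.otu_id)
        lineage = taxonomy.get(rep) if rep is not None else None
        taxon = lineage.at(rank) if lineage is not None else None
        groups.setdefault(taxon if taxon is not None else "UNASSIGNED", []).append(s)
    out = []
    for taxon in sorted(groups):
        members = groups[taxon]
        msds = [s.mean_msd for s in members if s.mean_msd is not None]
        blds = [s.mean_bld for s in members if s.mean_bld is not None]
        q1m, q2m, q3m = _quartiles(msds)
        q1b, q2b, q3b = _quartiles(blds)
        out.append(TaxonGroup(
            taxon=taxon, n_otus=len(members),
            mean_of_mean_msd=float(np.mean(msds)) if msds else None,
            mean_of_mean_bld=float(np.mean(blds)) if blds else None,
            q1_msd=q1m, median_msd=q2m, q3_msd=q3m,
            q1_bld=q1b, median_bld=q2b, q3_bld=q3b,
        ))
    return out


def distance_histogram(records: Iterable[DistanceRecord], metric: str,
                       bin_width: float = 0.01) -> list[tuple[float, float, int]]:
    """Half-open-bin histogram of one metric over a set of records.

    Returns ``(bin_left, bin_right, count)`` for every non-empty bin; a
    value exactly on a bin edge falls into the right bin.
    """
    if bin_width <= 0:
        raise InputError(f"bin_width must be > 0, got {bin_width}")
    if metric not in ("msd", "bld", "psd"):
        raise InputError(f"unknown metric {metric!r}")
    counts: dict[int, int] = {}
    for r in records:
        v = getattr(r, metric)
        if v is None:
            continue
        k = int(math.floor(v / bin_width + 1e-9))
        counts[k] = counts.get(k, 0) + 1
    return [(k * bin_width, (k + 1) * bin_width, counts[k]) for k in sorted(counts)]
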