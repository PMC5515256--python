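import numpy as np
import pytest

from _oracles import pearson_two_pass
from otuaudit.audit import (
    AuditConfig, distance_histogram, filter_otus, group_by_rank, pearson,
    summarize_dataset, summarize_otu,
)
from otuaudit.io_formats import Lineage, OTUCluster
from otuaudit.records import DistanceRecord

CFG = AuditConfig(threshold=0.03, min_otu_size=1)


def _records(otu, msds=None, blds=None):
    msds = msds or []
    blds = blds or []
    out = [DistanceRecord(otu, f"m{i}", msd=v) for i, v in enumerate(msds)]
    out += [DistanceRecord(otu, f"b{i}", bld=v) for i, v in enumerate(blds)]
    return out


class TestFilterOtus:
    def test_boundary_inclusive_at_min(self):
        clusters = [
            OTUCluster(f"o{n}", "r", frozenset(f"m{i}" for i in range(n - 1)))
            for n in (99, 100, 101)
        ]
        assert [c.otu_id for c in filter_otus(clusters, 100)] == ["o100", "o101"]

    def test_min_one_is_identity(self):
        clusters = [OTUCluster("o", "r", frozenset({"m"}))]
        assert filter_otus(clusters, 1) == clusters

    def test_empty(self):
        assert filter_otus([], 100) == []


class TestSummarizeOtu:
    def test_hand_arithmetic(self):
        s = summarize_otu(_records("o", msds=[0.01, 0.02, 0.06]), CFG)
        assert s.mean_msd == pytest.approx(0.03)
        assert s.max_msd == pytest.approx(0.06)
        assert s.frac_members_msd_gt == pytest.approx(1 / 3)
        assert s.flag_any_msd_gt is True
        assert s.flag_mean_msd_gt is False  # mean exactly at threshold, strict

    def test_all_zero(self):
        s = summarize_otu(_records("o", msds=[0.0, 0.0]), CFG)
        assert s.mean_msd == 0.0 and s.max_msd == 0.0
        assert not s.flag_any_msd_gt and not s.flag_mean_msd_gt

    def test_single_record_above_threshold(self):
        s = summarize_otu(_records("o", msds=[0.031]), CFG)
        assert s.flag_any_msd_gt and s.flag_mean_msd_gt

    def test_absent_metric_excluded(self):
        s = summarize_otu(_records("o", msds=[0.01], blds=[0.5]), CFG)
        assert s.mean_msd == 0.01 and s.mean_bld == 0.5
        assert s.n_members == 2


class TestSummarizeDataset:
    def test_otu_fraction_hand_count(self):
        recs1 = _records("o1", msds=[0.05, 0.01])
        recs2 = _records("o2", msds=[0.01, 0.02])
        summaries = [summarize_otu(r, CFG) for r in (recs1, recs2)]
        ds = summarize_dataset(recs1 + recs2, summaries, CFG)
        assert ds.frac_otus_any_msd_gt == pytest.approx(0.5)

    def test_sequence_fraction_hand_count(self):
        recs = _records("o", blds=[0.1] + [0.01] * 9)
        ds = summarize_dataset(recs, [summarize_otu(recs, CFG)], CFG)
        assert ds.frac_sequences_bld_gt == pytest.approx(0.1)

    def test_bld_msd_ratio(self):
        recs = _records("o", msds=[0.02, 0.02], blds=[0.068, 0.068])
        ds = summarize_dataset(recs, [summarize_otu(recs, CFG)], CFG)
        assert ds.bld_msd_ratio == pytest.approx(3.4)

    def test_recomposition_of_sequence_fractions(self, rng):
        """Dataset sequence fraction = member-weighted mean of OTU fractions."""
        all_records, summaries = [], []
        for i in range(8):
            n = int(rng.integers(2, 30))
            recs = _records(f"o{i}", msds=list(rng.random(n) * 0.08))
            all_records += recs
            summaries.append(summarize_otu(recs, CFG))
        ds = summarize_dataset(all_records, summaries, CFG)
        weighted = sum(s.n_members * s.frac_members_msd_gt for s in summaries) \
            / sum(s.n_members for s in summaries)
        assert ds.frac_sequences_msd_gt == pytest.approx(weighted, abs=1e-12)


class TestPearson:
    def test_exact_linearity(self):
        assert pearson([(0.01, 0.02), (0.02, 0.04), (0.03, 0.06)]) == pytest.approx(1.0)

    def test_exact_antilinearity(self):
        assert pearson([(0.01, 0.06), (0.02, 0.04), (0.03, 0.02)]) == pytest.approx(-1.0)

    def test_matches_two_pass_formula(self, rng):
        xs = list(rng.random(50))
        ys = list(rng.random(50))
        assert pearson(list(zip(xs, ys))) == pytest.approx(
            pearson_two_pass(xs, ys), abs=1e-12)

    def test_undefined_cases_reported_absent(self):
        assert pearson([(0.1, 0.2)]) is None
        assert pearson([(0.1, 0.2), (0.1, 0.4)]) is None  # zero x-variance
        assert pearson([(None, 0.2), (0.1, None), (0.3, 0.4)]) is None

    def test_incomplete_pairs_dropped(self):
        r = pearson([(None, 0.9), (0.01, 0.02), (0.02, 0.04), (0.03, 0.06)])
        assert r == pytest.approx(1.0)


class TestGroupByRank:
    def _setup(self):
        clusters = [
            OTUCluster("o1", "r1", frozenset({"m1"})),
            OTUCluster("o2", "r2", frozenset({"m2"})),
            OTUCluster("o3", "r3", frozenset({"m3"})),
        ]
        taxonomy = {
            "r1": Lineage.from_names("Bacteria", "P"),
            "r2": Lineage.from_names("Bacteria", "P"),
            "r3": Lineage.from_names("Bacteria"),  # unassigned at phylum
        }
        summaries = [
            summarize_otu(_records("o1", msds=[0.01]), CFG),
            summarize_otu(_records("o2", msds=[0.03]), CFG),
            summarize_otu(_records("o3", msds=[0.05]), CFG),
        ]
        return summaries, clusters, taxonomy

    def test_mean_of_means(self):
        summaries, clusters, taxonomy = self._setup()
        groups = {g.taxon: g for g in group_by_rank(summaries, clusters, taxonomy, "phylum")}
        assert groups["P"].n_otus == 2
        assert groups["P"].mean_of_mean_msd == pytest.approx(0.02)

    def test_unassigned_bucket(self):
        summaries, clusters, taxonomy = self._setup()
        groups = {g.taxon: g for g in group_by_rank(summaries, clusters, taxonomy, "phylum")}
        assert groups["UNASSIGNED"].n_otus == 1

    def test_single_otu_quartiles_degenerate(self):
        summaries, clusters, taxonomy = self._setup()
        groups = {g.taxon: g for g in group_by_rank(summaries, clusters, taxonomy, "phylum")}
        g = groups["UNASSIGNED"]
        assert g.q1_msd == g.median_msd == g.q3_msd == pytest.approx(0.05)


class TestDistanceHistogram:
    def test_hand_binning(self):
        recs = _records("o", msds=[0.00, 0.01, 0.01])
        bins = distance_histogram(recs, "msd", 0.01)
        assert bins == [(0.0, 0.01, 1), (0.01, 0.02, 2)]

    def test_empty(self):
        assert distance_histogram([], "msd", 0.01) == []

    def test_edge_value_goes_right(self):
        recs = _records("o", msds=[0.03])
        ((lo, hi, count),) = distance_histogram(recs, "msd", 0.01)
        assert lo == pytest.approx(0.03) and count == 1

    def test_counts_sum_to_present_records(self, rng):
        recs = _records("o", msds=list(rng.random(40)), blds=list(rng.random(7)))
        bins = distance_histogram(recs, "msd", 0.05)
        assert sum(c for _, _, c in bins) == 40
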