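import math

import dendropy
import numpy as np
import pytest

from otuaudit.concordance import ConcordanceClass, summarize_concordance, classify_pair
from otuaudit.io_formats import PhyloTree
from otuaudit.msa_distance import jc_correct, msd, msd_rep_vs_all
from otuaudit.synthetic_data import (
    GTRGamma, JC, SimulationConfig, evolve_sequences, expected_p_distance,
    make_dataset, sample_tree,
)
from otuaudit.tree_distance import bld


class TestExpectedPDistance:
    def test_fixed_points(self):
        assert expected_p_distance(0.0) == 0.0
        assert expected_p_distance(0.1) == pytest.approx(
            0.75 * (1 - math.exp(-0.4 / 3)), rel=1e-12)

    def test_inverse_of_jc_correct(self):
        for p in (0.01, 0.03, 0.1):
            assert expected_p_distance(jc_correct(p)) == pytest.approx(p, abs=1e-12)

    def test_monotone_with_asymptote(self):
        ds = np.linspace(0, 10, 200)
        ps = [expected_p_distance(d) for d in ds]
        assert all(b > a for a, b in zip(ps, ps[1:]))
        assert ps[-1] < 0.75


class TestSampleTree:
    def test_two_leaves_exact_depth(self):
        tree, dists = sample_tree(2, 0.07, seed=3)
        assert list(dists.values()) == [pytest.approx(0.07)]

    def test_same_seed_identical_newick(self):
        t1, _ = sample_tree(10, 0.05, seed=11)
        t2, _ = sample_tree(10, 0.05, seed=11)
        assert t1.newick() == t2.newick()

    def test_rescaling_exact_per_tree(self):
        for seed in range(50):
            _, dists = sample_tree(12, 0.1, seed=seed)
            assert np.mean(list(dists.values())) == pytest.approx(0.1, abs=1e-9)

    def test_reference_leaf_controls_rescaling(self):
        tree, dists = sample_tree(8, 0.04, seed=5, reference_leaf=3)
        labels = [f"s{i:04d}" for i in range(8)]
        assert labels[3] not in dists
        assert np.mean(list(dists.values())) == pytest.approx(0.04, abs=1e-12)

    def test_true_distances_match_tree(self):
        tree, dists = sample_tree(9, 0.06, seed=1)
        ref = next(l for l in tree.leaf_labels if l not in dists)
        for leaf, d in dists.items():
            assert bld(tree, ref, leaf) == pytest.approx(d, abs=1e-12)


class TestEvolveSequences:
    def test_zero_branch_lengths_no_evolution(self):
        tree = PhyloTree(dendropy.Tree.get(
            data="(A:0.0,B:0.0,C:0.0);", schema="newick",
            suppress_internal_node_taxa=True))
        msa = evolve_sequences(tree, 200, JC(), seed=4)
        rows = {s.residues for s in msa.sequences}
        assert len(rows) == 1

    def test_same_seed_identical_alignment(self):
        tree, _ = sample_tree(6, 0.1, seed=2)
        m1 = evolve_sequences(tree, 300, JC(), seed=9)
        m2 = evolve_sequences(tree, 300, JC(), seed=9)
        assert [s.residues for s in m1.sequences] == [s.residues for s in m2.sequences]

    def test_two_leaf_p_distance_matches_closed_form(self):
        d, L, reps = 0.1, 10_000, 30
        tree = PhyloTree(dendropy.Tree.get(
            data=f"(a:{d/2},b:{d/2});", schema="newick",
            suppress_internal_node_taxa=True))
        expected = expected_p_distance(d)
        observed = []
        for seed in range(reps):
            msa = evolve_sequences(tree, L, JC(), seed=seed)
            observed.append(msd(msa, "a", "b"))
        se = math.sqrt(expected * (1 - expected) / (L * reps))
        assert abs(np.mean(observed) - expected) < 3 * se

    def test_gtr_transition_matrices_are_stochastic(self):
        model = GTRGamma(rates=(1, 3, 1, 1, 3, 1), base_freqs=(0.3, 0.2, 0.2, 0.3),
                         alpha=0.5)
        P = model.transition_matrices(0.2)
        assert P.shape == (4, 4, 4)
        assert np.allclose(P.sum(axis=2), 1.0, atol=1e-10)
        assert (P >= 0).all()

    def test_gtr_evolution_runs_and_is_deterministic(self):
        tree, _ = sample_tree(5, 0.1, seed=8)
        model = GTRGamma()
        m1 = evolve_sequences(tree, 200, model, seed=3)
        m2 = evolve_sequences(tree, 200, model, seed=3)
        assert [s.residues for s in m1.sequences] == [s.residues for s in m2.sequences]

    def test_deletions_inherited_and_msd_still_defined(self):
        tree, _ = sample_tree(6, 0.1, seed=2)
        msa = evolve_sequences(tree, 500, JC(), indel_rate=0.5, seed=5)
        assert any("-" in s.residues for s in msa.sequences)
        ids = msa.ids()
        assert 0.0 <= msd(msa, ids[0], ids[1]) <= 1.0


class TestMakeDataset:
    def test_ground_truth_bld_consistency(self):
        cfg = SimulationConfig(n_otus=3, members_per_otu=8, seq_length=100, seed=6)
        for sim in make_dataset(cfg):
            for member, d in sim.true_rep_distances.items():
                assert bld(sim.true_tree, sim.cluster.representative_id,
                           member) == pytest.approx(d, abs=1e-12)

    def test_alignment_contains_all_sequences(self):
        cfg = SimulationConfig(n_otus=2, members_per_otu=5, seq_length=50, seed=1)
        for sim in make_dataset(cfg):
            assert sim.cluster.representative_id in sim.alignment
            assert all(m in sim.alignment for m in sim.cluster.member_ids)

    def test_no_discordance_when_p_zero(self):
        cfg = SimulationConfig(n_otus=5, members_per_otu=10, seq_length=50,
                               p_discordant=0.0, seed=2)
        for sim in make_dataset(cfg):
            s = summarize_concordance(sim.cluster, sim.lineages)
            assert not s.flag_differing

    def test_full_discordance_when_p_one(self):
        cfg = SimulationConfig(n_otus=5, members_per_otu=10, seq_length=50,
                               p_discordant=1.0, seed=3)
        for sim in make_dataset(cfg):
            s = summarize_concordance(sim.cluster, sim.lineages)
            assert s.flag_differing
            assert s.n_concordant == 0

    def test_truth_classes_recovered_by_classifier(self):
        cfg = SimulationConfig(n_otus=4, members_per_otu=15, seq_length=50,
                               p_discordant=0.4, seed=4)
        for sim in make_dataset(cfg):
            rep_lineage = sim.lineages[sim.cluster.representative_id]
            for member, expected in sim.truth_classes.items():
                assert classify_pair(rep_lineage, sim.lineages[member]) is expected

    def test_parameter_recovery_via_jc_correction(self):
        """jc_correct(msd) recovers the true distance on long simulated pairs."""
        cfg = SimulationConfig(n_otus=6, members_per_otu=2, seq_length=10_000,
                               target_depth=0.1, seed=9)
        errors = []
        for sim in make_dataset(cfg):
            for r in msd_rep_vs_all(sim.alignment, sim.cluster):
                d_true = sim.true_rep_distances[r.member_id]
                if d_true < 1e-3:
                    continue
                errors.append(abs(jc_correct(r.msd) - d_true) / d_true)
        assert np.mean(errors) < 0.05

    def test_master_seed_reproducibility(self):
        cfg = SimulationConfig(n_otus=2, members_per_otu=4, seq_length=60, seed=12)
        d1 = make_dataset(cfg)
        d2 = make_dataset(cfg)
        for a, b in zip(d1, d2):
            assert a.true_tree.newick() == b.true_tree.newick()
            assert [s.residues for s in a.alignment.sequences] == \
                [s.residues for s in b.alignment.sequences]
            assert a.truth_classes == b.truth_classes
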