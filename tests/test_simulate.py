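"""Synthetic-data generator: trees, characters, pairs, masks, tree sets."""

import math

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from mkanc import models as mk
from mkanc import simulate as sim
from mkanc.phylo_io import check_ultrametric, read_matrix


class TestYuleTree:
    def test_shape_and_ultrametricity(self):
        t = sim.simulate_yule_tree(5, seed=1)
        assert t.n_tips == 5
        assert t.n_internal == 4
        assert check_ultrametric(t, rel_tol=1e-9).passed

    def test_same_seed_same_newick(self):
        a = sim.simulate_yule_tree(20, seed=42).newick()
        b = sim.simulate_yule_tree(20, seed=42).newick()
        assert a == b

    def test_mean_root_age_matches_yule_expectation(self):
        # E[root age] = sum_{j=2..n} 1/(j * lambda)
        n, lam, reps = 50, 1.0, 600
        want = sum(1.0 / (j * lam) for j in range(2, n + 1))
        ages = [sim.simulate_yule_tree(n, lam, seed=s).depth() for s in range(reps)]
        assert abs(np.mean(ages) - want) / want < 0.15

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            sim.simulate_yule_tree(1, seed=0)
        with pytest.raises(ValueError):
            sim.simulate_yule_tree(5, birth_rate=0.0, seed=0)


class TestSimulateCharacter:
    def test_zero_rates_inherit_root_state(self):
        t = sim.simulate_yule_tree(15, seed=3)
        tips, nodes, events = sim.simulate_character(t, np.zeros((2, 2)), seed=5)
        assert len(set(tips.values())) == 1
        assert events == []
        assert set(nodes.values()) == set(tips.values())

    def test_high_rate_reaches_equilibrium(self):
        # one long branch: end state frequencies approach (1/2, 1/2)
        t = sim.simulate_yule_tree(2, seed=1)
        for nd in t.tree.preorder_node_iter():
            if nd.edge.length:
                nd.edge.length = 3.0
        Q = mk.build_rate_matrix(mk.mk_model("ER", 2), [5.0])
        rng = np.random.default_rng(7)
        freq = np.zeros(2)
        reps = 4000
        for _ in range(reps):
            tips, _, _ = sim.simulate_character(t, Q, root_prior=[1.0, 0.0],
                                                seed=rng, record_events=False)
            freq[tips["t1"]] += 1
        assert abs(freq[0] / reps - 0.5) < 0.02

    def test_single_branch_change_probability(self):
        # P(end != start) on a t=1 branch under ER q=0.5 is (1-e^{-1})/2
        rng = np.random.default_rng(11)
        Q = mk.build_rate_matrix(mk.mk_model("ER", 2), [0.5])
        flips = 0
        reps = 100_000
        for _ in range(reps):
            s = sim._simulate_branch(0, 1.0, Q, rng, [], 0, 0.0)
            flips += s != 0
        want = 0.5 * (1 - math.exp(-1.0))
        assert abs(flips / reps - want) < 0.005

    def test_record_matches_index_nodes(self):
        t = sim.simulate_yule_tree(10, seed=8)
        tips, nodes, _ = sim.simulate_character(
            t, mk.build_rate_matrix(mk.mk_model("ER", 2), [0.3]), seed=2)
        idx = t.index()
        for lb, tid in idx.tip_id.items():
            assert tips[lb] == nodes[tid]


class TestSimulatePair:
    def test_independent_spec_gives_no_association(self):
        spec = mk.build_pair_model("UNCORRnodual")
        phis = []
        for s in range(60):
            t = sim.simulate_yule_tree(500, seed=1000 + s)
            scale = 1.0 / t.depth()
            df, _, _ = sim.simulate_pair(t, spec, np.array([1, 1, 2, 2.0]) * scale,
                                         seed=s)
            a, b = df["A"].to_numpy(), df["B"].to_numpy()
            if a.std() == 0 or b.std() == 0:
                continue
            phis.append(np.corrcoef(a, b)[0, 1])
        assert abs(np.mean(phis)) < 0.05

    def test_dependent_spec_gives_association(self):
        # B's gain rate 10x higher when A=1 -> positive phi on average
        spec = mk.build_pair_model("ARDnodual")
        phis = []
        for s in range(40):
            t = sim.simulate_yule_tree(300, seed=2000 + s)
            c = 2.0 / t.depth()
            #            Again|B0 Again|B1 Aloss|B0 Aloss|B1 Bgain|A0 Bgain|A1 Bloss|A0 Bloss|A1
            rates = np.array([c,  c,       c,       c,       0.1 * c, 1.0 * c, c,       0.1 * c])
            df, _, _ = sim.simulate_pair(t, spec, rates, seed=s)
            a, b = df["A"].to_numpy(), df["B"].to_numpy()
            if a.std() == 0 or b.std() == 0:
                continue
            phis.append(np.corrcoef(a, b)[0, 1])
        assert np.mean(phis) > 0.1

    def test_no_dual_transitions_ever(self):
        spec = mk.build_pair_model("ARDnodual")
        t = sim.simulate_yule_tree(100, seed=4)
        _, _, events = sim.simulate_pair(t, spec,
                                         np.full(8, 3.0 / t.depth()), seed=9)
        assert len(events) > 0
        for _, frm, to, _ in events:
            assert bin(frm ^ to).count("1") == 1


class TestInjectMissing:
    def test_zero_rate_is_identity(self):
        m = read_matrix("species,c1\nA,0\nB,1\n")
        out, mask = sim.inject_missing(m, 0.0, seed=1)
        assert out.data.equals(m.data)
        assert not mask.to_numpy().any()

    def test_fraction_concentrates_at_target(self):
        rec = sim.study_shaped_dataset(n_species=792, n_chars=27, seed=3)
        frac = rec.matrix.missing_fraction()
        assert abs(frac - 0.27) < 0.01
        # inapplicable cells present and distinct from missing
        assert rec.matrix.missing_fraction(include_inapplicable=False) < frac

    def test_same_seed_same_mask(self):
        m = read_matrix("species,c1,c2\nA,0,1\nB,1,0\nC,0,0\n")
        _, m1 = sim.inject_missing(m, 0.4, seed=7)
        _, m2 = sim.inject_missing(m, 0.4, seed=7)
        assert m1.equals(m2)

    def test_invalid_rate(self):
        m = read_matrix("species,c1\nA,0\nB,1\n")
        with pytest.raises(ValueError):
            sim.inject_missing(m, 1.0, seed=0)


class TestPerturbTreeSample:
    def test_no_jitter_no_moves_identical_copies(self):
        base = sim.simulate_yule_tree(20, seed=6)
        sample = sim.perturb_tree_sample(base, 5, time_jitter=0.0, topo_moves=0, seed=1)
        assert len(sample) == 5
        for t in sample:
            assert t.newick() == base.newick()

    def test_jittered_trees_stay_ultrametric(self):
        base = sim.simulate_yule_tree(30, seed=2)
        sample = sim.perturb_tree_sample(base, 50, time_jitter=0.05, seed=3)
        for t in sample:
            assert check_ultrametric(t, rel_tol=1e-6).passed

    def test_nni_moves_bounded_rf_distance(self):
        base = sim.simulate_yule_tree(50, seed=10)
        sample = sim.perturb_tree_sample(base, 20, time_jitter=0.0,
                                         topo_moves=2, seed=11)
        tns = dendropy.TaxonNamespace()
        ref = dendropy.Tree.get(data=base.newick(), schema="newick",
                                taxon_namespace=tns)
        ref.encode_bipartitions()
        for t in sample:
            other = dendropy.Tree.get(data=t.newick(), schema="newick",
                                      taxon_namespace=tns)
            other.encode_bipartitions()
            rf = treecompare.symmetric_difference(ref, other)
            assert rf <= 4  # each NNI changes at most one bipartition per tree

    def test_tip_sets_consistent(self):
        base = sim.simulate_yule_tree(25, seed=12)
        sample = sim.perturb_tree_sample(base, 10, time_jitter=0.05,
                                         topo_moves=1, seed=13)
        sample.check_consistent()


class TestPaperShapedDataset:
    def test_desk_scale_replica_structure(self):
        rec = sim.study_shaped_dataset(n_species=60, n_chars=9, n_trees=4, seed=1)
        assert rec.matrix.data.shape == (60, 9)
        assert len(rec.trees) == 4
        kinds = {rec.matrix.n_states(c) for c in rec.matrix.characters}
        assert kinds >= {2, 3}
        assert any(rec.matrix.is_ordered(c) for c in rec.matrix.characters)

    def test_reproducible_and_sidecar(self):
        a = sim.study_shaped_dataset(n_species=40, n_chars=6, seed=5)
        b = sim.study_shaped_dataset(n_species=40, n_chars=6, seed=5)
        assert a.matrix.data.equals(b.matrix.data)
        assert a.trees[0].newick() == b.trees[0].newick()
        assert '"seed": 5' in a.sidecar()
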