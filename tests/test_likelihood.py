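"""Pruning likelihoods, ML fitting, AICc selection and marginal ancestors."""

import math

import numpy as np
import pytest

from mkanc import likelihood as lk
from mkanc import models as mk
from mkanc.phylo_io import Chronogram
from mkanc.simulate import simulate_character, simulate_yule_tree

from conftest import small_trees
from bruteforce import brute_loglik, brute_marginal


def _rate_settings(spec, rng):
    return [
        np.full(spec.n_free, 0.05),
        np.full(spec.n_free, 1.2),
        rng.uniform(0.1, 2.0, size=spec.n_free),
    ]


class TestLogLikelihood:
    def test_zero_rate_constant_data_is_root_prior(self, two_tip):
        spec = mk.mk_model("ER", 2)
        ll = lk.log_likelihood(two_tip, {"A": 0, "B": 0}, spec, [1e-12])
        assert ll == pytest.approx(math.log(0.5), abs=1e-6)

    def test_two_tip_closed_form(self, two_tip):
        # L = P_same(1) * P_diff(1) with q=0.5 under a flat root
        spec = mk.mk_model("ER", 2)
        ll = lk.log_likelihood(two_tip, {"A": 0, "B": 1}, spec, [0.5])
        p_same = 0.5 * (1 + math.exp(-1.0))
        assert ll == pytest.approx(math.log(p_same * (1 - p_same)), abs=1e-10)

    def test_missing_tip_equals_pruned_tree(self):
        tree = Chronogram.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        spec = mk.mk_model("ARD", 2)
        rates = [0.4, 0.9]
        ll_missing = lk.log_likelihood(tree, {"A": 0, "B": -1, "C": 1, "D": 1},
                                       spec, rates)
        Q = mk.build_rate_matrix(spec, rates)
        oracle = brute_loglik(tree.pruned_to(["A", "C", "D"]),
                              {"A": 0, "C": 1, "D": 1}, Q, np.array([0.5, 0.5]))
        assert ll_missing == pytest.approx(oracle, abs=1e-10)

    def test_all_missing_rejected(self, two_tip):
        with pytest.raises(ValueError, match="all missing"):
            lk.log_likelihood(two_tip, {"A": -1, "B": -1}, mk.mk_model("ER", 2), [0.5])

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_pruning_equals_brute_force(self, k, rng):
        """Exhaustive oracle battery over small trees, state counts and rate
        settings, including missing data and polytomies."""
        for tree in small_trees():
            labels = sorted(tree.tip_labels)
            for spec_name in ("ER", "ARD"):
                spec = mk.mk_model(spec_name, k)
                for rates in _rate_settings(spec, rng):
                    states = {lb: int(rng.integers(k)) for lb in labels}
                    states[labels[-1]] = -1  # one missing tip
                    Q = mk.build_rate_matrix(spec, rates)
                    for prior in (np.full(k, 1 / k), mk.stationary_distribution(Q)):
                        got = lk.log_likelihood(tree, states, spec, rates,
                                                root_prior=prior)
                        want = brute_loglik(tree, states, Q, prior)
                        assert got == pytest.approx(want, abs=1e-10)

    def test_invariant_to_tip_relabeling(self, rng):
        tree = small_trees()[2]
        spec = mk.mk_model("ER", 3)
        states = {lb: int(rng.integers(3)) for lb in tree.tip_labels}
        ll = lk.log_likelihood(tree, states, spec, [0.7])
        # same data presented in a different dict order
        shuffled = dict(reversed(list(states.items())))
        assert lk.log_likelihood(tree, shuffled, spec, [0.7]) == pytest.approx(ll)


class TestAicc:
    def test_formula(self):
        assert lk.aicc(-100.0, 2, 50) == pytest.approx(204.2553, abs=1e-4)

    def test_reduces_to_aic_for_large_n(self):
        aic = -2 * (-100.0) + 2 * 3
        assert lk.aicc(-100.0, 3, 10**6) == pytest.approx(aic, rel=1e-6)

    def test_undefined_when_overparameterized(self):
        with pytest.raises(ValueError, match="undefined"):
            lk.aicc(-10.0, 5, 6)

    def test_weights_for_delta_two(self):
        class F:
            def __init__(self, a):
                self.aicc = a
                self.weight = None
        fits = [F(100.0), F(102.0)]
        w = lk.akaike_weights(fits)
        assert w[0] == pytest.approx(0.73106, abs=1e-5)
        assert w[1] == pytest.approx(0.26894, abs=1e-5)


class TestFitMl:
    def test_constant_character_drives_rate_to_zero(self):
        tree = simulate_yule_tree(40, seed=5)
        states = {lb: 0 for lb in tree.tip_labels}
        fit = lk.fit_ml(tree, states, mk.mk_model("ER", 2))
        assert fit.rates[0] < 1e-6

    def test_nested_models_ordered_likelihoods(self, rng):
        tree = simulate_yule_tree(60, seed=7)
        Q = mk.build_rate_matrix(mk.mk_model("ER", 2), [0.5 / tree.depth()])
        tips, _, _ = simulate_character(tree, Q, seed=11)
        er = lk.fit_ml(tree, tips, mk.mk_model("ER", 2))
        ard = lk.fit_ml(tree, tips, mk.mk_model("ARD", 2))
        assert ard.lnL >= er.lnL - 1e-6

    def test_recovers_simulation_rate(self):
        tree = simulate_yule_tree(300, seed=3)
        q = 2.0 / tree.depth()
        Q = mk.build_rate_matrix(mk.mk_model("ER", 2), [q])
        tips, _, _ = simulate_character(tree, Q, seed=13)
        fit = lk.fit_ml(tree, tips, mk.mk_model("ER", 2))
        assert 0.3 * q < fit.rates[0] < 3.0 * q
        assert fit.converged


class TestModelSelect:
    def test_binary_candidate_set(self):
        names = [s.name for s in lk.candidate_models(2)]
        assert names == ["ER", "ARD", "ARDeq", "UNI01", "UNI10"]
        assert [n for n in names if n.startswith("UNI")] == ["UNI01", "UNI10"]

    def test_ordered_multistate_candidates_include_ord_family(self):
        names = {s.name for s in lk.candidate_models(4, ordered=True)}
        assert {"ORD", "ORDSYM", "ORDER", "ORDeq", "ORDSYMeq", "ORDEReq"} <= names

    def test_ranked_by_aicc_with_weights(self):
        tree = simulate_yule_tree(80, seed=2)
        Q = mk.build_rate_matrix(mk.mk_model("ER", 2), [1.0 / tree.depth()])
        tips, _, _ = simulate_character(tree, Q, seed=4)
        fits = lk.model_select(tree, tips, k=2)
        aiccs = [f.aicc for f in fits]
        assert aiccs == sorted(aiccs)
        assert sum(f.weight for f in fits) == pytest.approx(1.0)


class TestMarginalAncestral:
    def test_symmetric_configuration_root_is_even(self, balanced_four):
        spec = mk.mk_model("ER", 2)
        rec = lk.marginal_ancestral(balanced_four, {"A": 0, "B": 0, "C": 1, "D": 1},
                                    spec=spec, rates=[0.5])
        root = rec.index.root
        assert rec.prob(root) == pytest.approx([0.5, 0.5], abs=1e-10)
        assert rec.best(root) == (0, 1)  # reported as a tie, not broken

    def test_two_tip_closed_form(self, two_tip):
        spec = mk.mk_model("ER", 2)
        rec = lk.marginal_ancestral(two_tip, {"A": 0, "B": 0}, spec=spec, rates=[0.5])
        p_same = 0.5 * (1 + math.exp(-1.0))
        want = p_same**2 / (p_same**2 + (1 - p_same) ** 2)
        root_p = rec.prob(rec.index.root)[0]
        assert root_p == pytest.approx(want, abs=1e-10)
        assert root_p == pytest.approx(0.82403, abs=5e-6)

    def test_vectors_normalized(self, rng):
        tree = small_trees()[3]
        spec = mk.mk_model("ARD", 3)
        states = {lb: int(rng.integers(3)) for lb in tree.tip_labels}
        rec = lk.marginal_ancestral(tree, states, spec=spec,
                                    rates=rng.uniform(0.2, 1.0, 6))
        assert np.allclose(rec.probs.sum(axis=1), 1.0, atol=1e-9)

    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_brute_force_everywhere(self, k, rng):
        for tree in small_trees()[:3]:
            spec = mk.mk_model("ARD", k)
            rates = rng.uniform(0.2, 1.5, size=spec.n_free)
            states = {lb: int(rng.integers(k)) for lb in sorted(tree.tip_labels)}
            Q = mk.build_rate_matrix(spec, rates)
            prior = np.full(k, 1 / k)
            rec = lk.marginal_ancestral(tree, states, spec=spec, rates=rates)
            idx = tree.index()
            for node in idx.postorder:
                want = brute_marginal(tree, states, Q, prior, int(node))
                assert rec.prob(int(node)) == pytest.approx(want, abs=1e-10)


class TestMrca:
    def test_cherry_is_monophyletic(self, balanced_four):
        node, mono = lk.mrca(balanced_four, ["A", "B"])
        assert mono
        idx = balanced_four.index()
        assert node != idx.root

    def test_spanning_pair_hits_root(self, balanced_four):
        node, mono = lk.mrca(balanced_four, ["A", "C"])
        assert node == balanced_four.index().root
        assert not mono

    def test_single_taxon_rejected(self, balanced_four):
        with pytest.raises(ValueError):
            lk.mrca(balanced_four, ["A"])
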