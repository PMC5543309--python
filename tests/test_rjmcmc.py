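"""Reversible-jump sampler, credibility intervals and ESS diagnostics."""

import numpy as np
import pytest
import scipy.stats

from mkanc import models as mk
from mkanc.likelihood import marginal_ancestral
from mkanc.rjmcmc import (McmcSettings, credibility_interval,
                          effective_sample_size, run_rjmcmc,
                          sample_ancestral_state)
from mkanc.simulate import simulate_character, simulate_yule_tree


class TestCredibilityInterval:
    def test_degenerate_constant_samples(self):
        assert credibility_interval([0.7] * 10) == (0.7, 0.7)

    def test_uniform_quantiles(self):
        x = np.random.default_rng(1).random(1_000_000)
        lo, hi = credibility_interval(x, 0.95)
        assert lo == pytest.approx(0.025, abs=0.002)
        assert hi == pytest.approx(0.975, abs=0.002)

    def test_invalid_level(self):
        with pytest.raises(ValueError):
            credibility_interval([0.1, 0.2], level=1.2)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            credibility_interval([0.5])


class TestEffectiveSampleSize:
    def test_white_noise(self):
        x = np.random.default_rng(2).normal(size=1000)
        assert effective_sample_size(x) == pytest.approx(1000, rel=0.15)

    def test_ar1_series(self):
        # ESS ~= n (1-rho)/(1+rho) for an AR(1) chain
        rho, n = 0.9, 10_000
        rng = np.random.default_rng(3)
        x = np.empty(n)
        x[0] = rng.normal()
        for i in range(1, n):
            x[i] = rho * x[i - 1] + rng.normal() * np.sqrt(1 - rho**2)
        want = n * (1 - rho) / (1 + rho)
        assert effective_sample_size(x) == pytest.approx(want, rel=0.25)

    def test_constant_series_undefined(self):
        assert np.isnan(effective_sample_size(np.ones(100)))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            effective_sample_size([1.0, 2.0])


class TestSettings:
    def test_burnin_must_precede_end(self):
        with pytest.raises(ValueError):
            McmcSettings(generations=100, burnin=100, sample_interval=10)

    def test_interval_must_divide_span(self):
        with pytest.raises(ValueError):
            McmcSettings(generations=1000, burnin=100, sample_interval=70)


@pytest.fixture(scope="module")
def prior_chain():
    """Prior-only chain (every tip missing): the posterior is the prior."""
    tree = simulate_yule_tree(8, seed=1)
    states = {lb: -1 for lb in tree.tip_labels}
    settings = McmcSettings(generations=200_000, sample_interval=20,
                            burnin=20_000, seed=17)
    return run_rjmcmc(tree, states, settings, k=2), settings


class TestPriorOnly:
    def test_root_probability_is_half(self, prior_chain):
        res, _ = prior_chain
        row = res.summary.table
        mean = row.loc[row["state"] == "0", "mean"].iloc[0]
        assert mean == pytest.approx(0.5, abs=1e-9)  # flat root prior, no data

    def test_models_visited_uniformly(self, prior_chain):
        res, s = prior_chain
        post = res.trace[res.trace["generation"] > s.burnin]
        counts = post["model"].value_counts()
        assert set(counts.index) == {"0,0", "0,1", "0,-1", "-1,0"}
        p = scipy.stats.chisquare(counts.to_numpy()).pvalue
        assert p > 0.01

    def test_hyper_mean_marginal_uniform(self, prior_chain):
        res, s = prior_chain
        m = res.trace.loc[res.trace["generation"] > s.burnin, "hyperMean"]
        assert scipy.stats.kstest(m, "uniform").pvalue > 0.01


class TestChainBehaviour:
    def test_bit_for_bit_reproducible(self):
        tree = simulate_yule_tree(30, seed=4)
        Q = mk.build_rate_matrix(mk.mk_model("ER", 2), [1.0 / tree.depth()])
        tips, _, _ = simulate_character(tree, Q, seed=5)
        settings = McmcSettings(generations=4000, sample_interval=10,
                                burnin=1000, seed=99)
        a = run_rjmcmc(tree, tips, settings)
        b = run_rjmcmc(tree, tips, settings)
        assert a.trace.equals(b.trace)

    def test_strong_signal_recovers_root_state(self):
        hits = 0
        reps = 12
        for s in range(reps):
            tree = simulate_yule_tree(150, seed=300 + s)
            Q = mk.build_rate_matrix(mk.mk_model("ER", 2), [0.3 / tree.depth()])
            tips, nodes, _ = simulate_character(tree, Q, seed=600 + s)
            if len(set(tips.values())) < 2:
                hits += 1  # constant data: trivially consistent
                continue
            settings = McmcSettings(generations=6000, sample_interval=10,
                                    burnin=1000, seed=s)
            res = run_rjmcmc(tree, tips, settings)
            tab = res.summary.table
            modal = int(tab.loc[tab["mean"].idxmax(), "state"])
            hits += modal == nodes[tree.index().root]
        assert hits >= 0.7 * reps

    def test_focal_clade_monophyly_tracked(self):
        tree = simulate_yule_tree(20, seed=8)
        labels = sorted(tree.tip_labels)
        states = {lb: i % 2 for i, lb in enumerate(labels)}
        clade = {"pick": labels[:6], "root": "root"}
        settings = McmcSettings(generations=2000, sample_interval=10,
                                burnin=500, seed=3)
        res = run_rjmcmc(tree, states, settings, focal_clades=clade)
        assert set(res.summary.monophyly_fraction) == {"pick", "root"}
        assert res.summary.monophyly_fraction["root"] == 0.0

    def test_unresolvable_focal_clade_rejected(self):
        tree = simulate_yule_tree(10, seed=9)
        states = {lb: 0 for lb in tree.tip_labels}
        settings = McmcSettings(generations=2000, sample_interval=10,
                                burnin=500, seed=3)
        with pytest.raises(ValueError, match="unresolvable"):
            run_rjmcmc(tree, states, settings,
                       focal_clades={"bad": ["nope1", "nope2"]})

    def test_trace_has_tracer_columns(self):
        tree = simulate_yule_tree(10, seed=2)
        states = {lb: i % 2 for i, lb in enumerate(sorted(tree.tip_labels))}
        settings = McmcSettings(generations=1000, sample_interval=10,
                                burnin=500, seed=1)
        res = run_rjmcmc(tree, states, settings)
        for col in ("generation", "lnL", "treeIndex", "nClasses",
                    "zeroSetSize", "hyperMean"):
            assert col in res.trace.columns


class TestSampleAncestralState:
    def test_symmetric_configuration_even_draws(self, balanced_four):
        spec = mk.mk_model("ER", 2)
        # resolve the root via the MRCA of a spanning pair
        draws = sample_ancestral_state(balanced_four,
                                       {"A": 0, "B": 0, "C": 1, "D": 1},
                                       spec, [0.5], node=["A", "C"],
                                       seed=1, n_draws=10_000)
        freq = np.bincount(draws, minlength=2) / 10_000
        assert freq[0] == pytest.approx(0.5, abs=0.02)

    def test_constant_data_zero_rate_draws_tip_state(self, balanced_four):
        spec = mk.mk_model("ER", 2)
        draws = sample_ancestral_state(balanced_four, {t: 1 for t in "ABCD"},
                                       spec, [1e-12], node=["A", "C"],
                                       seed=2, n_draws=200)
        assert set(draws.tolist()) == {1}

    def test_draw_frequencies_match_marginals(self, balanced_four):
        spec = mk.mk_model("ARD", 2)
        states = {"A": 0, "B": 1, "C": 1, "D": 1}
        rates = [0.4, 0.9]
        node, _ = balanced_four.index().mrca(["A", "B"])
        p = sample_ancestral_state(balanced_four, states, spec, rates,
                                   node=node, draw=False)
        draws = sample_ancestral_state(balanced_four, states, spec, rates,
                                       node=node, seed=3, n_draws=100_000)
        freq = np.bincount(draws, minlength=2) / 100_000
        assert freq == pytest.approx(p, abs=0.02)
        rec = marginal_ancestral(balanced_four, states, spec=spec, rates=rates)
        assert p == pytest.approx(rec.prob(node), abs=1e-12)
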