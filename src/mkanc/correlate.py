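"""Pairwise correlated-evolution tests for binary characters.

Two routes per character pair, both on the 4-state joint chain (states
``00, 01, 10, 11``, first trait the high bit, simultaneous changes of both
traits excluded):

* **ML** — fit the seven named combined models (four correlated: ARDnodual,
  ARDnodualeq, SYMnodual, SYMnodualeq; three uncorrelated: ERnodual,
  UNCORRnodual, UNCORRnodualeq) and report the cumulative Akaike weight of
  the correlated set.
* **rjMCMC** — explore the full space of 21,146 rate-class combined models,
  classify every sampled model as dependent or independent, and report the
  Bayes factor

      BF_DI = [P(M_D | D) / P(M_I | D)] / [(21146 - 51) / 51],

  the posterior odds of dependent to independent models divided by the
  prior odds implied by a uniform prior over the enumerated space.

A tip missing one of the two traits still carries partial signal: its joint
partial vector is the indicator over the consistent combined states.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import models as mk
from .likelihood import ModelFit, _fit_partials, akaike_weights
from .phylo_io import CharacterMatrix, Chronogram, TreeSample
from .rjmcmc import McmcSettings, RjmcmcResult, run_rjmcmc

__all__ = [
    "PairResult",
    "pair_tip_partials",
    "fit_pair_ml",
    "bf_dependent_independent",
    "run_pair_rjmcmc",
    "all_pairs",
    "pair_matrix_table",
]


def pair_tip_partials(index, statesA: Mapping[str, int], statesB: Mapping[str, int]
                      ) -> np.ndarray:
    """Joint tip partial template over the 4 combined states.

    An observed pair gives a one-hot row; one trait missing gives the
    indicator over the two consistent joint states; both missing gives ones.
    """
    partials = np.ones((index.n_nodes, 4))
    for label, tid in index.tip_id.items():
        a = statesA.get(label, -1)
        b = statesB.get(label, -1)
        a = -1 if a is None else a
        b = -1 if b is None else b
        row = np.zeros(4)
        for s in range(4):
            if (a < 0 or (s >> 1) == a) and (b < 0 or (s & 1) == b):
                row[s] = 1.0
        partials[tid] = row
    return partials


@dataclass
class PairResult:
    """Results for one character pair (either or both routes filled in)."""

    pair: tuple[str, str]
    fits: dict[str, ModelFit] = field(default_factory=dict)
    cumulative_correlated_weight: float | None = None
    freq_dependent: float | None = None
    freq_independent: float | None = None
    bf_di: float | None = None
    bayes: RjmcmcResult | None = None

    @property
    def best_model(self) -> str | None:
        if not self.fits:
            return None
        return min(self.fits.values(), key=lambda f: f.aicc).name


def _binary_states(matrix_or_states, char=None) -> Mapping[str, int]:
    if isinstance(matrix_or_states, CharacterMatrix):
        if matrix_or_states.n_states(char) != 2:
            raise ValueError(f"character {char!r} is not binary")
        return matrix_or_states.states(char)
    states = matrix_or_states
    if any(s is not None and s > 1 for s in states.values()):
        raise ValueError("pair analyses require binary characters")
    return states


def fit_pair_ml(tree: Chronogram, statesA: Mapping[str, int],
                statesB: Mapping[str, int], n_starts: int = 4,
                seed: int = 0) -> PairResult:
    """Seven-model ML comparison for one pair of binary characters."""
    statesA = _binary_states(statesA)
    statesB = _binary_states(statesB)
    index = tree.index()
    partials = pair_tip_partials(index, statesA, statesB)
    # AICc sample size: tips carrying signal for at least one trait
    n_obs = int(np.sum(~np.all(partials[: index.n_tips] == 1.0, axis=1)))
    fits = {}
    for name in mk.PAIR_MODEL_NAMES:
        spec = mk.build_pair_model(name)
        fits[name] = _fit_partials(index, partials, spec, n_obs,
                                   n_starts=n_starts, seed=seed)
    akaike_weights(list(fits.values()))
    cum = sum(fits[name].weight for name in mk.CORRELATED_PAIR_MODELS)
    return PairResult(pair=("A", "B"), fits=fits,
                      cumulative_correlated_weight=float(cum))


def bf_dependent_independent(freq_dependent: float, freq_independent: float,
                             space: mk.ModelSpaceInfo | None = None) -> float:
    """Bayes factor for dependent vs independent evolution.

    Posterior odds of dependent models divided by the prior odds implied by
    a uniform prior over the enumerated combined-model space (by default the
    full 21,146-model space with its 51 independent members).  Returns
    ``inf`` when no independent model was ever sampled and 0 when no
    dependent model was.
    """
    if abs(freq_dependent + freq_independent - 1.0) > 1e-9:
        raise ValueError("sampling frequencies must sum to 1")
    if space is None:
        space = mk.pair_model_space()
    if space.n_independent is None or space.n_dependent is None:
        raise ValueError("model space lacks the dependent/independent split")
    prior_odds = space.n_dependent / space.n_independent
    if freq_independent == 0.0:
        return math.inf
    if freq_dependent == 0.0:
        return 0.0
    return (freq_dependent / freq_independent) / prior_odds


def run_pair_rjmcmc(trees: TreeSample | Chronogram, statesA: Mapping[str, int],
                    statesB: Mapping[str, int], settings: McmcSettings,
                    focal_clades=None, space: mk.ModelSpaceInfo | None = None
                    ) -> PairResult:
    """rjMCMC over the full combined-model space for one pair.

    Every post-burn-in sample's rate-class assignment is classified with the
    independence predicate; BF_DI follows from the sampling frequencies.
    """
    statesA = _binary_states(statesA)
    statesB = _binary_states(statesB)
    base = mk.build_pair_model("ARDnodual")

    def make_partials(index):
        return pair_tip_partials(index, statesA, statesB)

    result = run_rjmcmc(trees, {}, settings, k=4, base_spec=base,
                        focal_clades=focal_clades, tip_partials=make_partials)
    if space is None:
        space = mk.pair_model_space()
    post = result.trace[result.trace["generation"] > settings.burnin]
    # engine free-pair order == canonical pair parameter order
    assert base.free_pairs == sorted(mk.PAIR_FREE_PAIRS)
    reorder = [sorted(mk.PAIR_FREE_PAIRS).index(p) for p in mk.PAIR_FREE_PAIRS]
    flags = []
    for sig in post["model"]:
        a = [int(x) for x in sig.split(",")]
        flags.append(mk.is_independent_assignment([a[j] for j in reorder]))
    flags = np.asarray(flags)
    freq_i = float(flags.mean())
    freq_d = 1.0 - freq_i
    return PairResult(pair=("A", "B"),
                      freq_dependent=freq_d, freq_independent=freq_i,
                      bf_di=bf_dependent_independent(freq_d, freq_i, space),
                      bayes=result)


def all_pairs(matrix: CharacterMatrix, tree: Chronogram,
              trees: TreeSample | None = None,
              settings: McmcSettings | None = None,
              ml: bool = True, bayes: bool = False,
              weight_threshold: float = 0.5, bf_threshold: float = 3.0,
              n_starts: int = 3, seed: int = 0
              ) -> tuple[pd.DataFrame, dict]:
    """All n(n-1)/2 pairwise tests over the binary characters of ``matrix``.

    Returns a long-format table (one row per pair) and a summary dict with
    the fraction of pairs called significant under each criterion
    (cumulative correlated weight > ``weight_threshold``;
    BF_DI > ``bf_threshold``).
    """
    chars = matrix.characters
    for ch in chars:
        if matrix.n_states(ch) != 2:
            raise ValueError(f"character {ch!r} is not binary")
    if len(chars) < 2:
        raise ValueError("need at least two binary characters")
    space = mk.pair_model_space() if bayes else None
    rows = []
    for a, b in itertools.combinations(chars, 2):
        row: dict = {"charA": a, "charB": b}
        sa, sb = matrix.states(a), matrix.states(b)
        if ml:
            res = fit_pair_ml(tree, sa, sb, n_starts=n_starts, seed=seed)
            row["cum_correlated_weight"] = res.cumulative_correlated_weight
            row["best_model"] = res.best_model
        if bayes:
            if settings is None:
                raise ValueError("bayes=True needs McmcSettings")
            bres = run_pair_rjmcmc(trees if trees is not None else tree,
                                   sa, sb, settings, space=space)
            row["freq_dependent"] = bres.freq_dependent
            row["bf_di"] = bres.bf_di
        rows.append(row)
    table = pd.DataFrame(rows)
    summary: dict = {"n_pairs": len(rows)}
    if ml:
        summary["frac_significant_ml"] = float(
            (table["cum_correlated_weight"] > weight_threshold).mean())
    if bayes:
        summary["frac_significant_bayes"] = float(
            (table["bf_di"] > bf_threshold).mean())
    return table, summary


def pair_matrix_table(table: pd.DataFrame, characters: Sequence[str]) -> pd.DataFrame:
    """Symmetric character x character table: upper triangle BF_DI, lower
    triangle cumulative correlated Akaike weight."""
    out = pd.DataFrame(np.nan, index=list(characters), columns=list(characters))
    for _, row in table.iterrows():
        a, b = row["charA"], row["charB"]
        if "bf_di" in row and pd.notna(row.get("bf_di")):
            out.loc[a, b] = row["bf_di"]
        if "cum_correlated_weight" in row and pd.notna(row.get("cum_correlated_weight")):
            out.loc[b, a] = row["cum_correlated_weight"]
    return out
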