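"""Reversible-jump MCMC over rate-class partition models.

The model space is the one enumerated in :mod:`mkanc.models`: each free
transition parameter of the base model is assigned to an unlabeled positive
rate class or to a distinguished zero class (the all-zero model excluded).
The sampler places a uniform prior over that space — the convention under
which the prior odds of dependent to independent combined models equal the
ratio of the model counts — an exponential prior with mean ``m`` on each
class rate, and a uniform hyperprior on ``m`` over (0, 1].

Move kernel (all ratios exact, so prior-only chains recover the prior):

* rate update — multiplicative log-normal on one class rate;
* reassign — move one parameter to another existing class, to a fresh
  singleton class (rate born from the exponential prior) or to the zero
  class.  The number of legal placements depends only on the partition of
  the *other* parameters, hence is identical forwards and backwards, and the
  born/killed rate's prior density cancels against the proposal density, so
  the acceptance ratio reduces to the likelihood ratio.  This single move
  both splits and merges classes;
* tree switch — propose a uniformly drawn tree from the posterior sample
  (likelihood-ratio Metropolis step), integrating over phylogenetic and
  dating uncertainty;
* hyperprior update — fresh uniform draw of ``m``;
* model redraw — independence proposal of a whole model from the uniform
  prior with all rates drawn from the rate prior (enabled when the space is
  small enough to enumerate), again accepted on the likelihood ratio alone.

Ancestral states at focal nodes are recorded at each sampling generation as
marginal probability vectors under the current model and tree.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import models as mk
from .likelihood import _resolve_root_prior, tip_partial_matrix
from .phylo_io import Chronogram, TreeSample
from .pruning import branch_matrices, node_marginals, pruning_loglik

__all__ = [
    "McmcSettings",
    "PosteriorSummary",
    "RjmcmcResult",
    "run_rjmcmc",
    "credibility_interval",
    "effective_sample_size",
    "sample_ancestral_state",
]


@dataclass
class McmcSettings:
    """Chain settings.  Defaults are the long-run configuration (10M
    generations, sampling every 100, 1M burn-in); analyses at desk scale
    pass much smaller values."""

    generations: int = 10_000_000
    sample_interval: int = 100
    burnin: int = 1_000_000
    seed: int = 0
    root_prior: str = "flat"          # flat | equilibrium
    tree_switch_prob: float = 0.10
    rate_proposal_sd: float = 0.6
    redraw_prob: float = 0.05
    hyper_prob: float = 0.05
    rate_move_prob: float = 0.40
    marginalize_ancestral: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.burnin < self.generations):
            raise ValueError("need 0 < burnin < generations")
        if (self.generations - self.burnin) % self.sample_interval:
            raise ValueError("sample interval must divide the post-burn-in span")


def credibility_interval(samples: Sequence[float], level: float = 0.95
                         ) -> tuple[float, float]:
    """Equal-tailed credibility interval of a sample of probabilities."""
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two samples")
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(x, [a, 1.0 - a])
    return float(lo), float(hi)


def effective_sample_size(trace: Sequence[float]) -> float:
    """ESS = n / (1 + 2 sum rho_k), autocorrelations truncated by Geyer's
    initial-positive-sequence rule (pair sums kept while positive).

    Returns NaN for a zero-variance trace (ESS undefined).
    """
    x = np.asarray(trace, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 samples")
    xc = x - x.mean()
    if np.all(xc == 0):
        return float("nan")
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    if acov[0] <= 0:
        return float("nan")
    rho = acov / acov[0]
    tau = 0.0
    i = 0
    while i + 1 < n:
        pair = rho[i] + rho[i + 1]
        if pair <= 0.0:
            break
        tau += pair
        i += 2
    tau = max(2.0 * tau - 1.0, 1.0)
    return float(n / tau)


# ---------------------------------------------------------------------------
# chain internals


class _Chain:
    def __init__(self, tree_data, free_pairs, k, settings, rng, space):
        self.tree_data = tree_data            # list of (index, partials, no_signal)
        self.free_pairs = list(free_pairs)
        self.n_params = len(self.free_pairs)
        self.k = k
        self.s = settings
        self.rng = rng
        self.space = space                    # ModelSpaceInfo or None
        self.no_signal = all(t[2] for t in tree_data)
        # initial state: one shared class, parsimony-flavoured scale
        self.assignment = [0] * self.n_params
        self.rates = [1.0 / max(tree_data[0][0].tree_length(), 1e-9)]
        self.m = 0.5
        self.tree_i = 0
        self.lnL = self._loglik(self.tree_i, self.assignment, self.rates)
        self.accept = Counter()
        self.propose = Counter()

    # -- likelihood -------------------------------------------------------

    def _build_q(self, assignment, rates):
        Q = np.zeros((self.k, self.k))
        for idx, (i, j) in enumerate(self.free_pairs):
            a = assignment[idx]
            if a >= 0:
                Q[i, j] = rates[a]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def _loglik(self, tree_i, assignment, rates):
        index, partials, no_signal = self.tree_data[tree_i]
        if no_signal:
            return 0.0
        Q = self._build_q(assignment, rates)
        prior = self._root_prior(Q)
        P = branch_matrices(Q, index.edge_len)
        ll = pruning_loglik(index, P, partials, prior)
        if math.isnan(ll):
            raise FloatingPointError("non-finite log-likelihood in rjMCMC chain")
        # ll == -inf is legitimate: a model (e.g. with zero-rate classes)
        # under which the data are impossible; the proposal is then rejected
        return ll

    def _root_prior(self, Q):
        if self.s.root_prior == "flat":
            return np.full(self.k, 1.0 / self.k)
        if self.s.root_prior == "equilibrium":
            return mk.stationary_distribution(Q)
        raise ValueError(f"unsupported root prior {self.s.root_prior!r}")

    # -- moves ------------------------------------------------------------

    def _canon(self, assignment, rates):
        relabel: dict[int, int] = {}
        new_rates: list[float] = []
        out = []
        for a in assignment:
            if a < 0:
                out.append(-1)
                continue
            if a not in relabel:
                relabel[a] = len(new_rates)
                new_rates.append(rates[a])
            out.append(relabel[a])
        return out, new_rates

    def move_rate(self):
        self.propose["rate"] += 1
        c = int(self.rng.integers(len(self.rates)))
        r = self.rates[c]
        r_new = r * math.exp(self.rng.normal(0.0, self.s.rate_proposal_sd))
        rates = list(self.rates)
        rates[c] = r_new
        lnL = self._loglik(self.tree_i, self.assignment, rates)
        # exponential prior + multiplicative proposal Hastings term
        loga = (lnL - self.lnL) - (r_new - r) / self.m + math.log(r_new / r)
        if math.log(self.rng.random()) < loga:
            self.rates = rates
            self.lnL = lnL
            self.accept["rate"] += 1

    def move_reassign(self):
        self.propose["reassign"] += 1
        i = int(self.rng.integers(self.n_params))
        cur = self.assignment[i]
        others = [a for j, a in enumerate(self.assignment) if j != i]
        other_classes = sorted({a for a in others if a >= 0})
        placements: list = [("class", c) for c in other_classes]
        placements.append(("new", None))
        if other_classes:                       # zero placement would not
            placements.append(("zero", None))   # leave an all-zero model
        kind, target = placements[int(self.rng.integers(len(placements)))]
        assignment = list(self.assignment)
        rates = list(self.rates)
        if kind == "class":
            if target == cur:
                self.accept["reassign"] += 1
                return
            assignment[i] = target
        elif kind == "new":
            if cur >= 0 and others.count(cur) == 0:
                # already a singleton: proposing "new" reproduces the model
                self.accept["reassign"] += 1
                return
            assignment[i] = len(rates)
            rates.append(float(self.rng.exponential(self.m)))
        else:  # zero
            if cur < 0:
                self.accept["reassign"] += 1
                return
            assignment[i] = -1
        assignment, rates = self._canon(assignment, rates)
        lnL = self._loglik(self.tree_i, assignment, rates)
        if math.log(self.rng.random()) < (lnL - self.lnL):
            self.assignment = assignment
            self.rates = rates
            self.lnL = lnL
            self.accept["reassign"] += 1

    def move_tree(self):
        self.propose["tree"] += 1
        j = int(self.rng.integers(len(self.tree_data)))
        lnL = self._loglik(j, self.assignment, self.rates)
        if math.log(self.rng.random()) < (lnL - self.lnL):
            self.tree_i = j
            self.lnL = lnL
            self.accept["tree"] += 1

    def move_hyper(self):
        self.propose["hyper"] += 1
        m_new = float(self.rng.random())
        if m_new <= 0.0:
            return
        logp = 0.0
        for r in self.rates:
            logp += (-math.log(m_new) - r / m_new) - (-math.log(self.m) - r / self.m)
        if math.log(self.rng.random()) < logp:
            self.m = m_new
            self.accept["hyper"] += 1

    def move_redraw(self):
        self.propose["redraw"] += 1
        models = self.space.models
        assignment = list(models[int(self.rng.integers(len(models)))])
        n_classes = max(assignment) + 1 if any(a >= 0 for a in assignment) else 0
        rates = [float(self.rng.exponential(self.m)) for _ in range(n_classes)]
        lnL = self._loglik(self.tree_i, assignment, rates)
        if math.log(self.rng.random()) < (lnL - self.lnL):
            self.assignment = assignment
            self.rates = rates
            self.lnL = lnL
            self.accept["redraw"] += 1

    # -- sampling ---------------------------------------------------------

    def signature(self) -> str:
        return ",".join(str(a) for a in self.assignment)

    def focal_marginals(self, focal_nodes):
        index, partials, _ = self.tree_data[self.tree_i]
        Q = self._build_q(self.assignment, self.rates)
        prior = self._root_prior(Q)
        P = branch_matrices(Q, index.edge_len)
        _, marg = node_marginals(index, P, partials, prior)
        out = {}
        for name, per_tree in focal_nodes.items():
            node, mono = per_tree[self.tree_i]
            out[name] = (marg[node], mono)
        return out


# ---------------------------------------------------------------------------
# results


@dataclass
class PosteriorSummary:
    """Post-burn-in summaries: per focal node and state the mean posterior
    probability and its 95% equal-tailed CI across samples, chain ESS values
    (flagged below 200), model-visit frequencies, and per-clade fractions of
    samples in which the focal taxon set was not monophyletic."""

    table: pd.DataFrame
    ess: dict[str, float]
    low_ess: list[str]
    model_freqs: Counter
    monophyly_fraction: dict[str, float]
    acceptance: dict[str, float]

    @property
    def min_ess(self) -> float:
        vals = [v for v in self.ess.values() if np.isfinite(v)]
        return min(vals) if vals else float("nan")


@dataclass
class RjmcmcResult:
    trace: pd.DataFrame
    summary: PosteriorSummary
    settings: McmcSettings
    space: mk.ModelSpaceInfo | None = None

    def write_trace(self, path) -> None:
        """Tab-delimited, Tracer-compatible trace file."""
        self.trace.to_csv(path, sep="\t", index=False)


def _resolve_focal(tree_data, trees, focal_clades):
    """Per clade, per tree: (node id, monophyletic?).  'root' is special."""
    focal = {}
    for name, taxa in (focal_clades or {"root": "root"}).items():
        per_tree = []
        n_fail = 0
        for (index, _, _), _t in zip(tree_data, trees):
            if isinstance(taxa, str) and taxa == "root":
                per_tree.append((index.root, True))
                continue
            try:
                per_tree.append(index.mrca(taxa))
            except ValueError:
                per_tree.append((None, False))
                n_fail += 1
        if n_fail > 0.5 * len(per_tree):
            raise ValueError(f"focal clade {name!r} unresolvable in >50% of trees")
        # trees where the clade could not be placed fall back to that tree's root
        per_tree = [
            (p if p[0] is not None else (td[0].root, False))
            for p, td in zip(per_tree, tree_data)
        ]
        focal[name] = per_tree
    return focal


def run_rjmcmc(trees: TreeSample | Chronogram, states: Mapping[str, int],
               settings: McmcSettings, k: int | None = None,
               base_spec: mk.MkModelSpec | None = None,
               focal_clades: Mapping[str, Sequence[str] | str] | None = None,
               tip_partials=None) -> RjmcmcResult:
    """Run one reversible-jump chain for a single character.

    ``states`` maps tip label to state index (-1 = no signal); a chain with
    every tip missing is legitimate (prior-only run).  ``base_spec`` fixes
    which transitions are free parameters (default: all, i.e. ARD); its
    equality classes are ignored — the rjMCMC explores groupings itself.
    ``tip_partials``: advanced hook used by the pair analyses to supply
    ambiguous tip state vectors directly.
    """
    if isinstance(trees, Chronogram):
        trees = TreeSample([trees])
    trees.check_consistent()
    if k is None:
        k = base_spec.k if base_spec is not None else max(
            [s for s in states.values() if s is not None and s >= 0], default=1) + 1
        k = max(k, 2)
    if base_spec is None:
        base_spec = mk.mk_model("ARD", k)
    free_pairs = base_spec.free_pairs
    rng = np.random.default_rng(settings.seed)

    tree_data = []
    for t in trees:
        index = t.index()
        if tip_partials is not None:
            partials = tip_partials(index)
        else:
            partials = tip_partial_matrix(index, states, k)
        no_signal = bool(np.all(partials[: index.n_tips] == 1.0))
        tree_data.append((index, partials, no_signal))

    focal = _resolve_focal(tree_data, trees, focal_clades)
    n_params = len(free_pairs)
    space = None
    if n_params <= 8:
        space = mk.enumerate_rate_class_models(n_params, store=True)

    chain = _Chain(tree_data, free_pairs, k, settings, rng, space)

    # move schedule
    probs = {
        "rate": settings.rate_move_prob,
        "reassign": 0.0,
        "tree": settings.tree_switch_prob if len(trees) > 1 else 0.0,
        "hyper": settings.hyper_prob,
        "redraw": settings.redraw_prob if space is not None else 0.0,
    }
    probs["reassign"] = max(1.0 - sum(probs.values()), 0.0)
    names = list(probs)
    weights = np.array([probs[nm] for nm in names])
    weights = weights / weights.sum()
    movers = {"rate": chain.move_rate, "reassign": chain.move_reassign,
              "tree": chain.move_tree, "hyper": chain.move_hyper,
              "redraw": chain.move_redraw}

    rows: dict[str, list] = {c: [] for c in
                             ["generation", "lnL", "treeIndex", "nClasses",
                              "zeroSetSize", "hyperMean", "rate0", "model"]}
    prob_cols: dict[str, list] = {}
    mono_rows: dict[str, list] = {name: [] for name in focal}
    state_labels = [str(s) for s in range(k)]

    interval = settings.sample_interval
    moves = rng.choice(len(names), size=settings.generations, p=weights)
    for gen in range(1, settings.generations + 1):
        movers[names[moves[gen - 1]]]()
        if gen % interval == 0:
            rows["generation"].append(gen)
            rows["lnL"].append(chain.lnL)
            rows["treeIndex"].append(chain.tree_i)
            rows["nClasses"].append(len(chain.rates))
            rows["zeroSetSize"].append(sum(1 for a in chain.assignment if a < 0))
            rows["hyperMean"].append(chain.m)
            rows["rate0"].append(chain.rates[0])
            rows["model"].append(chain.signature())
            margs = chain.focal_marginals(focal)
            for name, (vec, mono) in margs.items():
                if settings.marginalize_ancestral:
                    vals = vec
                else:
                    drawn = rng.choice(k, p=vec / vec.sum())
                    vals = np.eye(k)[drawn]
                for s in range(k):
                    col = f"{name}.P({state_labels[s]})"
                    prob_cols.setdefault(col, []).append(float(vals[s]))
                mono_rows[name].append(mono)

    trace = pd.DataFrame({**rows, **prob_cols})
    post = trace[trace["generation"] > settings.burnin].reset_index(drop=True)

    # summaries
    recs = []
    ess: dict[str, float] = {}
    for col in ("lnL", "hyperMean", "nClasses"):
        ess[col] = effective_sample_size(post[col].to_numpy())
    for name in focal:
        for s in range(k):
            col = f"{name}.P({state_labels[s]})"
            x = post[col].to_numpy()
            lo, hi = credibility_interval(x, 0.95)
            e = effective_sample_size(x)
            ess[col] = e
            recs.append({"node": name, "state": state_labels[s],
                         "mean": float(x.mean()), "ci_lower": lo, "ci_upper": hi,
                         "ess": e})
    table = pd.DataFrame(recs)
    low = [nm for nm, v in ess.items() if np.isfinite(v) and v < 200]
    n_samp = np.arange(len(trace))
    post_mask = trace["generation"] > settings.burnin
    mono_frac = {}
    for name in focal:
        flags = np.asarray(mono_rows[name])[post_mask.to_numpy()]
        mono_frac[name] = float(1.0 - flags.mean())
    freqs = Counter(post["model"])
    acc = {nm: (chain.accept[nm] / chain.propose[nm]) if chain.propose[nm] else float("nan")
           for nm in names}
    summary = PosteriorSummary(table=table, ess=ess, low_ess=low,
                               model_freqs=freqs, monophyly_fraction=mono_frac,
                               acceptance=acc)
    return RjmcmcResult(trace=trace, summary=summary, settings=settings, space=space)


# ---------------------------------------------------------------------------
# single-model ancestral draws


def sample_ancestral_state(tree: Chronogram, states: Mapping[str, int],
                           spec: mk.MkModelSpec, rates: Sequence[float],
                           node, seed=0, n_draws: int = 1, draw: bool = True):
    """Marginal posterior at one node under a fixed model; optionally draw.

    ``node`` is a node id or a taxon list (resolved by MRCA).  With
    ``draw=False`` the marginal probability vector is returned; otherwise
    ``n_draws`` independent state draws from it.
    """
    from .likelihood import marginal_ancestral
    rec = marginal_ancestral(tree, states, spec=spec, rates=rates)
    if not isinstance(node, (int, np.integer)):
        node, _ = tree.index().mrca(node)
    p = rec.prob(int(node))
    if not draw:
        return p
    rng = np.random.default_rng(seed)
    out = rng.choice(len(p), size=n_draws, p=p / p.sum())
    return out if n_draws > 1 else int(out[0])
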