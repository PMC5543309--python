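"""Maximum-likelihood inference for Mk-family models.

Likelihoods use the pruning algorithm with per-node rescaling; missing and
inapplicable tips enter as all-ones partial vectors, which yields exactly the
likelihood of the tree with those tips pruned.  Model fitting optimizes log
rates with multistart L-BFGS-B; model choice is by AICc with Akaike weights;
ancestral states are marginal posteriors from the standard two-pass
(outside-inside) construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from . import models as mk
from .phylo_io import Chronogram
from .pruning import TreeIndex, branch_matrices, node_marginals, pruning_loglik

__all__ = [
    "ModelFit",
    "MarginalReconstruction",
    "log_likelihood",
    "fit_ml",
    "model_select",
    "marginal_ancestral",
    "mrca",
    "aicc",
    "akaike_weights",
    "candidate_models",
    "tip_partial_matrix",
]

RATE_BOUNDS = (1e-9, 1e2)


def tip_partial_matrix(index: TreeIndex, states: Mapping[str, int], k: int) -> np.ndarray:
    """(n_nodes, k) partial-likelihood template: one-hot rows for observed
    tips, ones for no-signal tips; internal rows are workspace."""
    partials = np.ones((index.n_nodes, k))
    for label, tid in index.tip_id.items():
        s = states.get(label, -1)
        if s is None or s < 0:
            continue
        if s >= k:
            raise ValueError(f"state {s} out of range for k={k} at tip {label!r}")
        partials[tid] = 0.0
        partials[tid, s] = 1.0
    return partials


def _resolve_root_prior(spec: mk.MkModelSpec, Q: np.ndarray,
                        root_prior) -> np.ndarray:
    if root_prior is not None and not isinstance(root_prior, str):
        p = np.asarray(root_prior, dtype=float)
        if p.shape != (spec.k,) or abs(p.sum() - 1) > 1e-9 or np.any(p < 0):
            raise ValueError("root prior must be a probability vector over the states")
        return p
    mode = root_prior if isinstance(root_prior, str) else spec.root_prior
    if mode == "flat":
        return np.full(spec.k, 1.0 / spec.k)
    if mode == "equilibrium":
        return mk.stationary_distribution(Q)
    if mode == "implied":
        p = np.zeros(spec.k)
        p[spec.source_state] = 1.0
        return p
    raise ValueError(f"unknown root prior {mode!r}")


def _observed(states: Mapping[str, int]) -> list[str]:
    return [sp for sp, s in states.items() if s is not None and s >= 0]


def log_likelihood(tree: Chronogram, states: Mapping[str, int],
                   spec: mk.MkModelSpec, rates: Sequence[float],
                   root_prior=None) -> float:
    """Log-likelihood of one character on one tree under ``spec``.

    ``states`` maps tip label -> state index, with ``-1`` (or absence) for
    missing/inapplicable.  Raises if no tip carries signal.
    """
    if not _observed(states):
        raise ValueError("character has no observed states (all missing)")
    index = tree.index()
    Q = mk.build_rate_matrix(spec, rates)
    partials = tip_partial_matrix(index, states, spec.k)
    P = branch_matrices(Q, index.edge_len)
    prior = _resolve_root_prior(spec, Q, root_prior)
    return pruning_loglik(index, P, partials, prior)


# ---------------------------------------------------------------------------
# model fit and selection


def aicc(lnL: float, K: int, n: int) -> float:
    """Akaike information criterion with small-sample correction."""
    if n - K - 1 <= 0:
        raise ValueError(f"AICc undefined: n={n}, K={K} gives n-K-1 <= 0")
    return -2.0 * lnL + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


@dataclass
class ModelFit:
    """One fitted model: rates at the optimum plus the AICc bookkeeping."""

    spec: mk.MkModelSpec
    rates: np.ndarray
    lnL: float
    n: int
    converged: bool = True
    weight: float | None = None

    @property
    def K(self) -> int:
        return self.spec.n_free

    @property
    def aicc(self) -> float:
        return aicc(self.lnL, self.K, self.n)

    @property
    def name(self) -> str:
        return self.spec.name


def akaike_weights(fits: Sequence[ModelFit]) -> list[float]:
    """Normalized ``exp(-dAICc/2)`` over a candidate set; stored on the fits."""
    a = np.array([f.aicc for f in fits])
    d = a - a.min()
    w = np.exp(-d / 2.0)
    w /= w.sum()
    for f, wi in zip(fits, w):
        f.weight = float(wi)
    return [float(x) for x in w]


def _fit_partials(index: TreeIndex, partials: np.ndarray, spec: mk.MkModelSpec,
                  n_obs: int, n_starts: int = 5, seed: int = 0,
                  root_prior=None, start_rate: float | None = None) -> ModelFit:
    """Core optimizer over a prebuilt partial template (shared by the
    single-character and two-character paths)."""
    K = spec.n_free
    lo, hi = np.log(RATE_BOUNDS[0]), np.log(RATE_BOUNDS[1])

    def neg(x):
        Q = mk.build_rate_matrix(spec, np.exp(x))
        P = branch_matrices(Q, index.edge_len)
        prior = _resolve_root_prior(spec, Q, root_prior)
        ll = pruning_loglik(index, P, partials, prior)
        return 1e10 if not np.isfinite(ll) else -ll

    rng = np.random.default_rng(seed)
    starts = []
    if start_rate is None:
        start_rate = 1.0 / max(index.tree_length(), 1e-9)
    base = np.clip(np.log(start_rate), lo + 1, hi - 1)
    starts.append(np.full(K, base))
    for _ in range(n_starts - 1):
        starts.append(np.clip(base + rng.normal(0, 2.0, size=K), lo, hi))
    best = None
    ok = False
    for x0 in starts:
        res = scipy.optimize.minimize(neg, x0, method="L-BFGS-B",
                                      bounds=[(lo, hi)] * K)
        if best is None or res.fun < best.fun:
            best = res
        ok = ok or bool(res.success)
    rates = np.exp(best.x)
    return ModelFit(spec=spec, rates=rates, lnL=-float(best.fun), n=n_obs,
                    converged=ok)


def fit_ml(tree: Chronogram, states: Mapping[str, int], spec: mk.MkModelSpec,
           n_starts: int = 5, seed: int = 0, root_prior=None,
           n_override: int | None = None) -> ModelFit:
    """Maximum-likelihood fit of ``spec`` to one character.

    AICc sample size defaults to the number of tips with observed states.
    A non-converged multistart budget is flagged on the fit, never silent.
    """
    obs = _observed(states)
    if not obs:
        raise ValueError("character has no observed states")
    index = tree.index()
    partials = tip_partial_matrix(index, states, spec.k)
    # parsimony-informed start: changes per unit of tree time
    from .parsimony import parsimony_score
    try:
        changes = parsimony_score(tree, states)
    except ValueError:
        changes = 1
    start = max(changes, 0.5) / max(index.tree_length(), 1e-9)
    n = n_override if n_override is not None else len(obs)
    return _fit_partials(index, partials, spec, n, n_starts=n_starts,
                         seed=seed, root_prior=root_prior, start_rate=start)


def candidate_models(k: int, ordered: bool = False) -> list[mk.MkModelSpec]:
    """Default candidate set per character kind: binary characters get
    {ER, ARD, ARDeq, UNI01, UNI10}; ordered multistate characters add the
    ordered variants; unordered multistate get {ER, SYM, SYMeq, ARD, ARDeq}."""
    if k == 2:
        names = ["ER", "ARD", "ARDeq", "UNI01", "UNI10"]
    elif ordered:
        names = ["ER", "SYM", "SYMeq", "ARD", "ARDeq",
                 "ORD", "ORDeq", "ORDSYM", "ORDSYMeq", "ORDER", "ORDEReq"]
    else:
        names = ["ER", "SYM", "SYMeq", "ARD", "ARDeq"]
    return [mk.mk_model(nm, k) for nm in names]


def model_select(tree: Chronogram, states: Mapping[str, int],
                 specs: Sequence[mk.MkModelSpec] | None = None,
                 k: int | None = None, ordered: bool = False,
                 n_starts: int = 5, seed: int = 0) -> list[ModelFit]:
    """Fit a candidate set and rank by AICc (ascending); the first entry is
    the best-fit ("the ML result")."""
    if specs is None:
        if k is None:
            k = max(s for s in states.values() if s >= 0) + 1
        specs = candidate_models(k, ordered=ordered)
    if not specs:
        raise ValueError("candidate set is empty")
    fits = [fit_ml(tree, states, sp, n_starts=n_starts, seed=seed) for sp in specs]
    for f in fits:
        f.aicc  # raises early, naming the offending spec via ValueError below
    fits.sort(key=lambda f: f.aicc)
    akaike_weights(fits)
    return fits


# ---------------------------------------------------------------------------
# marginal ancestral states


@dataclass
class MarginalReconstruction:
    """Per-node marginal state probabilities under a fitted model."""

    index: TreeIndex
    probs: np.ndarray           # (n_nodes, k); tip rows are their posteriors too
    lnL: float
    alphabet: tuple[str, ...] | None = None
    tie_tol: float = 1e-9

    def prob(self, node: int) -> np.ndarray:
        return self.probs[node]

    def best(self, node: int) -> tuple[int, ...]:
        """Most probable state(s); near-exact ties are reported, not broken."""
        p = self.probs[node]
        return tuple(np.flatnonzero(p >= p.max() - self.tie_tol))

    def to_frame(self) -> pd.DataFrame:
        k = self.probs.shape[1]
        cols = {f"P({self.alphabet[s] if self.alphabet else s})": self.probs[:, s]
                for s in range(k)}
        df = pd.DataFrame(cols)
        df.insert(0, "node", np.arange(self.probs.shape[0]))
        df.insert(1, "is_tip", df["node"] < self.index.n_tips)
        return df


def marginal_ancestral(tree: Chronogram, states: Mapping[str, int],
                       fit: ModelFit | None = None,
                       spec: mk.MkModelSpec | None = None,
                       rates: Sequence[float] | None = None,
                       root_prior=None) -> MarginalReconstruction:
    """Marginal ancestral state probabilities at every node.

    Pass either a :class:`ModelFit` or an explicit ``(spec, rates)`` pair.
    """
    if fit is not None:
        spec, rates = fit.spec, fit.rates
    if spec is None or rates is None:
        raise ValueError("need a ModelFit or spec+rates")
    index = tree.index()
    Q = mk.build_rate_matrix(spec, rates)
    partials = tip_partial_matrix(index, states, spec.k)
    P = branch_matrices(Q, index.edge_len)
    prior = _resolve_root_prior(spec, Q, root_prior)
    lnL, marg = node_marginals(index, P, partials, prior)
    return MarginalReconstruction(index=index, probs=marg, lnL=lnL)


def mrca(tree: Chronogram, taxa: Sequence[str]) -> tuple[int, bool]:
    """MRCA node id of ``taxa`` plus a monophyly flag (true iff the node's
    subtree contains exactly the queried tips)."""
    return tree.index().mrca(taxa)
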