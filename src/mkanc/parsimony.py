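"""Sankoff parsimony: minimum change counts and MPR state sets.

The down-pass computes, for every node and state, the cheapest cost of the
subtree given that state; the up-pass adds the cheapest cost of everything
outside the subtree.  A state belongs to a node's MPR (most parsimonious
reconstruction) set iff down + up equals the global minimum, i.e. some
minimum-length labeling of the whole tree places that state there.  Missing
and inapplicable tips cost zero in every state and so contribute no signal.
Polytomies are handled natively (the Sankoff recursion is a product over any
number of children).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .phylo_io import Chronogram
from .pruning import TreeIndex

__all__ = ["MprResult", "parsimony_score", "mpr_state_sets", "cost_matrix"]

INF = np.inf


def cost_matrix(k: int, costs: str | np.ndarray = "unit") -> np.ndarray:
    """Per-change cost matrix: ``"unit"`` (Fitch) or ``"ordered"`` (|i-j|),
    or an explicit k x k array with zero diagonal."""
    if isinstance(costs, str):
        if costs == "unit":
            return 1.0 - np.eye(k)
        if costs == "ordered":
            idx = np.arange(k)
            return np.abs(idx[:, None] - idx[None, :]).astype(float)
        raise ValueError(f"unknown cost scheme {costs!r}")
    C = np.asarray(costs, dtype=float)
    if C.shape != (k, k) or np.any(np.diag(C) != 0):
        raise ValueError("cost matrix must be k x k with zero diagonal")
    return C


def _down(index: TreeIndex, states: Mapping[str, int], k: int, C: np.ndarray) -> np.ndarray:
    D = np.zeros((index.n_nodes, k))
    any_obs = False
    for label, tid in index.tip_id.items():
        s = states.get(label, -1)
        if s is None or s < 0:
            continue
        any_obs = True
        D[tid] = INF
        D[tid, s] = 0.0
    if not any_obs:
        raise ValueError("all tips missing: parsimony undefined")
    for v in index.postorder:
        acc = np.zeros(k)
        for c in index.children_flat[index.children_ptr[v]:index.children_ptr[v + 1]]:
            acc += np.min(C + D[c][None, :], axis=1)
        D[v] = acc
    return D


def parsimony_score(tree: Chronogram, states: Mapping[str, int],
                    costs: str | np.ndarray = "unit", k: int | None = None) -> float:
    """Minimum total change cost over all internal labelings (tree length).

    Integer-valued for unit costs; returned as float for generality.
    """
    if k is None:
        k = max((s for s in states.values() if s is not None and s >= 0), default=-1) + 1
        if k < 1:
            raise ValueError("all tips missing: parsimony undefined")
        k = max(k, 2)
    C = cost_matrix(k, costs)
    D = _down(tree.index(), states, k, C)
    return float(D[tree.index().root].min())


@dataclass
class MprResult:
    """MPR sets per node plus the parsimony length."""

    length: float
    node_sets: dict[int, frozenset[int]]
    index: TreeIndex

    def equivocal_nodes(self) -> list[int]:
        return [v for v, s in self.node_sets.items() if len(s) > 1]

    def set_string(self, node: int, alphabet=None) -> str:
        states = sorted(self.node_sets[node])
        if alphabet is not None:
            return "|".join(alphabet[s] for s in states)
        return "|".join(str(s) for s in states)


def mpr_state_sets(tree: Chronogram, states: Mapping[str, int],
                   costs: str | np.ndarray = "unit", k: int | None = None) -> MprResult:
    """Full MPR sets by the Sankoff two-pass algorithm.

    ``node_sets[v]`` contains every state that appears at v in at least one
    minimum-cost labeling of the whole tree.
    """
    if k is None:
        k = max((s for s in states.values() if s is not None and s >= 0), default=-1) + 1
        if k < 1:
            raise ValueError("all tips missing: parsimony undefined")
        k = max(k, 2)
    index = tree.index()
    C = cost_matrix(k, costs)
    D = _down(index, states, k, C)
    root = index.root
    # U[v, s]: cheapest cost of the rest of the tree when v is in state s
    U = np.zeros((index.n_nodes, k))
    for v in index.postorder[::-1]:
        lo, hi = index.children_ptr[v], index.children_ptr[v + 1]
        kids = index.children_flat[lo:hi]
        # child messages m_c[s_parent] = min_t C[s_parent, t] + D[c, t]
        msgs = {int(c): np.min(C + D[c][None, :], axis=1) for c in kids}
        total = np.zeros(k)
        for c in kids:
            total += msgs[int(c)]
        for c in kids:
            # parent cost without child c, then push through the edge
            rest = U[v] + total - msgs[int(c)]
            U[c] = np.min(rest[:, None] + C, axis=0)
    best = float((D[root] + U[root]).min())
    sets: dict[int, frozenset[int]] = {}
    tol = 1e-9
    for v in range(index.n_nodes):
        sets[v] = frozenset(int(s) for s in np.flatnonzero(D[v] + U[v] <= best + tol))
    # a missing tip constrains nothing and is compatible with every state
    full = frozenset(range(k))
    for label, tid in index.tip_id.items():
        s = states.get(label, -1)
        if s is None or s < 0:
            sets[tid] = full
    return MprResult(length=best, node_sets=sets, index=index)
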