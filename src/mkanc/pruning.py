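"""Indexed tree arrays and the pruning (peeling) kernels.

Likelihood work never touches the dendropy object model directly: a
:class:`TreeIndex` flattens a chronogram into postorder arrays once, and the
numba-compiled kernels below run over those arrays.  Branch transition
matrices for a whole tree are computed in one shot by eigendecomposition of
the (small) generator, with a scaling-and-squaring fallback when the
eigenvector basis is ill-conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from numba import njit


__all__ = ["TreeIndex", "branch_matrices", "pruning_loglik", "node_marginals"]


@dataclass
class TreeIndex:
    """Flattened rooted tree: tips first, internal nodes in postorder.

    Node ids: tips ``0 .. n_tips-1`` in ``taxon_order``; internal nodes
    ``n_tips .. n_nodes-1`` numbered so that the full postorder is simply
    (tips in any order, then internals ascending).
    """

    n_tips: int
    n_nodes: int
    parent: np.ndarray          # int64, -1 at root
    children_flat: np.ndarray   # int64 csr
    children_ptr: np.ndarray    # int64, len n_nodes+1
    edge_len: np.ndarray        # float64, 0.0 at root
    postorder: np.ndarray       # int64, internal node ids, children-first
    root: int
    taxon_order: tuple[str, ...]
    tip_id: dict[str, int]
    _subtree_tips: np.ndarray | None = field(default=None, repr=False)
    _mrca_cache: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_dendropy(cls, tree, taxon_order=None) -> "TreeIndex":
        leaves = tree.leaf_nodes()
        labels = [lf.taxon.label if lf.taxon is not None else lf.label for lf in leaves]
        if any(lb is None for lb in labels):
            raise ValueError("every tip must be labelled")
        if taxon_order is None:
            taxon_order = tuple(sorted(labels))
        else:
            taxon_order = tuple(taxon_order)
        if set(labels) != set(taxon_order):
            raise ValueError("tree tips do not match the requested taxon order")
        tip_id = {lb: i for i, lb in enumerate(taxon_order)}
        n_tips = len(labels)
        nodes = [nd for nd in tree.postorder_node_iter()]
        n_nodes = len(nodes)
        ids: dict = {}
        next_internal = n_tips
        for nd in nodes:
            if nd.is_leaf():
                lb = nd.taxon.label if nd.taxon is not None else nd.label
                ids[id(nd)] = tip_id[lb]
            else:
                ids[id(nd)] = next_internal
                next_internal += 1
        parent = np.full(n_nodes, -1, dtype=np.int64)
        edge_len = np.zeros(n_nodes, dtype=np.float64)
        kids: list[list[int]] = [[] for _ in range(n_nodes)]
        root = ids[id(tree.seed_node)]
        for nd in nodes:
            me = ids[id(nd)]
            if nd.parent_node is not None:
                pa = ids[id(nd.parent_node)]
                parent[me] = pa
                kids[pa].append(me)
                bl = nd.edge.length
                if bl is None:
                    bl = 0.0
                if bl < 0:
                    raise ValueError(f"negative branch length {bl}")
                edge_len[me] = float(bl)
        children_ptr = np.zeros(n_nodes + 1, dtype=np.int64)
        for v in range(n_nodes):
            children_ptr[v + 1] = children_ptr[v] + len(kids[v])
        children_flat = np.empty(children_ptr[-1], dtype=np.int64)
        for v in range(n_nodes):
            children_flat[children_ptr[v]:children_ptr[v + 1]] = kids[v]
        postorder = np.array(
            [ids[id(nd)] for nd in nodes if not nd.is_leaf()], dtype=np.int64
        )
        return cls(
            n_tips=n_tips, n_nodes=n_nodes, parent=parent,
            children_flat=children_flat, children_ptr=children_ptr,
            edge_len=edge_len, postorder=postorder, root=root,
            taxon_order=taxon_order, tip_id=tip_id,
        )

    # -- clade queries ----------------------------------------------------

    def _tip_counts(self) -> np.ndarray:
        if self._subtree_tips is None:
            counts = np.zeros(self.n_nodes, dtype=np.int64)
            counts[: self.n_tips] = 1
            for v in self.postorder:
                s = 0
                for c in self.children_flat[self.children_ptr[v]:self.children_ptr[v + 1]]:
                    s += counts[c]
                counts[v] = s
            self._subtree_tips = counts
        return self._subtree_tips

    def mrca(self, labels) -> tuple[int, bool]:
        """Most recent common ancestor of ``labels``.

        Returns ``(node id, monophyletic?)`` where the flag is true iff the
        node's subtree contains exactly the queried tips.
        """
        key = frozenset(labels)
        if key in self._mrca_cache:
            return self._mrca_cache[key]
        present = [self.tip_id[lb] for lb in key if lb in self.tip_id]
        if len(present) < 2:
            raise ValueError("need at least two query taxa present in the tree")
        want = np.zeros(self.n_nodes, dtype=np.int64)
        for t in present:
            want[t] = 1
        total = self._tip_counts()
        for v in self.postorder:
            s = 0
            for c in self.children_flat[self.children_ptr[v]:self.children_ptr[v + 1]]:
                s += want[c]
            want[v] = s
            if s == len(present):
                result = (int(v), bool(total[v] == len(present)))
                self._mrca_cache[key] = result
                return result
        raise RuntimeError("unreachable: root contains all tips")

    def tree_length(self) -> float:
        return float(self.edge_len.sum())


# ---------------------------------------------------------------------------
# branch transition matrices


def branch_matrices(Q: np.ndarray, edge_len: np.ndarray) -> np.ndarray:
    """``P[c] = exp(Q * edge_len[c])`` for every node's parent edge.

    Eigendecomposition of Q lets all branches share one spectral factorisation;
    falls back to per-branch scaling-and-squaring (scipy ``expm``) when the
    eigenvector matrix is near-defective.
    """
    k = Q.shape[0]
    try:
        w, U = np.linalg.eig(Q)
        V = np.linalg.inv(U)
        cond = np.linalg.cond(U)
    except np.linalg.LinAlgError:
        cond = np.inf
    if np.isfinite(cond) and cond < 1e8:
        E = np.exp(np.multiply.outer(edge_len, w))          # (n, k)
        P = np.einsum("ij,nj,jk->nik", U, E, V).real
    else:
        P = np.empty((edge_len.shape[0], k, k))
        uniq, inv = np.unique(edge_len, return_inverse=True)
        mats = np.array([scipy.linalg.expm(Q * t) for t in uniq])
        P = mats[inv]
    np.clip(P, 0.0, 1.0, out=P)
    return np.ascontiguousarray(P)


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _down_pass(postorder, children_flat, children_ptr, P, partials, messages):
    """Fill internal partials and per-node up-messages; return log scale.

    ``messages[c, i] = sum_j P[c, i, j] * partials[c, j]`` — the contribution
    of child c's subtree seen from its parent in parent-state i.  Partials are
    rescaled per node to avoid underflow on large trees; the accumulated log
    factors are returned.
    """
    k = partials.shape[1]
    logscale = 0.0
    for n in range(postorder.shape[0]):
        v = postorder[n]
        for i in range(k):
            partials[v, i] = 1.0
        for ci in range(children_ptr[v], children_ptr[v + 1]):
            c = children_flat[ci]
            for i in range(k):
                s = 0.0
                for j in range(k):
                    s += P[c, i, j] * partials[c, j]
                messages[c, i] = s
                partials[v, i] *= s
        mx = partials[v, 0]
        for i in range(1, k):
            if partials[v, i] > mx:
                mx = partials[v, i]
        if mx <= 0.0:
            return -np.inf
        for i in range(k):
            partials[v, i] /= mx
        logscale += np.log(mx)
    return logscale


@njit(cache=True)
def _up_pass(rev_order, children_flat, children_ptr, P, messages, root_prior, root, up):
    """Outside probabilities: ``up[v]`` is the partial likelihood of
    everything outside v's subtree, as a function of v's state (normalized
    per node; only ratios matter for marginals)."""
    k = up.shape[1]
    for i in range(k):
        up[root, i] = root_prior[i]
    for n in range(rev_order.shape[0]):
        v = rev_order[n]
        lo = children_ptr[v]
        hi = children_ptr[v + 1]
        if hi == lo:
            continue
        for ci in range(lo, hi):
            c = children_flat[ci]
            # parent-state weight: up[v] * product of sibling messages
            tot = 0.0
            for j in range(k):
                acc = 0.0
                for i in range(k):
                    w = up[v, i]
                    for si in range(lo, hi):
                        s = children_flat[si]
                        if s != c:
                            w *= messages[s, i]
                    acc += w * P[c, i, j]
                up[c, j] = acc
                tot += acc
            if tot > 0.0:
                for j in range(k):
                    up[c, j] /= tot


def pruning_loglik(index: TreeIndex, P: np.ndarray, tip_partials: np.ndarray,
                   root_prior: np.ndarray) -> float:
    """Log-likelihood of one character on one tree by the pruning algorithm."""
    k = tip_partials.shape[1]
    partials = tip_partials.copy()
    messages = np.empty_like(partials)
    logscale = _down_pass(index.postorder, index.children_flat, index.children_ptr,
                          P, partials, messages)
    if not np.isfinite(logscale):
        return -np.inf
    L = float(np.dot(root_prior, partials[index.root]))
    if L <= 0.0:
        return -np.inf
    return float(np.log(L) + logscale)


def node_marginals(index: TreeIndex, P: np.ndarray, tip_partials: np.ndarray,
                   root_prior: np.ndarray) -> tuple[float, np.ndarray]:
    """Log-likelihood plus per-node marginal state probabilities.

    The marginal at node v is the normalized elementwise product of the
    outside vector and the subtree partial — the standard two-pass
    construction, equivalent to rerooting at each node in turn.
    """
    partials = tip_partials.copy()
    messages = np.empty_like(partials)
    logscale = _down_pass(index.postorder, index.children_flat, index.children_ptr,
                          P, partials, messages)
    L = float(np.dot(root_prior, partials[index.root]))
    lnL = float(np.log(L) + logscale) if (np.isfinite(logscale) and L > 0) else -np.inf
    up = np.zeros_like(partials)
    rev = index.postorder[::-1].copy()
    _up_pass(rev, index.children_flat, index.children_ptr, P, messages,
             np.asarray(root_prior, dtype=np.float64), index.root, up)
    marg = up * partials
    tot = marg.sum(axis=1, keepdims=True)
    tot[tot == 0.0] = 1.0
    return lnL, marg / tot
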