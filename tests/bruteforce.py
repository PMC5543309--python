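"""Independent brute-force oracles for small trees.

Everything here enumerates internal-node labelings explicitly and uses
scipy's matrix exponential per branch — no code shared with the pruning,
marginal or Sankoff implementations it is used to check.
"""

import itertools

import numpy as np
import scipy.linalg


def _edges(index):
    return [(int(index.parent[v]), v) for v in range(index.n_nodes)
            if index.parent[v] >= 0]


def brute_loglik(tree, states, Q, root_prior):
    """Log-likelihood by summation over all internal (and missing-tip)
    state assignments."""
    index = tree.index()
    k = Q.shape[0]
    P = {v: scipy.linalg.expm(Q * index.edge_len[v]) for v in range(index.n_nodes)}
    free = list(index.postorder)  # internal nodes
    tip_state = {}
    for label, tid in index.tip_id.items():
        s = states.get(label, -1)
        if s is None or s < 0:
            free.append(tid)
        else:
            tip_state[tid] = s
    total = 0.0
    for labeling in itertools.product(range(k), repeat=len(free)):
        lab = dict(zip(free, labeling))
        lab.update(tip_state)
        p = root_prior[lab[index.root]]
        for pa, v in _edges(index):
            p *= P[v][lab[pa], lab[v]]
        total += p
    return float(np.log(total))


def brute_marginal(tree, states, Q, root_prior, node):
    """Marginal state posterior at one node by the same enumeration."""
    index = tree.index()
    k = Q.shape[0]
    P = {v: scipy.linalg.expm(Q * index.edge_len[v]) for v in range(index.n_nodes)}
    free = list(index.postorder)
    tip_state = {}
    for label, tid in index.tip_id.items():
        s = states.get(label, -1)
        if s is None or s < 0:
            free.append(tid)
        else:
            tip_state[tid] = s
    mass = np.zeros(k)
    for labeling in itertools.product(range(k), repeat=len(free)):
        lab = dict(zip(free, labeling))
        lab.update(tip_state)
        p = root_prior[lab[index.root]]
        for pa, v in _edges(index):
            p *= P[v][lab[pa], lab[v]]
        mass[lab[node]] += p
    return mass / mass.sum()


def brute_parsimony(tree, states, k, C):
    """(min length, MPR set per node) by exhaustive labeling of internal
    nodes and missing tips."""
    index = tree.index()
    free = list(index.postorder)
    tip_state = {}
    for label, tid in index.tip_id.items():
        s = states.get(label, -1)
        if s is None or s < 0:
            free.append(tid)
        else:
            tip_state[tid] = s
    best = np.inf
    sets = {v: set() for v in range(index.n_nodes)}
    for labeling in itertools.product(range(k), repeat=len(free)):
        lab = dict(zip(free, labeling))
        lab.update(tip_state)
        cost = 0.0
        for pa, v in _edges(index):
            cost += C[lab[pa], lab[v]]
        if cost < best - 1e-12:
            best = cost
            sets = {v: {lab[v]} for v in range(index.n_nodes)}
        elif abs(cost - best) <= 1e-12:
            for v in range(index.n_nodes):
                sets[v].add(lab[v])
    return best, {v: frozenset(s) for v, s in sets.items()}
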