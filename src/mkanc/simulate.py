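"""Synthetic data with the statistical structure the analyses assume.

Yule (pure-birth) chronograms, forward simulation of discrete characters
under arbitrary Mk generators (exact event-time Gillespie sampling, so event
logs are available — e.g. to assert that "nodual" pair models never produce
a dual transition), correlated character pairs on the 4-state joint chain,
haphazard missing/inapplicable masking, and pseudo-posterior tree sets made
by jittering node times and applying a few NNI moves to weakly supported
(short) internal branches.

Everything is driven by an explicit seed or :class:`numpy.random.Generator`
and reproduces bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from . import models as mk
from .phylo_io import INAPPLICABLE, MISSING, CharacterMatrix, Chronogram, TreeSample

__all__ = [
    "SimulationRecord",
    "simulate_yule_tree",
    "simulate_character",
    "simulate_pair",
    "inject_missing",
    "perturb_tree_sample",
    "study_shaped_dataset",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# trees


def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0, seed=0) -> Chronogram:
    """Ultrametric pure-birth tree conditioned on ``n_tips`` extant tips.

    Forward simulation: with ``j`` lineages the next split waits an
    Exp(j * birth_rate) time; after the ``n``-th lineage appears one further
    Exp(n * birth_rate) wait elapses before the present, so the expected root
    age is ``sum_{j=2..n} 1/(j*birth_rate)``.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = _rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    # root splits immediately into two lineages at t=0 (root age measured
    # from the first split)
    active = [tree.seed_node.new_child(), tree.seed_node.new_child()]
    birth_time = {id(nd): 0.0 for nd in active}
    t = 0.0
    j = 2
    while j < n_tips:
        t += rng.exponential(1.0 / (j * birth_rate))
        i = rng.integers(j)
        nd = active[i]
        nd.edge.length = t - birth_time[id(nd)]
        left, right = nd.new_child(), nd.new_child()
        birth_time[id(left)] = birth_time[id(right)] = t
        active[i] = left
        active.append(right)
        j += 1
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    for i, nd in enumerate(active):
        nd.edge.length = t - birth_time[id(nd)]
        nd.taxon = tns.require_taxon(label=f"t{i + 1}")
    tree.seed_node.edge.length = None
    return Chronogram(tree)


# ---------------------------------------------------------------------------
# characters


@dataclass
class SimulationRecord:
    """Everything needed to reproduce and verify one simulated character set."""

    trees: TreeSample
    matrix: CharacterMatrix
    node_states: dict[str, dict[int, int]]       # char -> node id -> true state
    generators: dict[str, np.ndarray]            # char -> Q used
    seed: int | None
    events: dict[str, list[tuple]] = field(default_factory=dict)
    mask: pd.DataFrame | None = None

    def sidecar(self) -> str:
        """JSON sidecar with seed and generating parameters."""
        payload = {
            "seed": self.seed,
            "n_trees": len(self.trees),
            "characters": {
                ch: {"Q": Q.tolist()} for ch, Q in self.generators.items()
            },
        }
        return json.dumps(payload, indent=1)


def _simulate_branch(state: int, t: float, Q: np.ndarray,
                     rng: np.random.Generator, events: list, node_id, t0: float) -> int:
    """Exact CTMC path along one branch; appends (time, from, to, node)."""
    k = Q.shape[0]
    now = 0.0
    while True:
        out = -Q[state, state]
        if out <= 0.0:
            return state
        wait = rng.exponential(1.0 / out)
        if now + wait > t:
            return state
        now += wait
        probs = Q[state].copy()
        probs[state] = 0.0
        probs /= probs.sum()
        new = int(rng.choice(k, p=probs))
        events.append((t0 + now, state, new, node_id))
        state = new


def simulate_character(tree: Chronogram, Q: np.ndarray, root_prior=None,
                       seed=0, record_events: bool = True
                       ) -> tuple[dict[str, int], dict[int, int], list[tuple]]:
    """Forward-simulate one character on a tree.

    Returns ``(tip_states, node_states, events)`` where ``node_states`` maps
    every node id (of ``tree.index()``) to its true state, including the
    root, and ``events`` logs each state change as (time, from, to, node id).
    """
    rng = _rng(seed)
    Q = np.asarray(Q, dtype=float)
    k = Q.shape[0]
    if root_prior is None:
        root_prior = np.full(k, 1.0 / k)
    index = tree.index()
    node_states: dict[int, int] = {}
    events: list[tuple] = []
    root_state = int(rng.choice(k, p=np.asarray(root_prior, dtype=float)))
    # preorder over the flat index: reverse postorder is parents-first
    order = list(index.postorder[::-1]) + [
        v for v in range(index.n_tips)
    ]
    node_states[index.root] = root_state
    # ages for the event log: distance from root
    depth = np.zeros(index.n_nodes)
    for v in index.postorder[::-1]:
        for c in index.children_flat[index.children_ptr[v]:index.children_ptr[v + 1]]:
            depth[c] = depth[v] + index.edge_len[c]
    for v in order:
        if v == index.root:
            continue
        pa = index.parent[v]
        s = _simulate_branch(node_states[pa], index.edge_len[v], Q, rng,
                             events if record_events else [], v,
                             depth[pa])
        node_states[v] = s
    tip_states = {lb: node_states[tid] for lb, tid in index.tip_id.items()}
    return tip_states, node_states, events


def simulate_pair(tree: Chronogram, spec: mk.MkModelSpec,
                  rates: Sequence[float], root_prior=None, seed=0
                  ) -> tuple[pd.DataFrame, dict[int, int], list[tuple]]:
    """Simulate two binary traits jointly on the 4-state combined chain.

    ``spec`` must be a "nodual" pair model (dual transitions forced to
    zero).  Returns a two-column DataFrame (traits ``A``, ``B``; A is the
    high bit of the joint state), the true joint node states, and the event
    log — which by construction contains no dual transition.
    """
    Q = mk.build_rate_matrix(spec, rates)
    for i in range(4):
        for j in range(4):
            if i != j and bin(i ^ j).count("1") == 2 and Q[i, j] != 0:
                raise ValueError("pair spec must exclude dual transitions")
    if root_prior is None and spec.root_prior == "equilibrium":
        root_prior = mk.stationary_distribution(Q)
    tips, nodes, events = simulate_character(tree, Q, root_prior=root_prior, seed=seed)
    df = pd.DataFrame({
        "A": {sp: s >> 1 for sp, s in tips.items()},
        "B": {sp: s & 1 for sp, s in tips.items()},
    })
    return df, nodes, events


# ---------------------------------------------------------------------------
# missingness


def inject_missing(matrix: CharacterMatrix, missing_rate: float,
                   inapplicable_share: float = 0.0, seed=0
                   ) -> tuple[CharacterMatrix, pd.DataFrame]:
    """Mask cells independently at ``missing_rate``; a ``inapplicable_share``
    fraction of masked cells is coded inapplicable instead of missing.

    Returns the masked matrix and the boolean mask that was applied.
    """
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    if not (0.0 <= inapplicable_share <= 1.0):
        raise ValueError("inapplicable_share must be in [0, 1]")
    rng = _rng(seed)
    shape = matrix.data.shape
    mask = rng.random(shape) < missing_rate
    inap = mask & (rng.random(shape) < inapplicable_share)
    data = matrix.data.copy()
    vals = data.to_numpy(dtype=object)
    vals[mask] = MISSING
    vals[inap] = INAPPLICABLE
    out = pd.DataFrame(vals, index=data.index, columns=data.columns)
    mask_df = pd.DataFrame(mask, index=data.index, columns=data.columns)
    return CharacterMatrix(out, matrix.alphabets, matrix.ordered), mask_df


# ---------------------------------------------------------------------------
# pseudo-posterior tree sets


def _node_ages(tree: dendropy.Tree) -> dict:
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    depth = max(lf.root_distance for lf in tree.leaf_node_iter())
    return {nd: depth - nd.root_distance for nd in tree}, depth


def _jitter_ages(tree: dendropy.Tree, sd: float, rng: np.random.Generator) -> None:
    """Multiplicative lognormal jitter of internal node ages, bottom-up so
    parents stay older than children; tips stay at age zero (ultrametric)."""
    ages, _ = _node_ages(tree)
    new_age: dict = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            new_age[nd] = 0.0
            continue
        child_max_new = max(new_age[c] for c in nd.child_nodes())
        child_max_old = max(ages[c] for c in nd.child_nodes())
        gap = max(ages[nd] - child_max_old, 0.0)
        new_age[nd] = child_max_new + gap * float(np.exp(rng.normal(0.0, sd)))
    for nd in tree.postorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = new_age[nd.parent_node] - new_age[nd]


def _random_nni(tree: dendropy.Tree, rng: np.random.Generator) -> bool:
    """One age-respecting NNI on a randomly chosen short internal edge.

    Swaps a child subtree of an internal node with one of that node's
    siblings, preferring short edges (weakly supported splits); branch
    lengths are recomputed from node ages so the tree stays ultrametric.
    Returns False if no valid move exists.
    """
    ages, _ = _node_ages(tree)
    candidates = []
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        pa = nd.parent_node
        for sib in pa.child_nodes():
            if sib is nd:
                continue
            for child in nd.child_nodes():
                # swapping `child` (under nd) with `sib` (under pa) is valid
                # iff nd is older than sib's subtree root
                if ages[nd] > ages[sib]:
                    w = 1.0 / (1e-9 + (nd.edge.length or 0.0))
                    candidates.append((nd, pa, child, sib, w))
    if not candidates:
        return False
    weights = np.array([c[-1] for c in candidates])
    weights /= weights.sum()
    nd, pa, child, sib, _ = candidates[rng.choice(len(candidates), p=weights)]
    nd.remove_child(child)
    pa.remove_child(sib)
    nd.add_child(sib)
    pa.add_child(child)
    sib.edge.length = ages[nd] - ages[sib]
    child.edge.length = ages[pa] - ages[child]
    return True


def perturb_tree_sample(base: Chronogram, n_trees: int, time_jitter: float = 0.05,
                        topo_moves: int = 0, seed=0, label: str = "pseudo-posterior"
                        ) -> TreeSample:
    """Pseudo-posterior sample: copies of ``base`` with jittered node times
    and up to ``topo_moves`` NNI rearrangements each."""
    if n_trees < 1:
        raise ValueError("need at least one tree")
    rng = _rng(seed)
    out = []
    for _ in range(n_trees):
        clone = Chronogram(base.tree.clone(depth=1))
        if topo_moves > 0:
            for _ in range(topo_moves):
                _random_nni(clone.tree, rng)
        if time_jitter > 0:
            _jitter_ages(clone.tree, time_jitter, rng)
        out.append(clone)
    return TreeSample(out, label=label)


# ---------------------------------------------------------------------------
# the benchmark generator


def study_shaped_dataset(n_species: int = 792, n_chars: int = 27,
                         missing_rate: float = 0.27,
                         inapplicable_share: float = 0.3,
                         n_trees: int = 0, seed: int = 0) -> SimulationRecord:
    """A study-shaped synthetic benchmark: one Yule chronogram, a mixed-arity
    character matrix (binary, unordered 3-state, ordered count-derived
    4-state) with haphazard missing/inapplicable cells, and optionally a
    pseudo-posterior tree set.

    Defaults mirror the dimensions the pipeline is meant to carry (792
    species, 27 characters, 27% no-signal cells); smaller values give desk-
    scale replicas of identical structure.
    """
    rng = _rng(seed)
    tree = simulate_yule_tree(n_species, 1.0, rng)
    depth = tree.depth()
    cols: dict[str, dict[str, str]] = {}
    gens: dict[str, np.ndarray] = {}
    node_states: dict[str, dict[int, int]] = {}
    ordered = []
    for i in range(n_chars):
        kind = i % 3
        name = f"c{i + 1:02d}"
        # a few expected changes across the tree regardless of its depth
        scale = rng.uniform(2.0, 8.0) / depth
        if kind == 0:
            spec = mk.mk_model("ARD", 2)
            rates = rng.uniform(0.3, 1.5, size=spec.n_free) * scale
        elif kind == 1:
            spec = mk.mk_model("SYM", 3)
            rates = rng.uniform(0.3, 1.5, size=spec.n_free) * scale
        else:
            spec = mk.mk_model("ORD", 4)
            rates = rng.uniform(0.3, 1.5, size=spec.n_free) * scale
            ordered.append(name)
        Q = mk.build_rate_matrix(spec, rates)
        tips, nodes, _ = simulate_character(tree, Q, seed=rng, record_events=False)
        cols[name] = {sp: str(s) for sp, s in tips.items()}
        gens[name] = Q
        node_states[name] = nodes
    df = pd.DataFrame(cols).loc[sorted(cols[next(iter(cols))])]
    matrix = CharacterMatrix(df, ordered=ordered)
    masked, mask = inject_missing(matrix, missing_rate, inapplicable_share, rng)
    if n_trees > 0:
        trees = perturb_tree_sample(tree, n_trees, time_jitter=0.05,
                                    topo_moves=2, seed=rng)
    else:
        trees = TreeSample([tree], label="base")
    return SimulationRecord(trees=trees, matrix=masked, node_states=node_states,
                            generators=gens, seed=seed if isinstance(seed, int) else None,
                            mask=mask)
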