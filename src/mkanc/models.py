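"""Mk-family models of discrete character evolution.

A model here is a constraint pattern over the ordered state pairs ``(i, j)``,
``i != j``, of a continuous-time Markov chain on ``k`` character states:
pairs may share a transition rate (an equality class) or be forced to zero.
The zoo covers the standard named variants used for morphological characters:

* ``ER`` — equal rates (the Mk model proper), one free rate;
* ``SYM`` — symmetric rates, one rate per unordered pair;
* ``ARD`` — all rates different;
* ``ORD`` / ``ORDSYM`` / ``ORDER`` — ordered characters, transitions only
  between adjacent states (all-different / symmetric / single-rate);
* ``UNI01`` / ``UNI10`` — unidirectional binary models (the reverse rate is
  zero, the root state is implied by the model);
* ``*nodual`` — combined two-trait models on the four joint states
  ``00, 01, 10, 11`` with simultaneous ("dual") changes of both traits
  forbidden, used in pairwise correlated-evolution tests.

An ``eq`` suffix on a name selects the equilibrium (stationary) root prior
instead of the flat one; it changes nothing else.

The module also enumerates the reversible-jump model space: a model is a set
partition of the free transition parameters into unlabeled rate classes, plus
a distinguished zero class holding any (possibly empty) subset of parameters;
the all-zero model is excluded.  Under this convention the space for the
8-parameter combined two-binary-trait model has 21,146 members, of which 51
are independent (uncorrelated) models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np
import scipy.linalg


__all__ = [
    "MkModelSpec",
    "ModelSpaceInfo",
    "mk_model",
    "build_rate_matrix",
    "stationary_distribution",
    "transition_probability",
    "enumerate_rate_class_models",
    "build_pair_model",
    "pair_model_space",
    "is_independent_assignment",
    "PAIR_STATE_LABELS",
    "PAIR_FREE_PAIRS",
    "PAIR_PARAM_LABELS",
    "PAIR_MODEL_NAMES",
]


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class MkModelSpec:
    """Constraint pattern defining a named Mk-family model.

    Parameters
    ----------
    name:
        Zoo name, e.g. ``"ARDeq"`` or ``"SYMnodual"``.
    k:
        Number of character states.
    pattern:
        Mapping ``(i, j) -> class`` over every ordered pair ``i != j``;
        ``-1`` marks a forced-zero transition, nonnegative integers index
        equality classes ``0 .. K-1``.
    root_prior:
        ``"flat"``, ``"equilibrium"`` or ``"implied"`` (unidirectional
        models: point mass on the source state).
    source_state:
        Only for ``root_prior == "implied"``.
    """

    name: str
    k: int
    pattern: Mapping[tuple[int, int], int]
    root_prior: str = "flat"
    source_state: int | None = None

    def __post_init__(self) -> None:
        pairs = {(i, j) for i in range(self.k) for j in range(self.k) if i != j}
        if set(self.pattern) != pairs:
            raise ValueError(f"{self.name}: pattern must cover every ordered pair exactly once")
        classes = sorted({c for c in self.pattern.values() if c >= 0})
        if not classes:
            raise ValueError(f"{self.name}: all rates forced to zero")
        if classes != list(range(len(classes))):
            raise ValueError(f"{self.name}: class labels must be 0..K-1")
        if self.root_prior not in ("flat", "equilibrium", "implied"):
            raise ValueError(f"unknown root prior mode {self.root_prior!r}")

    @property
    def n_free(self) -> int:
        """K, the number of free rate parameters (equality classes)."""
        return 1 + max(c for c in self.pattern.values() if c >= 0)

    @property
    def free_pairs(self) -> list[tuple[int, int]]:
        """Ordered pairs not forced to zero, sorted."""
        return sorted(p for p, c in self.pattern.items() if c >= 0)


def _pairs(k: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(k) for j in range(k) if i != j]


def _spec_er(k: int) -> dict:
    return {p: 0 for p in _pairs(k)}


def _spec_sym(k: int) -> dict:
    classes: dict[tuple[int, int], int] = {}
    label = {}
    for i, j in _pairs(k):
        key = (min(i, j), max(i, j))
        if key not in label:
            label[key] = len(label)
        classes[(i, j)] = label[key]
    return classes


def _spec_ard(k: int) -> dict:
    return {p: n for n, p in enumerate(_pairs(k))}


def _spec_ord(k: int) -> dict:
    classes = {}
    n = 0
    for i, j in _pairs(k):
        if abs(i - j) == 1:
            classes[(i, j)] = n
            n += 1
        else:
            classes[(i, j)] = -1
    return classes


def _spec_ordsym(k: int) -> dict:
    classes = {}
    label = {}
    for i, j in _pairs(k):
        if abs(i - j) == 1:
            key = (min(i, j), max(i, j))
            if key not in label:
                label[key] = len(label)
            classes[(i, j)] = label[key]
        else:
            classes[(i, j)] = -1
    return classes


def _spec_order(k: int) -> dict:
    return {p: (0 if abs(p[0] - p[1]) == 1 else -1) for p in _pairs(k)}


_BASE_BUILDERS: dict[str, Callable[[int], dict]] = {
    "ER": _spec_er,
    "SYM": _spec_sym,
    "ARD": _spec_ard,
    "ORD": _spec_ord,
    "ORDSYM": _spec_ordsym,
    "ORDER": _spec_order,
}


def mk_model(name: str, k: int) -> MkModelSpec:
    """Build a named single-character model for ``k`` states.

    ``UNI01``/``UNI10`` are binary only and carry the implied (point-mass)
    root prior; the ``eq`` suffix requests the equilibrium root prior and is
    rejected for ``ER`` (equilibrium equals flat) and the unidirectional
    models (root state implied).
    """
    if name.endswith("nodual"):
        raise ValueError("combined two-trait models are built with build_pair_model()")
    if name in ("UNI01", "UNI10"):
        if k != 2:
            raise ValueError(f"{name} is defined for binary characters only")
        if name == "UNI01":
            # rate 1->0 set to zero: only gains, source state 0
            pattern = {(0, 1): 0, (1, 0): -1}
            src = 0
        else:
            pattern = {(0, 1): -1, (1, 0): 0}
            src = 1
        return MkModelSpec(name, 2, pattern, root_prior="implied", source_state=src)
    root = "flat"
    base = name
    if name.endswith("eq"):
        base = name[:-2]
        if base == "ER":
            raise ValueError("ER: equilibrium root prior equals the flat prior; use 'ER'")
        root = "equilibrium"
    if base not in _BASE_BUILDERS:
        raise ValueError(f"unknown model name {name!r}")
    if k < 2:
        raise ValueError("k must be >= 2")
    if base.startswith("ORD") and k < 3 and base != "ORDER":
        # with two states ORD degenerates to ARD / SYM; allowed but pointless
        pass
    return MkModelSpec(name, k, _BASE_BUILDERS[base](k), root_prior=root)


# ---------------------------------------------------------------------------
# rate matrices


def build_rate_matrix(spec: MkModelSpec, rates: Sequence[float]) -> np.ndarray:
    """Generator matrix Q for ``spec`` with one rate per equality class.

    Off-diagonal entries are the class rates (zero for forced-zero pairs);
    the diagonal is minus the row sum, so rows sum to zero.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (spec.n_free,):
        raise ValueError(f"{spec.name}: expected {spec.n_free} rates, got {rates.shape}")
    if np.any(rates < 0):
        raise ValueError("transition rates must be nonnegative")
    Q = np.zeros((spec.k, spec.k))
    for (i, j), c in spec.pattern.items():
        if c >= 0:
            Q[i, j] = rates[c]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary (limiting) distribution pi with ``pi Q = 0``.

    For an irreducible chain this is the unique null vector of ``Q^T``.  For
    reducible chains (e.g. unidirectional models) the stationary distribution
    is not unique; we return the limiting distribution reached from a uniform
    start, i.e. the mass ends up on the absorbing class.
    """
    Q = np.asarray(Q, dtype=float)
    k = Q.shape[0]
    ns = scipy.linalg.null_space(Q.T)
    if ns.shape[1] == 1:
        pi = ns[:, 0]
        if pi.sum() < 0:
            pi = -pi
        if np.all(pi >= -1e-12):
            pi = np.clip(pi, 0.0, None)
            return pi / pi.sum()
    # reducible or numerically awkward: take the long-time limit from uniform
    scale = max(np.abs(Q).max(), 1e-12)
    P = scipy.linalg.expm(Q * (1e7 / scale))
    pi = P.mean(axis=0)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def transition_probability(Q: np.ndarray, t: float) -> np.ndarray:
    """Transition probability matrix ``P(t) = exp(Q t)`` for branch time t."""
    if t < 0:
        raise ValueError("branch time must be nonnegative")
    P = scipy.linalg.expm(np.asarray(Q, dtype=float) * t)
    P = np.clip(P, 0.0, 1.0)
    return P


# ---------------------------------------------------------------------------
# reversible-jump model space


def _rate_class_assignments(n: int, include_zero: bool) -> Iterator[tuple[int, ...]]:
    # Restricted-growth strings with an extra symbol -1 for the distinguished
    # zero class; canonical labels (first occurrence order) make the classes
    # unlabeled. The all-zero string is excluded.
    a = [0] * n

    def rec(i: int, used: int) -> Iterator[tuple[int, ...]]:
        if i == n:
            yield tuple(a)
            return
        for lab in range(used + 1):
            a[i] = lab
            yield from rec(i + 1, used + (1 if lab == used else 0))
        if include_zero:
            a[i] = -1
            yield from rec(i + 1, used)

    for assignment in rec(0, 0):
        if any(x >= 0 for x in assignment):
            yield assignment


@dataclass
class ModelSpaceInfo:
    """Summary of an enumerated rate-class model space."""

    n_params: int
    n_models: int
    include_zero_class: bool = True
    n_independent: int | None = None
    n_dependent: int | None = None
    models: list[tuple[int, ...]] | None = field(default=None, repr=False)

    def iter_models(self) -> Iterator[tuple[int, ...]]:
        if self.models is not None:
            return iter(self.models)
        return _rate_class_assignments(self.n_params, self.include_zero_class)


def enumerate_rate_class_models(
    n_params: int, include_zero_class: bool = True, store: bool | None = None
) -> ModelSpaceInfo:
    """Enumerate rate-class partition models over ``n_params`` parameters.

    A model assigns each parameter to an unlabeled positive-rate class or to
    the distinguished zero class; the model with every parameter at zero is
    excluded.  The count equals ``Bell(n+1) - 1`` when the zero class is
    allowed, and ``Bell(n)`` otherwise, but is obtained here by explicit
    enumeration.
    """
    if n_params < 1:
        raise ValueError("n_params must be >= 1")
    if store is None:
        store = n_params <= 8
    if store:
        models = list(_rate_class_assignments(n_params, include_zero_class))
        return ModelSpaceInfo(n_params, len(models), include_zero_class, models=models)
    count = sum(1 for _ in _rate_class_assignments(n_params, include_zero_class))
    return ModelSpaceInfo(n_params, count, include_zero_class)


# ---------------------------------------------------------------------------
# combined two-trait ("nodual") models

#: Joint states in fixed order, trait A the high bit.
PAIR_STATE_LABELS: tuple[str, ...] = ("00", "01", "10", "11")

#: The 8 allowed single-trait transitions among the joint states, in the
#: canonical parameter order used everywhere (rjMCMC assignments, tables).
PAIR_FREE_PAIRS: tuple[tuple[int, int], ...] = (
    (0, 2),  # A gain while B=0
    (1, 3),  # A gain while B=1
    (2, 0),  # A loss while B=0
    (3, 1),  # A loss while B=1
    (0, 1),  # B gain while A=0
    (2, 3),  # B gain while A=1
    (1, 0),  # B loss while A=0
    (3, 2),  # B loss while A=1
)

PAIR_PARAM_LABELS: tuple[str, ...] = (
    "qA01|B0", "qA01|B1", "qA10|B0", "qA10|B1",
    "qB01|A0", "qB01|A1", "qB10|A0", "qB10|A1",
)

# Parameter index pairs that must share a class for the model to be
# independent: each trait's rate must not depend on the other trait's state.
_INDEP_MERGE = ((0, 1), (2, 3), (4, 5), (6, 7))

PAIR_MODEL_NAMES: tuple[str, ...] = (
    "ARDnodual", "ARDnodualeq", "SYMnodual", "SYMnodualeq",
    "ERnodual", "UNCORRnodual", "UNCORRnodualeq",
)

#: The four correlated (dependent) members of the seven-model ML set.
CORRELATED_PAIR_MODELS: tuple[str, ...] = (
    "ARDnodual", "ARDnodualeq", "SYMnodual", "SYMnodualeq",
)


def _pair_assignment(base: str) -> tuple[int, ...]:
    if base == "ARD":
        return tuple(range(8))
    if base == "SYM":
        # forward/backward equality for each of the four allowed edges
        # edges: 00<->10, 01<->11, 00<->01, 10<->11
        return (0, 1, 0, 1, 2, 3, 2, 3)
    if base == "ER":
        return (0,) * 8
    if base == "UNCORR":
        # one rate per trait per direction, shared across the other trait
        return (0, 0, 1, 1, 2, 2, 3, 3)
    raise ValueError(base)


def build_pair_model(name: str) -> MkModelSpec:
    """Combined two-binary-trait model on states ``00, 01, 10, 11``.

    Dual transitions (both traits changing at once) are forced to zero, so 8
    ordered transitions remain.  Trait A is the high bit of the joint state.
    """
    if name not in PAIR_MODEL_NAMES:
        raise ValueError(f"unknown pair model {name!r}")
    root = "flat"
    base = name
    if base.endswith("eq"):
        base = base[:-2]
        root = "equilibrium"
    base = base[: -len("nodual")]
    assignment = _pair_assignment(base)
    pattern: dict[tuple[int, int], int] = {}
    for idx, pair in enumerate(PAIR_FREE_PAIRS):
        pattern[pair] = assignment[idx]
    for i in range(4):
        for j in range(4):
            if i != j and (i, j) not in pattern:
                pattern[(i, j)] = -1  # dual transition
    # relabel classes canonically (first occurrence over sorted pairs order
    # is irrelevant for identity; keep assignment labels, already canonical)
    return MkModelSpec(name, 4, pattern, root_prior=root)


def is_independent_assignment(assignment: Sequence[int]) -> bool:
    """True if a rate-class assignment over the 8 combined-model parameters
    describes independent evolution of the two traits.

    Independence holds exactly when each trait's transition rates do not
    depend on the other trait's state, i.e. when the two context-specific
    copies of every trait transition share a class (or are both zero).
    """
    a = tuple(assignment)
    if len(a) != 8:
        raise ValueError("expected an assignment over 8 parameters")
    return all(a[i] == a[j] for i, j in _INDEP_MERGE)


def is_independent_pair_spec(spec: MkModelSpec) -> bool:
    """Independence classification of a named combined model."""
    assignment = tuple(spec.pattern[p] for p in PAIR_FREE_PAIRS)
    return is_independent_assignment(assignment)


def pair_model_space() -> ModelSpaceInfo:
    """The full reversible-jump space of combined two-binary-trait models,
    with each member classified as dependent or independent."""
    info = enumerate_rate_class_models(8, include_zero_class=True, store=True)
    n_indep = sum(1 for m in info.models if is_independent_assignment(m))
    info.n_independent = n_indep
    info.n_dependent = info.n_models - n_indep
    return info
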