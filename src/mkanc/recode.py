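"""Recoding primary characters into analysis characters.

Count-derived characters are discretized into ordered bins; multistate
characters are binarized for the correlation analyses by keeping the
hypothesized-ancestral state set as state 0 and pooling everything else as
state 1 (so "was the ancestral condition retained?" is always a state-0
question); redundant alternative codings of the same character are reduced
to one representative.  All recoding is deterministic, idempotent on
already-binary characters, and never changes which species carry data.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence
import warnings

import pandas as pd

from .phylo_io import INAPPLICABLE, MISSING, CharacterMatrix

__all__ = [
    "RecodingRule",
    "binarize_multistate",
    "discretize_count",
    "build_binary_set",
    "n_pairs",
]


@dataclass
class RecodingRule:
    """One declarative recoding step.

    kind: ``binarize_pool`` (params: ``retained`` state set),
    ``ordered_bins`` (params: ``edges``, ascending lower bounds),
    ``state_merge`` (params: ``merge`` map old->new) or ``drop``.
    """

    source: str
    kind: str
    params: dict = field(default_factory=dict)
    name: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("binarize_pool", "ordered_bins", "state_merge", "drop"):
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.kind == "ordered_bins":
            edges = list(self.params.get("edges", []))
            if edges != sorted(set(edges)):
                raise ValueError("bin edges must be strictly increasing")


def binarize_multistate(column: pd.Series, retained_states: Iterable[str],
                        alphabet: Sequence[str]) -> pd.Series:
    """Pool states: retained set -> ``"0"``, all other states -> ``"1"``.

    Missing and inapplicable cells pass through unchanged.
    """
    retained = {str(s) for s in retained_states}
    alpha = {str(s) for s in alphabet}
    if not retained:
        raise ValueError("retained state set must be nonempty")
    if not retained < alpha:
        raise ValueError("retained states must be a proper subset of the alphabet")

    def recode(v):
        if v in (MISSING, INAPPLICABLE):
            return v
        return "0" if v in retained else "1"

    return column.map(recode)


def discretize_count(raw: pd.Series, edges: Sequence[float]) -> pd.Series:
    """Bin integer counts into an ordered multistate character.

    ``edges`` are ascending bin lower bounds; bin i is the half-open
    interval ``[edges[i], edges[i+1])`` and the last bin is open-ended.
    Counts below the first edge have no bin and raise.  Missing /
    inapplicable cells pass through.  Higher counts never map to lower
    states (rank preservation).
    """
    edges = list(edges)
    if edges != sorted(set(edges)):
        raise ValueError("bin edges must be strictly increasing")

    def bin_of(v):
        if v in (MISSING, INAPPLICABLE):
            return v
        x = float(v)
        if x < edges[0]:
            raise ValueError(f"count {v} below the first bin edge {edges[0]}")
        return str(bisect_right(edges, x) - 1)

    out = raw.map(bin_of)
    observed = {v for v in out.unique() if v not in (MISSING, INAPPLICABLE)}
    if len(observed) == 1:
        warnings.warn("discretization produced a constant character")
    return out


def n_pairs(n: int) -> int:
    return n * (n - 1) // 2


def build_binary_set(matrix: CharacterMatrix,
                     rules: Sequence[RecodingRule] = (),
                     ancestral_hints: Mapping[str, Iterable[str]] | None = None,
                     redundancy_groups: Sequence[Sequence[str]] = (),
                     ) -> tuple[CharacterMatrix, int, list[str]]:
    """Reduce a matrix to presumably independent binary characters.

    Characters already binary are kept as-is; multistate characters with a
    ``binarize_pool`` rule or an ``ancestral_hints`` entry are pooled; each
    redundancy group (alternative codings of the same character) keeps only
    its first member.  Returns the binary matrix, the number of unordered
    pairwise combinations n(n-1)/2, and a provenance log.
    """
    ancestral_hints = dict(ancestral_hints or {})
    log: list[str] = []
    known = set(matrix.characters)
    for rule in rules:
        if rule.source not in known:
            raise ValueError(f"rule references unknown character {rule.source!r}")
    rule_by_char = {r.source: r for r in rules}
    drop: set[str] = set()
    for group in redundancy_groups:
        missing = [c for c in group if c not in known]
        if missing:
            raise ValueError(f"redundancy group references unknown characters {missing}")
        keep, *rest = group
        drop.update(rest)
        if rest:
            log.append(f"redundancy group {list(group)}: kept {keep!r}")
    cols = {}
    for ch in matrix.characters:
        if ch in drop:
            continue
        rule = rule_by_char.get(ch)
        if rule is not None and rule.kind == "drop":
            log.append(f"{ch}: dropped by rule")
            continue
        col = matrix.column(ch)
        alpha = matrix.alphabet(ch)
        if len(alpha) <= 2:
            cols[ch] = col
            continue
        if rule is not None and rule.kind == "binarize_pool":
            retained = rule.params["retained"]
        elif ch in ancestral_hints:
            retained = ancestral_hints[ch]
        else:
            raise ValueError(
                f"multistate character {ch!r} has no retained-state hint or rule")
        cols[ch] = binarize_multistate(col, retained, alpha)
        log.append(f"{ch}: pooled {sorted(map(str, retained))} as state 0")
    out = CharacterMatrix(pd.DataFrame(cols, index=matrix.data.index))
    return out, n_pairs(len(out.characters)), log
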