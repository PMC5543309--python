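"""Cross-method confidence scores and summary grids.

Each trait x focal-node cell compares the three reconstruction methods —
the parsimony MPR set, the ML best state and the rjMCMC modal state — and
grades the agreement on a 0-3 star scale using the lower bound of the
rjMCMC credibility interval:

* 3 stars: all three name the same single state and the CI lower bound is
  at least ``t_hi``;
* 2 stars: same agreement, CI lower bound at least ``t_mid``;
* 1 star: the single-state answers agree but the CI is weak, or exactly
  one method is soft (parsimony equivocal / an ML tie) while still
  containing the agreed state;
* 0 stars: any two single-state answers conflict, or broader disagreement.

Thresholds default to 0.75 / 0.5 and are configuration, not constants of
nature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = ["ConfidenceCell", "confidence_score", "summarize"]


@dataclass
class ConfidenceCell:
    trait: str
    node: str
    mp_set: frozenset
    ml_best: tuple          # one state, or several on a near-exact tie
    rj_modal: object
    rj_mean: float
    rj_ci_lower: float
    series: str = ""
    stars: int | None = None
    incomplete: bool = False


def confidence_score(mp_set: Iterable, ml_best, rj_modal,
                     rj_ci_lower: float, t_hi: float = 0.75,
                     t_mid: float = 0.5) -> int:
    """Stars 0-3 for one trait-node cell; see module docstring for the rule.

    ``ml_best`` may be a single state or a tuple of tied states.
    """
    mp = frozenset(mp_set)
    ml = tuple(ml_best) if isinstance(ml_best, (tuple, list, set, frozenset)) else (ml_best,)
    s = rj_modal
    # hard conflicts: any method committing to a different single state
    if len(ml) == 1 and ml[0] != s:
        return 0
    if len(mp) == 1 and next(iter(mp)) != s:
        return 0
    soft = 0
    if len(mp) != 1:
        if s not in mp:
            return 0
        soft += 1
    if len(ml) != 1:
        if s not in ml:
            return 0
        soft += 1
    if soft > 1:
        return 0
    if soft == 1:
        return 1
    # full three-way agreement on a single state
    if rj_ci_lower >= t_hi:
        return 3
    if rj_ci_lower >= t_mid:
        return 2
    return 1


def summarize(cells: Sequence[ConfidenceCell], t_hi: float = 0.75,
              t_mid: float = 0.5) -> dict[str, pd.DataFrame]:
    """Score cells and pivot into one trait x node grid per tree series.

    Incomplete cells (a method result missing) are flagged ``NA`` rather
    than scored.  Reordering traits or nodes permutes the grid without
    changing cell values.
    """
    scored = []
    for c in cells:
        if c.incomplete:
            c.stars = None
        else:
            c.stars = confidence_score(c.mp_set, c.ml_best, c.rj_modal,
                                       c.rj_ci_lower, t_hi=t_hi, t_mid=t_mid)
        scored.append(c)
    df = pd.DataFrame([{
        "series": c.series, "trait": c.trait, "node": c.node, "stars": c.stars,
    } for c in scored])
    grids = {}
    for series, block in df.groupby("series", sort=True):
        grids[series] = block.pivot(index="node", columns="trait", values="stars")
    return grids
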