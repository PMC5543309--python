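"""Trees, tree samples and character matrices: reading, validation, alignment.

Chronograms (trees with branch lengths in time units) are parsed with
dendropy from Newick or NEXUS; character matrices come from delimited text
(first column = species, header row = character names) or a NEXUS CHARACTERS
block.  Missing (``?``) and inapplicable (``-``) entries are stored
distinctly — both carry no signal downstream, but the two fractions are
reported separately, mirroring how morphological matrices are curated.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .pruning import TreeIndex

__all__ = [
    "Chronogram",
    "TreeSample",
    "CharacterMatrix",
    "UltrametryReport",
    "read_trees",
    "read_matrix",
    "check_ultrametric",
    "align_taxa",
    "MISSING",
    "INAPPLICABLE",
]

#: Canonical internal codes. User-facing codes are mapped onto these at read
#: time and back at write time.
MISSING = "?"
INAPPLICABLE = "-"


class Chronogram:
    """A rooted time-calibrated tree (branch lengths = time, arbitrary units).

    Thin wrapper over a dendropy :class:`~dendropy.Tree` adding validation,
    cached flat indexes for the likelihood/parsimony kernels, and small
    conveniences.  Polytomies are allowed and treated as hard.
    """

    def __init__(self, tree: dendropy.Tree):
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError(f"negative branch length {edge.length}")
        self.tree = tree
        self._indexes: dict[tuple[str, ...], TreeIndex] = {}

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Chronogram":
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True)
        return cls(tree)

    # -- basic queries ----------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    @property
    def n_internal(self) -> int:
        return sum(1 for nd in self.tree if not nd.is_leaf())

    def root_to_tip_depths(self) -> dict[str, float]:
        depths: dict[str, float] = {}
        self.tree.calc_node_root_distances(return_leaf_distances_only=False)
        for lf in self.tree.leaf_node_iter():
            depths[lf.taxon.label] = lf.root_distance
        return depths

    def depth(self) -> float:
        """Maximum root-to-tip path length (the tree's age for an
        ultrametric tree)."""
        return max(self.root_to_tip_depths().values())

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def index(self, taxon_order: Sequence[str] | None = None) -> TreeIndex:
        """Flat postorder index, cached per taxon order."""
        key = tuple(taxon_order) if taxon_order is not None else tuple(sorted(self.tip_labels))
        if key not in self._indexes:
            self._indexes[key] = TreeIndex.from_dendropy(self.tree, key)
        return self._indexes[key]

    def pruned_to(self, labels: Iterable[str]) -> "Chronogram":
        """Copy of the tree restricted to ``labels``; path lengths between
        retained tips are preserved (unifurcations are merged)."""
        keep = set(labels)
        clone = self.tree.clone(depth=1)
        clone.retain_taxa_with_labels(sorted(keep))
        clone.purge_taxon_namespace()
        return Chronogram(clone)


@dataclass
class TreeSample:
    """Ordered collection of chronograms, e.g. a posterior sample."""

    trees: list[Chronogram]
    label: str = ""

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i):
        return self.trees[i]

    @property
    def tip_labels(self) -> set[str]:
        return set(self.trees[0].tip_labels)

    def check_consistent(self) -> None:
        ref = self.tip_labels
        for i, t in enumerate(self.trees):
            if set(t.tip_labels) != ref:
                raise ValueError(f"tree {i} has a different tip set")


def read_trees(source: str, schema: str = "newick", label: str = "") -> TreeSample:
    """Read one or more trees from a file path or raw tree text.

    NEXUS translate tables are honoured by the parser.  Negative branch
    lengths are rejected; malformed input raises the parser's error, which
    names the offending position.
    """
    kwargs = dict(schema=schema, preserve_underscores=True)
    if "\n" in source or source.strip().startswith(("(", "#")):
        trees = dendropy.TreeList.get(data=source, **kwargs)
    else:
        trees = dendropy.TreeList.get(path=source, **kwargs)
    if len(trees) == 0:
        raise ValueError("no trees found in input")
    return TreeSample([Chronogram(t) for t in trees], label=label)


@dataclass
class UltrametryReport:
    max_deviation: float
    passed: bool
    depth: float


def check_ultrametric(tree: Chronogram, rel_tol: float = 1e-6) -> UltrametryReport:
    """Relative spread of root-to-tip path lengths.

    deviation = (max - min) / max; the check warns rather than fails because
    posterior tree samples routinely carry rounding noise.
    """
    depths = list(tree.root_to_tip_depths().values())
    if len(depths) < 2:
        raise ValueError("ultrametricity needs at least two tips")
    hi, lo = max(depths), min(depths)
    dev = 0.0 if hi == 0 else (hi - lo) / hi
    ok = dev <= rel_tol
    if not ok:
        warnings.warn(f"tree is not ultrametric: relative deviation {dev:.3g}")
    return UltrametryReport(max_deviation=dev, passed=ok, depth=hi)


class CharacterMatrix:
    """Species x character matrix of discrete states.

    Cells hold state symbols (strings), or the canonical missing /
    inapplicable codes.  Each character has a declared finite alphabet and an
    optional "ordered" flag (count-derived characters, eligible for the
    ordered model variants).
    """

    def __init__(self, data: pd.DataFrame,
                 alphabets: Mapping[str, Sequence[str]] | None = None,
                 ordered: Iterable[str] = ()):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate species rows: {dups}")
        self.data = data.astype(str)
        self.ordered = set(ordered)
        self.alphabets: dict[str, tuple[str, ...]] = {}
        for ch in self.data.columns:
            observed = sorted(
                v for v in self.data[ch].unique() if v not in (MISSING, INAPPLICABLE)
            )
            if alphabets is not None and ch in alphabets:
                alpha = tuple(str(s) for s in alphabets[ch])
                bad = set(observed) - set(alpha)
                if bad:
                    raise ValueError(f"character {ch!r}: values {sorted(bad)} outside alphabet")
            else:
                alpha = tuple(observed)
            self.alphabets[ch] = alpha

    # -- queries ----------------------------------------------------------

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def characters(self) -> list[str]:
        return list(self.data.columns)

    def alphabet(self, char: str) -> tuple[str, ...]:
        return self.alphabets[char]

    def n_states(self, char: str) -> int:
        return len(self.alphabets[char])

    def is_ordered(self, char: str) -> bool:
        return char in self.ordered

    def column(self, char: str) -> pd.Series:
        return self.data[char]

    def encoded(self, char: str) -> pd.Series:
        """Integer-coded column: state index in the alphabet, or -1 for
        missing and -2 for inapplicable (both are no-signal downstream)."""
        alpha = {s: i for i, s in enumerate(self.alphabets[char])}
        code = {MISSING: -1, INAPPLICABLE: -2, **alpha}
        return self.data[char].map(code)

    def states(self, char: str) -> dict[str, int]:
        """Species -> state index mapping with -1 for any no-signal cell,
        the form the likelihood and parsimony layers consume."""
        enc = self.encoded(char)
        return {sp: (int(v) if v >= 0 else -1) for sp, v in enc.items()}

    def missing_fraction(self, char: str | None = None,
                         include_inapplicable: bool = True) -> float:
        block = self.data if char is None else self.data[[char]]
        codes = (MISSING, INAPPLICABLE) if include_inapplicable else (MISSING,)
        return float(block.isin(codes).to_numpy().mean())

    def subset_species(self, species: Iterable[str]) -> "CharacterMatrix":
        keep = [sp for sp in self.species if sp in set(species)]
        return CharacterMatrix(self.data.loc[keep], self.alphabets, self.ordered)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="species")


def read_matrix(source: str, schema: str = "csv",
                missing_code: str = "?", inapplicable_code: str = "-",
                alphabets: Mapping[str, Sequence[str]] | None = None,
                ordered: Iterable[str] = ()) -> CharacterMatrix:
    """Read a character matrix from delimited text or a NEXUS CHARACTERS block.

    ``source`` may be a path or the raw text itself.  User missing /
    inapplicable codes are mapped to the canonical ``?`` / ``-``.
    """
    if schema in ("csv", "tsv"):
        sep = "," if schema == "csv" else "\t"
        buf = io.StringIO(source) if "\n" in source else source
        df = pd.read_csv(buf, sep=sep, index_col=0, dtype=str)
        df.index = df.index.astype(str)
    elif schema == "nexus":
        data = source if "\n" in source else open(source).read()
        cm = dendropy.StandardCharacterMatrix.get(data=data, schema="nexus")
        rows = {}
        nchar = max(len(seq) for seq in cm.values())
        for taxon, seq in cm.items():
            rows[taxon.label] = [str(s.symbol) for s in seq]
        df = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=[f"char{i+1}" for i in range(nchar)])
    else:
        raise ValueError(f"unknown matrix schema {schema!r}")
    # normalize special codes
    df = df.replace({missing_code: MISSING, inapplicable_code: INAPPLICABLE})
    df = df.where(~df.isna(), MISSING)
    return CharacterMatrix(df, alphabets=alphabets, ordered=ordered)


@dataclass
class AlignmentLog:
    dropped_from_trees: list[str]
    dropped_from_matrix: list[str]


def align_taxa(trees: TreeSample | Chronogram, matrix: CharacterMatrix
               ) -> tuple[TreeSample, CharacterMatrix, AlignmentLog]:
    """Restrict trees and matrix to their shared species.

    Species present only in the trees (e.g. outgroups never scored for the
    traits) are pruned out of every tree; matrix rows without a tip are
    dropped.  Pruning preserves branch-time sums along retained paths.
    """
    if isinstance(trees, Chronogram):
        trees = TreeSample([trees])
    tree_taxa = trees.tip_labels
    mat_taxa = set(matrix.species)
    shared = tree_taxa & mat_taxa
    if not shared:
        raise ValueError("trees and matrix share no species")
    log = AlignmentLog(
        dropped_from_trees=sorted(tree_taxa - shared),
        dropped_from_matrix=sorted(mat_taxa - shared),
    )
    if tree_taxa == shared:
        new_trees = trees
    else:
        new_trees = TreeSample([t.pruned_to(shared) for t in trees], label=trees.label)
    new_matrix = matrix if mat_taxa == shared else matrix.subset_species(shared)
    new_trees.check_consistent()
    return new_trees, new_matrix, log
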