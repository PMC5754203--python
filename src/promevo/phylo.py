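"""Parsimony reconstruction of the species tree from promoter turnover.

Presence/absence of each promoter across the clade is a binary character
(with '?' for non-alignable regions).  Unrooted binary topologies are scored
by Fitch parsimony — for two-state unordered characters this coincides with
Wagner parsimony — and, for up to 9 taxa, the optimum is found by exhaustive
enumeration of all (2n-5)!! topologies.

A tree is stored rooted at its lexicographically first taxon: the remaining
taxa form a nested-pair structure whose top node, joined with that taxon,
is the degree-3 internal node of the unrooted tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CharacterMatrix", "Tree", "enumerate_topologies",
           "fitch_length", "best_tree"]

MISSING = -1  # '?' state code


@dataclass
class CharacterMatrix:
    """Taxa x characters binary matrix with optional missing states.

    ``states`` is an int8 array of shape ``(n_taxa, n_characters)`` holding
    0, 1 or -1 (missing, written '?').
    """

    taxa: list[str]
    states: np.ndarray
    metadata: list = field(default_factory=list)

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int8)
        if len(self.taxa) < 3:
            raise ValueError("need at least 3 taxa")
        if self.states.ndim != 2 or self.states.shape[0] != len(self.taxa):
            raise ValueError("states must be (n_taxa, n_characters)")
        bad = ~np.isin(self.states, (-1, 0, 1))
        if bad.any():
            raise ValueError("states must be 0, 1 or -1 ('?')")

    @property
    def n_characters(self) -> int:
        return self.states.shape[1]

    def informative_mask(self) -> np.ndarray:
        """Characters with at least two taxa in each observed state."""
        ones = (self.states == 1).sum(axis=0)
        zeros = (self.states == 0).sum(axis=0)
        return (ones >= 2) & (zeros >= 2)

    def to_phylip(self) -> str:
        """Relaxed PHYLIP serialization ('?' for missing)."""
        lines = [f"{len(self.taxa)} {self.n_characters}"]
        sym = {1: "1", 0: "0", -1: "?"}
        for i, t in enumerate(self.taxa):
            lines.append(f"{t}  " + "".join(sym[int(s)] for s in self.states[i]))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_phylip(cls, text: str) -> "CharacterMatrix":
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        n_taxa, n_chars = map(int, lines[0].split())
        taxa, rows = [], []
        code = {"1": 1, "0": 0, "?": -1}
        for ln in lines[1:1 + n_taxa]:
            name, seq = ln.split(None, 1)
            seq = seq.replace(" ", "")
            if len(seq) != n_chars:
                raise ValueError(f"row for {name} has {len(seq)} characters, "
                                 f"expected {n_chars}")
            taxa.append(name)
            rows.append([code[c] for c in seq])
        return cls(taxa=taxa, states=np.array(rows, dtype=np.int8))


class Tree:
    """Unrooted binary tree over a set of taxa.

    ``structure`` is a nested tuple over all taxa except ``pivot`` (the
    lexicographically smallest taxon); leaves are taxon labels and internal
    nodes are pairs.  The unrooted tree joins ``pivot`` to the top node.
    """

    __slots__ = ("pivot", "structure", "_newick", "_splits")

    def __init__(self, pivot: str, structure):
        self.pivot = pivot
        self.structure = structure
        self._newick = None
        self._splits = None

    @property
    def taxa(self) -> frozenset:
        return frozenset([self.pivot]) | _leafset(self.structure)

    def newick(self) -> str:
        """Canonical newick string (children sorted, no branch lengths)."""
        if self._newick is None:
            if isinstance(self.structure, str):
                parts = [self.pivot, self.structure]
            else:
                a, b = self.structure
                parts = [self.pivot, _nwk(a), _nwk(b)]
            self._newick = "(" + ",".join(sorted(parts)) + ");"
        return self._newick

    def splits(self) -> frozenset:
        """Non-trivial bipartitions, each as the side without the pivot."""
        if self._splits is None:
            acc = set()
            _collect_splits(self.structure, acc)
            full = self.taxa
            acc = {s for s in acc if 1 < len(s) < len(full) - 1}
            self._splits = frozenset(acc)
        return self._splits

    def __eq__(self, other):
        return (isinstance(other, Tree) and self.taxa == other.taxa
                and self.splits() == other.splits())

    def __hash__(self):
        return hash((self.taxa, self.splits()))

    def __repr__(self):
        return f"Tree({self.newick()})"


def _leafset(sub) -> frozenset:
    if isinstance(sub, str):
        return frozenset([sub])
    return _leafset(sub[0]) | _leafset(sub[1])


def _nwk(sub) -> str:
    if isinstance(sub, str):
        return sub
    return "(" + ",".join(sorted((_nwk(sub[0]), _nwk(sub[1])))) + ")"


def _collect_splits(sub, acc) -> frozenset:
    if isinstance(sub, str):
        return frozenset([sub])
    left = _collect_splits(sub[0], acc)
    right = _collect_splits(sub[1], acc)
    here = left | right
    acc.add(here)
    return here


def tree_from_nested(nested) -> Tree:
    """Build a Tree from any nested-pair topology over all taxa.

    The nesting is re-anchored at the lexicographically smallest taxon, so
    topologically identical inputs yield equal trees.
    """
    # flatten to splits by treating the input as unrooted
    taxa = sorted(_leafset(nested))
    pivot = taxa[0]
    # enumerate all topologies is wasteful; instead peel the pivot off
    structure = _detach(nested, pivot)
    return Tree(pivot, structure)


def _detach(sub, leaf):
    """Remove ``leaf`` from a nested-pair tree, returning the remainder."""
    if isinstance(sub, str):
        raise ValueError("cannot detach from a single leaf")
    a, b = sub
    if a == leaf:
        return b
    if b == leaf:
        return a
    if leaf in _leafset(a):
        return (_detach(a, leaf), b)
    return (a, _detach(b, leaf))


def enumerate_topologies(taxa: list[str]):
    """All unrooted binary topologies over ``taxa`` (deterministic order).

    Yields (2n-5)!! trees, e.g. 15 for 5 taxa, by stepwise addition of each
    taxon to every edge of the growing structure.
    """
    taxa = sorted(taxa)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    pivot, rest = taxa[0], taxa[1:]

    def insertions(sub, leaf):
        yield (sub, leaf)
        if isinstance(sub, tuple):
            a, b = sub
            for a2 in insertions(a, leaf):
                yield (a2, b)
            for b2 in insertions(b, leaf):
                yield (a, b2)

    structures = [rest[0] if len(rest) == 1 else (rest[0], rest[1])]
    for leaf in rest[2:]:
        structures = [s2 for s in structures for s2 in insertions(s, leaf)]
    for s in structures:
        yield Tree(pivot, s)


def fitch_length(tree: Tree, matrix: CharacterMatrix,
                 per_character: bool = False):
    """Parsimony length of a character matrix on a tree (Fitch counting).

    Missing states contribute the minimum over their possible assignments
    (the leaf starts with the full state set).  Vectorized across
    characters; returns the total integer length, or the per-character
    vector when ``per_character`` is true.
    """
    if tree.taxa != frozenset(matrix.taxa):
        raise ValueError("tree leaves do not match matrix taxa")
    idx = {t: i for i, t in enumerate(matrix.taxa)}
    # state bitmasks: 0 -> 0b01, 1 -> 0b10, ? -> 0b11
    masks = np.where(matrix.states == 0, 1,
                     np.where(matrix.states == 1, 2, 3)).astype(np.uint8)
    changes = np.zeros(matrix.n_characters, dtype=np.int64)

    def visit(sub) -> np.ndarray:
        if isinstance(sub, str):
            return masks[idx[sub]]
        left = visit(sub[0])
        right = visit(sub[1])
        inter = left & right
        disjoint = inter == 0
        changes[disjoint] += 1
        return np.where(disjoint, left | right, inter).astype(np.uint8)

    top = visit(tree.structure)
    pivot_mask = masks[idx[tree.pivot]]
    inter = top & pivot_mask
    changes[inter == 0] += 1
    return changes if per_character else int(changes.sum())


def best_tree(matrix: CharacterMatrix):
    """Maximum-parsimony topology search by exhaustive enumeration.

    Supports 4 to 9 taxa (10395+ topologies beyond that call for heuristic
    software).  Returns ``(best_trees, length)`` where ``best_trees`` lists
    every co-optimal topology sorted by canonical newick string.
    """
    n = len(matrix.taxa)
    if n < 4:
        raise ValueError("need at least 4 taxa for a nontrivial topology")
    if n > 9:
        raise ValueError("more than 9 taxa: use dedicated parsimony software "
                         "(e.g. PHYLIP pars) for heuristic search")
    best_len = None
    best: list[Tree] = []
    for tree in enumerate_topologies(matrix.taxa):
        length = fitch_length(tree, matrix)
        if best_len is None or length < best_len:
            best_len, best = length, [tree]
        elif length == best_len:
            best.append(tree)
    best.sort(key=lambda t: t.newick())
    return best, best_len
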