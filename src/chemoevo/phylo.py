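"""Camin-Sokal (irreversible) parsimony phylogenies for sequenced clones.

Clone genotypes are recoded as binary presence/absence characters, one column
per mutation, with the ancestor as an all-zero outgroup.  Under the
Camin-Sokal criterion a character may be gained (0→1) any number of times but
never lost — the appropriate model here, where an extreme transversion bias
makes exact reversion vanishingly unlikely.  The score of a topology is the
total number of gain events; for a fixed rooted topology the optimal gain set
of a character with carrier set S is the minimal set of branches whose
subtended leaf sets partition S, i.e. the maximal clades wholly contained in
S.  Characters gained on more than one branch are within-vessel parallel
origins (homoplasy).

Search strategy: matrices whose characters are pairwise compatible admit a
perfect phylogeny (every character gained exactly once), which is constructed
directly and is provably optimal.  Otherwise identical genotypes are collapsed
and, for at most 8 collapsed taxa, all rooted binary topologies are
enumerated; beyond that, greedy stepwise addition (taxa in decreasing
mutation count) refined by nearest-neighbor interchange is used.  Zero-gain
internal edges are collapsed, so unresolved relationships surface as
polytomies rather than arbitrary bifurcations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .catalog import CloneGenotype, MutationId

__all__ = [
    "CharacterMatrix",
    "PhyloNode",
    "PhyloTree",
    "build_character_matrix",
    "characters_compatible",
    "is_perfect_phylogeny_matrix",
    "camin_sokal_tree",
    "count_independent_origins",
    "cross_vessel_allele_sharing",
    "export_newick",
]

ANCESTOR = "ancestor"


@dataclass
class CharacterMatrix:
    """Binary taxa x characters presence/absence matrix, ancestor row all-zero."""

    taxa: list[str]
    characters: list[MutationId]
    states: np.ndarray  # bool, shape (len(taxa), len(characters))
    vessel: str | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=bool)
        if self.states.shape != (len(self.taxa), len(self.characters)):
            raise ValueError("states shape does not match taxa x characters")
        if ANCESTOR not in self.taxa:
            raise ValueError("matrix must include the ancestor taxon")
        anc = self.taxa.index(ANCESTOR)
        if self.states[anc].any():
            raise ValueError("ancestor row must be all zeros")

    def genotype(self, taxon: str) -> frozenset[MutationId]:
        row = self.states[self.taxa.index(taxon)]
        return frozenset(c for c, bit in zip(self.characters, row) if bit)


def build_character_matrix(
    clones: Sequence[CloneGenotype],
    ancestor: CloneGenotype | None = None,
) -> CharacterMatrix:
    """Recode clone genotypes as binary characters over their mutation union.

    Every mutation carried by at least one clone becomes a column (singletons
    included); duplicate rows are preserved so each clone keeps its identity.
    The ancestor contributes the all-zero outgroup row.
    """
    if ancestor is not None and ancestor.mutations:
        raise ValueError("ancestor genotype must be the empty set (derived alleles only)")
    vessels = {c.vessel for c in clones}
    if len(vessels) > 1:
        raise ValueError(f"clones must come from a single vessel, got {sorted(vessels)}")
    anc_name = ancestor.clone_id if ancestor is not None else ANCESTOR
    characters = sorted(set().union(*(c.mutations for c in clones)) if clones else set())
    taxa = [ANCESTOR] + [c.clone_id for c in clones]
    if anc_name != ANCESTOR:
        taxa[0] = ANCESTOR  # canonical outgroup label
    states = np.zeros((len(taxa), len(characters)), dtype=bool)
    index = {m: j for j, m in enumerate(characters)}
    for i, clone in enumerate(clones, start=1):
        for m in clone.mutations:
            states[i, index[m]] = True
    return CharacterMatrix(taxa, characters, states, vessel=vessels.pop() if vessels else None)


def characters_compatible(col_a: np.ndarray, col_b: np.ndarray) -> bool:
    """Pairwise compatibility: carrier sets nested or disjoint.

    Two binary characters conflict iff the taxon patterns (1,0), (0,1) and
    (1,1) all occur; conflicting characters cannot both be single-origin on
    any tree without reversals.
    """
    a, b = np.asarray(col_a, bool), np.asarray(col_b, bool)
    return not ((a & ~b).any() and (~a & b).any() and (a & b).any())


def is_perfect_phylogeny_matrix(matrix: CharacterMatrix) -> bool:
    """True iff all character pairs are compatible (perfect phylogeny exists)."""
    cols = matrix.states.T
    return all(
        characters_compatible(cols[i], cols[j])
        for i, j in itertools.combinations(range(len(cols)), 2)
    )


@dataclass
class PhyloNode:
    """Node of a rooted clone phylogeny; ``gains`` are the mutations acquired
    on the branch leading into this node."""

    name: str | None = None
    children: list["PhyloNode"] = field(default_factory=list)
    gains: list[MutationId] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.walk() if n.is_leaf]


@dataclass
class PhyloTree:
    """Rooted Camin-Sokal tree with the ancestor as outgroup at the root."""

    root: PhyloNode
    matrix: CharacterMatrix
    length: int
    n_optimal: int | None = None  # co-optimal topology count (exact search only)
    vessel: str | None = None

    def gain_nodes(self, mutation: MutationId) -> list[PhyloNode]:
        return [n for n in self.root.walk() if mutation in n.gains]

    def clusters(self) -> set[frozenset[str]]:
        """Leaf sets subtended by gain-supported branches (nontrivial clades)."""
        out = set()
        for node in self.root.walk():
            if node is self.root or not node.gains:
                continue
            out.add(frozenset(node.leaf_names()))
        return out

    def validate(self) -> None:
        """Structural irreversibility: every taxon's genotype equals the union
        of gains on its root path, and no character repeats on a path."""
        def descend(node: PhyloNode, acquired: frozenset[MutationId]) -> None:
            overlap = acquired & set(node.gains)
            if overlap:
                raise AssertionError(f"character(s) {overlap} gained twice on one path")
            acquired = acquired | set(node.gains)
            if node.is_leaf:
                expected = self.matrix.genotype(node.name)
                if acquired != expected:
                    raise AssertionError(
                        f"taxon {node.name}: path gains {acquired} != genotype {expected}"
                    )
            for child in node.children:
                descend(child, acquired)

        descend(self.root, frozenset())


# -- scoring ---------------------------------------------------------------
# During search, collapsed taxa are bit positions; a topology is a nested
# tuple of ints (leaf = bitmask with one bit, internal = (left, right)).


def _mask(tree) -> int:
    if isinstance(tree, int):
        return tree
    return _mask(tree[0]) | _mask(tree[1])


def _gains_for_character(tree, carriers: int, mask: int) -> int:
    """Minimal gain count for one character on a rooted topology: number of
    maximal clades wholly inside the carrier set."""
    if mask & carriers == mask:
        return 1
    if isinstance(tree, int):
        return 0
    left, right = tree
    return _gains_for_character(left, carriers, _mask(left)) + _gains_for_character(
        right, carriers, _mask(right)
    )


def _tree_length(tree, char_masks: Sequence[int]) -> int:
    mask = _mask(tree)
    return sum(_gains_for_character(tree, c, mask) for c in char_masks)


def _canonical(tree) -> tuple:
    """Order-invariant canonical form used for deterministic tie-breaking."""
    if isinstance(tree, int):
        return (0, tree)
    a, b = _canonical(tree[0]), _canonical(tree[1])
    return (1, min(a, b), max(a, b))


def _all_rooted_topologies(n: int):
    """All rooted binary topologies on leaves 0..n-1 (as bitmask tuples)."""
    trees = [1 << 0]
    for leaf in range(1, n):
        bit = 1 << leaf
        nxt = []
        for t in trees:
            nxt.extend(_insert_everywhere(t, bit))
        trees = nxt
    return trees


def _insert_everywhere(tree, bit):
    yield (tree, bit)
    if not isinstance(tree, int):
        left, right = tree
        for sub in _insert_everywhere(left, bit):
            yield (sub, right)
        for sub in _insert_everywhere(right, bit):
            yield (left, sub)


def _stepwise_addition(order: Sequence[int], char_masks: Sequence[int]):
    tree = 1 << order[0]
    for leaf in order[1:]:
        bit = 1 << leaf
        best, best_len = None, None
        for cand in _insert_everywhere(tree, bit):
            length = _tree_length(cand, char_masks)
            key = (length, _canonical(cand))
            if best is None or key < (best_len, _canonical(best)):
                best, best_len = cand, length
        tree = best
    return tree


def _nni_refine(tree, char_masks: Sequence[int], max_rounds: int = 20):
    """Nearest-neighbor interchange hill climbing; never worsens the score."""
    best_len = _tree_length(tree, char_masks)
    for _ in range(max_rounds):
        improved = False
        for cand in _nni_neighbors(tree):
            length = _tree_length(cand, char_masks)
            if length < best_len:
                tree, best_len, improved = cand, length, True
                break
        if not improved:
            break
    return tree, best_len


def _nni_neighbors(tree):
    """Rooted NNI moves: for each internal edge swap a grandchild across it."""
    if isinstance(tree, int):
        return
    left, right = tree
    if not isinstance(left, int):
        a, b = left
        yield ((a, right), b)
        yield ((b, right), a)
    if not isinstance(right, int):
        a, b = right
        yield (a, (b, left))
        yield (b, (a, left))
    for sub in _nni_neighbors(left):
        yield (sub, right)
    for sub in _nni_neighbors(right):
        yield (left, sub)


def _is_laminar(char_masks: Sequence[int]) -> bool:
    """True iff the carrier sets are pairwise nested or disjoint (no character
    conflict at collapsed-group level), i.e. a perfect phylogeny exists."""
    masks = sorted(set(char_masks))
    return not any(
        a & b and a & b not in (a, b) for a, b in itertools.combinations(masks, 2)
    )


def camin_sokal_tree(
    matrix: CharacterMatrix,
    search: str = "auto",
    exact_limit: int = 8,
) -> PhyloTree:
    """Minimum-gain Camin-Sokal tree rooted on the all-zero ancestor.

    ``search``: ``"auto"`` (perfect-phylogeny shortcut, exact enumeration for
    at most ``exact_limit`` collapsed taxa, heuristic beyond), ``"exact"`` or
    ``"heuristic"`` to force a strategy.  Identical genotypes are collapsed
    for the search and re-expanded as polytomies in the output; ties among
    co-optimal topologies break deterministically on a canonical form.
    """
    if search not in ("auto", "exact", "heuristic"):
        raise ValueError(f"unknown search mode {search!r}")
    anc_idx = matrix.taxa.index(ANCESTOR)
    # collapse identical genotypes (all-zero clones group with the ancestor)
    pattern_to_taxa: dict[bytes, list[str]] = {}
    for i, taxon in enumerate(matrix.taxa):
        pattern_to_taxa.setdefault(matrix.states[i].tobytes(), []).append(taxon)
    zero_key = np.zeros(len(matrix.characters), dtype=bool).tobytes()
    root_taxa = pattern_to_taxa.pop(zero_key, [matrix.taxa[anc_idx]])
    # deterministic group order: by first representative's row pattern
    groups = sorted(pattern_to_taxa.items(), key=lambda kv: min(kv[1]))
    group_rows = [np.frombuffer(k, dtype=bool) for k, _ in groups]
    group_taxa = [taxa for _, taxa in groups]
    n_groups = len(groups)

    char_masks = []
    for j in range(len(matrix.characters)):
        m = 0
        for g, row in enumerate(group_rows):
            if row[j]:
                m |= 1 << g
        char_masks.append(m)
    if any(m == 0 for m in char_masks):
        bad = [matrix.characters[j].token() for j, m in enumerate(char_masks) if m == 0]
        raise ValueError(f"all-zero character column(s): {bad}")

    n_optimal: int | None = None
    if n_groups == 0:
        topo = None
        length = 0
    elif n_groups == 1:
        topo = 1 << 0
        length = _tree_length(topo, char_masks)
    else:
        if search != "heuristic" and _is_laminar(char_masks):
            topo = _laminar_to_topology(n_groups, char_masks)
            length = _tree_length(topo, char_masks)
            assert length == len(char_masks)
        elif search == "exact" or (search == "auto" and n_groups <= exact_limit):
            best, best_len, best_key, ties = None, None, None, 0
            for cand in _all_rooted_topologies(n_groups):
                length = _tree_length(cand, char_masks)
                if best_len is None or length < best_len:
                    best, best_len, best_key, ties = cand, length, _canonical(cand), 1
                elif length == best_len:
                    ties += 1
                    key = _canonical(cand)
                    if key < best_key:
                        best, best_key = cand, key
            topo, length, n_optimal = best, best_len, ties
        else:
            order = sorted(
                range(n_groups),
                key=lambda g: (-int(group_rows[g].sum()), min(group_taxa[g])),
            )
            topo = _stepwise_addition(order, char_masks)
            topo, length = _nni_refine(topo, char_masks)

    root = _materialise(topo, char_masks, matrix, group_taxa, root_taxa)
    tree = PhyloTree(root, matrix, length, n_optimal=n_optimal, vessel=matrix.vessel)
    tree.validate()
    return tree


def _laminar_to_topology(n_groups: int, char_masks: Sequence[int]):
    """Assemble a topology realising a laminar carrier family exactly.

    Each distinct carrier mask becomes a clade; groups nest inside the
    smallest carrier mask containing them.  The result has one gain per
    character, hence is optimal.
    """
    masks = sorted(set(char_masks) | {(1 << n_groups) - 1},
                   key=lambda m: (bin(m).count("1"), m))
    built: dict[int, object] = {}
    for m in masks:
        inner = [built.pop(k) for k in list(built) if k & m == k]
        covered = 0
        for sub in inner:
            covered |= _mask(sub)
        parts = list(inner) + [1 << g for g in range(n_groups) if (m >> g) & 1 and not (covered >> g) & 1]
        node = parts[0]
        for p in parts[1:]:
            node = (node, p)
        built[m] = node
    (top,) = built.values()
    return top


def _materialise(
    topo,
    char_masks: Sequence[int],
    matrix: CharacterMatrix,
    group_taxa: list[list[str]],
    root_taxa: list[str],
) -> PhyloNode:
    """Turn a bitmask topology into a PhyloNode tree: assign gains, collapse
    zero-gain internal edges, expand collapsed groups as polytomies, and hang
    the ancestor (plus any mutation-free clones) at the root."""
    gains_at: dict[int, list[MutationId]] = {}

    def assign(tree, carriers: int, char: MutationId) -> None:
        if _mask(tree) & carriers == _mask(tree):
            gains_at.setdefault(id(tree), []).append(char)
            return
        if isinstance(tree, int):
            return
        assign(tree[0], carriers, char)
        assign(tree[1], carriers, char)

    if topo is not None:
        for char, mask in zip(matrix.characters, char_masks):
            assign(topo, mask, char)

    def build(tree) -> PhyloNode:
        gains = sorted(gains_at.get(id(tree), []))
        if isinstance(tree, int):
            g = tree.bit_length() - 1
            taxa = sorted(group_taxa[g])
            if len(taxa) == 1:
                return PhyloNode(name=taxa[0], gains=gains)
            node = PhyloNode(gains=gains)
            node.children = [PhyloNode(name=t) for t in taxa]
            return node
        node = PhyloNode(gains=gains)
        for sub in tree:
            child = build(sub)
            if not child.is_leaf and not child.gains:
                node.children.extend(child.children)  # collapse zero-gain edge
            else:
                node.children.append(child)
        return node

    root = PhyloNode()
    for t in sorted(root_taxa, key=lambda t: (t != ANCESTOR, t)):
        root.children.append(PhyloNode(name=t))
    if topo is not None:
        top = build(topo)
        if not top.is_leaf and not top.gains:
            root.children.extend(top.children)
        else:
            root.children.append(top)
    return root


def count_independent_origins(tree: PhyloTree, mutation: MutationId) -> int:
    """Number of branches on which ``mutation`` is gained (>= 2 means
    independent parallel origin within the vessel)."""
    if mutation not in tree.matrix.characters:
        raise KeyError(f"{mutation.token()} is not a character of this tree")
    return len(tree.gain_nodes(mutation))


def cross_vessel_allele_sharing(
    trees: Iterable[PhyloTree],
) -> dict[MutationId, list[str]]:
    """Map each mutation to the vessels whose clone trees contain it.

    Vessels share no descent, so a mutation keyed to several vessels arose
    independently in each.
    """
    shared: dict[MutationId, list[str]] = {}
    for i, tree in enumerate(trees):
        vessel = tree.vessel if tree.vessel is not None else str(i + 1)
        for char in tree.matrix.characters:
            shared.setdefault(char, [])
            if vessel not in shared[char]:
                shared[char].append(vessel)
    return shared


def _newick_label(name: str) -> str:
    # underscores are quoted too: unquoted they read back as spaces
    if any(ch in name for ch in " _(),:;'\t"):
        return "'" + name.replace("'", "''") + "'"
    return name


def export_newick(tree: PhyloTree, annotate: bool = False) -> str:
    """Serialise to Newick; ``annotate`` adds per-branch gain lists as
    bracketed comments readable by standard tree viewers."""

    def render(node: PhyloNode) -> str:
        body = (
            _newick_label(node.name)
            if node.is_leaf
            else "(" + ",".join(render(c) for c in node.children) + ")"
        )
        length = f":{len(node.gains)}"
        comment = ""
        if annotate and node.gains:
            comment = "[&gains=" + "|".join(m.token() for m in node.gains) + "]"
        return body + length + comment

    return "(" + ",".join(render(c) for c in tree.root.children) + ");"
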