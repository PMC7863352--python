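"""Camin-Sokal parsimony: oracle equivalence, irreversibility, export."""

import itertools

import dendropy
import numpy as np
import pytest

from chemoevo.catalog import CloneGenotype, MutationId
from chemoevo.phylo import (
    ANCESTOR,
    CharacterMatrix,
    build_character_matrix,
    camin_sokal_tree,
    characters_compatible,
    count_independent_origins,
    cross_vessel_allele_sharing,
    export_newick,
    is_perfect_phylogeny_matrix,
)
from chemoevo.simulate import sample_clones, simulate
from conftest import small_sim_config

A = MutationId(10, "C", "A")
B = MutationId(20, "G", "T")
C = MutationId(30, "C", "A")
D = MutationId(40, "G", "T")


# ---------------------------------------------------------------------------
# independent brute-force oracle
# ---------------------------------------------------------------------------


def rooted_topologies(taxa):
    """All rooted binary topologies, generated by recursive set bipartition
    (a different construction from the implementation's leaf insertion)."""
    taxa = tuple(taxa)
    if len(taxa) == 1:
        yield taxa[0]
        return
    first, rest = taxa[0], taxa[1:]
    # all subsets of rest joined with first on the left side
    for r in range(len(rest) + 1):
        for left_rest in itertools.combinations(rest, r):
            right = tuple(t for t in rest if t not in left_rest)
            if not right:
                continue
            for lt in rooted_topologies((first,) + left_rest):
                for rt in rooted_topologies(right):
                    yield (lt, rt)


def leafset(tree):
    if not isinstance(tree, tuple):
        return frozenset([tree])
    return leafset(tree[0]) | leafset(tree[1])


def gains_by_edge_enumeration(tree, carriers):
    """Ultra-brute-force minimal gains: try all subsets of edges as gain
    placements and keep the smallest that reproduces the carrier set exactly
    (gains are inherited by all leaves below; no losses)."""
    edges = []

    def collect(node):
        edges.append(node)
        if isinstance(node, tuple):
            collect(node[0])
            collect(node[1])

    collect(tree)
    best = None
    for k in range(0, len(carriers) + 1):
        for subset in itertools.combinations(range(len(edges)), k):
            covered = frozenset()
            ok = True
            for i in subset:
                ls = leafset(edges[i])
                if covered & ls:
                    ok = False  # nested gains would re-gain on a path
                    break
                covered |= ls
            if ok and covered == carriers:
                best = k
                break
        if best is not None:
            return best
    raise AssertionError("no gain placement found")


def greedy_gains(tree, carriers):
    """Clade-cover gain count (independent re-implementation)."""
    ls = leafset(tree)
    if ls <= carriers:
        return 1
    if not isinstance(tree, tuple):
        return 0
    return greedy_gains(tree[0], carriers) + greedy_gains(tree[1], carriers)


def brute_force_min_length(taxa_genotypes):
    """Minimum Camin-Sokal length over all rooted binary topologies."""
    taxa = sorted(taxa_genotypes)
    characters = sorted(set().union(*taxa_genotypes.values()))
    best = None
    for topo in rooted_topologies(taxa):
        length = sum(
            greedy_gains(topo, frozenset(t for t in taxa if ch in taxa_genotypes[t]))
            for ch in characters
        )
        best = length if best is None else min(best, length)
    return best


def test_greedy_gain_count_matches_edge_enumeration():
    """The clade-cover rule equals exhaustive gain placement on tiny trees."""
    rng = np.random.default_rng(3)
    taxa = ("t1", "t2", "t3", "t4")
    for topo in rooted_topologies(taxa):
        for _ in range(3):
            carriers = frozenset(t for t in taxa if rng.random() < 0.5)
            if not carriers:
                continue
            assert greedy_gains(topo, carriers) == gains_by_edge_enumeration(topo, carriers)


# ---------------------------------------------------------------------------
# character matrix
# ---------------------------------------------------------------------------


class TestCharacterMatrix:
    def test_build_from_nested_clones(self, toy_clones):
        m = build_character_matrix(toy_clones)
        assert m.taxa[0] == ANCESTOR
        assert len(m.characters) == 3
        assert m.genotype("c3") == frozenset({A, B, C})
        assert m.genotype(ANCESTOR) == frozenset()

    def test_identical_clones_keep_identity(self):
        clones = [CloneGenotype(f"c{i}", "1", frozenset({A})) for i in range(96)]
        m = build_character_matrix(clones)
        assert len(m.taxa) == 97
        assert m.states[1:].all()

    def test_nonempty_ancestor_rejected(self, toy_clones):
        with pytest.raises(ValueError, match="ancestor"):
            build_character_matrix(toy_clones, CloneGenotype("anc", "1", frozenset({A})))

    def test_mixed_vessels_rejected(self):
        clones = [CloneGenotype("a", "1", frozenset({A})),
                  CloneGenotype("b", "2", frozenset({B}))]
        with pytest.raises(ValueError, match="single vessel"):
            build_character_matrix(clones)

    def test_compatibility_predicate(self):
        a = np.array([1, 0, 1, 0], bool)
        b = np.array([0, 1, 1, 0], bool)
        nested = np.array([1, 0, 0, 0], bool)
        assert not characters_compatible(a, b)
        assert characters_compatible(a, nested)


# ---------------------------------------------------------------------------
# tree search
# ---------------------------------------------------------------------------


class TestCaminSokal:
    def test_perfect_nested_chain(self, toy_clones):
        tree = camin_sokal_tree(build_character_matrix(toy_clones))
        assert tree.length == 3  # one gain per character
        for mut in (A, B, C):
            assert count_independent_origins(tree, mut) == 1

    def test_conflict_forces_homoplasy(self):
        clones = [
            CloneGenotype("A", "1", frozenset({A})),
            CloneGenotype("B", "1", frozenset({B})),
            CloneGenotype("C", "1", frozenset({A, B})),
        ]
        tree = camin_sokal_tree(build_character_matrix(clones))
        expected = brute_force_min_length(
            {"A": {A}, "B": {B}, "C": {A, B}}
        )
        assert tree.length == expected == 3
        origins = sorted(
            count_independent_origins(tree, m) for m in (A, B)
        )
        assert origins == [1, 2]  # exactly one character gained twice

    @pytest.mark.parametrize("search", ["auto", "exact", "heuristic"])
    def test_search_modes_agree_on_small_conflict(self, search):
        clones = [
            CloneGenotype("A", "1", frozenset({A, C})),
            CloneGenotype("B", "1", frozenset({B, C})),
            CloneGenotype("C", "1", frozenset({A, B})),
            CloneGenotype("D", "1", frozenset({D})),
        ]
        tree = camin_sokal_tree(build_character_matrix(clones), search=search)
        if search != "heuristic":
            expected = brute_force_min_length(
                {"A": {A, C}, "B": {B, C}, "C": {A, B}, "D": {D}}
            )
            assert tree.length == expected
        tree.validate()

    def test_random_matrices_match_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            n_taxa = int(rng.integers(2, 6))
            n_chars = int(rng.integers(1, 5))
            states = rng.random((n_taxa, n_chars)) < 0.5
            keep = states.any(axis=0)
            if not keep.any():
                continue
            states = states[:, keep]
            muts = [MutationId(10 * (j + 1), "C", "A") for j in range(states.shape[1])]
            clones = [
                CloneGenotype(f"t{i}", "1",
                              frozenset(m for m, bit in zip(muts, states[i]) if bit))
                for i in range(n_taxa)
            ]
            tree = camin_sokal_tree(build_character_matrix(clones), search="exact")
            genotypes = {c.clone_id: set(c.mutations) for c in clones if c.mutations}
            if not genotypes:
                continue
            assert tree.length == brute_force_min_length(genotypes)
            tree.validate()

    def test_length_lower_bound_and_perfect_phylogeny(self, toy_clones):
        m = build_character_matrix(toy_clones)
        assert is_perfect_phylogeny_matrix(m)
        tree = camin_sokal_tree(m)
        assert tree.length == len(m.characters)

    def test_incompatible_matrix_exceeds_character_count(self):
        clones = [
            CloneGenotype("A", "1", frozenset({A})),
            CloneGenotype("B", "1", frozenset({B})),
            CloneGenotype("C", "1", frozenset({A, B})),
        ]
        m = build_character_matrix(clones)
        assert not is_perfect_phylogeny_matrix(m)
        assert camin_sokal_tree(m).length > len(m.characters)

    def test_heuristic_on_simulated_sample_is_valid_and_bounded(self):
        cfg = small_sim_config(seed=5)
        truth = simulate(cfg, "1")
        clones = sample_clones(truth, cfg.n_generations, n=40)
        m = build_character_matrix(clones)
        tree = camin_sokal_tree(m)
        tree.validate()
        assert tree.length >= len(m.characters)

    def test_simulated_no_recurrence_recovers_true_clusters(self):
        cfg = small_sim_config(seed=9, allow_recurrence=False)
        truth = simulate(cfg, "1")
        clones = sample_clones(truth, cfg.n_generations, n=20)
        m = build_character_matrix(clones)
        tree = camin_sokal_tree(m)
        assert tree.length == len(m.characters)
        # true clusters: carrier sets of each mutation among sampled clones
        true_clusters = set()
        for mut in m.characters:
            carriers = frozenset(c.clone_id for c in clones if mut in c.mutations)
            true_clusters.add(carriers)
        assert tree.clusters() == true_clusters


class TestOriginsAndSharing:
    def test_unknown_mutation_rejected(self, toy_clones):
        tree = camin_sokal_tree(build_character_matrix(toy_clones))
        with pytest.raises(KeyError):
            count_independent_origins(tree, MutationId(999, "C", "A"))

    def test_cross_vessel_sharing(self):
        t1 = camin_sokal_tree(
            build_character_matrix([CloneGenotype("a", "1", frozenset({A, B}))])
        )
        t2 = camin_sokal_tree(
            build_character_matrix([CloneGenotype("b", "2", frozenset({A, C}))])
        )
        shared = cross_vessel_allele_sharing([t1, t2])
        assert shared[A] == ["1", "2"]
        assert shared[B] == ["1"]
        assert shared[C] == ["2"]


class TestNewick:
    def test_two_taxon_shape(self):
        tree = camin_sokal_tree(
            build_character_matrix([CloneGenotype("cloneA", "1", frozenset({A}))])
        )
        nwk = export_newick(tree)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == {
            "ancestor", "cloneA"
        }

    def test_round_trip_preserves_topology(self, toy_clones):
        tree = camin_sokal_tree(build_character_matrix(toy_clones))
        nwk = export_newick(tree)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        parsed_clusters = {
            frozenset(leaf.taxon.label for leaf in node.leaf_iter())
            for node in parsed.preorder_internal_node_iter()
        }
        own_clusters = {frozenset(tree.root.leaf_names())} | {
            frozenset(n.leaf_names())
            for n in tree.root.walk()
            if not n.is_leaf and n is not tree.root
        }
        assert parsed_clusters == own_clusters

    def test_simulated_sample_round_trips_losslessly(self):
        cfg = small_sim_config(seed=13)
        truth = simulate(cfg, "1")
        clones = sample_clones(truth, cfg.n_generations, n=96)
        tree = camin_sokal_tree(build_character_matrix(clones))
        nwk = export_newick(tree, annotate=True)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        assert {l.taxon.label for l in parsed.leaf_node_iter()} == set(
            [ANCESTOR] + [c.clone_id for c in clones]
        )
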