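import itertools

import numpy as np
import pytest
from scipy.optimize import nnls

from geoclade.io import read_tree, write_tree
from geoclade.phylo import (
    aligned_p_distances,
    annotate_supports,
    bipartition_keys,
    bootstrap_support,
    fitch_ancestral,
    midpoint_root,
    neighbor_joining,
    pairwise_distance,
    poisson_correct,
)
from geoclade.simulate import AMINO_ACIDS
from geoclade.util import child_rng


def random_seq(rng, length):
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, length))


def tree_distances(tree):
    """Leaf-to-leaf path-length matrix of a tree, via tip-to-tip traversal."""
    tips = sorted(tree.tips(), key=lambda t: t.name)
    labels = [t.name for t in tips]
    n = len(tips)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = tips[i].distance(tips[j])
    return labels, D


def random_additive_tree(rng, n_taxa):
    """Random binary unrooted tree with positive branch lengths, as newick."""
    nodes = [f"T{i}" for i in range(n_taxa)]
    parts = [f"{x}:{rng.uniform(0.1, 1.0):.4f}" for x in nodes]
    while len(parts) > 3:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        a, b = parts[i], parts[j]
        parts = [p for k, p in enumerate(parts) if k not in (i, j)]
        parts.append(f"({a},{b}):{rng.uniform(0.1, 1.0):.4f}")
    return "(" + ",".join(parts) + ");"


class TestPairwiseDistance:
    def test_identical_sequences_zero(self):
        assert pairwise_distance("MKVAW", "MKVAW") == 0.0

    def test_single_mismatch_fraction(self):
        a = "MKVAWLLRND"
        b = "MKVAWLLRNE"
        assert pairwise_distance(a, b) == pytest.approx(0.1)

    def test_symmetry_over_random_pairs(self):
        rng = child_rng(8)
        for _ in range(50):
            a, b = random_seq(rng, 30), random_seq(rng, 28)
            assert pairwise_distance(a, b) == pytest.approx(pairwise_distance(b, a))

    def test_poisson_correction_monotone_and_guarded(self):
        D = np.array([[0.0, 0.5], [0.5, 0.0]])
        assert poisson_correct(D)[0, 1] == pytest.approx(-np.log(0.5))
        with pytest.raises(ValueError):
            poisson_correct(np.array([[0.0, 1.0], [1.0, 0.0]]))


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = np.array([[0, 2, 4], [2, 0, 6], [4, 6, 0]], dtype=float)
        tree = neighbor_joining(D, ["A", "B", "C"])
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 0.0, "B": 2.0, "C": 4.0}

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(np.zeros((2, 2)), ["A", "B"])

    @pytest.mark.parametrize("seed", range(10))
    def test_additive_matrices_reproduce_the_generating_tree(self, seed):
        """On additive input NJ returns a tree realizing the distances exactly."""
        rng = child_rng(100 + seed)
        n = int(rng.integers(5, 11))
        source = read_tree(random_additive_tree(rng, n))
        labels, D = tree_distances(source)
        nj = neighbor_joining(D, labels)
        labels2, D2 = tree_distances(nj)
        assert labels2 == labels
        assert np.abs(D2 - D).max() < 1e-9
        # and the topology matches: same nontrivial bipartitions
        assert set(bipartition_keys(nj).values()) == set(bipartition_keys(source).values())

    @pytest.mark.parametrize("seed", range(5))
    def test_four_taxon_topology_matches_exhaustive_least_squares(self, seed):
        rng = child_rng(300 + seed)
        source = read_tree(random_additive_tree(rng, 4))
        labels, D = tree_distances(source)

        def ls_residual(split):
            # topology ((a,b),(c,d)): path matrix over 5 edges; nonneg LS fit
            (a, b), (c, d) = split
            idx = {lab: k for k, lab in enumerate(labels)}
            pairs = list(itertools.combinations(range(4), 2))
            rows, rhs = [], []
            edges = [a, b, c, d, "mid"]
            for i, j in pairs:
                row = [0.0] * 5
                for lab, e in zip(labels, range(4)):
                    if idx[lab] in (i, j):
                        row[edges.index(lab)] = 1.0
                one_side = {idx[a], idx[b]}
                if len({i, j} & one_side) == 1:
                    row[4] = 1.0
                rows.append(row)
                rhs.append(D[i, j])
            sol, res = nnls(np.array(rows), np.array(rhs))
            return res

        splits = [
            ((labels[0], labels[1]), (labels[2], labels[3])),
            ((labels[0], labels[2]), (labels[1], labels[3])),
            ((labels[0], labels[3]), (labels[1], labels[2])),
        ]
        best = min(splits, key=ls_residual)
        nj = neighbor_joining(D, labels)
        nj_split = next(iter(bipartition_keys(nj).values()))
        assert nj_split in (frozenset(best[0]), frozenset(best[1]))

    @pytest.mark.parametrize("seed", range(3))
    def test_topology_agrees_with_dendropy_reference(self, seed):
        dendropy = pytest.importorskip("dendropy")
        rng = child_rng(700 + seed)
        n = 7
        source = read_tree(random_additive_tree(rng, n))
        labels, D = tree_distances(source)
        # perturb slightly so the comparison is not the pure additive case
        noise = rng.uniform(-0.01, 0.01, size=D.shape)
        noise = noise + noise.T
        np.fill_diagonal(noise, 0)
        D = np.maximum(D + noise, 0.01)
        np.fill_diagonal(D, 0.0)
        mine = neighbor_joining(D, labels)
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(
                "," + ",".join(labels) + "\n"
                + "\n".join(lab + "," + ",".join(f"{D[i, j]:.10f}" for j in range(n))
                             for i, lab in enumerate(labels))
            ),
            delimiter=",",
        )
        ref = pdm.nj_tree()
        ref_skbio = read_tree(ref.as_string(schema="newick").replace("[&U] ", "").strip())
        assert set(bipartition_keys(mine).values()) == set(bipartition_keys(ref_skbio).values())


class TestBootstrap:
    def perfect_split_alignment(self):
        return [("A", "K" * 50), ("B", "K" * 50), ("C", "R" * 50), ("D", "R" * 50)]

    def test_perfectly_repeated_synapomorphy_gives_support_100(self):
        tree, supports = bootstrap_support(self.perfect_split_alignment(), n_replicates=100, seed=1)
        assert supports == {frozenset({"C", "D"}): 100}
        [node] = [n for n in tree.non_tips() if n.support_value is not None]
        assert node.support_value == 100

    def test_fixed_seed_reproduces_support_vector(self):
        rng = child_rng(42)
        aln = [(f"T{i}", random_seq(rng, 40)) for i in range(6)]
        _, s1 = bootstrap_support(aln, n_replicates=100, seed=9)
        _, s2 = bootstrap_support(aln, n_replicates=100, seed=9)
        assert s1 == s2

    def test_supports_bounded_and_bipartitions_from_full_tree(self):
        rng = child_rng(43)
        aln = [(f"T{i}", random_seq(rng, 30)) for i in range(7)]
        tree, supports = bootstrap_support(aln, n_replicates=50, seed=3)
        full_keys = set(bipartition_keys(tree).values())
        for key, val in supports.items():
            assert 0 <= val <= 100
            assert key in full_keys

    def test_supports_invariant_under_taxon_order_permutation(self):
        rng = child_rng(44)
        aln = [(f"T{i}", random_seq(rng, 40)) for i in range(6)]
        _, s1 = bootstrap_support(aln, n_replicates=60, seed=5)
        _, s2 = bootstrap_support(list(reversed(aln)), n_replicates=60, seed=5)
        assert s1 == s2

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal-length"):
            bootstrap_support([("A", "KK"), ("B", "K")], n_replicates=5, seed=0)


def random_topology(rng, leaves):
    parts = [f"{lab}:1" for lab in leaves]
    while len(parts) > 2:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        a, b = parts[i], parts[j]
        parts = [p for k, p in enumerate(parts) if k not in (i, j)]
        parts.append(f"({a},{b}):1")
    return read_tree("(" + ",".join(parts) + ");")


def brute_force_parsimony(tree, leaf_states, states=("family", "non-family")):
    internal = list(tree.non_tips(include_self=True))
    best = None
    for assignment in itertools.product(states, repeat=len(internal)):
        label = {id(n): s for n, s in zip(internal, assignment)}
        for tip in tree.tips():
            label[id(tip)] = leaf_states[tip.name]
        changes = 0
        for node in tree.traverse(include_self=False):
            changes += label[id(node)] != label[id(node.parent)]
        best = changes if best is None else min(best, changes)
    return best


class TestFitch:
    def test_cherry_of_equal_states_costs_nothing(self):
        tree = read_tree("(A:1,B:1);")
        states, score = fitch_ancestral(tree, {"A": "family", "B": "family"})
        assert score == 0
        assert states[id(tree)] == frozenset({"family"})

    def test_hand_worked_three_leaf_case(self):
        tree = read_tree("((A:1,B:1):1,C:1);")
        states, score = fitch_ancestral(
            tree, {"A": "family", "B": "non-family", "C": "non-family"}
        )
        cherry = next(n for n in tree.non_tips() if {t.name for t in n.tips()} == {"A", "B"})
        assert states[id(cherry)] == frozenset({"family", "non-family"})
        assert states[id(tree)] == frozenset({"non-family"})
        assert score == 1

    def test_unannotated_leaf_is_error(self):
        tree = read_tree("(A:1,B:1);")
        with pytest.raises(ValueError, match="no character state"):
            fitch_ancestral(tree, {"A": "family"})

    @pytest.mark.parametrize("seed", range(8))
    def test_score_matches_exhaustive_minimization(self, seed):
        rng = child_rng(500 + seed)
        n = int(rng.integers(4, 9))
        tree = random_topology(rng, [f"L{i}" for i in range(n)])
        leaf_states = {f"L{i}": ("family" if rng.random() < 0.5 else "non-family") for i in range(n)}
        _, score = fitch_ancestral(tree, leaf_states)
        assert score == brute_force_parsimony(tree, leaf_states)

    @pytest.mark.parametrize("seed", range(4))
    def test_score_invariant_under_rerooting(self, seed):
        rng = child_rng(600 + seed)
        n = 7
        tree = random_topology(rng, [f"L{i}" for i in range(n)])
        leaf_states = {f"L{i}": ("family" if rng.random() < 0.4 else "non-family") for i in range(n)}
        _, score = fitch_ancestral(tree, leaf_states)
        targets = [{t.name for t in node.tips()} for node in tree.non_tips(include_self=False)][:4]
        for target in targets:
            work = tree.copy()
            node = next(m for m in work.non_tips(include_self=False)
                        if {t.name for t in m.tips()} == target)
            rerooted = work.root_at(node)
            _, score2 = fitch_ancestral(rerooted, leaf_states)
            assert score2 == score
        mid = midpoint_root(tree)
        _, score3 = fitch_ancestral(mid, leaf_states)
        assert score3 == score


class TestMidpointAndSupports:
    def test_midpoint_rooting_preserves_supports_via_bipartition_map(self):
        rng = child_rng(77)
        aln = [(f"T{i}", random_seq(rng, 50)) for i in range(6)]
        tree, supports = bootstrap_support(aln, n_replicates=40, seed=2)
        rooted = midpoint_root(tree, supports)
        keys = bipartition_keys(rooted)
        for node in rooted.non_tips(include_self=False):
            key = keys.get(id(node))
            if key is not None and key in supports:
                assert node.support_value == supports[key]

    def test_newick_round_trip_keeps_supports_on_internal_nodes(self):
        tree, _ = bootstrap_support(
            [("A", "K" * 30), ("B", "K" * 30), ("C", "R" * 30), ("D", "R" * 30)],
            n_replicates=20,
            seed=0,
        )
        text = write_tree(tree)
        again = read_tree(text)
        sups = [n.support_value for n in again.non_tips() if n.support_value is not None]
        assert sups == [100]
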