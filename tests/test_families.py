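import networkx as nx
import numpy as np
import pytest

from geoclade.io import SimilarityHit
from geoclade.families import (
    assemble_families,
    build_graph,
    clade_specific_families,
    large_families,
    markov_cluster,
    paralog_expansions,
    pattern_census,
    phyletic_pattern,
    phyletic_pattern_text,
    ProteinFamily,
    single_copy_universal,
)
from geoclade.mcl import mcl_partition
from geoclade.similarity import RBHPair, all_vs_all, reciprocal_best_hits
from geoclade.util import child_rng

GENOMES = ["Gs", "Gm", "Gu", "Gf", "Gb", "Gl"]


def reference_mcl(A, inflation, prune=1e-5, tol=1e-6, max_iter=300):
    """Independent MCL: column-wise loops + attractor-system cluster extraction."""
    n = A.shape[0]
    M = A.astype(float).copy()
    for i in range(n):
        M[i, i] = 0.0
    for i in range(n):
        incident = max(M[i, :].max(), M[:, i].max())
        M[i, i] = incident if incident > 0 else 1.0
    for j in range(n):
        M[:, j] /= M[:, j].sum()
    for _ in range(max_iter):
        prev = M.copy()
        M = M @ M
        M = M**inflation
        M[M < prune] = 0.0
        for j in range(n):
            s = M[:, j].sum()
            if s:
                M[:, j] /= s
        if np.abs(M - prev).max() < tol:
            break
    # attractors: nodes with positive return flow; cluster of an attractor i is
    # every node j that flows into i; overlapping systems merge
    clusters = []
    for i in range(n):
        if M[i, i] > prune:
            clusters.append({i} | {j for j in range(n) if M[i, j] > prune})
    merged = True
    while merged:
        merged = False
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                if clusters[x] & clusters[y]:
                    clusters[x] |= clusters.pop(y)
                    merged = True
                    break
            if merged:
                break
    leftover = set(range(n)) - set().union(*clusters) if clusters else set(range(n))
    clusters += [{i} for i in leftover]
    return [frozenset(c) for c in clusters]


def fam(fid, members):
    present = {g for g, _ in members}
    return ProteinFamily(fid, frozenset(members), phyletic_pattern_text(present, GENOMES))


class TestMCL:
    def test_two_disconnected_cliques_split(self):
        A = np.zeros((6, 6))
        for block in ((0, 1, 2), (3, 4, 5)):
            for i in block:
                for j in block:
                    if i != j:
                        A[i, j] = 1.0
        parts = mcl_partition(A, inflation=2.0)
        assert sorted(map(sorted, parts)) == [[0, 1, 2], [3, 4, 5]]

    def test_single_edge_is_one_cluster(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert [sorted(c) for c in mcl_partition(A, inflation=2.0)] == [[0, 1]]

    def test_inflation_at_or_below_one_rejected(self):
        with pytest.raises(ValueError):
            mcl_partition(np.zeros((2, 2)), inflation=1.0)

    @pytest.mark.parametrize("inflation", [1.5, 2.0, 4.0])
    def test_path_graph_matches_reference_implementation(self, inflation):
        n = 6
        A = np.zeros((n, n))
        for i in range(n - 1):
            A[i, i + 1] = A[i + 1, i] = 1.0
        mine = {frozenset(c) for c in mcl_partition(A, inflation=inflation, tol=1e-6)}
        assert mine == set(reference_mcl(A, inflation))

    @pytest.mark.parametrize("seed", range(6))
    def test_random_graphs_match_reference_implementation(self, seed):
        rng = child_rng(900 + seed)
        n = int(rng.integers(8, 31))
        A = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.18:
                    A[i, j] = A[j, i] = float(rng.integers(1, 10))
        mine = {frozenset(c) for c in mcl_partition(A, inflation=2.0)}
        assert mine == set(reference_mcl(A, 2.0))

    def test_partition_covers_all_nodes_disjointly(self):
        rng = child_rng(4)
        n = 20
        A = (rng.random((n, n)) < 0.2).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        parts = mcl_partition(A, inflation=2.0)
        flat = [i for c in parts for i in c]
        assert sorted(flat) == list(range(n))


class TestBuildGraph:
    def mk_hits(self, bits_pq, p_cross, q_cross):
        P, Q = ("Gs", "p"), ("Gs", "q")
        X = ("Gm", "x")
        hits = [
            SimilarityHit(P, P, 200, 200), SimilarityHit(Q, Q, 190, 190),
            SimilarityHit(X, X, 200, 200),
            SimilarityHit(P, Q, bits_pq, bits_pq), SimilarityHit(Q, P, bits_pq, bits_pq),
            SimilarityHit(P, X, p_cross, p_cross), SimilarityHit(X, P, p_cross, p_cross),
            SimilarityHit(Q, X, q_cross, q_cross), SimilarityHit(X, Q, q_cross, q_cross),
        ]
        rbh = reciprocal_best_hits(hits)
        return build_graph(rbh, hits), P, Q

    def test_recent_paralog_edge_when_closer_than_cross_hits(self):
        graph, P, Q = self.mk_hits(bits_pq=180, p_cross=150, q_cross=140)
        assert graph.has_edge(P, Q)

    def test_no_paralog_edge_when_cross_hit_is_closer(self):
        graph, P, Q = self.mk_hits(bits_pq=120, p_cross=150, q_cross=140)
        assert not graph.has_edge(P, Q)

    def test_identical_cross_genome_singletons_weight_one(self):
        P, X = ("Gs", "p"), ("Gm", "x")
        hits = [
            SimilarityHit(P, P, 200, 200), SimilarityHit(X, X, 200, 200),
            SimilarityHit(P, X, 200, 200), SimilarityHit(X, P, 200, 200),
        ]
        graph = build_graph(reciprocal_best_hits(hits), hits)
        assert graph[P][X]["weight"] == pytest.approx(1.0)


class TestFamilies:
    def test_assembly_separates_singletons_and_numbers_by_size(self):
        partition = [
            frozenset({("Gs", "a"), ("Gm", "b")}),
            frozenset({("Gu", "c")}),
            frozenset({("Gs", "d"), ("Gm", "e"), ("Gu", "f")}),
        ]
        families, singletons = assemble_families(partition, GENOMES)
        assert [f.size for f in families] == [3, 2]
        assert singletons == [("Gu", "c")]
        # coverage fraction of the toy: 2 of 3 proteins in the size-2 run
        assert families[1].pattern == "GsGm--------"

    def test_patterns_match_presence(self):
        f = fam(1, [("Gs", "a"), ("Gu", "b"), ("Gf", "c"), ("Gl", "d")])
        assert phyletic_pattern(f, GENOMES) == "Gs--GuGf--Gl"
        f6 = fam(2, [(g, f"p{g}") for g in GENOMES])
        assert f6.pattern == "GsGmGuGfGbGl"
        f1 = fam(3, [("Gu", "only")])
        assert f1.pattern == "----Gu------"

    def test_pattern_census_fractions_and_totals(self):
        families = [fam(1, [("Gs", "a"), ("Gm", "b")])]
        singles = [("Gu", "c"), ("Gl", "d")]
        rows = pattern_census(families, singles, GENOMES)
        assert sum(r["proteins"] for r in rows) == 4
        top = next(r for r in rows if r["pattern"] == "GsGm--------")
        assert top["pct_of_proteins"] == 50.0
        assert sum(r["pct_of_proteins"] for r in rows) <= 100.0 + 1.0  # rounding slack

    def test_large_families_threshold(self):
        fams = [
            fam(1, [("Gs", f"a{i}") for i in range(12)]),
            fam(2, [("Gm", f"b{i}") for i in range(10)]),
            fam(3, [("Gu", f"c{i}") for i in range(9)]),
        ]
        assert [f.family_id for f in large_families(fams, 10)] == [1, 2]

    def test_clade_specific_exact_presence_semantics(self):
        clade = {"Gu", "Gf", "Gb"}
        inside = fam(1, [("Gu", "a"), ("Gf", "b"), ("Gb", "c")])
        everywhere = fam(2, [(g, f"p{g}") for g in GENOMES])
        partial = fam(3, [("Gu", "a"), ("Gb", "c")])
        assert clade_specific_families([inside, everywhere, partial], clade) == [inside]

    def test_paralog_expansions_detect_multicopy_genomes(self):
        expanded = fam(1, [("Gs", "a"), ("Gs", "b"), ("Gm", "c")])
        flat = fam(2, [("Gs", "a2"), ("Gm", "b2")])
        triple = fam(3, [("Gu", "x"), ("Gu", "y"), ("Gu", "z")])
        result = paralog_expansions([expanded, flat, triple])
        assert [f.family_id for f, _ in result] == [1, 3]
        assert result[0][1] == {"Gs": 2, "Gm": 1}


class TestSingleCopyUniversal:
    def test_zero_divergence_all_families_selected(self, zero_divergence_clade):
        pset = zero_divergence_clade.proteomes
        hits = all_vs_all(pset)
        graph = build_graph(reciprocal_best_hits(hits), hits)
        selected = single_copy_universal(graph, pset.genomes, inflations=[1.5, 3.0])
        assert len(selected) == 10

    def test_multicopy_cluster_never_selected(self):
        # a 7-node cluster with 2 members in Gs stays unselected at any inflation
        members = [("Gs", "a"), ("Gs", "b")] + [(g, f"p{g}") for g in GENOMES if g != "Gs"]
        graph = nx.Graph()
        hub = members[0]
        for m in members[1:]:
            graph.add_edge(hub, m, weight=1.0)
        selected = single_copy_universal(graph, GENOMES, inflations=[1.5, 3.0])
        assert selected == []

    def test_sweep_needs_two_values(self):
        with pytest.raises(ValueError):
            single_copy_universal(nx.Graph(), GENOMES, inflations=[1.5])
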