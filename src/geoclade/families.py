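"""Ortholog families: RBH graph construction, MCL partition, phyletic patterns.

A family is a cluster of orthologs and recent paralogs.  The graph has an
edge for every cross-genome reciprocal best hit, plus within-genome "recent
paralog" edges for pairs that are each closer to the other than to anything
outside their genome; edge weights are mean bit-score ratios (or normalized
-log10 e-values when external BLAST input supplies them).  Markov clustering
of this graph yields the families; each family's phyletic pattern records
which genomes contribute members, in the fixed genome order (e.g.
``GsGmGuGfGbGl`` for a family present in all six, ``Gs--GuGf--Gl`` with the
absent genomes blanked).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .io import ProteinKey, SimilarityHit
from .similarity import RBHPair
from .mcl import mcl_partition
from .util import round_half_away

ABSENT_SLOT = "--"


def phyletic_pattern_text(present: set[str], genome_order: Sequence[str]) -> str:
    """Fixed-width pattern: genome code if present, '--' per absent genome."""
    return "".join(g if g in present else ABSENT_SLOT for g in genome_order)


@dataclass
class ProteinFamily:
    """A cluster of orthologs/recent paralogs with its phyletic pattern."""

    family_id: int
    members: frozenset[ProteinKey]
    pattern: str

    @property
    def size(self) -> int:
        return len(self.members)

    def genomes_present(self) -> set[str]:
        return {g for g, _ in self.members}

    def per_genome_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for g, _ in self.members:
            counts[g] = counts.get(g, 0) + 1
        return counts


def build_graph(
    rbh_pairs: list[RBHPair],
    hits: list[SimilarityHit],
    weight_scheme: str = "bsr",
) -> nx.Graph:
    """Similarity graph over proteins: RBH edges plus recent-paralog edges.

    A within-genome pair (p, q) gets an edge iff bits(p,q) >= the best
    cross-genome bit score of p AND of q — each is closer to the other than
    to any protein outside the genome.  ``weight_scheme`` 'bsr' weights
    edges by the mean of the two directed bit-score ratios; 'evalue' weights
    by -log10(e-value) capped at 300 (requires e-values on the hits) with
    per-node mean normalization in the OrthoMCL style.
    """
    if weight_scheme not in ("bsr", "evalue"):
        raise ValueError(f"unknown weight scheme {weight_scheme!r}")
    graph = nx.Graph()
    self_bits: dict[ProteinKey, float] = {}
    best_cross: dict[ProteinKey, float] = {}
    within: dict[tuple[ProteinKey, ProteinKey], SimilarityHit] = {}
    evalue_of: dict[tuple[ProteinKey, ProteinKey], float] = {}
    for h in hits:
        graph.add_node(h.query)
        graph.add_node(h.subject)
        if h.query == h.subject:
            self_bits[h.query] = h.bit_score
        elif h.query[0] == h.subject[0]:
            key = (min(h.query, h.subject), max(h.query, h.subject))
            within.setdefault(key, h)
        else:
            if h.bit_score > best_cross.get(h.query, 0.0):
                best_cross[h.query] = h.bit_score
        if h.e_value is not None:
            evalue_of[(h.query, h.subject)] = h.e_value

    def edge_weight(a: ProteinKey, b: ProteinKey, bsr_weight: float) -> float:
        if weight_scheme == "bsr":
            return bsr_weight
        ev = evalue_of.get((a, b), evalue_of.get((b, a)))
        if ev is None:
            raise ValueError("weight_scheme 'evalue' requires e-values on hits")
        return 300.0 if ev <= 0 else min(300.0, -np.log10(ev))

    for pair in rbh_pairs:
        graph.add_edge(pair.a, pair.b, weight=edge_weight(pair.a, pair.b, pair.mean_bsr))
    for (p, q), h in within.items():
        if h.bit_score >= best_cross.get(p, 0.0) and h.bit_score >= best_cross.get(q, 0.0):
            sp, sq = self_bits.get(p), self_bits.get(q)
            if sp is None or sq is None:
                raise ValueError(f"within-genome pair {p}/{q} lacks self-hits")
            bsr = 0.5 * (h.bit_score / sp + h.bit_score / sq)
            graph.add_edge(p, q, weight=edge_weight(p, q, bsr))
    if weight_scheme == "evalue":
        _normalize_evalue_weights(graph)
    return graph


def _normalize_evalue_weights(graph: nx.Graph) -> None:
    """OrthoMCL-style normalization: divide each edge by the mean incident weight."""
    mean_w = {
        n: float(np.mean([d["weight"] for _, _, d in graph.edges(n, data=True)]) or 1.0)
        for n in graph.nodes
        if graph.degree(n) > 0
    }
    for u, v, d in graph.edges(data=True):
        d["weight"] = d["weight"] / (0.5 * (mean_w[u] + mean_w[v]))


def markov_cluster(
    graph: nx.Graph,
    inflation: float = 1.5,
    prune_threshold: float = 1e-5,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> list[frozenset[ProteinKey]]:
    """Partition the graph's nodes by MCL; run per connected component.

    MCL flow never crosses between components, so clustering each component
    separately is exact and keeps the matrices small.
    """
    clusters: list[frozenset[ProteinKey]] = []
    for comp in nx.connected_components(graph):
        nodes = sorted(comp)
        if len(nodes) == 1:
            clusters.append(frozenset(nodes))
            continue
        index = {n: i for i, n in enumerate(nodes)}
        A = np.zeros((len(nodes), len(nodes)))
        for u, v, d in graph.subgraph(comp).edges(data=True):
            A[index[u], index[v]] = A[index[v], index[u]] = d["weight"]
        for part in mcl_partition(A, inflation, prune_threshold, tol, max_iter):
            clusters.append(frozenset(nodes[i] for i in part))
    return clusters


def assemble_families(
    partition: Iterable[frozenset[ProteinKey]],
    genome_order: Sequence[str],
) -> tuple[list[ProteinFamily], list[ProteinKey]]:
    """Number clusters of size >= 2 into families; return (families, singletons).

    Families are numbered by decreasing size, ties by lexicographically
    smallest member, so numbering is deterministic.  Singleton clusters are
    returned separately: they are proteins found in only one copy overall.
    """
    clusters = [c for c in partition if len(c) >= 2]
    singletons = sorted(p for c in partition if len(c) == 1 for p in c)
    clusters.sort(key=lambda c: (-len(c), min(c)))
    families = [
        ProteinFamily(
            family_id=i + 1,
            members=c,
            pattern=phyletic_pattern_text({g for g, _ in c}, genome_order),
        )
        for i, c in enumerate(clusters)
    ]
    return families, singletons


def phyletic_pattern(family: ProteinFamily, genome_order: Sequence[str]) -> str:
    if not family.members:
        raise ValueError("empty family has no phyletic pattern")
    return phyletic_pattern_text(family.genomes_present(), genome_order)


def pattern_census(
    families: list[ProteinFamily],
    singletons: list[ProteinKey],
    genome_order: Sequence[str],
) -> list[dict]:
    """Pattern -> (family count, protein count, percent of ALL proteins).

    Percentages use the full protein total (family members plus singletons)
    as denominator and are rounded to whole percent, half away from zero.
    Singletons are tallied under their own single-genome patterns with
    family count 0 contribution (they are not families).
    """
    total = sum(f.size for f in families) + len(singletons)
    rows: dict[str, dict] = {}
    for f in families:
        row = rows.setdefault(f.pattern, {"pattern": f.pattern, "families": 0, "proteins": 0})
        row["families"] += 1
        row["proteins"] += f.size
    for g, _ in singletons:
        pat = phyletic_pattern_text({g}, genome_order)
        row = rows.setdefault(pat, {"pattern": pat, "families": 0, "proteins": 0})
        row["proteins"] += 1
    out = sorted(rows.values(), key=lambda r: (-r["proteins"], r["pattern"]))
    for row in out:
        row["pct_of_proteins"] = round_half_away(100.0 * row["proteins"] / total) if total else 0.0
    return out


def large_families(families: list[ProteinFamily], min_size: int = 10) -> list[ProteinFamily]:
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    return sorted((f for f in families if f.size >= min_size), key=lambda f: (-f.size, f.family_id))


def clade_specific_families(
    families: list[ProteinFamily], clade: set[str]
) -> list[ProteinFamily]:
    """Families present in every clade genome and in no genome outside it."""
    if not clade:
        raise ValueError("clade must be non-empty")
    return [f for f in families if f.genomes_present() == set(clade)]


def paralog_expansions(families: list[ProteinFamily]) -> list[tuple[ProteinFamily, dict[str, int]]]:
    """Families where some genome contributes >= 2 members (duplication signature)."""
    out = []
    for f in families:
        counts = f.per_genome_counts()
        if any(v >= 2 for v in counts.values()):
            out.append((f, counts))
    return out


def single_copy_universal(
    graph: nx.Graph,
    genome_order: Sequence[str],
    inflations: Sequence[float] = tuple(np.arange(1.1, 5.01, 0.3)),
    **mcl_kwargs,
) -> list[frozenset[ProteinKey]]:
    """Clusters with exactly one member per genome, under ANY swept inflation.

    The union over the inflation sweep is deduplicated by member-set
    identity; this is the marker-gene selection rule for the concatenated
    genome phylogeny.
    """
    if len(inflations) < 2:
        raise ValueError("sweep needs at least 2 inflation values")
    want = set(genome_order)
    seen: set[frozenset[ProteinKey]] = set()
    for inflation in inflations:
        for cluster in markov_cluster(graph, inflation=inflation, **mcl_kwargs):
            if len(cluster) == len(want):
                genomes = [g for g, _ in cluster]
                if set(genomes) == want and len(set(genomes)) == len(genomes):
                    seen.add(cluster)
    return sorted(seen, key=min)
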