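"""All-vs-all similarity: bit scores, reciprocal best hits, bit-score ratios.

The similarity layer is pluggable: either an external BLAST tabular file is
read (:func:`geoclade.io.read_similarity_table`) or the built-in pairwise
scorer computes exact Smith-Waterman local-alignment scores under BLOSUM62
with affine gaps (open 11, extend 1) and converts them to bits with the
ungapped Karlin-Altschul normalization ``bits = (lambda*S - ln K) / ln 2``
(lambda 0.267, K 0.041, the BLASTP defaults).  The built-in scorer computes
no e-values.

Conservation between reciprocal orthologs is expressed as the bit-score
ratio (BSR): the bit score of the pair divided by the query's self-match
bit score, 1.0 for identical sequences.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

from Bio import Align
from Bio.Align import substitution_matrices

from .io import ProteinKey, ProteomeSet, SimilarityHit

LN2 = math.log(2.0)


def _blosum62_x_neutral():
    """BLOSUM62 with the X row/column zeroed (ambiguity scores 0 vs everything)."""
    m = substitution_matrices.load("BLOSUM62")
    m = m.copy()
    for ch in m.alphabet:
        m["X", ch] = 0.0
        m[ch, "X"] = 0.0
    return m


@dataclass
class ScoringParams:
    """Alignment scoring and bits-normalization constants.

    gap_open is the cost of opening a gap (first gapped position costs
    gap_open + gap_extend, as in BLASTP's -11/-1 convention).
    """

    gap_open: float = 11.0
    gap_extend: float = 1.0
    lam: float = 0.267
    k: float = 0.041
    substitution_matrix: object = field(default_factory=_blosum62_x_neutral)

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")

    def bits(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.k)) / LN2

    def make_aligner(self, mode: str = "local") -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = self.substitution_matrix
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        aligner.mode = mode
        return aligner


@dataclass(frozen=True)
class RBHPair:
    """A reciprocal best hit across two genomes, with both directed BSRs."""

    a: ProteinKey
    b: ProteinKey
    bsr_ab: float  # bits(a,b) / bits(a,a)
    bsr_ba: float  # bits(b,a) / bits(b,b)

    @property
    def mean_bsr(self) -> float:
        return 0.5 * (self.bsr_ab + self.bsr_ba)


def score_pair(a: str, b: str, params: ScoringParams | None = None) -> tuple[float, float]:
    """Optimal local-alignment raw score of two sequences, and its bit score.

    Symmetric in its arguments; two sequences with no positive-scoring
    residue pair score 0 (the empty local alignment).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    params = params or ScoringParams()
    aligner = params.make_aligner("local")
    raw = float(aligner.score(a, b))
    return raw, params.bits(raw)


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def shared_kmer_counts(query_kmers: set[str], postings: dict[str, list]) -> Counter:
    """How many distinct k-mer words each database entry shares with the query."""
    counts: Counter = Counter()
    for kmer in query_kmers:
        counts.update(postings.get(kmer, ()))
    return counts


def all_vs_all(
    proteomes: ProteomeSet,
    params: ScoringParams | None = None,
    min_bits: float = 50.0,
    prescreen_k: int | None = 5,
    min_shared_kmers: int = 1,
) -> list[SimilarityHit]:
    """Score every ordered protein pair (cross- and within-genome).

    Hits below ``min_bits`` are dropped; self-hits are always retained (they
    are the BSR denominators).  When ``prescreen_k`` is set, only pairs
    sharing at least ``min_shared_kmers`` length-``prescreen_k`` words are
    aligned (via an inverted word index) — an exact filter in practice for
    the divergences this pipeline targets, and disableable
    (``prescreen_k=None``) for exhaustive scoring.
    """
    if len(proteomes.genomes) < 2:
        raise ValueError("all_vs_all needs at least 2 genomes")
    params = params or ScoringParams()
    aligner = params.make_aligner("local")
    keys = sorted(proteomes.proteins)
    seqs = {k: proteomes.proteins[k] for k in keys}
    hits: list[SimilarityHit] = []
    # self-hits: local self-alignment score = sum of diagonal matrix scores
    for k in keys:
        raw = float(aligner.score(seqs[k], seqs[k]))
        hits.append(SimilarityHit(k, k, raw, params.bits(raw)))
    if prescreen_k:
        postings: dict[str, list[ProteinKey]] = {}
        kmers = {}
        for k in keys:
            kmers[k] = _kmer_set(seqs[k], prescreen_k)
            for kmer in kmers[k]:
                postings.setdefault(kmer, []).append(k)
        pairs = set()
        for ka in keys:
            for kb, n_shared in shared_kmer_counts(kmers[ka], postings).items():
                if kb > ka and n_shared >= min_shared_kmers:
                    pairs.add((ka, kb))
        pair_iter = sorted(pairs)
    else:
        pair_iter = combinations(keys, 2)
    for ka, kb in pair_iter:
        raw = float(aligner.score(seqs[ka], seqs[kb]))
        bits = params.bits(raw)
        if bits < min_bits:
            continue
        hits.append(SimilarityHit(ka, kb, raw, bits))
        hits.append(SimilarityHit(kb, ka, raw, bits))
    return hits


def _best_subject(candidates: list[SimilarityHit]) -> SimilarityHit:
    """Highest bit score; ties by smaller e-value (when present), then ID."""

    def sort_key(h: SimilarityHit):
        ev = h.e_value if h.e_value is not None else 0.0
        return (-h.bit_score, ev, h.subject)

    return min(candidates, key=sort_key)


def reciprocal_best_hits(hits: list[SimilarityHit]) -> list[RBHPair]:
    """Reciprocal best cross-genome hits, with bit-score ratios attached.

    For each protein and each other genome, the best hit is the
    maximum-bit-score subject (ties by e-value, then lexicographic subject
    ID); a pair qualifies iff each member is the other's best hit in its
    genome.  Every protein with cross hits must have a self-hit, otherwise
    its ratio denominator is undefined.
    """
    self_bits: dict[ProteinKey, float] = {}
    by_query: dict[tuple[ProteinKey, str], list[SimilarityHit]] = {}
    pair_bits: dict[tuple[ProteinKey, ProteinKey], float] = {}
    for h in hits:
        if h.query == h.subject:
            self_bits[h.query] = h.bit_score
        else:
            pair_bits[(h.query, h.subject)] = h.bit_score
            if h.subject[0] != h.query[0]:
                by_query.setdefault((h.query, h.subject[0]), []).append(h)
    best: dict[tuple[ProteinKey, str], ProteinKey] = {}
    for (query, sgenome), cands in by_query.items():
        if query not in self_bits:
            raise ValueError(f"protein {query} has cross hits but no self-hit")
        best[(query, sgenome)] = _best_subject(cands).subject
    pairs: list[RBHPair] = []
    for (query, sgenome), subject in best.items():
        if query >= subject:  # emit each unordered pair once
            continue
        if best.get((subject, query[0])) != query:
            continue
        bits_ab = pair_bits[(query, subject)]
        bits_ba = pair_bits.get((subject, query), bits_ab)
        pairs.append(
            RBHPair(
                a=query,
                b=subject,
                bsr_ab=bit_score_ratio(bits_ab, self_bits[query]),
                bsr_ba=bit_score_ratio(bits_ba, self_bits[subject]),
            )
        )
    return sorted(pairs, key=lambda p: (p.a, p.b))


def bit_score_ratio(pair_bits: float, self_bits: float) -> float:
    """BSR = bits(query, subject) / bits(query, query); in (0, 1] under BLOSUM62."""
    if self_bits <= 0:
        raise ValueError("self bit score must be positive")
    return pair_bits / self_bits


def average_bsr(
    protein: ProteinKey, rbh_pairs: list[RBHPair], genomes: list[str]
) -> float | None:
    """Mean directed BSR of ``protein`` against its RBH partner in every other genome.

    Returns None unless the protein has a reciprocal ortholog in each of the
    other genomes (the "full reciprocal coverage" condition the conservation
    ranking requires).
    """
    ratios: dict[str, float] = {}
    for p in rbh_pairs:
        if p.a == protein:
            ratios[p.b[0]] = p.bsr_ab
        elif p.b == protein:
            ratios[p.a[0]] = p.bsr_ba
    others = [g for g in genomes if g != protein[0]]
    if set(ratios) != set(others):
        return None
    return sum(ratios.values()) / len(ratios)


def conservation_ranking(
    proteomes: ProteomeSet, rbh_pairs: list[RBHPair], genome: str, min_avg: float = 0.90
) -> list[tuple[ProteinKey, float]]:
    """Proteins of ``genome`` with full reciprocal coverage and avg BSR >= ``min_avg``.

    Sorted descending by average ratio, then by protein ID — the "best
    conserved proteins" table.
    """
    out = []
    for key in proteomes.genome_proteins(genome):
        avg = average_bsr(key, rbh_pairs, proteomes.genomes)
        if avg is not None and avg >= min_avg:
            out.append((key, avg))
    return sorted(out, key=lambda t: (-t[1], t[0]))
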