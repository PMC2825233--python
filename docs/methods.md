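# Methods

## Overview

`geoclade` implements the analysis chain of a small-clade comparative
proteomics study: an all-vs-all similarity layer, ortholog-family
construction by reciprocal best hits plus Markov clustering, phyletic
pattern and conservation statistics, a two-evidence c-type cytochrome
census, distance-based gene trees with bootstrap, and a sister-group
decision procedure for lateral gene transfer. A synthetic clade generator
with full ground truth backs every stage, so the pipeline's recovery
properties are measured rather than assumed.

## Similarity and bit scores

The built-in scorer computes exact optimal local alignments
(Smith-Waterman with affine gaps) under BLOSUM62, gap open 11 / extend 1,
via `Bio.Align.PairwiseAligner`. Raw scores are converted to bits with the
ungapped Karlin-Altschul normalization `bits = (λS − ln K)/ln 2` using the
BLASTP defaults λ = 0.267, K = 0.041. This mirrors the scoring regime
behind typical protein BLAST bit scores while staying self-contained; when
fidelity to a real BLAST run matters, an external tabular file (outfmt 6)
is read instead and its bits and e-values are used directly. No e-values
are computed internally (they depend on database size), so the built-in
path breaks best-hit ties by bits, then e-value when present, then
lexicographic subject ID — an invented but deterministic rule.

The ambiguity codes B, Z, U are accepted on input and mapped to X; X scores
0 against every residue (neutral handling). The self-score used as the BSR
denominator is the full local self-alignment, i.e. the sum of diagonal
matrix scores, so BSR = 1 exactly for identical sequences and, because
BLOSUM62 is diagonal-dominant, every ratio lies in (0, 1].

All-vs-all scoring prescreens pairs with an inverted index of length-5
words: only pairs sharing ≥ 1 word (≥ 2 for the transfer screen's homolog
search) are aligned. At the divergences this pipeline targets (per-branch
lengths ≤ 0.1, cross-genome identities ≳ 70%), related pairs share dozens
of words, so the prescreen is an exact filter in practice; it can be
disabled (`prescreen_k=None`), and the oracle-equivalence tests that
compare pair sets against an independent dense aligner run with it off.

## Ortholog families

The family graph has one edge per cross-genome reciprocal best hit and,
within genomes, a "recent paralog" edge for pairs (p, q) where
bits(p,q) ≥ the best cross-genome bits of p *and* of q. Edge weights are
mean directed BSRs; with external BLAST input an e-value scheme
(−log10 E capped at 300, per-node mean normalization in the OrthoMCL
style) is selectable instead. Markov clustering runs per connected
component (flow never crosses components, so this is exact): add
self-loops at each node's maximum incident weight, column-normalize, then
alternate expansion (matrix squaring) and inflation (entrywise power,
default 1.5, renormalize), pruning entries below 1e-5, until the iterate
changes by < 1e-6 (cap 300 iterations — the low end of the inflation sweep
legitimately needs 80–120). Clusters are connected components of the
converged matrix's non-zero structure. Clusters of size ≥ 2 become
numbered families (by size, then smallest member, so numbering is
deterministic); size-1 clusters are reported as singletons.

The marker-gene selection for genome phylogeny sweeps inflation 1.1–5.0
(step 0.3) and takes the union, deduplicated by member set, of clusters
with exactly one member per genome.

Phyletic patterns are fixed-width strings over the genome order
(`GsGmGuGfGbGl`), two characters per genome, `--` for absence. Pattern
census percentages are over **all** proteins (family members plus
singletons).

## Cytochrome census

A protein is a c-type cytochrome iff it has ≥ 1 CXXCH motif and ≥ 1
profile hit. The motif scan is left-to-right and non-overlapping (resume
after each match); overlapping counting is config-exposed because tandem
arrangements make the choice matter. X matches the two wildcard slots but
never the C/C/H anchors — the anchors are the chemically required
residues. Profile evidence is an identifier join against a supplied table
(the shipped 26-identifier c-type cytochrome profile list, or any other);
no profile scanner is run. Without a profile table the pipeline degrades
to the motif-only "minimal definition" and flags the census accordingly.

Census percentages are printed at 1 decimal; the clade-average row is the
arithmetic column mean with counts rounded to integer. All rounding in the
package is half-away-from-zero at the printed precision (whole percents
for coverage/pattern/conserved-cytochrome fractions, 1 decimal for the
transfer fractions); the report checker recomputes every printed fraction
from the printed counts.

## Trees

Distances are p-distances on pairwise global alignments (gap-containing
columns excluded), or on the supplied alignment when sequences are already
aligned; a Poisson correction (−ln(1 − p)) is config-exposed. Neighbor
joining follows the standard Q-criterion agglomeration with ties broken by
the lexicographically smallest label pair (a working node's key is the
smallest leaf label beneath it), making output deterministic; negative
branch-length estimates are clamped to 0 with a warning. Bootstrap
supports are percentages of column-resampled replicate trees containing
each nontrivial bipartition of the full-data tree. Supports are keyed by
bipartition, not by node, so rerooting (e.g. midpoint rooting before the
transfer rules) re-annotates them by lookup rather than trusting node
identity across reroots. Fitch parsimony is the usual bottom-up
intersection/union pass; ambiguity is preserved as a state set.

## Lateral transfer decision procedure

Gene trees are midpoint-rooted. Let S be the query's sibling subtree and T
the sibling subtree at its grandparent. The query is a **candidate** iff
(S is entirely out-group and the edge subtending {query}∪S has bootstrap
≥ 50) or (that edge is weak and the best database hit is out-group).
Candidates are **confirmed** as transfers by a single out-group leaf at T;
a single in-group leaf rejects; if T is a clade or weakly attached, the
Fitch ancestral state of T decides, with ambiguous states rejecting
(conservative: minimizes false transfer calls). A query too close to the
root for a grandparent is rejected as topologically insufficient. The
support threshold direction (≥ 50 = strong) and value are config-exposed.

The screen selects, per query, the top-25 database homologs by bit score
(≥ 50 bits); tree taxa are additionally restricted to homologs the query
can be column-aligned with (equal length — the generator is indel-free, so
equal length is alignment; for real data, supply aligned homolog sets),
while the best-hit flag uses the overall top scorer. Queries with < 3
usable homologs are vertical by insufficient evidence. Bootstrap
replicates (default 100) are computed lazily: a query whose sibling group
contains an in-group leaf while its best hit is in-group is vertical at
every support value, so most vertical proteins never pay for replicates;
verdicts are identical to the eager procedure.

## Synthetic clade generator

Defaults are the package's study conditions: 6 in-group taxa on a fixed
species tree (two "model-organism" taxa, a three-taxon subsurface-style
clade, one deep branch; per-branch lengths ≤ 0.1 expected
substitutions/site), 200 families, mean protein length 300 (gamma-drawn
per family, floor 60), duplication/loss/transfer probabilities 0 unless
enabled, cytochrome fraction 0.03 (roughly the fraction of cytochrome
families seen in cytochrome-rich clades), donor pool of 8 lineages.

Substitution model: Poisson(t·L) events per branch, each rewriting a
uniformly chosen unprotected site with a uniformly chosen different
residue. This uniform model is deliberately simple — downstream logic
depends on divergence, not on matrix realism — and keeps the Monte-Carlo
oracle closed-form: the expected per-site difference after time t is
(19/20)(1 − e^(−20t/19)), which the generator reproduces within
Monte-Carlo error.

Planted cytochromes carry h CXXCH motifs (h ~ 15% single-heme, else
2 + Poisson(6.9); mean ≈ 7.7, matching the observed census shape) at
evenly spaced, substitution-protected positions, and every descendant copy
emits a synthetic profile ID; a false-positive profile noise rate is
available (default 0). Lateral transfer replaces one uniformly chosen
surviving in-group copy with a fresh sequence evolved from that family's
*donor ancestor* — an independent random sequence (same length, same
planted motifs), also evolved into the donor-pool lineages. A transferred
gene's true relatives are therefore the donor lineages, not its sister
species, which is the recent-transfer phenotype the screen is designed to
detect. The truth table keeps the transferred protein in its family slot
and records the event separately.

What the generator does **not** emulate: indels (all family copies stay
column-aligned), rate heterogeneity, codon structure, domain
architectures, and partial ORFs from draft assemblies. Passing tests
therefore demonstrate the pipeline's logic and its recovery behaviour
under clean divergence, not robustness to alignment error or annotation
noise on real proteomes. No length filter is applied on input (draft
genomes with partial ORFs are taken as annotated).

## Published-count arithmetic

The per-genome cytochrome census counts and six-genome totals of the
original *Geobacter* comparison are shipped as a small reference table
(`geoclade.datasets`). Only counts are stored; the acceptance script and
tests recompute every derived average and percentage (cytochromes per
genome, multiheme fraction, hemes per cytochrome, the family-coverage,
pattern, conserved-cytochrome and transfer fractions) through the same
calculators the pipeline uses on simulated data. The full-scale counts
themselves (e.g. 4,062 families from 22,434 proteins) depend on the six
real proteomes and a specific BLAST/profile-scanner run and are not
recomputed here; the published total of 22,434 proteins is used as the
canonical denominator where the source reports two totals, and the
published per-genome transfer-cytochrome list (which sums to 17 against a
printed 19) is left unreconciled.

## Problem sizes and determinism

The shipped analyses and acceptance run use 200-family clades
(1,200 proteins), 100 bootstrap replicates, and 8-donor pools — sizes
chosen so the full chain, including two transfer screens, completes in
about a minute on one CPU while leaving every decision rule exercised.
All randomness flows from a single integer seed through named substreams
(`numpy` `SeedSequence` spawning), so simulation output, bootstrap
supports and screen verdicts are byte-reproducible; per-query replicate
seeds are derived with CRC32 of the protein ID, never Python's salted
`hash`.

## Known limitations

- The built-in scorer computes no e-values; statistics needing them
  (OrthoMCL-style e-value weighting) require external BLAST input.
- The transfer screen consumes equal-length (pre-aligned) homolog sets;
  unaligned homolog databases need an external aligner first.
- MCL on very low inflation (< 1.2) converges slowly and can, on
  pathological graphs, stop at the iteration cap with a warning.
- The decision procedure's "nearest relative" is operationalized as the
  sibling subtree under midpoint rooting; other rootings can change
  verdicts for queries near the root.
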