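"""Synthetic clade generator with ground truth.

Emulates the statistical structure of a six-genome comparative study: gene
families evolved down a known species tree with per-branch duplication and
loss, a subset of families planted as multiheme c-type cytochromes (CXXCH
motifs at protected positions plus a synthetic profile hit for every
descendant copy), and a subset of families hit by lateral transfer (one
in-group copy replaced by a sequence from an independently evolved donor
pool).  Every protein's true family, every planted heme count and every
transfer event is recorded in a truth table, so family recovery, cytochrome
recall and transfer detection can be scored exactly.

Substitution model: the number of events on a branch of length ``t``
(expected substitutions/site) is Poisson(t * L); each event rewrites one
uniformly chosen unprotected site with a uniformly chosen different residue.
Protected intervals (the planted motif columns) are never altered.  No
indels, so all copies in a family stay equal-length and column-aligned.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from skbio import TreeNode

from .io import ProfileHitTable, ProteinKey, ProteomeSet, write_proteomes
from .util import child_rng

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)

#: default six-taxon species tree: two model organisms (Gs, Gm), a
#: three-taxon subsurface clade (Gu, Gf, Gb), and Gl as the deepest branch;
#: per-branch lengths <= 0.1 expected substitutions/site.
DEFAULT_SPECIES_TREE = (
    "(((Gs:0.05,Gm:0.05):0.03,((Gu:0.04,Gf:0.04):0.02,Gb:0.06):0.03):0.02,Gl:0.09);"
)


def default_heme_count_law(rng: np.random.Generator) -> int:
    """Planted CXXCH copies per cytochrome: ~15% single-heme, mean ~7.7.

    Mixture of a point mass at 1 and 2 + Poisson(6.9) for the multiheme
    class, mirroring the observed census shape (most cytochromes multiheme,
    7-8 hemes per cytochrome on average).
    """
    if rng.random() < 0.15:
        return 1
    return 2 + int(rng.poisson(6.9))


@dataclass
class SimulationParams:
    """Knobs of the synthetic clade; defaults are the package's study conditions."""

    species_tree: str = DEFAULT_SPECIES_TREE
    n_families: int = 200
    duplication_prob: float = 0.0   # per-family per-branch
    loss_prob: float = 0.0          # per-family per-branch
    lgt_prob: float = 0.0           # per-family probability of one donor replacement
    cytochrome_fraction: float = 0.03
    heme_count_law: Callable[[np.random.Generator], int] = field(
        default=default_heme_count_law
    )
    mean_protein_length: int = 300
    donor_pool_size: int = 8
    donor_branch_length: float = 0.05
    profile_noise: float = 0.0      # false-positive profile-hit rate per non-cytochrome
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duplication_prob", "loss_prob", "lgt_prob", "cytochrome_fraction", "profile_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mean_protein_length < 30:
            raise ValueError("mean_protein_length must be >= 30")


@dataclass
class TruthTable:
    """Ground truth of a simulated clade."""

    family_of: dict[ProteinKey, int]
    is_cytochrome: dict[int, int]      # family -> planted heme count (0 = not planted)
    lgt_events: set[ProteinKey]        # donor-replaced proteins
    pattern_of: dict[int, str]         # family -> true phyletic pattern

    def family_members(self) -> dict[int, set[ProteinKey]]:
        out: dict[int, set[ProteinKey]] = {}
        for key, fam in self.family_of.items():
            out.setdefault(fam, set()).add(key)
        return out

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("genome\tprotein\tfamily\tplanted_hemes\tlgt\tfamily_pattern\n")
            for (g, p), fam in sorted(self.family_of.items()):
                fh.write(
                    f"{g}\t{p}\t{fam}\t{self.is_cytochrome.get(fam, 0)}\t"
                    f"{int((g, p) in self.lgt_events)}\t{self.pattern_of[fam]}\n"
                )


@dataclass
class SimulationResult:
    """Outputs of :func:`simulate_clade`; the first three are the core triple."""

    proteomes: ProteomeSet
    profiles: ProfileHitTable
    truth: TruthTable
    donor_proteins: dict[str, str]     # donor-pool sequences, ID -> sequence
    donor_family_of: dict[str, int]    # donor ID -> family it is homologous to

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_proteomes(self.proteomes, outdir)
        with open(outdir / "profile_hits.tsv", "w") as fh:
            for (g, p), profs in sorted(self.profiles.hits.items()):
                for prof in sorted(profs):
                    fh.write(f"{g}\t{p}\t{prof}\n")
        self.truth.write_tsv(outdir / "truth.tsv")
        with open(outdir / "donor_pool.faa", "w") as fh:
            for pid, seq in sorted(self.donor_proteins.items()):
                fh.write(f">{pid}\n{seq}\n")


def _parse_intervals(protected: list[tuple[int, int]], length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for start, end in protected:
        if not (1 <= start <= end <= length):
            raise ValueError(f"protected interval ({start}, {end}) out of range for length {length}")
        mask[start - 1 : end] = True
    return mask


def evolve_sequence(
    seq: str,
    t: float,
    protected: list[tuple[int, int]] | None = None,
    rng: np.random.Generator | int = 0,
) -> str:
    """Evolve ``seq`` for branch length ``t`` under the Poisson substitution model.

    ``Poisson(t * len(seq))`` substitution events; each rewrites a uniformly
    chosen unprotected site with a uniformly chosen different residue.
    1-based closed ``protected`` intervals are never altered.
    """
    if t < 0:
        raise ValueError("branch length must be non-negative")
    if isinstance(rng, (int, np.integer)):
        rng = child_rng(int(rng))
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    mask = _parse_intervals(protected or [], len(arr))
    free = np.flatnonzero(~mask)
    if t == 0 or free.size == 0:
        return seq
    n_events = int(rng.poisson(t * len(arr)))
    for _ in range(n_events):
        site = int(free[rng.integers(free.size)])
        alternatives = _AA[_AA != arr[site]]
        arr[site] = alternatives[rng.integers(alternatives.size)]
    return arr.tobytes().decode()


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), size=length))


def _plant_motifs(seq: str, n_motifs: int, rng: np.random.Generator) -> tuple[str, list[tuple[int, int]]]:
    """Write ``n_motifs`` CXXCH motifs at evenly spaced positions; return intervals."""
    arr = list(seq)
    length = len(arr)
    stride = length // (n_motifs + 1)
    intervals = []
    for m in range(n_motifs):
        start = (m + 1) * stride - 2  # 0-based start of the 5-mer
        # wildcards drawn away from C/H so planting never creates overlapping motifs
        inner_pool = AMINO_ACIDS.replace("C", "").replace("H", "")
        motif = ["C", *(inner_pool[i] for i in rng.integers(0, len(inner_pool), size=2)), "C", "H"]
        arr[start : start + 5] = motif
        intervals.append((start + 1, start + 5))  # 1-based closed
    return "".join(arr), intervals


def _evolve_family_down_tree(
    tree: TreeNode,
    ancestor: str,
    protected: list[tuple[int, int]],
    dup_p: float,
    loss_p: float,
    rng: np.random.Generator,
) -> dict[str, list[str]]:
    """Evolve copies down the species tree; returns genome -> surviving sequences.

    At the start of each branch every incoming copy is independently lost
    with ``loss_p``; surviving copies duplicate with ``dup_p`` (both copies
    then evolve independently along the branch).
    """

    def descend(node: TreeNode, copies: list[str]) -> dict[str, list[str]]:
        if node.parent is not None:  # apply branch events
            survivors: list[str] = []
            for c in copies:
                if rng.random() < loss_p:
                    continue
                survivors.append(c)
                if rng.random() < dup_p:
                    survivors.append(c)
            t = node.length or 0.0
            copies = [evolve_sequence(c, t, protected, rng) for c in survivors]
        if node.is_tip():
            return {node.name: copies}
        out: dict[str, list[str]] = {}
        for child in node.children:
            out.update(descend(child, copies))
        return out

    return descend(tree, [ancestor])


def simulate_clade(params: SimulationParams) -> SimulationResult:
    """Simulate a clade of proteomes with known families, cytochromes and LGT.

    Identical parameters and seed give byte-identical outputs.  Each family
    additionally seeds a homologous donor family in the out-group donor pool
    (independent random ancestor, hence non-homologous to the in-group
    family); transfer events replace one in-group copy with a fresh sequence
    evolved from that donor ancestor, so a transferred gene's true relatives
    are the donor lineages, not its genome's sister species.
    """
    tree = TreeNode.read(_stdio.StringIO(params.species_tree))
    genome_order = [t.name for t in tree.tips()]
    if len(genome_order) < 2:
        raise ValueError("species tree must have at least 2 leaves")
    # canonical display order: keep the conventional Gs..Gl order when the
    # default roster is used, else the tree's tip order
    canonical = ["Gs", "Gm", "Gu", "Gf", "Gb", "Gl"]
    if set(genome_order) == set(canonical):
        genome_order = canonical

    master = child_rng(params.seed)
    n = params.n_families
    n_cyt = int(round(params.cytochrome_fraction * n))
    cyt_families = set(master.choice(n, size=n_cyt, replace=False).tolist()) if n_cyt else set()
    lgt_families = {f for f in range(n) if master.random() < params.lgt_prob}

    proteins: dict[ProteinKey, str] = {}
    profile_hits: dict[ProteinKey, set[str]] = {}
    family_of: dict[ProteinKey, int] = {}
    is_cytochrome: dict[int, int] = {}
    lgt_events: set[ProteinKey] = set()
    pattern_of: dict[int, str] = {}
    donor_proteins: dict[str, str] = {}
    donor_family_of: dict[str, int] = {}

    for fam in range(n):
        rng = child_rng(params.seed, 1, fam)
        length = max(60, int(round(rng.gamma(6.0, params.mean_protein_length / 6.0))))
        hemes = 0
        protected: list[tuple[int, int]] = []
        ancestor = _random_sequence(length, rng)
        if fam in cyt_families:
            hemes = params.heme_count_law(rng)
            length = max(length, hemes * 12 + 40)
            ancestor = _random_sequence(length, rng)
            ancestor, protected = _plant_motifs(ancestor, hemes, rng)
        is_cytochrome[fam] = hemes

        leaf_copies = _evolve_family_down_tree(
            tree, ancestor, protected, params.duplication_prob, params.loss_prob, rng
        )

        # donor family: independent ancestor of the same length, same planted
        # motifs, evolved into donor_pool_size out-group lineages
        donor_anc = _random_sequence(length, rng)
        if hemes:
            donor_anc, _ = _plant_motifs(donor_anc, hemes, rng)
        for d in range(params.donor_pool_size):
            t_d = params.donor_branch_length * (1.0 + 0.5 * d / max(1, params.donor_pool_size - 1))
            did = f"D{fam:04d}_{d}"
            donor_proteins[did] = evolve_sequence(donor_anc, t_d, protected, rng)
            donor_family_of[did] = fam

        # register surviving copies
        fam_keys: list[ProteinKey] = []
        for genome in genome_order:
            for copy_idx, seq in enumerate(leaf_copies.get(genome, [])):
                suffix = "" if copy_idx == 0 else chr(ord("a") + copy_idx)
                key = (genome, f"{genome}_{fam:04d}{suffix}")
                proteins[key] = seq
                family_of[key] = fam
                fam_keys.append(key)

        # lateral replacement: one uniformly chosen surviving copy
        if fam in lgt_families and fam_keys:
            victim = fam_keys[int(rng.integers(len(fam_keys)))]
            proteins[victim] = evolve_sequence(donor_anc, params.donor_branch_length, protected, rng)
            lgt_events.add(victim)

        if hemes:
            for key in fam_keys:
                profile_hits.setdefault(key, set()).add(f"SYNCYT{fam:04d}")

        present = {g for (g, _p) in fam_keys}
        pattern_of[fam] = "".join(g if g in present else "--" for g in genome_order)

    if params.profile_noise > 0:
        noise_rng = child_rng(params.seed, 2)
        for key in sorted(proteins):
            if is_cytochrome.get(family_of[key], 0) == 0 and noise_rng.random() < params.profile_noise:
                profile_hits.setdefault(key, set()).add("SYNNOISE")

    proteomes = ProteomeSet(genomes=genome_order, proteins=proteins)
    return SimulationResult(
        proteomes=proteomes,
        profiles=ProfileHitTable(hits=profile_hits),
        truth=TruthTable(
            family_of=family_of,
            is_cytochrome=is_cytochrome,
            lgt_events=lgt_events,
            pattern_of=pattern_of,
        ),
        donor_proteins=donor_proteins,
        donor_family_of=donor_family_of,
    )
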