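"""Input/output for every external format the pipeline touches.

Formats: protein FASTA (one file per genome), BLAST tabular (outfmt 6),
2+-column TSV of profile hits, and newick trees whose internal-node labels
carry integer bootstrap supports.  Parsing is strict: dangling references,
duplicate IDs and malformed rows are hard errors, never silent drops.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from skbio import TreeNode

#: residues allowed after normalization: the 20 standard amino acids plus X.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")
#: ambiguity codes accepted on input and mapped to X for scoring.
AMBIGUOUS_TO_X = {"B": "X", "Z": "X", "U": "X", "J": "X", "O": "X"}

ProteinKey = tuple[str, str]  # (genome code, protein ID)


@dataclass
class ProteomeSet:
    """All proteins of all genomes, keyed by (genome code, protein ID).

    ``genomes`` fixes the genome order used everywhere a phyletic pattern is
    printed; ``proteins`` maps ``(code, protein_id)`` to an uppercase
    amino-acid sequence over the 20 residues plus X.
    """

    genomes: list[str]
    proteins: dict[ProteinKey, str]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = {g for g, _ in self.proteins} - set(self.genomes)
        if unknown:
            raise ValueError(f"proteins reference genomes not in roster: {sorted(unknown)}")

    def genome_proteins(self, genome: str) -> list[ProteinKey]:
        return [k for k in self.proteins if k[0] == genome]

    def counts(self) -> dict[str, int]:
        out = {g: 0 for g in self.genomes}
        for g, _ in self.proteins:
            out[g] += 1
        return out

    def __len__(self) -> int:
        return len(self.proteins)

    def genome_of(self, protein_id: str) -> str:
        """Resolve a bare protein ID to its genome; IDs must be globally unique."""
        idx = self._id_index()
        if protein_id not in idx:
            raise ValueError(f"protein ID {protein_id!r} not found in any genome")
        return idx[protein_id]

    def _id_index(self) -> dict[str, str]:
        idx = getattr(self, "_idx", None)
        if idx is None:
            idx = {}
            for g, p in self.proteins:
                if p in idx and idx[p] != g:
                    raise ValueError(f"protein ID {p!r} occurs in two genomes; cannot resolve bare IDs")
                idx[p] = g
            self._idx = idx
        return idx


@dataclass(frozen=True)
class SimilarityHit:
    """One scored, directed pair of proteins."""

    query: ProteinKey
    subject: ProteinKey
    raw_score: float
    bit_score: float
    e_value: float | None = None


@dataclass
class ProfileHitTable:
    """Map (genome, protein) -> set of profile identifiers (opaque strings)."""

    hits: dict[ProteinKey, set[str]] = field(default_factory=dict)

    def profiles_for(self, key: ProteinKey) -> frozenset[str]:
        return frozenset(self.hits.get(key, ()))

    def check_against(self, proteomes: ProteomeSet) -> None:
        dangling = [k for k in self.hits if k not in proteomes.proteins]
        if dangling:
            raise ValueError(f"profile hits reference unknown proteins: {sorted(dangling)[:5]}")


def _normalize_sequence(seq: str, where: str) -> str:
    seq = seq.upper().rstrip("*")
    out = []
    for i, ch in enumerate(seq, start=1):
        ch = AMBIGUOUS_TO_X.get(ch, ch)
        if ch not in STANDARD_RESIDUES:
            raise ValueError(f"illegal residue {ch!r} at position {i} in {where}")
        out.append(ch)
    if not out:
        raise ValueError(f"empty sequence in {where}")
    return "".join(out)


def read_proteomes(
    paths: Iterable[str | Path],
    genome_codes: Iterable[str],
    metadata: Mapping[str, str] | None = None,
) -> ProteomeSet:
    """Read one protein FASTA per genome into a :class:`ProteomeSet`.

    The record ID is the header token up to the first whitespace (NCBI
    convention); sequences are uppercased, trailing stop characters (``*``)
    stripped, and the ambiguity codes B/Z/U mapped to X.  Duplicate IDs
    within a genome and residues outside the 20+X alphabet are hard errors.
    """
    paths = [Path(p) for p in paths]
    codes = list(genome_codes)
    if len(paths) != len(codes):
        raise ValueError("paths and genome_codes must be parallel lists")
    if len(set(codes)) != len(codes):
        raise ValueError("genome codes must be unique")
    proteins: dict[ProteinKey, str] = {}
    for path, code in zip(paths, codes):
        n_before = len(proteins)
        for rec in SeqIO.parse(str(path), "fasta"):
            pid = rec.id  # Bio.SeqIO already truncates at first whitespace
            key = (code, pid)
            if key in proteins:
                raise ValueError(f"duplicate protein ID {pid!r} in genome {code} ({path})")
            proteins[key] = _normalize_sequence(str(rec.seq), f"{code}:{pid}")
        if len(proteins) == n_before:
            raise ValueError(f"no FASTA records in {path} (genome {code})")
    return ProteomeSet(genomes=codes, proteins=proteins, metadata=dict(metadata or {}))


def write_proteomes(proteomes: ProteomeSet, outdir: str | Path, width: int = 60) -> dict[str, Path]:
    """Write one ``<code>.faa`` per genome; returns code -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out = {}
    for code in proteomes.genomes:
        path = outdir / f"{code}.faa"
        with open(path, "w") as fh:
            for (g, pid), seq in sorted(proteomes.proteins.items()):
                if g != code:
                    continue
                fh.write(f">{pid}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
        out[code] = path
    return out


def read_similarity_table(
    path: str | Path, id_to_genome: Mapping[str, str]
) -> list[SimilarityHit]:
    """Parse BLAST tabular (outfmt 6) rows into :class:`SimilarityHit` objects.

    Query/subject IDs are resolved to (genome, protein) through
    ``id_to_genome``; an unresolvable ID or a row without exactly 12 columns
    is a hard error naming the line.
    """
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}")
            q, s = fields[0], fields[1]
            for pid in (q, s):
                if pid not in id_to_genome:
                    raise ValueError(f"{path}:{lineno}: protein ID {pid!r} not resolvable to a genome")
            try:
                evalue = float(fields[10])
                bits = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field: {exc}") from None
            hits.append(
                SimilarityHit(
                    query=(id_to_genome[q], q),
                    subject=(id_to_genome[s], s),
                    raw_score=bits,  # raw score is not in outfmt 6; carry bits
                    bit_score=bits,
                    e_value=evalue,
                )
            )
    return hits


def read_profile_hits(path: str | Path) -> ProfileHitTable:
    """Read a tab-separated (protein ID or genome\\tprotein, profile ID) table.

    Two layouts are accepted: 2 columns ``protein_id<TAB>profile_id`` (genome
    resolved later against the ProteomeSet) or 3+ columns
    ``genome<TAB>protein_id<TAB>profile_id``; extra columns are ignored.
    Duplicate lines collapse under set semantics.
    """
    table = ProfileHitTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 tab-separated columns")
            if len(fields) == 2:
                key: ProteinKey = ("", fields[0])
                profile = fields[1]
            else:
                key = (fields[0], fields[1])
                profile = fields[2]
            if not profile:
                raise ValueError(f"{path}:{lineno}: empty profile identifier")
            table.hits.setdefault(key, set()).add(profile)
    return table


def resolve_profile_hits(table: ProfileHitTable, proteomes: ProteomeSet) -> ProfileHitTable:
    """Fill in genome codes for 2-column profile tables and validate the join."""
    resolved = ProfileHitTable()
    for (g, pid), profs in table.hits.items():
        if g == "":
            g = proteomes.genome_of(pid)
        if (g, pid) not in proteomes.proteins:
            raise ValueError(f"profile hit references unknown protein ({g!r}, {pid!r})")
        resolved.hits.setdefault((g, pid), set()).update(profs)
    return resolved


# ---------------------------------------------------------------------------
# newick trees


def read_tree(source: str | Path) -> TreeNode:
    """Parse a newick string or file into a tree.

    Internal node labels, when numeric, are bootstrap supports in [0, 100]
    and are exposed as ``node.support`` (int); branch lengths must be
    non-negative.
    """
    text = Path(source).read_text() if isinstance(source, Path) else str(source)
    if isinstance(source, str) and "(" not in source and Path(source).exists():
        text = Path(source).read_text()
    try:
        tree = TreeNode.read(_stdio.StringIO(text), convert_underscores=False)
    except Exception as exc:
        raise ValueError(f"newick parse error: {exc}") from None
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            raise ValueError(f"negative branch length {node.length} in newick input")
        node.support_value = None
        if not node.is_tip() and node.name not in (None, ""):
            try:
                sup = int(round(float(node.name)))
            except ValueError:
                continue
            if not 0 <= sup <= 100:
                raise ValueError(f"support {node.name!r} outside [0, 100]")
            node.support_value = sup
    return tree


def write_tree(tree: TreeNode, path: str | Path | None = None) -> str:
    """Serialize a tree to newick, supports as internal labels, lengths to 6 dp."""

    def fmt(node: TreeNode) -> str:
        if node.is_tip():
            base = node.name or ""
        else:
            inner = ",".join(fmt(c) for c in node.children)
            sup = getattr(node, "support_value", None)
            label = "" if sup is None else str(int(sup))
            base = f"({inner}){label}"
        if node.length is not None:
            base += f":{node.length:.6f}".rstrip("0").rstrip(".")
            if base.endswith(":"):
                base += "0"
        return base

    text = fmt(tree) + ";"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
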