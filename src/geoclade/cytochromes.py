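"""c-type cytochrome identification and census.

A protein is called a c-type cytochrome under the two-evidence rule: its
sequence contains at least one covalent heme-binding motif CXXCH (cysteine,
any, any, cysteine, histidine) AND it matches at least one c-type cytochrome
sequence profile (profile hits are consumed as an external table; matching is
an identifier join, not a scan).  A motif-only census (>=1 CXXCH, profiles
ignored) is kept as the minimal definition.  Multiheme cytochromes carry
more than one motif.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .io import ProfileHitTable, ProteinKey, ProteomeSet
from .families import ProteinFamily
from .util import round_half_away

#: the 26 c-type cytochrome sequence profiles used for the published census
#: (InterPro/SUPERFAMILY identifiers; the list as published repeats two IDs).
CYTOCHROME_PROFILE_IDS = (
    "IPR000298", "IPR000763", "IPR000883", "IPR001128", "IPR002016",
    "IPR002321", "IPR002322", "IPR002585", "IPR003317", "IPR004203",
    "IPR009056", "IPR010176", "IPR010177", "IPR010255", "IPR010960",
    "IPR011031", "IPR011048", "IPR012282", "IPR012292",
    "SSF47175", "SSF48613", "SSF48695", "SSF81342", "SSF81648",
)


@dataclass(frozen=True)
class CytochromeCall:
    """Per-protein cytochrome verdict with heme-motif count and positions."""

    protein: ProteinKey
    heme_count: int
    heme_positions: tuple[int, ...]  # 1-based motif start positions
    profile_ids: frozenset[str]
    is_cytochrome: bool


def count_heme_motifs(sequence: str, overlap: bool = False) -> tuple[int, list[int]]:
    """Count CXXCH motifs left-to-right; returns (count, 1-based start positions).

    The two wildcard slots match the 20 residues and X; the C/C/H anchors
    must be literal (X never anchors).  By default matches do not overlap:
    the scan resumes after each match; ``overlap=True`` resumes one position
    after each match start instead.
    """
    positions: list[int] = []
    i = 0
    while i + 5 <= len(sequence):
        if (
            sequence[i] == "C"
            and sequence[i + 3] == "C"
            and sequence[i + 4] == "H"
        ):
            positions.append(i + 1)
            i += 1 if overlap else 5
        else:
            i += 1
    return len(positions), positions


def call_cytochromes(
    proteomes: ProteomeSet,
    profiles: ProfileHitTable | None,
    cytochrome_profiles: frozenset[str] | None = None,
    overlap: bool = False,
) -> list[CytochromeCall]:
    """One :class:`CytochromeCall` per protein under the two-evidence rule.

    ``cytochrome_profiles`` restricts which profile identifiers count as
    cytochrome evidence (default: any identifier in the table).  With
    ``profiles=None`` every call has an empty profile set, so
    ``is_cytochrome`` is False for all and only the motif-only counts are
    meaningful.
    """
    if profiles is not None:
        profiles.check_against(proteomes)
    calls = []
    for key in sorted(proteomes.proteins):
        count, positions = count_heme_motifs(proteomes.proteins[key], overlap=overlap)
        profs = profiles.profiles_for(key) if profiles is not None else frozenset()
        if cytochrome_profiles is not None:
            profs = profs & cytochrome_profiles
        calls.append(
            CytochromeCall(
                protein=key,
                heme_count=count,
                heme_positions=tuple(positions),
                profile_ids=profs,
                is_cytochrome=bool(count >= 1 and profs),
            )
        )
    return calls


@dataclass(frozen=True)
class CensusRow:
    """Per-genome cytochrome statistics (one row of the census table)."""

    genome: str
    orfs: int
    cytochromes: int
    pct_genome: float          # cytochromes / ORFs * 100, 1 decimal
    multiheme: int             # cytochromes with heme_count > 1
    pct_multiheme: float       # multiheme / cytochromes * 100, 1 decimal
    hemes_per_cytochrome: float  # mean heme_count over cytochromes, 1 decimal


def _row(genome: str, orfs: int, n_cyt: int, n_multi: int, mean_hemes: float) -> CensusRow:
    if n_cyt == 0:
        warnings.warn(f"genome {genome} has no cytochromes; multiheme statistics set to 0.0")
    return CensusRow(
        genome=genome,
        orfs=orfs,
        cytochromes=n_cyt,
        pct_genome=round_half_away(100.0 * n_cyt / orfs, 1) if orfs else 0.0,
        multiheme=n_multi,
        pct_multiheme=round_half_away(100.0 * n_multi / n_cyt, 1) if n_cyt else 0.0,
        hemes_per_cytochrome=round_half_away(mean_hemes, 1) if n_cyt else 0.0,
    )


def census(
    calls: list[CytochromeCall],
    orf_counts: dict[str, int],
    genome_order: list[str] | None = None,
) -> tuple[list[CensusRow], CensusRow]:
    """Per-genome census rows plus the clade-average row.

    The average row takes the arithmetic mean of each column over genomes:
    count columns are rounded to integer, percentages and mean-heme values
    to 1 decimal (half away from zero).
    """
    genomes = genome_order or sorted(orf_counts)
    if not genomes:
        raise ValueError("census needs at least one genome")
    rows = []
    for g in genomes:
        mine = [c for c in calls if c.protein[0] == g and c.is_cytochrome]
        n_multi = sum(1 for c in mine if c.heme_count > 1)
        mean_hemes = sum(c.heme_count for c in mine) / len(mine) if mine else 0.0
        rows.append(_row(g, orf_counts[g], len(mine), n_multi, mean_hemes))
    return rows, average_census_row(rows)


def average_census_row(rows: list[CensusRow]) -> CensusRow:
    """Column-wise mean of per-genome census rows, at printed precision."""
    n = len(rows)
    if n == 0:
        raise ValueError("no census rows to average")
    return CensusRow(
        genome="average",
        orfs=int(round_half_away(sum(r.orfs for r in rows) / n)),
        cytochromes=int(round_half_away(sum(r.cytochromes for r in rows) / n)),
        pct_genome=round_half_away(sum(r.pct_genome for r in rows) / n, 1),
        multiheme=int(round_half_away(sum(r.multiheme for r in rows) / n)),
        pct_multiheme=round_half_away(sum(r.pct_multiheme for r in rows) / n, 1),
        hemes_per_cytochrome=round_half_away(sum(r.hemes_per_cytochrome for r in rows) / n, 1),
    )


def minimal_motif_census(proteomes: ProteomeSet, overlap: bool = False) -> dict[str, int]:
    """Per-genome count of proteins with >= 1 CXXCH motif (profiles ignored)."""
    out = {g: 0 for g in proteomes.genomes}
    for (g, _), seq in proteomes.proteins.items():
        if count_heme_motifs(seq, overlap=overlap)[0] >= 1:
            out[g] += 1
    return out


def conserved_cytochrome_families(
    families: list[ProteinFamily],
    calls: list[CytochromeCall],
    genome_order: list[str],
) -> tuple[list[ProteinFamily], int, float]:
    """Families with >= 1 cytochrome member from EVERY genome.

    Returns (qualifying families, number of cytochromes they contain,
    percent of all cytochromes, whole percent).
    """
    is_cyt = {c.protein for c in calls if c.is_cytochrome}
    total_cyt = len(is_cyt)
    qualifying = []
    conserved_members = 0
    for fam in families:
        cyt_genomes = {g for (g, p) in fam.members if (g, p) in is_cyt}
        if cyt_genomes == set(genome_order):
            qualifying.append(fam)
            conserved_members += sum(1 for m in fam.members if m in is_cyt)
    pct = round_half_away(100.0 * conserved_members / total_cyt) if total_cyt else 0.0
    return qualifying, conserved_members, pct
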