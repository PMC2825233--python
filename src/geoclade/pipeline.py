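"""Whole-analysis orchestration and the summary report.

``analyze_clade`` runs the in-memory pipeline (similarity -> RBH -> graph ->
MCL families -> phyletic census -> cytochrome census -> [LGT screen]) and
returns a :class:`SummaryReport` whose every printed fraction is recomputable
from the counts in the same report.  ``run_pipeline`` is the file-based
wrapper driven by a YAML config; each stage writes a TSV and a structured
log line with its input/output counts, so the filtering narrative (family
size >= 2, >= 10 members, average BSR >= 0.90, >= 1 motif + >= 1 profile) is
auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import yaml

from . import __version__
from .io import (
    ProfileHitTable,
    ProteomeSet,
    SimilarityHit,
    read_profile_hits,
    read_proteomes,
    read_similarity_table,
    resolve_profile_hits,
)
from .similarity import (
    RBHPair,
    ScoringParams,
    all_vs_all,
    conservation_ranking,
    reciprocal_best_hits,
)
from .families import (
    ProteinFamily,
    assemble_families,
    build_graph,
    clade_specific_families,
    large_families,
    markov_cluster,
    paralog_expansions,
    pattern_census,
    single_copy_universal,
)
from .cytochromes import (
    CensusRow,
    call_cytochromes,
    census,
    conserved_cytochrome_families,
    minimal_motif_census,
)
from .lgt import ScreenParams, ScreenResult, lgt_screen
from .util import round_half_away

log = logging.getLogger("geoclade")


def fraction_pct(numerator: int, denominator: int, decimals: int = 0) -> float:
    """percent = 100 * numerator / denominator, half away from zero."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round_half_away(100.0 * numerator / denominator, decimals)


def headline_fractions(counts: dict[str, int]) -> dict[str, float]:
    """The summary fractions, at their printed precisions.

    Whole percents for family coverage, the all-present pattern and
    conserved cytochromes; one decimal for the transfer fractions.
    Only the fractions whose counts are present are emitted.
    """
    out: dict[str, float] = {}
    total = counts.get("total_proteins", 0)
    if total:
        if "proteins_in_families" in counts:
            out["pct_proteins_in_families"] = fraction_pct(counts["proteins_in_families"], total)
        if "proteins_all_genomes_pattern" in counts:
            out["pct_all_genomes_pattern"] = fraction_pct(
                counts["proteins_all_genomes_pattern"], total
            )
        if "proteins_all_but_Gl_pattern" in counts:
            out["pct_all_but_Gl_pattern"] = fraction_pct(
                counts["proteins_all_but_Gl_pattern"], total
            )
        if "lgt_proteins" in counts:
            out["pct_lgt"] = fraction_pct(counts["lgt_proteins"], total, 1)
    if counts.get("cytochromes_total"):
        if "conserved_cytochromes" in counts:
            out["pct_conserved_cytochromes"] = fraction_pct(
                counts["conserved_cytochromes"], counts["cytochromes_total"]
            )
    if counts.get("cytochromes_screened_for_lgt") and "lgt_cytochromes" in counts:
        out["pct_lgt_cytochromes"] = fraction_pct(
            counts["lgt_cytochromes"], counts["cytochromes_screened_for_lgt"], 1
        )
    return out


@dataclass
class SummaryReport:
    """Aggregated results of one pipeline run; counts first, fractions derived."""

    genome_order: list[str]
    counts: dict[str, int]
    fractions: dict[str, float]
    families: list[ProteinFamily]
    singletons: list
    pattern_rows: list[dict]
    census_rows: list[CensusRow] | None
    census_average: CensusRow | None
    census_definition: str
    conserved_cytochrome_families: list[ProteinFamily]
    single_copy_families: list[frozenset]
    conservation_top: list[tuple]
    screen: ScreenResult | None
    provenance: dict[str, Any]

    def to_dict(self) -> dict[str, Any]:
        return {
            "genomes": self.genome_order,
            "counts": self.counts,
            "fractions": self.fractions,
            "census_definition": self.census_definition,
            "census": [vars(r) for r in self.census_rows] if self.census_rows else None,
            "census_average": vars(self.census_average) if self.census_average else None,
            "provenance": self.provenance,
        }

    def check_self_consistency(self) -> None:
        """Recompute every printed fraction from the printed counts; raise on drift."""
        recomputed = headline_fractions(self.counts)
        for key, value in recomputed.items():
            if key in self.fractions and self.fractions[key] != value:
                raise AssertionError(f"fraction {key}: printed {self.fractions[key]} != recomputed {value}")
        if self.census_rows:
            for row in self.census_rows:
                if row.cytochromes:
                    assert row.pct_multiheme == round_half_away(
                        100.0 * row.multiheme / row.cytochromes, 1
                    ), f"census row {row.genome} multiheme percent inconsistent"
                assert row.pct_genome == round_half_away(100.0 * row.cytochromes / row.orfs, 1)


def analyze_clade(
    proteomes: ProteomeSet,
    profiles: ProfileHitTable | None = None,
    hits: list[SimilarityHit] | None = None,
    scoring: ScoringParams | None = None,
    min_bits: float = 50.0,
    prescreen_k: int | None = 5,
    inflation: float = 1.5,
    sweep: Sequence[float] | None = None,
    weight_scheme: str = "bsr",
    homolog_db: dict[str, tuple[str, bool]] | None = None,
    screen_params: ScreenParams | None = None,
    clade: set[str] | None = None,
    run_sweep: bool = True,
    provenance: dict[str, Any] | None = None,
) -> SummaryReport:
    """Run the full comparative analysis in memory."""
    scoring = scoring or ScoringParams()
    if hits is None:
        log.info("similarity: built-in scorer, %d proteins", len(proteomes))
        hits = all_vs_all(proteomes, scoring, min_bits=min_bits, prescreen_k=prescreen_k)
    log.info("similarity: %d hits retained", len(hits))
    rbh = reciprocal_best_hits(hits)
    log.info("rbh: %d reciprocal best pairs", len(rbh))
    graph = build_graph(rbh, hits, weight_scheme=weight_scheme)
    partition = markov_cluster(graph, inflation=inflation)
    families, singletons = assemble_families(partition, proteomes.genomes)
    # proteins never entering the graph (no hits at all) are singletons too
    covered = {m for f in families for m in f.members} | set(singletons)
    singletons += sorted(set(proteomes.proteins) - covered)
    log.info("families: %d (size >= 2), %d singletons", len(families), len(singletons))

    total = len(proteomes)
    in_families = sum(f.size for f in families)
    all_present = [f for f in families if f.genomes_present() == set(proteomes.genomes)]
    counts: dict[str, int] = {
        "total_proteins": total,
        "proteins_in_families": in_families,
        "families": len(families),
        "singletons": len(singletons),
        "proteins_all_genomes_pattern": sum(f.size for f in all_present),
        "families_all_genomes_pattern": len(all_present),
        "large_families": len(large_families(families)),
        "paralog_expanded_families": len(paralog_expansions(families)),
    }
    pattern_rows = pattern_census(families, singletons, proteomes.genomes)

    single_copy: list[frozenset] = []
    if run_sweep:
        kwargs = {"inflations": sweep} if sweep is not None else {}
        single_copy = single_copy_universal(graph, proteomes.genomes, **kwargs)
        counts["single_copy_universal_families"] = len(single_copy)

    ranking = conservation_ranking(proteomes, rbh, proteomes.genomes[0])
    counts["high_bsr_proteins"] = len(ranking)

    census_rows = census_avg = None
    conserved_fams: list[ProteinFamily] = []
    if profiles is not None:
        profiles = resolve_profile_hits(profiles, proteomes)
        calls = call_cytochromes(proteomes, profiles)
        census_definition = "two-evidence (>=1 CXXCH motif and >=1 profile match)"
    else:
        calls = call_cytochromes(proteomes, None)
        # minimal definition: treat motif-only counts as the census
        calls = [
            c.__class__(c.protein, c.heme_count, c.heme_positions, c.profile_ids, c.heme_count >= 1)
            for c in calls
        ]
        census_definition = "minimal definition (motif-only; no profile table supplied)"
    census_rows, census_avg = census(calls, proteomes.counts(), proteomes.genomes)
    counts["cytochromes_total"] = sum(r.cytochromes for r in census_rows)
    counts["motif_only_proteins"] = sum(minimal_motif_census(proteomes).values())
    conserved_fams, n_conserved_cyt, _pct = conserved_cytochrome_families(
        families, calls, proteomes.genomes
    )
    counts["conserved_cytochromes"] = n_conserved_cyt
    counts["conserved_cytochrome_families"] = len(conserved_fams)
    if clade:
        sub = clade_specific_families(families, clade)
        counts["clade_specific_families"] = len(sub)
        counts["clade_specific_proteins"] = sum(f.size for f in sub)

    screen = None
    if homolog_db is not None:
        cyt_keys = {c.protein for c in calls if c.is_cytochrome}
        screen = lgt_screen(proteomes, homolog_db, screen_params, cytochrome_proteins=cyt_keys)
        counts["lgt_proteins"] = screen.n_lgt
        counts["proteins_screened_for_lgt"] = screen.n_screened
        counts["cytochromes_screened_for_lgt"] = screen.n_cytochromes or 0
        counts["lgt_cytochromes"] = screen.n_lgt_cytochromes or 0

    fractions = headline_fractions(counts)
    report = SummaryReport(
        genome_order=list(proteomes.genomes),
        counts=counts,
        fractions=fractions,
        families=families,
        singletons=singletons,
        pattern_rows=pattern_rows,
        census_rows=census_rows,
        census_average=census_avg,
        census_definition=census_definition,
        conserved_cytochrome_families=conserved_fams,
        single_copy_families=single_copy,
        conservation_top=ranking,
        screen=screen,
        provenance={"version": __version__, **(provenance or {})},
    )
    report.check_self_consistency()
    return report


# ---------------------------------------------------------------------------
# file-based pipeline


@dataclass
class PipelineConfig:
    """YAML-loadable configuration of a file-based run."""

    proteomes: list[str]
    genome_codes: list[str]
    blast_tab: str | None = None
    profile_hits: str | None = None
    homolog_db: str | None = None
    homolog_labels: str | None = None
    outdir: str = "geoclade_out"
    min_bits: float = 50.0
    inflation: float = 1.5
    sweep: list[float] | None = None
    strong_support: int = 50
    replicates: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(vars(self), sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> SummaryReport:
    """Run all stages from files per ``config``; write TSV artifacts + report.json."""
    for path in filter(None, [*config.proteomes, config.blast_tab, config.profile_hits, config.homolog_db]):
        if not Path(path).exists():
            raise FileNotFoundError(f"input path does not exist: {path}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteomes = read_proteomes(config.proteomes, config.genome_codes)
    hits = None
    if config.blast_tab:
        id_map = {pid: g for g, pid in proteomes.proteins}
        hits = read_similarity_table(config.blast_tab, id_map)
    profiles = read_profile_hits(config.profile_hits) if config.profile_hits else None
    homolog_db = None
    if config.homolog_db:
        from Bio import SeqIO

        labels: dict[str, bool] = {}
        if config.homolog_labels:
            for line in Path(config.homolog_labels).read_text().splitlines():
                if line.strip():
                    pid, lab = line.split("\t")[:2]
                    labels[pid] = lab.strip() == "family"
        homolog_db = {}
        for rec in SeqIO.parse(config.homolog_db, "fasta"):
            homolog_db[rec.id] = (str(rec.seq).upper(), labels.get(rec.id, False))
        for pid_key, seq in proteomes.proteins.items():
            homolog_db[pid_key[1]] = (seq, True)
    report = analyze_clade(
        proteomes,
        profiles=profiles,
        hits=hits,
        min_bits=config.min_bits,
        inflation=config.inflation,
        sweep=config.sweep,
        homolog_db=homolog_db,
        screen_params=ScreenParams(
            n_replicates=config.replicates,
            strong_support=config.strong_support,
            seed=config.seed,
            min_bits=config.min_bits,
        ),
        provenance={"config_sha256": config.digest(), "seed": config.seed},
    )
    write_report(report, outdir)
    return report


def write_report(report: SummaryReport, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "families.tsv", "w") as fh:
        fh.write("family_id\tpattern\tsize\tmembers\n")
        for f in report.families:
            members = ",".join(f"{g}:{p}" for g, p in sorted(f.members))
            fh.write(f"{f.family_id}\t{f.pattern}\t{f.size}\t{members}\n")
    with open(outdir / "pattern_census.tsv", "w") as fh:
        fh.write("pattern\tfamilies\tproteins\tpct_of_proteins\n")
        for row in report.pattern_rows:
            fh.write(f"{row['pattern']}\t{row['families']}\t{row['proteins']}\t{row['pct_of_proteins']:.0f}\n")
    if report.census_rows:
        with open(outdir / "cytochrome_census.tsv", "w") as fh:
            fh.write(
                "genome\torfs\tcytochromes\tpct_genome\tmultiheme\tpct_multiheme\themes_per_cytochrome\n"
            )
            for row in [*report.census_rows, report.census_average]:
                fh.write(
                    f"{row.genome}\t{row.orfs}\t{row.cytochromes}\t{row.pct_genome:.1f}\t"
                    f"{row.multiheme}\t{row.pct_multiheme:.1f}\t{row.hemes_per_cytochrome:.1f}\n"
                )
    if report.screen is not None:
        with open(outdir / "lgt_verdicts.tsv", "w") as fh:
            fh.write("genome\tprotein\tverdict\tsupport_at_decision\trule_trace\n")
            for v in report.screen.verdicts:
                sup = "" if v.support_at_decision is None else v.support_at_decision
                fh.write(f"{v.protein[0]}\t{v.protein[1]}\t{v.verdict}\t{sup}\t{';'.join(v.rule_trace)}\n")
    (outdir / "report.json").write_text(json.dumps(report.to_dict(), indent=2, default=str) + "\n")
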