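#!/usr/bin/env python
"""Ortholog families, phyletic patterns and conservation on the null clade.

Reads results/clades/null (run 01 first), computes all-vs-all similarity,
reciprocal best hits, MCL families at inflation 1.5, the phyletic-pattern
census, the single-copy sweep (inflation 1.1-5.0) and the average-BSR
conservation ranking, scores family recovery against the truth table, and
writes the family/pattern tables under results/.
"""

import csv
from pathlib import Path

from geoclade.families import assemble_families, build_graph, markov_cluster, pattern_census, single_copy_universal
from geoclade.io import read_proteomes
from geoclade.similarity import all_vs_all, conservation_ranking, reciprocal_best_hits

BASE = Path(__file__).resolve().parent.parent / "results"
GENOMES = ["Gs", "Gm", "Gu", "Gf", "Gb", "Gl"]


def read_truth(path):
    truth = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            truth.setdefault(int(row["family"]), set()).add((row["genome"], row["protein"]))
    return truth


def main() -> None:
    clade = BASE / "clades" / "null"
    pset = read_proteomes([clade / f"{g}.faa" for g in GENOMES], GENOMES)
    hits = all_vs_all(pset)
    rbh = reciprocal_best_hits(hits)
    graph = build_graph(rbh, hits)
    families, singletons = assemble_families(markov_cluster(graph), GENOMES)
    print(f"{len(families)} families (>=2 members), {len(singletons)} singletons "
          f"from {len(pset)} proteins")

    truth = read_truth(clade / "truth.tsv")
    truth_sets = {frozenset(m) for m in truth.values()}
    recovered = truth_sets & {frozenset(f.members) for f in families}
    print(f"exact family recovery: {len(recovered)}/{len(truth_sets)} "
          f"({100 * len(recovered) / len(truth_sets):.1f}%)")

    rows = pattern_census(families, singletons, GENOMES)
    with open(BASE / "pattern_census.tsv", "w") as fh:
        fh.write("pattern\tfamilies\tproteins\tpct_of_proteins\n")
        for r in rows:
            fh.write(f"{r['pattern']}\t{r['families']}\t{r['proteins']}\t{r['pct_of_proteins']:.0f}\n")
    print(f"most common pattern: {rows[0]['pattern']} "
          f"({rows[0]['pct_of_proteins']:.0f}% of proteins)")

    single_copy = single_copy_universal(graph, GENOMES)
    print(f"single-copy universal families over the inflation sweep: {len(single_copy)}")

    full_coverage = conservation_ranking(pset, rbh, GENOMES[0], min_avg=0.0)
    top = [t for t in full_coverage if t[1] >= 0.90]
    mean_bsr = sum(a for _, a in full_coverage) / len(full_coverage) if full_coverage else 0.0
    with open(BASE / "best_conserved.tsv", "w") as fh:
        fh.write("genome\tprotein\tavg_bsr\n")
        for (g, p), avg in full_coverage:
            fh.write(f"{g}\t{p}\t{avg:.2f}\n")
    print(f"{len(full_coverage)} {GENOMES[0]} proteins have reciprocal orthologs in every "
          f"other genome; mean average BSR {100 * mean_bsr:.0f}%, {len(top)} at >= 0.90")

    with open(BASE / "families.tsv", "w") as fh:
        fh.write("family_id\tpattern\tsize\tmembers\n")
        for f in families:
            fh.write(f"{f.family_id}\t{f.pattern}\t{f.size}\t"
                     + ",".join(f"{g}:{p}" for g, p in sorted(f.members)) + "\n")


if __name__ == "__main__":
    main()
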