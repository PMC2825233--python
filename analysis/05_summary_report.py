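#!/usr/bin/env python
"""End-to-end summary report of the null clade through the single entry point.

Runs the whole pipeline in memory (similarity -> families -> censuses ->
single-copy sweep) via analyze_clade, checks the report's internal
consistency (every printed fraction recomputed from its printed counts), and
writes all report tables under results/report/.
"""

import json
from pathlib import Path

from geoclade.io import read_profile_hits, read_proteomes
from geoclade.pipeline import analyze_clade, write_report

BASE = Path(__file__).resolve().parent.parent / "results"
GENOMES = ["Gs", "Gm", "Gu", "Gf", "Gb", "Gl"]


def main() -> None:
    clade = BASE / "clades" / "null"
    pset = read_proteomes([clade / f"{g}.faa" for g in GENOMES], GENOMES)
    profiles = read_profile_hits(clade / "profile_hits.tsv")
    report = analyze_clade(pset, profiles=profiles)
    report.check_self_consistency()
    write_report(report, BASE / "report")
    print(json.dumps({"counts": report.counts, "fractions": report.fractions}, indent=2))


if __name__ == "__main__":
    main()
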