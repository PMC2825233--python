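"""Published reference numbers for the six-genome *Geobacter* study.

The original study's per-genome cytochrome census and headline protein-family
counts are shipped here so the summary arithmetic (per-genome percentages,
clade averages, headline fractions) can be recomputed and checked without the
multi-gigabyte inputs the counts were derived from.  Only printed counts are
stored; every percentage and average is recomputed by this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: the fixed genome order used in phyletic patterns ("GsGmGuGfGbGl").
GENOME_ORDER = ["Gs", "Gm", "Gu", "Gf", "Gb", "Gl"]

#: headline counts of the six-genome comparison.  All fractions derived from
#: these are recomputed by :func:`geoclade.pipeline.headline_fractions`.
HEADLINE_COUNTS = {
    "total_proteins": 22_434,          # protein-coding genes across the six genomes
    "proteins_in_families": 17_620,    # members of families with >= 2 orthologs
    "families": 4_062,                 # families with >= 2 orthologs
    "proteins_all_genomes_pattern": 7_774,   # members of families present in all six
    "proteins_all_but_Gl_pattern": 1_246,    # second most common pattern
    "single_copy_universal_families": 697,   # one ortholog per genome (+outgroup)
    "full_rbh_proteins": 1_266,        # G. sulfurreducens proteins with RBHs everywhere
    "avg_bsr_pct_full_rbh": 70,        # their average bit-score ratio, percent
    "high_bsr_proteins": 61,           # average BSR >= 0.90
    "large_families": 43,              # families with >= 10 members
    "subsurface_only_families": 89,
    "subsurface_only_proteins": 283,
    "cytochromes_total": 471,          # six-genome cytochrome total (census table)
    "conserved_cytochromes": 64,       # in families with a cytochrome from every genome
    "conserved_cytochrome_families": 9,
    "cytochrome_families": 115,
    "cytochrome_families_with_paralogs": 28,
    "lgt_proteins": 2_196,             # predicted lateral-transfer acquisitions
    "lgt_cytochromes": 19,
    "cytochromes_screened_for_lgt": 472,
}


def load_cytochrome_census() -> pd.DataFrame:
    """Per-genome cytochrome census counts of the published six-genome study.

    Columns: genome, orfs (protein-coding ORFs), cytochromes (two-evidence
    calls: >=1 CXXCH motif and >=1 c-type cytochrome profile match), multiheme
    (cytochromes with >1 heme motif), hemes_per_cytochrome (mean motif count,
    1 decimal as printed).
    """
    ref = resources.files("geoclade.data") / "geobacter_cytochrome_census.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
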