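#!/usr/bin/env python
"""Genome-scale analysis driver (requires external downloads; not run in CI).

Inputs you must provide (none are bundled):
  * Ensembl GTF per species (e.g. GRCh38 release 103, GRCm39 release 103)
  * InterProScan TSV output for the matching proteome (Pfam at minimum)
  * APPRIS principal-isoform list (optional)
  * BioMart homolog tables with query %identity, in both directions

Produces, per species: the annotation store, a per-(gene, accession) status
table for each standard and the alternative-domain percentages; across
species: reciprocal-best-hit pairs, the conservation summary, and the
splicing-potential correlation (>=50 occurrences in both genomes).

Example:
  python scripts/genome_scale_analysis.py \
    --gtf-a human.gtf --interpro-a human_ipr.tsv \
    --gtf-b mouse.gtf --interpro-b mouse_ipr.tsv \
    --ab h2m.tsv --ba m2h.tsv --out results/genome_scale
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

from altfeat.alt_classifier import Standard, domain_status_table
from altfeat.annotation_store import build_store
from altfeat.homology import (
    best_hits,
    compare_domain_status,
    read_identity_table,
    reciprocal_best_hits,
    splicing_potential,
)


def species_tables(gtf, interpro, appris, tools, out_dir, label):
    store = build_store(gtf, interpro, appris, tools=tools)
    summary = store.summary()
    print(f"[{label}] {summary}", file=sys.stderr)
    tables = {}
    for std in (Standard("coding"), Standard("cds_ratio", 0.5), Standard("overlap_cds")):
        table = domain_status_table(store, std, tools=tools)
        frac = (table["status"] == "alternative").mean() if len(table) else float("nan")
        print(f"[{label}] {std.label}: {len(table)} units, "
              f"{100 * frac:.1f}% alternative", file=sys.stderr)
        table.to_csv(out_dir / f"status_{label}_{std.kind}.tsv", sep="\t", index=False)
        tables[std.kind] = table
    print(f"[{label}] mean features per coding transcript: "
          f"{summary['mean_features_per_coding_transcript']:.1f}", file=sys.stderr)
    return tables


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    for suffix in ("a", "b"):
        parser.add_argument(f"--gtf-{suffix}", required=True)
        parser.add_argument(f"--interpro-{suffix}", required=True)
        parser.add_argument(f"--appris-{suffix}", default=None)
    parser.add_argument("--ab", required=True, help="A->B identity TSV")
    parser.add_argument("--ba", required=True, help="B->A identity TSV")
    parser.add_argument("--tools", default="Pfam")
    parser.add_argument("--min-count", type=int, default=50)
    parser.add_argument("--out", type=Path, required=True)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    tools = args.tools.split(",")

    tables_a = species_tables(args.gtf_a, args.interpro_a, args.appris_a,
                              tools, args.out, "a")
    tables_b = species_tables(args.gtf_b, args.interpro_b, args.appris_b,
                              tools, args.out, "b")

    pairs = reciprocal_best_hits(
        best_hits(read_identity_table(args.ab)),
        best_hits(read_identity_table(args.ba)),
    )
    print(f"reciprocal best hits: {len(pairs)} pairs", file=sys.stderr)
    pd.DataFrame([(p.gene_a, p.gene_b) for p in pairs],
                 columns=["gene_a", "gene_b"]).to_csv(
        args.out / "homolog_pairs.tsv", sep="\t", index=False)

    summary = compare_domain_status(pairs, tables_a["overlap_cds"],
                                    tables_b["overlap_cds"])
    print(f"common units: {summary.n_common}; "
          f"a-specific: {summary.a_specific}; b-specific: {summary.b_specific}; "
          f"specific-vs-common chi2 p = {summary.p:.3g}", file=sys.stderr)
    alt_a_alt_b = summary.common.get(("alternative", "alternative"), 0)
    alt_a = sum(n for (sa, _), n in summary.common.items() if sa == "alternative")
    alt_b = sum(n for (_, sb), n in summary.common.items() if sb == "alternative")
    if alt_a:
        print(f"alternative-in-A units also alternative in B: "
              f"{alt_a_alt_b}/{alt_a} ({100 * alt_a_alt_b / alt_a:.0f}%)",
              file=sys.stderr)
    if alt_b:
        print(f"alternative-in-B units also alternative in A: "
              f"{alt_a_alt_b}/{alt_b} ({100 * alt_a_alt_b / alt_b:.0f}%)",
              file=sys.stderr)

    potential, corr = splicing_potential(tables_a["overlap_cds"],
                                         tables_b["overlap_cds"],
                                         min_count=args.min_count)
    potential.to_csv(args.out / "splicing_potential.tsv", sep="\t", index=False)
    print(f"splicing potential: {corr}", file=sys.stderr)
    return 0


if __name__ == "__main__":
    sys.exit(main())
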