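"""GO-slim scan: per term, the fraction of alternative (gene, accession)
domain units among the term's genes, tested against the genomic average."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from altfeat.homology import _status_units


@dataclass
class GoTermSet:
    term_id: str
    term_name: str
    gene_ids: set[str]


def read_go_sets(path: str | Path) -> list[GoTermSet]:
    """Read a TSV of (term_id, term_name, gene_id) rows into term sets.

    Duplicate (term, gene) rows collapse; malformed rows are skipped with a
    warning.  Output is sorted by term id.
    """
    path = Path(path)
    terms: dict[str, GoTermSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0] or not fields[2]:
                warnings.warn(f"{path}:{lineno}: malformed GO row skipped")
                continue
            term = terms.setdefault(fields[0], GoTermSet(fields[0], fields[1], set()))
            term.gene_ids.add(fields[2])
    return [terms[t] for t in sorted(terms)]


def go_alternative_scan(
    sets: Sequence[GoTermSet],
    status: pd.DataFrame,
    include_term_in_genome: bool = True,
    correction: bool = True,
) -> pd.DataFrame:
    """Test each term's alternative-domain fraction against the genome.

    Units are (gene, accession) pairs; a unit is alternative if any of its
    status rows is.  The 2x2 per term compares the term's units against the
    genome-wide units (term included by default; set
    ``include_term_in_genome=False`` for term-vs-complement).  Chi-square
    with continuity correction, BH adjustment across terms with >=1 unit,
    rows sorted by fraction descending.  Terms with no units are excluded.
    """
    units = _status_units(status)
    genome_alt = sum(
        1 for per_gene in units.values() for st in per_gene.values()
        if st == "alternative"
    )
    genome_total = sum(len(per_gene) for per_gene in units.values())

    rows = []
    for term in sets:
        term_alt = term_total = 0
        for gene_id in term.gene_ids:
            per_gene = units.get(gene_id)
            if not per_gene:
                continue
            term_total += len(per_gene)
            term_alt += sum(1 for st in per_gene.values() if st == "alternative")
        if term_total == 0:
            continue
        if include_term_in_genome:
            other_alt, other_total = genome_alt, genome_total
        else:
            other_alt = genome_alt - term_alt
            other_total = genome_total - term_total
        table = np.array(
            [
                [term_alt, term_total - term_alt],
                [other_alt, other_total - other_alt],
            ],
            dtype=float,
        )
        if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            chi2, p = 0.0, 1.0
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
        rows.append(
            {
                "term_id": term.term_id,
                "term_name": term.term_name,
                "n_domains": term_total,
                "n_alternative": term_alt,
                "fraction": term_alt / term_total,
                "chi2": float(chi2),
                "p": float(p),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "n_domains", "n_alternative", "fraction",
                 "chi2", "p"],
    )
    if out.empty:
        out["q"] = pd.Series(dtype=float)
        return out
    _, q, _, _ = multipletests(out["p"].to_numpy(), method="fdr_bh")
    out["q"] = q
    return out.sort_values(
        ["fraction", "term_id"], ascending=[False, True]
    ).reset_index(drop=True)
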