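"""Reciprocal-best-hit homology from percentage-identity tables and
cross-species comparison of alternative/constitutive domain status."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from altfeat.errors import DataError, ParseError


@dataclass(frozen=True)
class IdentityRow:
    query_gene: str
    target_gene: str
    pct_identity_query: float


@dataclass(frozen=True)
class HomologPair:
    gene_a: str
    gene_b: str


def read_identity_table(path: str | Path) -> list[IdentityRow]:
    """Read a BioMart-style TSV: query gene, target gene, % identity of the
    query (extra columns ignored).  A header line is skipped if its identity
    column is not numeric."""
    path = Path(path)
    rows: list[IdentityRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError("identity table needs >=3 columns", str(path), lineno)
            if not fields[1] or not fields[2]:
                continue  # query without any homolog
            try:
                pct = float(fields[2])
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise ParseError("non-numeric identity", str(path), lineno)
            rows.append(IdentityRow(fields[0], fields[1], pct))
    return rows


def best_hits(rows: Iterable[IdentityRow]) -> dict[str, str]:
    """Per query gene, the target with the highest query identity.

    Ties are broken deterministically by the lexicographically smallest
    target id.
    """
    best: dict[str, tuple[float, str]] = {}
    for row in rows:
        cur = best.get(row.query_gene)
        cand = (row.pct_identity_query, row.target_gene)
        if cur is None:
            best[row.query_gene] = cand
        elif cand[0] > cur[0] or (cand[0] == cur[0] and cand[1] < cur[1]):
            best[row.query_gene] = cand
    return {q: t for q, (_, t) in best.items()}


def reciprocal_best_hits(
    bh_ab: Mapping[str, str], bh_ba: Mapping[str, str]
) -> list[HomologPair]:
    """Pairs (a, b) with bh_ab[a] == b and bh_ba[b] == a, sorted by gene_a."""
    pairs = [
        HomologPair(a, b)
        for a, b in bh_ab.items()
        if bh_ba.get(b) == a
    ]
    pairs.sort(key=lambda p: p.gene_a)
    return pairs


# ---------------------------------------------------------------------------
# status comparison
# ---------------------------------------------------------------------------


def _status_units(status: pd.DataFrame) -> dict[str, dict[str, str]]:
    """gene_id -> {signature_acc -> status}; a (gene, accession) unit is
    alternative if any of its rows is alternative."""
    units: dict[str, dict[str, str]] = {}
    for gene_id, acc, st in zip(
        status["gene_id"], status["signature_acc"], status["status"]
    ):
        per_gene = units.setdefault(gene_id, {})
        if st == "alternative" or acc not in per_gene:
            per_gene[acc] = st if st == "alternative" else per_gene.get(acc, st)
    return units


@dataclass
class ConservationSummary:
    """Counts of (gene pair, accession) units by cross-species status."""

    #: (status in A, status in B) -> count, for domains present in both genes
    common: dict[tuple[str, str], int] = field(default_factory=dict)
    #: status -> count for domains present only in the species-A gene
    a_specific: dict[str, int] = field(default_factory=dict)
    #: status -> count for domains present only in the species-B gene
    b_specific: dict[str, int] = field(default_factory=dict)
    n_pairs_used: int = 0
    n_pairs_skipped: int = 0
    #: chi-square comparing the alternative fraction of species-specific vs
    #: common units (species-A status for common units)
    chi2: float = float("nan")
    p: float = float("nan")

    @property
    def n_common(self) -> int:
        return sum(self.common.values())

    @property
    def n_a_specific(self) -> int:
        return sum(self.a_specific.values())

    @property
    def n_b_specific(self) -> int:
        return sum(self.b_specific.values())

    @property
    def total(self) -> int:
        return self.n_common + self.n_a_specific + self.n_b_specific


def compare_domain_status(
    pairs: Sequence[HomologPair],
    status_a: pd.DataFrame,
    status_b: pd.DataFrame,
) -> ConservationSummary:
    """Tabulate common and species-specific (gene pair, accession) units.

    A unit is common when the accession has a status row in both genes of a
    pair, species-specific when it is present in exactly one.  Pairs whose
    genes are absent from both status tables are skipped and counted.
    """
    units_a = _status_units(status_a)
    units_b = _status_units(status_b)
    summary = ConservationSummary()
    alt_specific = con_specific = alt_common = con_common = 0
    for pair in pairs:
        in_a = units_a.get(pair.gene_a)
        in_b = units_b.get(pair.gene_b)
        if in_a is None and in_b is None:
            summary.n_pairs_skipped += 1
            continue
        summary.n_pairs_used += 1
        in_a = in_a or {}
        in_b = in_b or {}
        for acc in sorted(set(in_a) | set(in_b)):
            if acc in in_a and acc in in_b:
                key = (in_a[acc], in_b[acc])
                summary.common[key] = summary.common.get(key, 0) + 1
                if in_a[acc] == "alternative":
                    alt_common += 1
                else:
                    con_common += 1
            elif acc in in_a:
                summary.a_specific[in_a[acc]] = summary.a_specific.get(in_a[acc], 0) + 1
                if in_a[acc] == "alternative":
                    alt_specific += 1
                else:
                    con_specific += 1
            else:
                summary.b_specific[in_b[acc]] = summary.b_specific.get(in_b[acc], 0) + 1
                if in_b[acc] == "alternative":
                    alt_specific += 1
                else:
                    con_specific += 1
    table = np.array(
        [[alt_specific, con_specific], [alt_common, con_common]], dtype=float
    )
    if table.sum() and not (table.sum(axis=0) == 0).any() and not (table.sum(axis=1) == 0).any():
        chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
        summary.chi2, summary.p = float(chi2), float(p)
    return summary


def splicing_potential(
    status_a: pd.DataFrame,
    status_b: pd.DataFrame,
    min_count: int = 50,
) -> tuple[pd.DataFrame, dict]:
    """Per-accession alternative fraction in each species, plus correlation.

    Accessions observed fewer than ``min_count`` times ((gene, accession)
    units) in either species are excluded.  Pearson and Spearman
    coefficients with p-values are computed over the retained accessions;
    with fewer than 3 retained accessions the correlation is undefined
    (reported as NaN).
    """
    if min_count < 1:
        raise DataError("min_count must be >= 1")

    def tally(status: pd.DataFrame) -> pd.DataFrame:
        units = _status_units(status)
        rows = [
            (acc, st)
            for per_gene in units.values()
            for acc, st in per_gene.items()
        ]
        df = pd.DataFrame(rows, columns=["signature_acc", "status"])
        if df.empty:
            return pd.DataFrame(columns=["signature_acc", "total", "alt", "fraction"])
        g = df.groupby("signature_acc")["status"]
        out = pd.DataFrame(
            {
                "total": g.size(),
                "alt": g.apply(lambda s: int((s == "alternative").sum())),
            }
        ).reset_index()
        out["fraction"] = out["alt"] / out["total"]
        return out

    ta, tb = tally(status_a), tally(status_b)
    merged = ta.merge(tb, on="signature_acc", suffixes=("_a", "_b"))
    merged = merged[
        (merged["total_a"] >= min_count) & (merged["total_b"] >= min_count)
    ].reset_index(drop=True)
    corr: dict = {"n_accessions": len(merged)}
    if len(merged) >= 3:
        pearson = stats.pearsonr(merged["fraction_a"], merged["fraction_b"])
        spearman = stats.spearmanr(merged["fraction_a"], merged["fraction_b"])
        corr.update(
            pearson_r=float(pearson.statistic), pearson_p=float(pearson.pvalue),
            spearman_r=float(spearman.statistic), spearman_p=float(spearman.pvalue),
        )
    else:
        corr.update(
            pearson_r=float("nan"), pearson_p=float("nan"),
            spearman_r=float("nan"), spearman_p=float("nan"),
        )
    return merged, corr
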