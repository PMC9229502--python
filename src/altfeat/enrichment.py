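"""Feature enrichment between a target and a background genomic-region list.

Each region list is intersected with the projected feature spans; per
signature accession a 2x2 contingency table of regions-with vs
regions-without is tested with a chi-square (Yates continuity correction by
default) and p-values are Benjamini-Hochberg adjusted across all tested
accessions.  The fold change is the target-list frequency over the pooled
target+background frequency, which never divides by zero for a tested
accession.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from altfeat.annotation_store import AnnotationStore, GenomicInterval, normalize_chrom
from altfeat.errors import DataError, ParseError


@dataclass
class RegionList:
    """A list of genomic regions; duplicates count separately."""

    regions: list[tuple[GenomicInterval, str]] = field(default_factory=list)
    label: str = "target"

    @property
    def n(self) -> int:
        return len(self.regions)


def read_bed(path: str | Path, label: str = "target") -> RegionList:
    """Read a BED file (>=3 columns, 0-based half-open; column 4 kept as the
    region name; strand, if present, is ignored for overlap)."""
    path = Path(path)
    regions: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError("BED line has fewer than 3 columns", str(path), lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError("non-integer BED coordinates", str(path), lineno)
            if end <= start:
                raise ParseError(f"empty or inverted BED interval ({start}, {end})",
                                 str(path), lineno)
            name = fields[3] if len(fields) > 3 else f"{label}_{lineno}"
            regions.append((GenomicInterval(fields[0], start, end), name))
    return RegionList(regions, label)


def annotate_regions(
    regions: RegionList,
    store: AnnotationStore,
    tools: Iterable[str] | None = None,
) -> pd.DataFrame:
    """One row per (region, overlapping feature instance); regions with no
    overlap appear once with empty feature fields.  Overlap is strandless and
    requires >=1 shared nucleotide between region and feature span; "chr"
    prefixes are normalized away on both sides."""
    selected = set(tools) if tools is not None else None
    rows = []
    for idx, (interval, name) in enumerate(regions.regions):
        chrom = normalize_chrom(interval.chrom)
        hits = [
            gf
            for gf in store.query_features(chrom, interval.start, interval.end)
            if selected is None or gf.tool in selected
        ]
        if not hits:
            rows.append(
                {
                    "region_index": idx, "region_name": name,
                    "chrom": interval.chrom, "start": interval.start,
                    "end": interval.end, "tool": "", "signature_acc": "",
                    "interpro_acc": "", "description": "", "transcript_id": "",
                    "feature_start": pd.NA, "feature_end": pd.NA,
                }
            )
            continue
        for gf in hits:
            aa = gf.feature
            rows.append(
                {
                    "region_index": idx, "region_name": name,
                    "chrom": interval.chrom, "start": interval.start,
                    "end": interval.end, "tool": gf.tool,
                    "signature_acc": gf.signature_acc,
                    "interpro_acc": aa.interpro_acc,
                    "description": aa.description,
                    "transcript_id": gf.transcript_id,
                    "feature_start": gf.span.start, "feature_end": gf.span.end,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["region_index", "region_name", "chrom", "start", "end", "tool",
                 "signature_acc", "interpro_acc", "description", "transcript_id",
                 "feature_start", "feature_end"],
    )


def feature_region_counts(annotated: pd.DataFrame, distinct: bool = True) -> pd.DataFrame:
    """Per (tool, signature_acc): number of overlapping regions.

    With ``distinct=True`` (default) a region counts at most once per
    accession even when it overlaps several instances; ``distinct=False``
    counts raw (region, instance) overlap rows instead.
    """
    hits = annotated[annotated["signature_acc"] != ""]
    if hits.empty:
        return pd.DataFrame(columns=["tool", "signature_acc", "interpro_acc", "count"])
    if distinct:
        dedup = hits.drop_duplicates(["region_index", "tool", "signature_acc"])
    else:
        dedup = hits
    grouped = (
        dedup.groupby(["tool", "signature_acc"], sort=True)
        .agg(interpro_acc=("interpro_acc", "first"), count=("region_index", "size"))
        .reset_index()
    )
    return grouped


def fold_change(c_t: int, n_t: int, c_b: int, n_b: int) -> float:
    """Target frequency over pooled target+background frequency."""
    if n_t < 1 or n_b < 1:
        raise DataError("fold change requires non-empty region lists")
    if c_t + c_b < 1:
        raise DataError("fold change undefined when the feature hits no region")
    return (c_t / n_t) / ((c_t + c_b) / (n_t + n_b))


def _chi2_2x2(c_t: int, n_t: int, c_b: int, n_b: int, correction: bool) -> tuple[float, float, bool]:
    """Chi-square on [[c_t, n_t-c_t], [c_b, n_b-c_b]]; returns (chi2, p,
    low_expected).  Degenerate tables (a zero margin) give chi2=0, p=1."""
    table = np.array([[c_t, n_t - c_t], [c_b, n_b - c_b]], dtype=float)
    expected = stats.contingency.expected_freq(table) if table.sum() else table
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0, True
    low_expected = bool((expected < 5).any())
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(chi2), float(p), low_expected


def enrich(
    target: RegionList,
    background: RegionList,
    store: AnnotationStore,
    tools: Iterable[str] | None = None,
    correction: bool = True,
    distinct: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Test per-accession enrichment of target regions vs background regions.

    Returns (rows, summary): one row per accession overlapping at least one
    region in either list, sorted by adjusted p then descending fold change;
    the summary reports list sizes, the number of tested accessions and the
    top (<=5) rows.
    """
    if target.n == 0 or background.n == 0:
        raise DataError("both region lists must be non-empty")
    ann_t = annotate_regions(target, store, tools)
    ann_b = annotate_regions(background, store, tools)
    counts_t = feature_region_counts(ann_t, distinct=distinct)
    counts_b = feature_region_counts(ann_b, distinct=distinct)
    merged = counts_t.merge(
        counts_b,
        on=["tool", "signature_acc"],
        how="outer",
        suffixes=("_t", "_b"),
    )
    if merged.empty:
        rows = pd.DataFrame(
            columns=["tool", "signature_acc", "interpro_acc", "count_target",
                     "count_background", "n_target", "n_background", "chi2", "p",
                     "q", "fold_change", "low_expected"]
        )
        summary = {"n_target": target.n, "n_background": background.n,
                   "n_accessions": 0, "top": rows}
        return rows, summary
    merged["count_target"] = merged.pop("count_t").fillna(0).astype(int)
    merged["count_background"] = merged.pop("count_b").fillna(0).astype(int)
    merged["interpro_acc"] = (
        merged.pop("interpro_acc_t").fillna(merged.pop("interpro_acc_b")).fillna("")
    )
    n_t, n_b = target.n, background.n

    stats_rows = []
    for _, row in merged.iterrows():
        c_t, c_b = int(row["count_target"]), int(row["count_background"])
        chi2, p, low = _chi2_2x2(c_t, n_t, c_b, n_b, correction)
        stats_rows.append(
            {
                "tool": row["tool"], "signature_acc": row["signature_acc"],
                "interpro_acc": row["interpro_acc"], "count_target": c_t,
                "count_background": c_b, "n_target": n_t, "n_background": n_b,
                "chi2": chi2, "p": p,
                "fold_change": fold_change(c_t, n_t, c_b, n_b),
                "low_expected": low,
            }
        )
    out = pd.DataFrame(stats_rows)
    _, q, _, _ = multipletests(out["p"].to_numpy(), method="fdr_bh")
    out["q"] = q
    out = out.sort_values(
        ["q", "fold_change", "signature_acc"], ascending=[True, False, True]
    ).reset_index(drop=True)
    out = out[["tool", "signature_acc", "interpro_acc", "count_target",
               "count_background", "n_target", "n_background", "chi2", "p", "q",
               "fold_change", "low_expected"]]
    summary = {
        "n_target": n_t,
        "n_background": n_b,
        "n_accessions": len(out),
        "top": out.head(5),
    }
    return out, summary
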