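"""Grouping of equivalent feature instances across a gene's transcripts and
classification of each group as alternative or constitutive.

Three candidate-transcript standards are supported:

``coding``
    all coding transcripts of the gene;
``cds_ratio``
    coding transcripts whose CDS length is at least a threshold fraction of
    the gene's longest CDS (the longest-CDS transcript — the major isoform —
    always qualifies, including all length ties);
``overlap_cds``
    coding transcripts whose CDS genomic span (first CDS base to last,
    introns included) entirely contains the feature group's genomic span;
    the candidate set therefore varies per feature group.

A group is constitutive under a standard iff every candidate transcript
carries a member instance; otherwise it is alternative.  Non-coding
transcripts never participate: counting them would make every feature
alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from altfeat.annotation_store import (
    AnnotationStore,
    Gene,
    GenomicFeature,
    GenomicInterval,
    Transcript,
)
from altfeat.errors import DataError, LookupFailure

logger = logging.getLogger(__name__)

STANDARD_KINDS = ("coding", "cds_ratio", "overlap_cds")


@dataclass(frozen=True)
class Standard:
    """One classification standard; ``threshold`` only applies to cds_ratio."""

    kind: str
    threshold: float | None = None
    #: treat the CDS ratio comparison as inclusive (ratio >= threshold)
    inclusive: bool = True

    def __post_init__(self) -> None:
        if self.kind not in STANDARD_KINDS:
            raise ValueError(f"unknown standard kind {self.kind!r}")
        if self.kind == "cds_ratio":
            if self.threshold is None or not (0.0 <= self.threshold <= 1.0):
                raise ValueError("cds_ratio requires a threshold in [0, 1]")
        elif self.threshold is not None:
            raise ValueError(f"threshold is only valid for cds_ratio, not {self.kind}")

    @property
    def label(self) -> str:
        if self.kind == "cds_ratio":
            return f"cds_ratio:{self.threshold:g}"
        return self.kind


def default_standards(threshold: float = 0.5) -> tuple[Standard, Standard, Standard]:
    return (
        Standard("coding"),
        Standard("cds_ratio", threshold),
        Standard("overlap_cds"),
    )


@dataclass
class FeatureGroup:
    """Connected component of same-accession, genomically overlapping
    instances within one gene — the unit that gets classified."""

    gene_id: str
    tool: str
    signature_acc: str
    members: list[tuple[str, GenomicFeature]] = field(default_factory=list)

    @property
    def group_span(self) -> GenomicInterval:
        spans = [gf.span for _, gf in self.members]
        first = spans[0]
        return GenomicInterval(
            first.chrom,
            min(s.start for s in spans),
            max(s.end for s in spans),
            first.strand,
        )

    @property
    def member_transcripts(self) -> set[str]:
        return {tid for tid, _ in self.members}

    @property
    def interpro_acc(self) -> str:
        for _, gf in self.members:
            if gf.feature.interpro_acc:
                return gf.feature.interpro_acc
        return ""

    @property
    def description(self) -> str:
        for _, gf in self.members:
            if gf.feature.description:
                return gf.feature.description
        return ""


@dataclass(frozen=True)
class ClassificationRecord:
    gene_id: str
    tool: str
    signature_acc: str
    standard: Standard
    status: str  # "constitutive" | "alternative"
    n_candidates: int
    n_present: int

    def __post_init__(self) -> None:
        if self.status not in ("constitutive", "alternative"):
            raise ValueError(f"invalid status {self.status!r}")


def group_common_features(
    gene_features: Iterable[GenomicFeature], gene_id: str = ""
) -> list[FeatureGroup]:
    """Cluster instances into groups of "common" features.

    Two instances are directly common iff they share tool and signature
    accession and their genomic spans (hulls, introns included) overlap by
    at least one nucleotide; groups are the connected components of that
    relation.  For intervals, components fall out of a single sorted sweep.
    """
    by_acc: dict[tuple[str, str], list[GenomicFeature]] = {}
    for gf in gene_features:
        by_acc.setdefault((gf.tool, gf.signature_acc), []).append(gf)

    groups: list[FeatureGroup] = []
    for (tool, acc), members in sorted(by_acc.items()):
        members.sort(key=lambda gf: (gf.span.start, gf.span.end, gf.transcript_id))
        current: list[GenomicFeature] = []
        reach = -1
        for gf in members:
            if current and gf.span.start >= reach:
                groups.append(_make_group(gene_id, tool, acc, current))
                current = []
            current.append(gf)
            reach = max(reach, gf.span.end)
        if current:
            groups.append(_make_group(gene_id, tool, acc, current))
    return groups


def _make_group(
    gene_id: str, tool: str, acc: str, members: Sequence[GenomicFeature]
) -> FeatureGroup:
    return FeatureGroup(
        gene_id=gene_id,
        tool=tool,
        signature_acc=acc,
        members=[(gf.transcript_id, gf) for gf in members],
    )


def _major_cds_length(coding: Sequence[Transcript]) -> int:
    return max(t.cds_length for t in coding)


def candidate_transcripts(
    gene: Gene,
    transcripts: Sequence[Transcript],
    standard: Standard,
    feature_group: FeatureGroup | None = None,
) -> set[str]:
    """Candidate transcript ids for one standard (and, for overlap_cds, one
    feature group).  Returns the empty set for genes without coding
    transcripts — no classification is possible there."""
    coding = [t for t in transcripts if t.is_coding]
    if not coding:
        return set()
    if standard.kind == "coding":
        return {t.transcript_id for t in coding}
    if standard.kind == "cds_ratio":
        major = _major_cds_length(coding)
        out = set()
        for t in coding:
            ratio = t.cds_length / major
            ok = ratio >= standard.threshold if standard.inclusive else ratio > standard.threshold
            if ok or t.cds_length == major:  # the major isoform always qualifies
                out.add(t.transcript_id)
        return out
    # overlap_cds
    if feature_group is None:
        raise DataError("overlap_cds candidates require a feature group")
    hull = feature_group.group_span
    out = set()
    for t in coding:
        span = t.cds_span
        if span is not None and span.contains(hull):
            out.add(t.transcript_id)
    return out


def classify_group(
    gene: Gene,
    transcripts: Sequence[Transcript],
    group: FeatureGroup,
    standard: Standard,
) -> ClassificationRecord | None:
    """Classify one group under one standard; None when no candidates exist."""
    candidates = candidate_transcripts(gene, transcripts, standard, group)
    if not candidates:
        logger.info(
            "group %s/%s in %s has no candidate transcripts under %s",
            group.tool, group.signature_acc, gene.gene_id, standard.label,
        )
        return None
    present = group.member_transcripts & candidates
    status = "constitutive" if present == candidates else "alternative"
    return ClassificationRecord(
        gene_id=gene.gene_id,
        tool=group.tool,
        signature_acc=group.signature_acc,
        standard=standard,
        status=status,
        n_candidates=len(candidates),
        n_present=len(present),
    )


def classify_gene(
    gene_query: str,
    store: AnnotationStore,
    standards: Sequence[Standard] | None = None,
    tools: Iterable[str] | None = None,
) -> list[ClassificationRecord]:
    """Classify every feature group of a gene under each standard.

    One record per (group × standard); groups with an empty candidate set
    under a standard are omitted with a logged note.
    """
    gene = store.resolve_gene(gene_query)
    if standards is None:
        standards = default_standards()
    transcripts = [store.transcripts[tid] for tid in gene.transcript_ids]
    features = store.features_of_gene(gene.gene_id)
    if tools is not None:
        selected = set(tools)
        features = [f for f in features if f.tool in selected]
    groups = group_common_features(features, gene.gene_id)
    records: list[ClassificationRecord] = []
    for group in groups:
        for standard in standards:
            rec = classify_group(gene, transcripts, group, standard)
            if rec is not None:
                records.append(rec)
    return records


def domain_status_table(
    store: AnnotationStore,
    standard: Standard,
    tools: Iterable[str] | None = None,
    per_group: bool = False,
) -> pd.DataFrame:
    """Per-(gene, accession) alternative/constitutive status for one standard.

    By default multiple groups of one accession within a gene collapse to a
    single unit that is alternative if any group is alternative (one
    alternative instance suffices to alter the protein).  ``per_group=True``
    keeps one row per group instead.

    Columns: gene_id, tool, signature_acc, status, standard.
    """
    rows = []
    for gene_id in store.genes:
        try:
            records = classify_gene(gene_id, store, [standard], tools)
        except LookupFailure:  # pragma: no cover - ids come from the store
            continue
        if per_group:
            for rec in records:
                rows.append((gene_id, rec.tool, rec.signature_acc, rec.status))
        else:
            unit_status: dict[tuple[str, str], str] = {}
            for rec in records:
                key = (rec.tool, rec.signature_acc)
                if rec.status == "alternative" or key not in unit_status:
                    unit_status[key] = (
                        "alternative" if rec.status == "alternative"
                        else unit_status.get(key, "constitutive")
                    )
            for (tool, acc), status in sorted(unit_status.items()):
                rows.append((gene_id, tool, acc, status))
    df = pd.DataFrame(rows, columns=["gene_id", "tool", "signature_acc", "status"])
    df["standard"] = standard.label
    return df


# ---------------------------------------------------------------------------
# single-gene report
# ---------------------------------------------------------------------------


@dataclass
class TranscriptTrack:
    transcript_id: str
    appris_principal: bool
    exons: list[GenomicInterval]
    cds_blocks: list[GenomicInterval]
    #: (label, span, blocks) per feature instance on this transcript
    features: list[tuple[str, GenomicInterval, tuple[GenomicInterval, ...]]]


@dataclass
class DiagramModel:
    """Drawing-ready model: per-transcript exon boxes, CDS sub-boxes and
    feature bars spanning the encoding exons and their intervening introns."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    xmin: int
    xmax: int
    tracks: list[TranscriptTrack]


def annotate_gene(
    gene_query: str,
    store: AnnotationStore,
    threshold: float = 0.5,
    tools: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, DiagramModel]:
    """Full single-gene report: feature table, classification table, diagram.

    The feature table has one row per (transcript, feature instance); the
    classification table one row per (group × standard) for the three
    standards at the given CDS-ratio threshold.
    """
    gene = store.resolve_gene(gene_query)
    selected = set(tools) if tools is not None else None

    feature_rows = []
    tracks = []
    for tid in gene.transcript_ids:
        tx = store.transcripts[tid]
        track_feats = []
        for gf in store.features_of_transcript(tid):
            if selected is not None and gf.tool not in selected:
                continue
            aa = gf.feature
            feature_rows.append(
                {
                    "gene_id": gene.gene_id,
                    "gene_name": gene.name,
                    "transcript_id": tid,
                    "appris_principal": tx.appris_principal,
                    "tool": aa.tool,
                    "signature_acc": aa.signature_acc,
                    "interpro_acc": aa.interpro_acc,
                    "description": aa.description,
                    "aa_start": aa.aa_start,
                    "aa_end": aa.aa_end,
                    "chrom": gf.span.chrom,
                    "start": gf.span.start,
                    "end": gf.span.end,
                    "strand": gf.span.strand,
                    "truncated": gf.truncated,
                }
            )
            label = aa.interpro_acc or aa.signature_acc
            track_feats.append((label, gf.span, gf.blocks))
        tracks.append(
            TranscriptTrack(tid, tx.appris_principal, list(tx.exons),
                            list(tx.cds_blocks), track_feats)
        )
    feature_table = pd.DataFrame(
        feature_rows,
        columns=[
            "gene_id", "gene_name", "transcript_id", "appris_principal", "tool",
            "signature_acc", "interpro_acc", "description", "aa_start", "aa_end",
            "chrom", "start", "end", "strand", "truncated",
        ],
    )

    records = classify_gene(gene.gene_id, store, default_standards(threshold), tools)
    class_rows = [
        {
            "gene_id": r.gene_id,
            "tool": r.tool,
            "signature_acc": r.signature_acc,
            "standard": r.standard.label,
            "status": r.status,
            "n_candidates": r.n_candidates,
            "n_present": r.n_present,
        }
        for r in records
    ]
    classification_table = pd.DataFrame(
        class_rows,
        columns=["gene_id", "tool", "signature_acc", "standard", "status",
                 "n_candidates", "n_present"],
    )

    all_tx = [store.transcripts[t] for t in gene.transcript_ids]
    xmin = min(t.exons[0].start for t in all_tx)
    xmax = max(t.exons[-1].end for t in all_tx)
    diagram = DiagramModel(
        gene.gene_id, gene.name, gene.chrom, gene.strand, xmin, xmax, tracks
    )
    return feature_table, classification_table, diagram
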