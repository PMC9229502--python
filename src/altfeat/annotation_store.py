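"""Annotation model: GTF/InterProScan/APPRIS readers, amino-acid-to-genomic
projection, and an indexed store of genes, transcripts and projected features.

Coordinate convention: all internal intervals are 0-based half-open.  GTF
coordinates (1-based inclusive) are converted on read and write; BED is
native.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from bisect import bisect_left
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

from altfeat.errors import DataError, LookupFailure, ParseError, ProjectionError

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")

#: default identifier normalizer: strip Ensembl-style ".N" version suffixes
def strip_version(identifier: str) -> str:
    return re.sub(r"\.\d+$", "", identifier)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on one strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strandless ≥1 nt overlap on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class Gene:
    gene_id: str
    name: str
    chrom: str
    strand: str
    biotype: str = ""
    transcript_ids: list[str] = field(default_factory=list)


@dataclass
class Transcript:
    """One transcript model; ``exons`` and ``cds_blocks`` sorted by start."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    cds_blocks: list[GenomicInterval] = field(default_factory=list)
    protein_id: str = ""
    appris_principal: bool = False
    biotype: str = ""

    @property
    def is_coding(self) -> bool:
        return len(self.cds_blocks) > 0

    @property
    def cds_length(self) -> int:
        return sum(b.length for b in self.cds_blocks)

    @property
    def protein_length(self) -> int:
        """Floor of cds_length/3; incomplete terminal codons are dropped."""
        return self.cds_length // 3

    @property
    def cds_span(self) -> GenomicInterval | None:
        """Genomic hull of the CDS (first block start to last block end,
        introns included), or None for non-coding transcripts."""
        if not self.cds_blocks:
            return None
        return GenomicInterval(
            self.chrom, self.cds_blocks[0].start, self.cds_blocks[-1].end, self.strand
        )

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )


@dataclass(frozen=True)
class ProteinFeatureAA:
    """One InterProScan prediction in protein (amino-acid) coordinates.

    ``aa_start``/``aa_end`` are 1-based inclusive, as emitted by InterProScan.
    """

    protein_id: str
    tool: str
    signature_acc: str
    aa_start: int
    aa_end: int
    interpro_acc: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.aa_start <= self.aa_end):
            raise ValueError(
                f"invalid amino-acid range {self.aa_start}..{self.aa_end}"
            )


@dataclass(frozen=True)
class GenomicFeature:
    """A protein feature projected onto the genome through its transcript."""

    feature: ProteinFeatureAA
    transcript_id: str
    blocks: tuple[GenomicInterval, ...]
    truncated: bool = False

    @property
    def span(self) -> GenomicInterval:
        first, last = self.blocks[0], self.blocks[-1]
        return GenomicInterval(first.chrom, first.start, last.end, first.strand)

    @property
    def tool(self) -> str:
        return self.feature.tool

    @property
    def signature_acc(self) -> str:
        return self.feature.signature_acc


# ---------------------------------------------------------------------------
# interval index
# ---------------------------------------------------------------------------


class IntervalIndex:
    """Static per-chromosome interval index (sorted starts + running max end).

    Query cost is O(log n + k') where k' is the scan bounded by the prefix
    maximum of interval ends; exact equivalence with a brute-force scan is a
    tested invariant.
    """

    def __init__(self, items: Iterable[tuple[str, int, int, object]]):
        per_chrom: dict[str, list[tuple[int, int, object]]] = {}
        for chrom, start, end, payload in items:
            per_chrom.setdefault(chrom, []).append((start, end, payload))
        self._index: dict[str, tuple[list[int], list[int], list[int], list[object]]] = {}
        for chrom, triples in per_chrom.items():
            triples.sort(key=lambda t: (t[0], t[1]))
            starts = [t[0] for t in triples]
            ends = [t[1] for t in triples]
            payloads = [t[2] for t in triples]
            max_ends: list[int] = []
            running = 0
            for e in ends:
                running = max(running, e)
                max_ends.append(running)
            self._index[chrom] = (starts, ends, max_ends, payloads)

    def query(self, chrom: str, start: int, end: int) -> list[object]:
        entry = self._index.get(chrom)
        if entry is None:
            return []
        starts, ends, max_ends, payloads = entry
        hi = bisect_left(starts, end)  # intervals with start < end
        out = []
        for i in range(hi - 1, -1, -1):
            if max_ends[i] <= start:
                break  # nothing earlier can reach past `start`
            if ends[i] > start:
                out.append(payloads[i])
        out.reverse()
        return out


# ---------------------------------------------------------------------------
# store
# ---------------------------------------------------------------------------


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix so BED and GTF dialects can be mixed."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


class AnnotationStore:
    """Indexed collection of genes, transcripts and projected features."""

    def __init__(self) -> None:
        self.genes: dict[str, Gene] = {}
        self.transcripts: dict[str, Transcript] = {}
        self.features: list[GenomicFeature] = []
        self.unattached: list[ProteinFeatureAA] = []
        self.rejected: list[tuple[ProteinFeatureAA, str]] = []
        self._features_by_transcript: dict[str, list[GenomicFeature]] = {}
        self._genes_by_name: dict[str, list[str]] = {}
        self._protein_to_transcript: dict[str, str] = {}
        self._feature_index: IntervalIndex | None = None

    # -- construction ------------------------------------------------------

    def add_gene(self, gene: Gene) -> None:
        if gene.gene_id in self.genes:
            raise DataError(f"duplicate gene id {gene.gene_id}")
        self.genes[gene.gene_id] = gene
        if gene.name:
            self._genes_by_name.setdefault(gene.name, []).append(gene.gene_id)

    def add_transcript(self, tx: Transcript) -> None:
        if tx.transcript_id in self.transcripts:
            raise DataError(f"duplicate transcript id {tx.transcript_id}")
        self.transcripts[tx.transcript_id] = tx
        gene = self.genes.get(tx.gene_id)
        if gene is None:
            gene = Gene(tx.gene_id, "", tx.chrom, tx.strand)
            self.add_gene(gene)
        if tx.chrom != gene.chrom or tx.strand != gene.strand:
            raise DataError(
                f"transcript {tx.transcript_id} disagrees with gene "
                f"{tx.gene_id} on chrom/strand"
            )
        gene.transcript_ids.append(tx.transcript_id)
        if tx.protein_id:
            self._protein_to_transcript[tx.protein_id] = tx.transcript_id

    def attach_features(
        self,
        aa_features: Iterable[ProteinFeatureAA],
        id_normalizer: Callable[[str], str] = strip_version,
    ) -> None:
        """Project protein-coordinate features onto their transcripts.

        Features whose protein identifier matches no transcript are kept in
        ``self.unattached``; features falling outside the CDS are kept in
        ``self.rejected`` with a reason.
        """
        lut: dict[str, str] = {}
        for tx in self.transcripts.values():
            lut[id_normalizer(tx.transcript_id)] = tx.transcript_id
            if tx.protein_id:
                lut[id_normalizer(tx.protein_id)] = tx.transcript_id
        for aa in aa_features:
            tid = lut.get(id_normalizer(aa.protein_id))
            if tid is None:
                self.unattached.append(aa)
                continue
            tx = self.transcripts[tid]
            if not tx.is_coding:
                self.rejected.append((aa, "transcript is non-coding"))
                continue
            try:
                gf = project_aa_to_genomic(aa, tx)
            except ProjectionError as exc:
                self.rejected.append((aa, str(exc)))
                continue
            self.features.append(gf)
            self._features_by_transcript.setdefault(tid, []).append(gf)
        self._feature_index = None
        if self.unattached:
            logger.warning(
                "%d features could not be attached to any transcript",
                len(self.unattached),
            )

    # -- queries -----------------------------------------------------------

    def features_of_transcript(self, transcript_id: str) -> list[GenomicFeature]:
        return list(self._features_by_transcript.get(transcript_id, []))

    def features_of_gene(self, gene_id: str) -> list[GenomicFeature]:
        gene = self.genes.get(gene_id)
        if gene is None:
            raise LookupFailure(f"unknown gene id {gene_id!r}")
        out: list[GenomicFeature] = []
        for tid in gene.transcript_ids:
            out.extend(self._features_by_transcript.get(tid, []))
        return out

    def query_features(self, chrom: str, start: int, end: int) -> list[GenomicFeature]:
        """All features whose genomic span overlaps ``[start, end)``."""
        if self._feature_index is None:
            self._feature_index = IntervalIndex(
                (f.span.chrom, f.span.start, f.span.end, f) for f in self.features
            )
        return self._feature_index.query(normalize_chrom(chrom), start, end)  # type: ignore[return-value]

    def resolve_gene(self, query: str) -> Gene:
        """Resolve an id-or-name query to exactly one gene."""
        if query in self.genes:
            return self.genes[query]
        ids = self._genes_by_name.get(query, [])
        if len(ids) == 1:
            return self.genes[ids[0]]
        if len(ids) > 1:
            raise LookupFailure(
                f"gene name {query!r} is ambiguous: candidates {sorted(ids)}"
            )
        raise LookupFailure(f"unknown gene {query!r}")

    def coding_transcripts(self, gene_id: str) -> list[Transcript]:
        gene = self.genes.get(gene_id)
        if gene is None:
            raise LookupFailure(f"unknown gene id {gene_id!r}")
        return [
            self.transcripts[tid]
            for tid in gene.transcript_ids
            if self.transcripts[tid].is_coding
        ]

    def summary(self) -> dict:
        """Manifest counts: per-tool features and mean features/transcript."""
        per_tool: dict[str, int] = {}
        for f in self.features:
            per_tool[f.tool] = per_tool.get(f.tool, 0) + 1
        n_coding = sum(1 for t in self.transcripts.values() if t.is_coding)
        mean = len(self.features) / n_coding if n_coding else 0.0
        return {
            "n_genes": len(self.genes),
            "n_transcripts": len(self.transcripts),
            "n_coding_transcripts": n_coding,
            "n_features": len(self.features),
            "n_unattached": len(self.unattached),
            "n_rejected": len(self.rejected),
            "features_per_tool": per_tool,
            "mean_features_per_coding_transcript": mean,
        }

    # -- persistence (plain-text directory) --------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "genes.tsv", "w") as fh:
            fh.write("gene_id\tname\tchrom\tstrand\tbiotype\n")
            for g in self.genes.values():
                fh.write(f"{g.gene_id}\t{g.name}\t{g.chrom}\t{g.strand}\t{g.biotype}\n")
        with open(directory / "transcripts.tsv", "w") as fh:
            fh.write(
                "transcript_id\tgene_id\tchrom\tstrand\texons\tcds_blocks\t"
                "protein_id\tappris_principal\tbiotype\n"
            )
            for t in self.transcripts.values():
                exons = ";".join(f"{b.start}-{b.end}" for b in t.exons)
                cds = ";".join(f"{b.start}-{b.end}" for b in t.cds_blocks)
                fh.write(
                    f"{t.transcript_id}\t{t.gene_id}\t{t.chrom}\t{t.strand}\t"
                    f"{exons}\t{cds}\t{t.protein_id}\t"
                    f"{int(t.appris_principal)}\t{t.biotype}\n"
                )
        with open(directory / "features.tsv", "w") as fh:
            fh.write(
                "transcript_id\tprotein_id\ttool\tsignature_acc\tinterpro_acc\t"
                "description\taa_start\taa_end\tblocks\ttruncated\n"
            )
            for f in self.features:
                blocks = ";".join(f"{b.start}-{b.end}" for b in f.blocks)
                aa = f.feature
                fh.write(
                    f"{f.transcript_id}\t{aa.protein_id}\t{aa.tool}\t"
                    f"{aa.signature_acc}\t{aa.interpro_acc}\t{aa.description}\t"
                    f"{aa.aa_start}\t{aa.aa_end}\t{blocks}\t{int(f.truncated)}\n"
                )
        with open(directory / "manifest.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, directory: str | Path) -> "AnnotationStore":
        directory = Path(directory)
        if not (directory / "transcripts.tsv").exists():
            raise DataError(f"not a store directory: {directory}")
        store = cls()
        with open(directory / "genes.tsv") as fh:
            next(fh)
            for line in fh:
                gid, name, chrom, strand, biotype = line.rstrip("\n").split("\t")
                store.add_gene(Gene(gid, name, chrom, strand, biotype))
        with open(directory / "transcripts.tsv") as fh:
            next(fh)
            for line in fh:
                (tid, gid, chrom, strand, exons_s, cds_s, pid, appris, biotype) = (
                    line.rstrip("\n").split("\t")
                )
                exons = _parse_blocks(exons_s, chrom, strand)
                cds = _parse_blocks(cds_s, chrom, strand)
                store.add_transcript(
                    Transcript(
                        tid, gid, chrom, strand, exons, cds, pid,
                        bool(int(appris)), biotype,
                    )
                )
        feats_path = directory / "features.tsv"
        if feats_path.exists():
            with open(feats_path) as fh:
                next(fh)
                for line in fh:
                    (tid, pid, tool, sig, ipr, desc, a0, a1, blocks_s, trunc) = (
                        line.rstrip("\n").split("\t")
                    )
                    tx = store.transcripts[tid]
                    aa = ProteinFeatureAA(pid, tool, sig, int(a0), int(a1), ipr, desc)
                    blocks = tuple(_parse_blocks(blocks_s, tx.chrom, tx.strand))
                    gf = GenomicFeature(aa, tid, blocks, bool(int(trunc)))
                    store.features.append(gf)
                    store._features_by_transcript.setdefault(tid, []).append(gf)
        return store


def _parse_blocks(text: str, chrom: str, strand: str) -> list[GenomicInterval]:
    if not text:
        return []
    out = []
    for part in text.split(";"):
        s, e = part.split("-")
        out.append(GenomicInterval(chrom, int(s), int(e), strand))
    return out


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _gtf_attributes(text: str) -> dict[str, str]:
    return dict(_GTF_ATTR_RE.findall(text))


def read_gtf(path: str | Path) -> AnnotationStore:
    """Parse an Ensembl-dialect GTF into a store of genes and transcripts.

    GTF 1-based inclusive coordinates become 0-based half-open.  Transcripts
    without CDS lines are kept with ``is_coding=False``; records on unplaced
    contigs are kept verbatim.
    """
    path = Path(path)
    genes: dict[str, Gene] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    tx_meta: dict[str, dict] = {}
    order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError("expected 9 GTF columns", str(path), lineno)
            chrom, _src, kind, start_s, end_s, _score, strand, _frame, attr_s = fields[:9]
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError("non-integer coordinates", str(path), lineno)
            if end1 < start1:
                raise ParseError(f"end < start ({end1} < {start1})", str(path), lineno)
            if strand not in STRANDS:
                continue  # strandless records carry no transcript structure
            attrs = _gtf_attributes(attr_s)
            if kind not in ("gene", "transcript", "exon", "CDS"):
                continue
            gid = attrs.get("gene_id")
            if gid is None:
                raise ParseError("missing gene_id attribute", str(path), lineno)
            if kind == "gene":
                genes.setdefault(
                    gid,
                    Gene(
                        gid,
                        attrs.get("gene_name", ""),
                        chrom,
                        strand,
                        attrs.get("gene_biotype", ""),
                    ),
                )
                continue
            tid = attrs.get("transcript_id")
            if tid is None:
                raise ParseError("missing transcript_id attribute", str(path), lineno)
            meta = tx_meta.setdefault(
                tid,
                {"gene_id": gid, "chrom": chrom, "strand": strand, "protein_id": "",
                 "biotype": attrs.get("transcript_biotype", "")},
            )
            if tid not in exons:
                exons[tid] = []
                cds[tid] = []
                order.append(tid)
            interval = GenomicInterval(chrom, start1 - 1, end1, strand)
            if kind == "exon":
                exons[tid].append(interval)
            elif kind == "CDS":
                cds[tid].append(interval)
                if attrs.get("protein_id"):
                    meta["protein_id"] = attrs["protein_id"]
            elif kind == "transcript" and attrs.get("transcript_biotype"):
                meta["biotype"] = attrs["transcript_biotype"]

    store = AnnotationStore()
    for gene in genes.values():
        store.add_gene(gene)
    for tid in order:
        meta = tx_meta[tid]
        store.add_transcript(
            Transcript(
                tid,
                meta["gene_id"],
                meta["chrom"],
                meta["strand"],
                sorted(exons[tid], key=lambda b: b.start),
                sorted(cds[tid], key=lambda b: b.start),
                meta["protein_id"],
                biotype=meta["biotype"],
            )
        )
    return store


def write_gtf(store: AnnotationStore, path: str | Path) -> None:
    """Write the store's gene/transcript structure back to Ensembl-style GTF."""
    with open(path, "w") as fh:
        fh.write("#!genome-build synthetic\n")
        for gene in store.genes.values():
            tx_list = [store.transcripts[t] for t in gene.transcript_ids]
            if not tx_list:
                continue
            g_start = min(t.exons[0].start for t in tx_list)
            g_end = max(t.exons[-1].end for t in tx_list)
            base_attr = (
                f'gene_id "{gene.gene_id}"; gene_name "{gene.name}"; '
                f'gene_biotype "{gene.biotype}";'
            )
            fh.write(
                f"{gene.chrom}\taltfeat\tgene\t{g_start + 1}\t{g_end}\t.\t"
                f"{gene.strand}\t.\t{base_attr}\n"
            )
            for tx in tx_list:
                t_attr = base_attr + (
                    f' transcript_id "{tx.transcript_id}"; '
                    f'transcript_biotype "{tx.biotype}";'
                )
                fh.write(
                    f"{tx.chrom}\taltfeat\ttranscript\t{tx.exons[0].start + 1}\t"
                    f"{tx.exons[-1].end}\t.\t{tx.strand}\t.\t{t_attr}\n"
                )
                exon_iter: Sequence[GenomicInterval] = (
                    tx.exons if tx.strand == "+" else list(reversed(tx.exons))
                )
                for i, ex in enumerate(exon_iter, start=1):
                    fh.write(
                        f"{tx.chrom}\taltfeat\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                        f"{tx.strand}\t.\t{t_attr} exon_number \"{i}\";\n"
                    )
                cds_iter: Sequence[GenomicInterval] = (
                    tx.cds_blocks if tx.strand == "+" else list(reversed(tx.cds_blocks))
                )
                for block in cds_iter:
                    fh.write(
                        f"{tx.chrom}\taltfeat\tCDS\t{block.start + 1}\t{block.end}\t.\t"
                        f"{tx.strand}\t.\t{t_attr} protein_id \"{tx.protein_id}\";\n"
                    )


def read_interproscan_tsv(
    path: str | Path, tools: Iterable[str] | None = None
) -> list[ProteinFeatureAA]:
    """Read InterProScan tabular output.

    Columns (0-based): 0 protein accession, 1 MD5, 2 length, 3 analysis,
    4 signature accession, 5 description, 6 start, 7 stop, then optional
    score/status/date/InterPro accession/InterPro description.  Rows whose
    analysis is not in ``tools`` (when given) are dropped; rows with
    ``stop < start`` are rejected with a warning.
    """
    path = Path(path)
    selected = set(tools) if tools is not None else None
    out: list[ProteinFeatureAA] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise ParseError(
                    "expected at least 8 InterProScan columns", str(path), lineno
                )
            analysis = fields[3]
            if selected is not None and analysis not in selected:
                continue
            try:
                aa_start, aa_end = int(fields[6]), int(fields[7])
            except ValueError:
                raise ParseError("non-integer feature coordinates", str(path), lineno)
            if aa_end < aa_start:
                warnings.warn(
                    f"{path}:{lineno}: stop < start ({aa_end} < {aa_start}), row rejected"
                )
                continue
            interpro = fields[11] if len(fields) > 11 else ""
            if interpro == "-":
                interpro = ""
            out.append(
                ProteinFeatureAA(
                    protein_id=fields[0],
                    tool=analysis,
                    signature_acc=fields[4],
                    aa_start=aa_start,
                    aa_end=aa_end,
                    interpro_acc=interpro,
                    description=fields[5],
                )
            )
    return out


_APPRIS_LABEL_RE = re.compile(r"^(PRINCIPAL|ALTERNATIVE|MINOR)", re.IGNORECASE)


def read_appris(path: str | Path) -> dict[str, bool]:
    """Read a tab-separated APPRIS list into ``transcript_id -> principal``.

    Rows with ≥3 columns are read as (gene, transcript, ..., label); 2-column
    rows as (transcript, label).  Labels starting with ``PRINCIPAL`` map to
    True; anything else to False.  Malformed rows are skipped with a warning.
    """
    path = Path(path)
    out: dict[str, bool] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = re.split(r"\s+", line.strip())
            if len(fields) < 2:
                warnings.warn(f"{path}:{lineno}: malformed APPRIS row skipped")
                continue
            tid = fields[1] if len(fields) >= 3 else fields[0]
            label = fields[-1]
            out[tid] = label.upper().startswith("PRINCIPAL")
    return out


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------


def project_aa_to_genomic(
    aa: ProteinFeatureAA, transcript: Transcript
) -> GenomicFeature:
    """Map an amino-acid interval onto genomic blocks through the CDS.

    Amino acid ``i`` (1-based) occupies CDS nucleotide offsets
    ``[3(i-1), 3i)`` counted 5'→3' along the coding sequence: from the
    leftmost CDS base on the + strand, from the rightmost on −.  Features
    running ≤2 nt past an incomplete terminal codon are truncated and
    flagged; anything further out is an error.
    """
    if not transcript.is_coding:
        raise ProjectionError(f"transcript {transcript.transcript_id} is non-coding")
    cds_len = transcript.cds_length
    nt_start = 3 * (aa.aa_start - 1)
    nt_end = 3 * aa.aa_end
    truncated = False
    if nt_start >= cds_len:
        raise ProjectionError(
            f"feature {aa.signature_acc} {aa.aa_start}..{aa.aa_end} outside CDS "
            f"of {transcript.transcript_id} (CDS {cds_len} nt)"
        )
    if nt_end > cds_len:
        if nt_end - cds_len <= 2:
            nt_end = cds_len
            truncated = True
        else:
            raise ProjectionError(
                f"feature {aa.signature_acc} {aa.aa_start}..{aa.aa_end} outside CDS "
                f"of {transcript.transcript_id} (CDS {cds_len} nt)"
            )

    blocks: list[GenomicInterval] = []
    offset = 0
    if transcript.strand == "+":
        ordered: Iterator[GenomicInterval] = iter(transcript.cds_blocks)
    else:
        ordered = iter(reversed(transcript.cds_blocks))
    for block in ordered:
        blen = block.length
        lo = max(nt_start, offset)
        hi = min(nt_end, offset + blen)
        if lo < hi:
            local_lo, local_hi = lo - offset, hi - offset
            if transcript.strand == "+":
                g = GenomicInterval(
                    block.chrom, block.start + local_lo, block.start + local_hi, "+"
                )
            else:
                g = GenomicInterval(
                    block.chrom, block.end - local_hi, block.end - local_lo, "-"
                )
            blocks.append(g)
        offset += blen
        if offset >= nt_end:
            break
    blocks.sort(key=lambda b: b.start)
    return GenomicFeature(aa, transcript.transcript_id, tuple(blocks), truncated)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def build_store(
    gtf: str | Path,
    interpro_tsv: str | Path,
    appris: str | Path | None = None,
    tools: Iterable[str] | None = None,
    id_normalizer: Callable[[str], str] = strip_version,
) -> AnnotationStore:
    """Assemble the full store: annotation + projected features + APPRIS flags."""
    store = read_gtf(gtf)
    if appris is not None:
        flags = read_appris(appris)
        for tid, tx in store.transcripts.items():
            if flags.get(tid) or flags.get(id_normalizer(tid)):
                store.transcripts[tid] = replace(tx, appris_principal=True)
    aa_features = read_interproscan_tsv(interpro_tsv, tools=tools)
    store.attach_features(aa_features, id_normalizer=id_normalizer)
    if not any(t.is_coding for t in store.transcripts.values()):
        warnings.warn("store contains no coding transcripts")
    return store
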