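"""Synthetic fixture generator with machine-readable ground truth.

Emits toy GTF / InterProScan TSV / APPRIS / BED / identity-table / GO-slim
inputs whose expected analysis results are known by construction, so every
analysis module can be tested offline.

Construction template: each gene is a set of non-overlapping exons on a
small synthetic chromosome; every transcript is a subset of those exons and,
when coding, uses its two terminal exons as pure UTR and all internal exons
as full CDS blocks.  Exon lengths are multiples of 3, so protein features
can be planted on contiguous exon runs with exact amino-acid coordinates.
Distinct features within a gene occupy disjoint exon runs, which keeps their
genomic hulls disjoint and makes region-overlap truth unambiguous.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from altfeat.annotation_store import (
    AnnotationStore,
    Gene,
    GenomicInterval,
    Transcript,
    write_gtf,
)
from altfeat.errors import DataError

DEFAULT_ALPHABET = tuple(f"PF{10001 + i:05d}" for i in range(12))


@dataclass
class SimConfig:
    """Parameters of the annotation fixture; identical (config, seed) pairs
    produce byte-identical files."""

    n_genes: int = 8
    transcripts_per_gene: tuple[int, int] = (2, 5)
    exons_per_gene: tuple[int, int] = (5, 9)
    noncoding_fraction: float = 0.15
    features_per_gene: tuple[int, int] = (1, 3)
    tool: str = "Pfam"
    accession_alphabet: tuple[str, ...] = DEFAULT_ALPHABET
    chrom: str = "1"
    include_fig_gene: bool = True
    ratio_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise DataError("n_genes must be >= 0")
        if not (0.0 <= self.noncoding_fraction <= 1.0):
            raise DataError("noncoding_fraction must be in [0, 1]")
        if not (0.0 <= self.ratio_threshold <= 1.0):
            raise DataError("ratio_threshold must be in [0, 1]")
        if self.features_per_gene[1] > len(self.accession_alphabet):
            raise DataError("accession alphabet smaller than features_per_gene max")


# ---------------------------------------------------------------------------
# gene plans
# ---------------------------------------------------------------------------


@dataclass
class _TxPlan:
    transcript_id: str
    exon_idx: list[int]  # genomic-order indices into the gene exon list
    coding: bool

    def coding_idx(self) -> list[int]:
        if not self.coding or len(self.exon_idx) < 3:
            return []
        return self.exon_idx[1:-1]


@dataclass
class _FeatPlan:
    tool: str
    signature_acc: str
    interpro_acc: str
    description: str
    run: tuple[int, int]  # inclusive exon-index range


@dataclass
class _GenePlan:
    gene_id: str
    name: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # genomic order
    transcripts: list[_TxPlan] = field(default_factory=list)
    features: list[_FeatPlan] = field(default_factory=list)

    # -- plan arithmetic (the independent truth computation) ---------------

    def cds_length(self, tx: _TxPlan) -> int:
        return sum(self.exons[i][1] - self.exons[i][0] for i in tx.coding_idx())

    def cds_span(self, tx: _TxPlan) -> tuple[int, int] | None:
        idx = tx.coding_idx()
        if not idx:
            return None
        return (self.exons[idx[0]][0], self.exons[idx[-1]][1])

    def hull(self, feat: _FeatPlan) -> tuple[int, int]:
        lo, hi = feat.run
        return (self.exons[lo][0], self.exons[hi][1])

    def carriers(self, feat: _FeatPlan) -> list[_TxPlan]:
        lo, hi = feat.run
        run = set(range(lo, hi + 1))
        return [t for t in self.transcripts if t.coding and run <= set(t.coding_idx())]

    def aa_coords(self, feat: _FeatPlan, tx: _TxPlan) -> tuple[int, int]:
        """1-based inclusive amino-acid range of the feature on a carrier."""
        lo, hi = feat.run
        coding = tx.coding_idx()
        order = coding if self.strand == "+" else list(reversed(coding))
        prior = 0
        for i in order:
            if lo <= i <= hi:
                break
            prior += self.exons[i][1] - self.exons[i][0]
        run_len = sum(self.exons[i][1] - self.exons[i][0] for i in range(lo, hi + 1))
        return (prior // 3 + 1, (prior + run_len) // 3)

    def candidates(self, standard: str, threshold: float,
                   feat: _FeatPlan | None = None) -> list[str]:
        coding = [t for t in self.transcripts if t.coding]
        if not coding:
            return []
        if standard == "coding":
            return sorted(t.transcript_id for t in coding)
        if standard == "cds_ratio":
            major = max(self.cds_length(t) for t in coding)
            return sorted(
                t.transcript_id
                for t in coding
                if self.cds_length(t) / major >= threshold
                or self.cds_length(t) == major
            )
        assert standard == "overlap_cds" and feat is not None
        hs, he = self.hull(feat)
        out = []
        for t in coding:
            span = self.cds_span(t)
            if span is not None and span[0] <= hs and he <= span[1]:
                out.append(t.transcript_id)
        return sorted(out)

    def status(self, standard: str, threshold: float, feat: _FeatPlan) -> str | None:
        cands = self.candidates(standard, threshold, feat)
        if not cands:
            return None
        carriers = {t.transcript_id for t in self.carriers(feat)}
        return "constitutive" if set(cands) <= carriers else "alternative"

    def principal_transcript(self) -> str | None:
        coding = [t for t in self.transcripts if t.coding]
        if not coding:
            return None
        return max(coding, key=lambda t: (self.cds_length(t), t.transcript_id)).transcript_id


def _fig_gene_plan(chrom: str) -> _GenePlan:
    """The packaged illustration gene: five transcripts covering alternative
    internal exons, an alternative TSS, a short-CDS isoform below a 50%%
    ratio, and a non-coding isoform; three planted features with known
    status under every standard."""
    exons = [
        (1000, 1090),   # 0: 5' UTR exon
        (1200, 1350),   # 1: coding, 150 nt
        (1500, 1590),   # 2: coding, 90 nt  (skipped by T2, UTR in T3)
        (1700, 1880),   # 3: coding, 180 nt
        (2000, 2120),   # 4: coding, 120 nt
        (2300, 2420),   # 5: 3' UTR exon
    ]
    plan = _GenePlan("SIMGFIG", "FIGGENE", chrom, "+", exons)
    plan.transcripts = [
        _TxPlan("SIMTFIG01", [0, 1, 2, 3, 4, 5], True),   # major, CDS 540
        _TxPlan("SIMTFIG02", [0, 1, 3, 4, 5], True),      # exon-2 skip, CDS 450
        _TxPlan("SIMTFIG03", [2, 3, 4, 5], True),         # alt TSS, CDS 300
        _TxPlan("SIMTFIG04", [3, 4, 5], True),            # short CDS 120 (<50%)
        _TxPlan("SIMTFIG05", [0, 1, 2], False),           # non-coding
    ]
    plan.features = [
        _FeatPlan("Pfam", "PF90001", "IPR900001", "planted domain A", (3, 3)),
        _FeatPlan("Pfam", "PF90002", "IPR900002", "planted domain B", (2, 2)),
        _FeatPlan("Pfam", "PF90003", "", "planted domain C", (4, 4)),
    ]
    return plan


def _random_gene_plan(cfg: SimConfig, rng: np.random.Generator,
                      index: int, cursor: int) -> tuple[_GenePlan, int]:
    n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    exons: list[tuple[int, int]] = []
    pos = cursor
    for _ in range(n_exons):
        length = 3 * int(rng.integers(20, 81))  # 60..240 nt, multiple of 3
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(80, 501))
    gid = f"SIMG{index:04d}"
    plan = _GenePlan(gid, f"GENE{index:04d}", cfg.chrom, strand, exons)

    n_tx = int(rng.integers(cfg.transcripts_per_gene[0], cfg.transcripts_per_gene[1] + 1))
    all_idx = list(range(n_exons))
    plan.transcripts.append(_TxPlan(f"SIMT{index:04d}01", all_idx, True))
    for j in range(2, n_tx + 1):
        idx = list(all_idx)
        if rng.random() < 0.35:  # alternative TSS: trim leading exons
            k = int(rng.integers(1, max(2, n_exons - 3)))
            idx = idx[k:]
        if rng.random() < 0.35 and len(idx) > 3:  # alternative TTS
            k = int(rng.integers(1, len(idx) - 2))
            idx = idx[:-k]
        internal = idx[1:-1]
        keep = [i for i in internal if rng.random() >= 0.3]
        if not keep:
            keep = [internal[int(rng.integers(0, len(internal)))]] if internal else []
        idx = [idx[0]] + keep + [idx[-1]] if len(idx) >= 2 else idx
        if len(idx) < 3:
            idx = all_idx[:3]
        coding = rng.random() >= cfg.noncoding_fraction
        plan.transcripts.append(_TxPlan(f"SIMT{index:04d}{j:02d}", idx, coding))

    n_feat = int(rng.integers(cfg.features_per_gene[0], cfg.features_per_gene[1] + 1))
    accs = [
        cfg.accession_alphabet[i]
        for i in rng.choice(len(cfg.accession_alphabet), size=n_feat, replace=False)
    ]
    used: set[int] = set()
    for k, acc in enumerate(sorted(accs)):
        for _attempt in range(40):
            lo = int(rng.integers(1, n_exons - 1))
            hi = min(lo + int(rng.integers(0, 2)), n_exons - 2)
            run = set(range(lo, hi + 1))
            if run & used:
                continue
            feat = _FeatPlan(
                cfg.tool, acc,
                f"IPR{800000 + int(acc[2:]):06d}" if k % 3 != 2 else "",
                f"synthetic domain {acc}", (lo, hi),
            )
            if plan.carriers(feat):  # major always carries; defensive
                used |= run
                plan.features.append(feat)
                break
    return plan, pos + int(rng.integers(2000, 5001))


# ---------------------------------------------------------------------------
# emission
# ---------------------------------------------------------------------------


def _plans_to_store(plans: list[_GenePlan]) -> AnnotationStore:
    store = AnnotationStore()
    for plan in plans:
        store.add_gene(Gene(plan.gene_id, plan.name, plan.chrom, plan.strand,
                            "protein_coding"))
        principal = plan.principal_transcript()
        for tx in plan.transcripts:
            exons = [
                GenomicInterval(plan.chrom, *plan.exons[i], plan.strand)
                for i in tx.exon_idx
            ]
            cds = [
                GenomicInterval(plan.chrom, *plan.exons[i], plan.strand)
                for i in tx.coding_idx()
            ]
            store.add_transcript(
                Transcript(
                    tx.transcript_id, plan.gene_id, plan.chrom, plan.strand,
                    exons, cds,
                    protein_id=tx.transcript_id.replace("SIMT", "SIMP") if tx.coding else "",
                    appris_principal=tx.transcript_id == principal,
                    biotype="protein_coding" if tx.coding else "processed_transcript",
                )
            )
    return store


def _truth_manifest(cfg: SimConfig, plans: list[_GenePlan], n_rows: int) -> dict:
    genes: dict = {}
    for plan in plans:
        genes[plan.gene_id] = {
            "name": plan.name,
            "strand": plan.strand,
            "n_exons": len(plan.exons),
            "n_transcripts": len(plan.transcripts),
            "principal": plan.principal_transcript(),
            "transcripts": {
                t.transcript_id: {
                    "coding": t.coding,
                    "n_exons": len(t.exon_idx),
                    "cds_length": plan.cds_length(t),
                    "cds_span": plan.cds_span(t),
                }
                for t in plan.transcripts
            },
        }
    groups = []
    for plan in plans:
        for feat in plan.features:
            carriers = plan.carriers(feat)
            instances = []
            for tx in carriers:
                a0, a1 = plan.aa_coords(feat, tx)
                lo, hi = feat.run
                instances.append(
                    {
                        "transcript_id": tx.transcript_id,
                        "aa_start": a0,
                        "aa_end": a1,
                        "blocks": [list(plan.exons[i]) for i in range(lo, hi + 1)],
                    }
                )
            groups.append(
                {
                    "gene_id": plan.gene_id,
                    "tool": feat.tool,
                    "signature_acc": feat.signature_acc,
                    "interpro_acc": feat.interpro_acc,
                    "hull": list(plan.hull(feat)),
                    "carriers": sorted(t.transcript_id for t in carriers),
                    "instances": instances,
                    "candidates": {
                        s: plan.candidates(s, cfg.ratio_threshold, feat)
                        for s in ("coding", "cds_ratio", "overlap_cds")
                    },
                    "status": {
                        s: plan.status(s, cfg.ratio_threshold, feat)
                        for s in ("coding", "cds_ratio", "overlap_cds")
                    },
                }
            )
    spans = sorted(
        (plan.exons[0][0], plan.exons[-1][1]) for plan in plans
    )
    gaps = []
    prev = 200
    for s, e in spans:
        if s - 100 > prev + 100:
            gaps.append([prev + 100, s - 100])
        prev = max(prev, e)
    gaps.append([prev + 100, prev + 100_000])
    return {
        "config": {**asdict(cfg), "accession_alphabet": list(cfg.accession_alphabet)},
        "ratio_threshold": cfg.ratio_threshold,
        "n_genes": len(plans),
        "n_transcripts": sum(len(p.transcripts) for p in plans),
        "n_exon_records": sum(len(t.exon_idx) for p in plans for t in p.transcripts),
        "n_interpro_rows": n_rows,
        "genes": genes,
        "groups": groups,
        "intergenic": gaps,
    }


def simulate_annotation(cfg: SimConfig, out_dir: str | Path) -> tuple[dict, dict]:
    """Generate GTF + InterProScan TSV + APPRIS files and a truth manifest.

    Returns ``(paths, manifest)``; the manifest is also written as
    ``manifest.json`` in the output directory.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    plans: list[_GenePlan] = []
    cursor = 1000
    if cfg.include_fig_gene:
        plans.append(_fig_gene_plan(cfg.chrom))
        cursor = 2420 + 3000
    for i in range(1, cfg.n_genes + 1):
        plan, cursor = _random_gene_plan(cfg, rng, i, cursor)
        plans.append(plan)

    store = _plans_to_store(plans)
    gtf_path = out_dir / "annotation.gtf"
    write_gtf(store, gtf_path)

    ipr_path = out_dir / "interproscan.tsv"
    n_rows = 0
    with open(ipr_path, "w") as fh:
        for plan in plans:
            for feat in plan.features:
                for tx in plan.carriers(feat):
                    a0, a1 = plan.aa_coords(feat, tx)
                    pid = tx.transcript_id.replace("SIMT", "SIMP") + ".1"
                    cds_len = plan.cds_length(tx)
                    fh.write(
                        "\t".join(
                            [
                                pid, "-", str(cds_len // 3), feat.tool,
                                feat.signature_acc, feat.description,
                                str(a0), str(a1), "1.0E-10", "T", "01-01-2022",
                                feat.interpro_acc or "-",
                                feat.description if feat.interpro_acc else "-",
                            ]
                        )
                        + "\n"
                    )
                    n_rows += 1

    appris_path = out_dir / "appris.tsv"
    with open(appris_path, "w") as fh:
        for plan in plans:
            principal = plan.principal_transcript()
            for tx in plan.transcripts:
                if not tx.coding:
                    continue
                label = "PRINCIPAL:1" if tx.transcript_id == principal else "ALTERNATIVE:2"
                fh.write(f"{plan.gene_id}\t{tx.transcript_id}\t{label}\n")

    manifest = _truth_manifest(cfg, plans, n_rows)
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    paths = {
        "gtf": str(gtf_path),
        "interpro": str(ipr_path),
        "appris": str(appris_path),
        "manifest": str(manifest_path),
    }
    return paths, manifest


# ---------------------------------------------------------------------------
# region fixtures
# ---------------------------------------------------------------------------


def simulate_regions(
    manifest: dict,
    out_dir: str | Path,
    planted_acc: str | None = None,
    fold: float = 4.0,
    n_target: int = 200,
    n_background: int = 200,
    base_rate: float = 0.05,
    region_length: int = 50,
    seed: int = 0,
) -> tuple[dict, dict]:
    """Emit target/background BED files with one accession planted at
    ``fold`` times the background hit rate; every other accession is hit at
    ``base_rate`` in both lists and remaining regions fall in intergenic
    gaps.  Returns (paths, region manifest with realized per-accession
    counts)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    by_acc: dict[str, list[tuple[int, int]]] = {}
    for group in manifest["groups"]:
        by_acc.setdefault(group["signature_acc"], []).append(tuple(group["hull"]))
    if not by_acc:
        raise DataError("annotation fixture contains no features")
    accs = sorted(by_acc)
    if planted_acc is None:
        planted_acc = accs[0]
    if planted_acc not in by_acc:
        raise DataError(f"planted accession {planted_acc} not in fixture")
    p_target = fold * base_rate
    others = [a for a in accs if a != planted_acc]
    if p_target > 1.0 or p_target + base_rate * len(others) > 1.0:
        raise DataError("requested fold incompatible with base_rate (p > 1)")

    chrom = manifest["config"]["chrom"]
    gaps = manifest["intergenic"]

    def place_in(lo: int, hi: int) -> tuple[int, int]:
        length = min(region_length, hi - lo)
        start = int(rng.integers(lo, max(lo + 1, hi - length + 1)))
        return start, start + length

    def make_list(n: int, p_planted: float) -> tuple[list[tuple[int, int, str]], dict[str, int]]:
        regions = []
        counts: dict[str, int] = {a: 0 for a in accs}
        for i in range(n):
            u = float(rng.random())
            acc = None
            edge = p_planted
            if u < edge:
                acc = planted_acc
            else:
                for a in others:
                    edge += base_rate
                    if u < edge:
                        acc = a
                        break
            if acc is None:
                gap = gaps[int(rng.integers(0, len(gaps)))]
                s, e = place_in(gap[0], gap[1])
            else:
                hulls = by_acc[acc]
                hull = hulls[int(rng.integers(0, len(hulls)))]
                s, e = place_in(hull[0], hull[1])
                counts[acc] += 1
            regions.append((s, e, f"r{i}"))
        return regions, counts

    target_regions, counts_t = make_list(n_target, p_target)
    background_regions, counts_b = make_list(n_background, base_rate)

    paths = {}
    for label, regions in (("target", target_regions), ("background", background_regions)):
        path = out_dir / f"{label}.bed"
        with open(path, "w") as fh:
            for s, e, name in regions:
                fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")
        paths[label] = str(path)

    region_manifest = {
        "planted_acc": planted_acc,
        "fold": fold,
        "base_rate": base_rate,
        "n_target": n_target,
        "n_background": n_background,
        "counts_target": counts_t,
        "counts_background": counts_b,
    }
    manifest_path = out_dir / "regions_manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(region_manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    paths["manifest"] = str(manifest_path)
    return paths, region_manifest


# ---------------------------------------------------------------------------
# identity + GO fixtures
# ---------------------------------------------------------------------------


def status_truth_units(manifest: dict, standard: str = "overlap_cds") -> dict[str, dict[str, str]]:
    """Planted (gene -> accession -> status) units for one standard."""
    units: dict[str, dict[str, str]] = {}
    for group in manifest["groups"]:
        st = group["status"][standard]
        if st is None:
            continue
        per_gene = units.setdefault(group["gene_id"], {})
        acc = group["signature_acc"]
        if st == "alternative" or acc not in per_gene:
            per_gene[acc] = st if st == "alternative" else per_gene.get(acc, st)
    return units


def simulate_identity_and_go(
    manifest_a: dict,
    manifest_b: dict,
    out_dir: str | Path,
    n_pairs: int = 50,
    n_decoys: int = 20,
    n_terms: int = 5,
    seed: int = 0,
) -> tuple[dict, dict]:
    """Emit two identity tables whose reciprocal best hits are exactly the
    planted pairs (plus one-way and tie decoys that must not pair), and a
    GO-slim membership table over species-A genes with per-term truth
    tallies computed from the planted domain statuses."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    genes_a = sorted(manifest_a["genes"])
    genes_b = sorted(manifest_b["genes"])
    if len(genes_a) < n_pairs + n_decoys or len(genes_b) < n_pairs:
        raise DataError(
            f"need >= {n_pairs + n_decoys} species-A genes and >= {n_pairs} "
            "species-B genes for the requested plant"
        )
    paired_a = genes_a[:n_pairs]
    paired_b = genes_b[:n_pairs]
    decoy_a = genes_a[n_pairs:n_pairs + n_decoys]

    rows_ab: list[tuple[str, str, float]] = []
    rows_ba: list[tuple[str, str, float]] = []
    for a, b in zip(paired_a, paired_b):
        ident = float(np.round(rng.uniform(70, 95), 2))
        rows_ab.append((a, b, ident))
        rows_ba.append((b, a, float(np.round(rng.uniform(70, 95), 2))))
        # lower-identity noise hit so the argmax is non-trivial
        other = paired_b[int(rng.integers(0, n_pairs))]
        if other != b:
            rows_ab.append((a, other, float(np.round(rng.uniform(10, ident - 5), 2))))
    for i, a in enumerate(decoy_a):
        # one-way decoy: its best hit is a paired B gene whose own best hit
        # points back to its partner, so reciprocity fails
        b = paired_b[int(rng.integers(0, n_pairs))]
        if i == 0 and n_pairs >= 2:
            # tie decoy: two equal-identity targets; best hit must resolve to
            # the lexicographically smaller id
            b1, b2 = sorted((paired_b[0], paired_b[1]))
            rows_ab.append((a, b1, 55.0))
            rows_ab.append((a, b2, 55.0))
        else:
            rows_ab.append((a, b, float(np.round(rng.uniform(40, 60), 2))))

    ab_path = out_dir / "identity_ab.tsv"
    ba_path = out_dir / "identity_ba.tsv"
    for path, rows in ((ab_path, rows_ab), (ba_path, rows_ba)):
        with open(path, "w") as fh:
            fh.write("query_gene\ttarget_gene\tpct_identity_query\n")
            for q, t, pct in rows:
                fh.write(f"{q}\t{t}\t{pct}\n")

    units = status_truth_units(manifest_a)
    genes_with_units = sorted(units)
    alt_genes = sorted(
        g for g, per in units.items()
        if any(s == "alternative" for s in per.values())
    )
    con_genes = sorted(
        g for g, per in units.items()
        if all(s == "constitutive" for s in per.values())
    )

    term_members: dict[str, tuple[str, list[str]]] = {}
    if genes_with_units:
        term_members["GO:SIM0001"] = ("planted high-alternative process", alt_genes)
        term_members["GO:SIM0002"] = ("planted constitutive process", con_genes)
        for i in range(3, n_terms + 1):
            k = max(1, len(genes_with_units) // 2)
            pick = sorted(
                genes_with_units[j]
                for j in rng.choice(len(genes_with_units), size=k, replace=False)
            )
            term_members[f"GO:SIM{i:04d}"] = (f"random process {i}", pick)

    go_path = out_dir / "go_slim.tsv"
    go_truth = {}
    with open(go_path, "w") as fh:
        for term_id, (term_name, members) in sorted(term_members.items()):
            n_units = n_alt = 0
            for g in members:
                fh.write(f"{term_id}\t{term_name}\t{g}\n")
                per = units.get(g, {})
                n_units += len(per)
                n_alt += sum(1 for s in per.values() if s == "alternative")
            go_truth[term_id] = {"n_genes": len(members), "n_units": n_units,
                                 "n_alternative": n_alt}

    truth = {
        "pairs": [[a, b] for a, b in zip(paired_a, paired_b)],
        "decoys_a": decoy_a,
        "tie_decoy": decoy_a[0] if decoy_a and n_pairs >= 2 else None,
        "tie_expected_hit": sorted((paired_b[0], paired_b[1]))[0] if n_pairs >= 2 else None,
        "go_terms": go_truth,
    }
    truth_path = out_dir / "identity_go_manifest.json"
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    paths = {
        "ab": str(ab_path),
        "ba": str(ba_path),
        "go": str(go_path),
        "manifest": str(truth_path),
    }
    return paths, truth
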