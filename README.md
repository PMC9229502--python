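# altfeat

Identification of **alternatively included protein features** — domains,
motifs and sites predicted in protein coordinates — across the transcript
isoforms of a gene, plus downstream analyses built on that classification:

* **Annotation store** — parses an Ensembl-dialect GTF, InterProScan TSV
  output and an APPRIS principal-isoform list, projects each protein-coordinate
  feature onto genomic blocks through its transcript's CDS, and indexes
  everything for interval queries.
* **Alternative/constitutive classification** — feature instances with the
  same signature accession and overlapping genomic spans are grouped; each
  group is classified under three candidate-transcript standards:
  all coding transcripts, a CDS-length-ratio cutoff against the gene's longest
  CDS, and an "overlap CDS" standard where only transcripts whose CDS genomic
  span fully contains the feature span count (candidates vary per feature).
* **Region enrichment** — a target vs background BED comparison: per-accession
  2×2 chi-square (Yates correction) with Benjamini–Hochberg adjustment and a
  pooled-frequency fold change that never divides by zero.
* **Cross-species conservation** — reciprocal-best-hit homologs from
  percentage-identity tables; common vs species-specific domain units and their
  alternative/constitutive status; per-accession splicing-potential correlation.
* **GO-slim scan** — per-term alternative-domain fraction tested against the
  genomic average.
* **Synthetic fixtures** — a generator that emits GTF/InterProScan/APPRIS/
  BED/identity/GO files with a machine-readable truth manifest, so the entire
  pipeline is testable offline with planted ground truth.

## CLI

```bash
# generate a synthetic fixture (annotation + planted-enrichment regions)
altfeat simulate --seed 1 --n-genes 8 --regions --out sim/

# build the annotation store
altfeat build-db --gtf sim/annotation/annotation.gtf \
    --interpro sim/annotation/interproscan.tsv \
    --appris sim/annotation/appris.tsv --out db/

# single-gene report: feature table, classification table, diagram
altfeat annotate-gene --db db/ --gene SIMGFIG --ratio 0.5 --out gene/ \
    --plot gene/diagram.svg

# genome-wide status table for one standard
altfeat classify --db db/ --standard overlap_cds --out status.tsv

# region-list enrichment
altfeat enrich --db db/ --target sim/regions/target.bed \
    --background sim/regions/background.bed --out enrich/

# reciprocal-best-hit homologs (+ optional status comparison)
altfeat homology --ab h2m.tsv --ba m2h.tsv \
    --status-a h_status.tsv --status-b m_status.tsv --min-count 50 --out hom/

# GO-slim alternative-domain scan
altfeat go-scan --go go_slim.tsv --status status.tsv --out scan.tsv
```

Exit codes: `0` success, `1` usage error, `2` data error.

## Layout

```
src/altfeat/
  annotation_store.py  GTF/InterProScan/APPRIS readers, aa→genomic projection,
                       interval-indexed store
  alt_classifier.py    feature grouping, the three standards, per-gene reports
  enrichment.py        BED reading, region annotation, chi-square + BH + FC
  homology.py          best hits, reciprocal best hits, status comparison,
                       splicing potential
  go_analysis.py       GO-slim term scan
  simulate.py          synthetic fixture generator + truth manifests
  diagram.py           transcript/feature diagram rendering
  cli.py               `altfeat` entry point
```

Internal coordinates are 0-based half-open everywhere; GTF (1-based
inclusive) is converted on read/write, BED is native.
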