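import pytest

from altfeat.annotation_store import (
    GenomicInterval,
    ProteinFeatureAA,
    Transcript,
    build_store,
)
from altfeat.simulate import SimConfig, simulate_annotation


def make_transcript(
    tid="T1",
    gene_id="G1",
    chrom="1",
    strand="+",
    exons=((100, 130),),
    cds=((100, 130),),
    protein_id="P1",
):
    """Small hand-built transcript for unit tests."""
    exon_iv = [GenomicInterval(chrom, s, e, strand) for s, e in exons]
    cds_iv = [GenomicInterval(chrom, s, e, strand) for s, e in cds]
    return Transcript(tid, gene_id, chrom, strand, exon_iv, cds_iv, protein_id)


def make_feature(protein_id="P1", tool="Pfam", acc="PF00001", start=1, end=1,
                 interpro="", description=""):
    return ProteinFeatureAA(protein_id, tool, acc, start, end, interpro, description)


def brute_force_projection(transcript, aa_start, aa_end):
    """Independent per-nucleotide oracle for the CDS coordinate map.

    Enumerates every CDS nucleotide in 5'->3' order, slices the feature's
    codon range, and re-assembles genomic blocks from the sorted positions.
    Truncates silently at the CDS end (mirrors the documented <=2 nt rule).
    """
    positions = []
    if transcript.strand == "+":
        for block in transcript.cds_blocks:
            positions.extend(range(block.start, block.end))
    else:
        for block in reversed(transcript.cds_blocks):
            positions.extend(range(block.end - 1, block.start - 1, -1))
    selected = sorted(positions[3 * (aa_start - 1): 3 * aa_end])
    blocks = []
    for pos in selected:
        if blocks and pos == blocks[-1][1]:
            blocks[-1][1] = pos + 1
        else:
            blocks.append([pos, pos + 1])
    return [tuple(b) for b in blocks]


def brute_force_overlaps(spans, chrom, start, end):
    """All indices i whose span (chrom, s, e) overlaps [start, end)."""
    return [
        i
        for i, (c, s, e) in enumerate(spans)
        if c == chrom and s < end and start < e
    ]


@pytest.fixture(scope="session")
def fixture_data(tmp_path_factory):
    """Standard annotation fixture (seed 1) with its truth manifest."""
    out = tmp_path_factory.mktemp("fixture_seed1")
    paths, manifest = simulate_annotation(SimConfig(n_genes=8, seed=1), out)
    return paths, manifest


@pytest.fixture(scope="session")
def fixture_store(fixture_data):
    paths, _ = fixture_data
    return build_store(paths["gtf"], paths["interpro"], paths["appris"])


@pytest.fixture(scope="session")
def fig_gene_store(tmp_path_factory):
    """Store containing only the packaged five-transcript illustration gene."""
    out = tmp_path_factory.mktemp("fig_gene")
    paths, manifest = simulate_annotation(
        SimConfig(n_genes=0, include_fig_gene=True, seed=0), out
    )
    return build_store(paths["gtf"], paths["interpro"], paths["appris"]), manifest
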