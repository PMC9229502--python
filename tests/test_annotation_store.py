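import numpy as np
import pytest

from altfeat.annotation_store import (
    AnnotationStore,
    GenomicInterval,
    IntervalIndex,
    ProteinFeatureAA,
    build_store,
    project_aa_to_genomic,
    read_appris,
    read_gtf,
    read_interproscan_tsv,
    strip_version,
    write_gtf,
)
from altfeat.errors import LookupFailure, ParseError, ProjectionError

from conftest import (
    brute_force_overlaps,
    brute_force_projection,
    make_feature,
    make_transcript,
)

TOY_GTF = """\
1\ttest\tgene\t101\t500\t.\t+\t.\tgene_id "G1"; gene_name "ALPHA"; gene_biotype "protein_coding";
1\ttest\ttranscript\t101\t500\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T1"; exon_number "1";
1\ttest\texon\t301\t500\t.\t+\t.\tgene_id "G1"; transcript_id "T1"; exon_number "2";
1\ttest\tCDS\t131\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T1"; protein_id "P1";
1\ttest\tCDS\t301\t400\t.\t+\t.\tgene_id "G1"; transcript_id "T1"; protein_id "P1";
1\ttest\ttranscript\t101\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T2";
1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T2"; exon_number "1";
"""


class TestGenomicInterval:
    def test_invariants(self):
        with pytest.raises(ValueError):
            GenomicInterval("1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("1", -1, 10)
        with pytest.raises(ValueError):
            GenomicInterval("1", 5, 10, ".")

    def test_overlap_is_strandless(self):
        a = GenomicInterval("1", 0, 10, "+")
        b = GenomicInterval("1", 9, 20, "-")
        assert a.overlaps(b) and b.overlaps(a)
        assert not a.overlaps(GenomicInterval("1", 10, 20))
        assert not a.overlaps(GenomicInterval("2", 0, 10))


class TestReadGtf:
    def test_toy_gene_two_transcripts(self, tmp_path):
        path = tmp_path / "toy.gtf"
        path.write_text(TOY_GTF)
        store = read_gtf(path)
        assert len(store.genes) == 1
        assert len(store.transcripts) == 2
        assert store.transcripts["T1"].is_coding
        assert not store.transcripts["T2"].is_coding
        assert store.genes["G1"].name == "ALPHA"

    def test_one_based_conversion(self, tmp_path):
        path = tmp_path / "conv.gtf"
        path.write_text(
            '1\tx\texon\t101\t130\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
        )
        store = read_gtf(path)
        (exon,) = store.transcripts["T"].exons
        assert (exon.start, exon.end) == (100, 130)
        assert exon.length == 30

    def test_missing_attribute_names_line(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text("# header\n1\tx\texon\t1\t10\t.\t+\t.\tfoo \"bar\";\n")
        with pytest.raises(ParseError, match="line 2"):
            read_gtf(path)

    def test_end_before_start_rejected(self, tmp_path):
        path = tmp_path / "bad2.gtf"
        path.write_text('1\tx\texon\t50\t10\t.\t+\t.\tgene_id "G"; transcript_id "T";\n')
        with pytest.raises(ParseError, match="end < start"):
            read_gtf(path)

    def test_unplaced_contig_kept_verbatim(self, tmp_path):
        path = tmp_path / "contig.gtf"
        path.write_text(
            'KI270728.1\tx\texon\t1\t60\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
        )
        store = read_gtf(path)
        assert store.transcripts["T"].chrom == "KI270728.1"

    def test_fixture_counts_match_manifest(self, fixture_data):
        paths, manifest = fixture_data
        store = read_gtf(paths["gtf"])
        assert len(store.genes) == manifest["n_genes"]
        assert len(store.transcripts) == manifest["n_transcripts"]
        n_exons = sum(len(t.exons) for t in store.transcripts.values())
        assert n_exons == manifest["n_exon_records"]

    def test_write_then_read_preserves_intervals(self, fixture_store, tmp_path):
        out = tmp_path / "roundtrip.gtf"
        write_gtf(fixture_store, out)
        again = read_gtf(out)
        assert set(again.transcripts) == set(fixture_store.transcripts)
        for tid, tx in fixture_store.transcripts.items():
            assert again.transcripts[tid].exons == tx.exons
            assert again.transcripts[tid].cds_blocks == tx.cds_blocks


class TestReadInterproscan:
    def test_field_mapping(self, tmp_path):
        path = tmp_path / "ipr.tsv"
        path.write_text(
            "P1\t-\t100\tPfam\tPF00001\ta domain\t10\t60\t1e-5\tT\t01-01-2022\tIPR000001\tsame\n"
        )
        (rec,) = read_interproscan_tsv(path)
        assert rec == ProteinFeatureAA("P1", "Pfam", "PF00001", 10, 60,
                                       "IPR000001", "a domain")

    def test_tool_filter(self, tmp_path):
        path = tmp_path / "ipr.tsv"
        rows = [
            "P1\t-\t100\tPfam\tPF00001\td\t1\t10",
            "P1\t-\t100\tPfam\tPF00002\td\t20\t30",
            "P1\t-\t100\tPRINTS\tPR00001\td\t1\t10",
        ]
        path.write_text("\n".join(rows) + "\n")
        assert len(read_interproscan_tsv(path, tools={"Pfam"})) == 2
        assert len(read_interproscan_tsv(path)) == 3

    def test_dash_interpro_stored_empty(self, tmp_path):
        path = tmp_path / "ipr.tsv"
        path.write_text("P1\t-\t100\tPfam\tPF1\td\t1\t10\t.\tT\t.\t-\t-\n")
        (rec,) = read_interproscan_tsv(path)
        assert rec.interpro_acc == ""

    def test_stop_before_start_rejected_with_warning(self, tmp_path):
        path = tmp_path / "ipr.tsv"
        path.write_text("P1\t-\t100\tPfam\tPF1\td\t60\t10\n")
        with pytest.warns(UserWarning, match="stop < start"):
            assert read_interproscan_tsv(path) == []

    def test_fixture_count_matches_manifest(self, fixture_data):
        paths, manifest = fixture_data
        records = read_interproscan_tsv(paths["interpro"])
        assert len(records) == manifest["n_interpro_rows"]


class TestReadAppris:
    def test_principal_and_alternative(self, tmp_path):
        path = tmp_path / "appris.tsv"
        path.write_text("ENST0001\tPRINCIPAL:1\nENST0002\tALTERNATIVE:2\n")
        flags = read_appris(path)
        assert flags == {"ENST0001": True, "ENST0002": False}

    def test_malformed_row_skipped(self, tmp_path):
        path = tmp_path / "appris.tsv"
        path.write_text("justonefield\nENST0001\tPRINCIPAL:1\n")
        with pytest.warns(UserWarning):
            flags = read_appris(path)
        assert flags == {"ENST0001": True}

    def test_fixture_principals_flagged(self, fixture_data, fixture_store):
        _, manifest = fixture_data
        for gid, ginfo in manifest["genes"].items():
            for tid in ginfo["transcripts"]:
                expected = tid == ginfo["principal"]
                assert fixture_store.transcripts[tid].appris_principal == expected


class TestProjection:
    def test_first_codon_plus_strand(self):
        tx = make_transcript(exons=((100, 130),), cds=((100, 130),))
        gf = project_aa_to_genomic(make_feature(start=1, end=1), tx)
        assert [(b.start, b.end) for b in gf.blocks] == [(100, 103)]
        assert not gf.truncated

    def test_plus_strand_across_junction(self):
        tx = make_transcript(exons=((100, 110), (200, 220)),
                             cds=((100, 110), (200, 220)))
        # aa 2..5 -> CDS offsets [3, 15): 7 nt from the first block and 5 nt
        # from the second (12 nt = 4 codons total)
        gf = project_aa_to_genomic(make_feature(start=2, end=5), tx)
        assert [(b.start, b.end) for b in gf.blocks] == [(103, 110), (200, 205)]
        assert [(b.start, b.end) for b in gf.blocks] == brute_force_projection(tx, 2, 5)

    def test_minus_strand_first_two_codons(self):
        tx = make_transcript(strand="-", exons=((100, 130),), cds=((100, 130),))
        gf = project_aa_to_genomic(make_feature(start=1, end=2), tx)
        assert [(b.start, b.end) for b in gf.blocks] == [(124, 130)]
        assert [(b.start, b.end) for b in gf.blocks] == brute_force_projection(tx, 1, 2)

    def test_outside_cds_raises(self):
        tx = make_transcript(exons=((100, 130),), cds=((100, 130),))  # 10 aa
        with pytest.raises(ProjectionError, match="outside CDS"):
            project_aa_to_genomic(make_feature(start=5, end=12), tx)

    def test_incomplete_terminal_codon_truncates(self):
        # CDS length 31: 10 full codons + 1 dangling nt
        tx = make_transcript(exons=((100, 131),), cds=((100, 131),))
        gf = project_aa_to_genomic(make_feature(start=9, end=11), tx)
        assert gf.truncated
        assert sum(b.length for b in gf.blocks) == 31 - 24

    def test_noncoding_transcript_rejected(self):
        tx = make_transcript(cds=())
        with pytest.raises(ProjectionError, match="non-coding"):
            project_aa_to_genomic(make_feature(), tx)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_random_features_match_bruteforce(self, strand):
        rng = np.random.default_rng(0 if strand == "+" else 1)
        for _ in range(200):
            n_blocks = int(rng.integers(1, 5))
            pos = int(rng.integers(0, 1000))
            blocks = []
            for _ in range(n_blocks):
                length = int(rng.integers(3, 120))
                blocks.append((pos, pos + length))
                pos += length + int(rng.integers(30, 200))
            tx = make_transcript(strand=strand, exons=tuple(blocks), cds=tuple(blocks))
            n_aa = tx.protein_length
            if n_aa < 1:
                continue
            a0 = int(rng.integers(1, n_aa + 1))
            a1 = int(rng.integers(a0, n_aa + 1))
            gf = project_aa_to_genomic(make_feature(start=a0, end=a1), tx)
            assert [(b.start, b.end) for b in gf.blocks] == brute_force_projection(tx, a0, a1)
            if not gf.truncated:
                assert sum(b.length for b in gf.blocks) == 3 * (a1 - a0 + 1)

    def test_strand_symmetry_mirror(self):
        """Reflecting all coordinates (x -> C - x) and flipping strand yields
        the mirrored blocks."""
        C = 10_000
        exons = ((100, 110), (200, 220), (400, 430))
        tx_plus = make_transcript(strand="+", exons=exons, cds=exons)
        mirrored = tuple(sorted((C - e, C - s) for s, e in exons))
        tx_minus = make_transcript(strand="-", exons=mirrored, cds=mirrored)
        for a0, a1 in [(1, 1), (2, 5), (1, 20), (7, 13)]:
            fwd = project_aa_to_genomic(make_feature(start=a0, end=a1), tx_plus)
            rev = project_aa_to_genomic(make_feature(start=a0, end=a1), tx_minus)
            expected = sorted((C - b.end, C - b.start) for b in fwd.blocks)
            assert [(b.start, b.end) for b in rev.blocks] == expected

    def test_blocks_within_cds_sorted_disjoint(self, fixture_store):
        for gf in fixture_store.features:
            tx = fixture_store.transcripts[gf.transcript_id]
            for block in gf.blocks:
                assert any(cb.contains(block) for cb in tx.cds_blocks)
            for left, right in zip(gf.blocks, gf.blocks[1:]):
                assert left.end <= right.start


class TestIntervalIndex:
    def test_matches_bruteforce_on_random_queries(self):
        rng = np.random.default_rng(7)
        spans = []
        for _ in range(500):
            s = int(rng.integers(0, 100_000))
            spans.append(("1", s, s + int(rng.integers(1, 5000))))
        index = IntervalIndex((c, s, e, i) for i, (c, s, e) in enumerate(spans))
        for _ in range(1000):
            q0 = int(rng.integers(0, 105_000))
            q1 = q0 + int(rng.integers(1, 3000))
            got = sorted(index.query("1", q0, q1))
            assert got == brute_force_overlaps(spans, "1", q0, q1)

    def test_unknown_chrom_empty(self):
        index = IntervalIndex([("1", 0, 10, "x")])
        assert index.query("2", 0, 100) == []


class TestStore:
    def test_store_query_matches_bruteforce(self, fixture_store):
        rng = np.random.default_rng(3)
        spans = [(f.span.chrom, f.span.start, f.span.end) for f in fixture_store.features]
        hi = max(s[2] for s in spans) + 1000
        for _ in range(500):
            q0 = int(rng.integers(0, hi))
            q1 = q0 + int(rng.integers(1, 4000))
            got = fixture_store.query_features("1", q0, q1)
            expected = brute_force_overlaps(spans, "1", q0, q1)
            assert sorted(id(f) for f in got) == sorted(
                id(fixture_store.features[i]) for i in expected
            )

    def test_empty_interpro_gives_zero_features(self, fixture_data, tmp_path):
        paths, _ = fixture_data
        empty = tmp_path / "empty.tsv"
        empty.write_text("")
        store = build_store(paths["gtf"], empty, paths["appris"])
        assert store.features == []
        assert store.summary()["n_features"] == 0

    def test_unknown_protein_goes_unattached(self, tmp_path, fixture_data):
        paths, _ = fixture_data
        ipr = tmp_path / "orphan.tsv"
        ipr.write_text("NOSUCH\t-\t100\tPfam\tPF1\td\t1\t5\n")
        store = build_store(paths["gtf"], ipr, paths["appris"])
        assert len(store.unattached) == 1
        assert store.features == []

    def test_version_suffix_normalized(self):
        assert strip_version("ENSP00000001.7") == "ENSP00000001"
        assert strip_version("SIMP000101") == "SIMP000101"

    def test_resolve_gene_by_name_and_errors(self, fixture_store):
        gene = next(iter(fixture_store.genes.values()))
        assert fixture_store.resolve_gene(gene.name).gene_id == gene.gene_id
        with pytest.raises(LookupFailure, match="unknown gene"):
            fixture_store.resolve_gene("NOPE")

    def test_ambiguous_name_lists_candidates(self):
        from altfeat.annotation_store import Gene

        store = AnnotationStore()
        store.add_gene(Gene("G1", "SHARED", "1", "+"))
        store.add_gene(Gene("G2", "SHARED", "1", "+"))
        with pytest.raises(LookupFailure, match="G1.*G2"):
            store.resolve_gene("SHARED")

    def test_invalid_aa_range_rejected(self):
        with pytest.raises(ValueError):
            ProteinFeatureAA("P1", "Pfam", "PF1", 5, 4)
        with pytest.raises(ValueError):
            ProteinFeatureAA("P1", "Pfam", "PF1", 0, 4)

    def test_save_load_roundtrip(self, fixture_store, tmp_path):
        fixture_store.save(tmp_path / "db")
        again = AnnotationStore.load(tmp_path / "db")
        assert set(again.genes) == set(fixture_store.genes)
        assert set(again.transcripts) == set(fixture_store.transcripts)
        assert len(again.features) == len(fixture_store.features)
        spans_a = sorted((f.span.start, f.span.end) for f in again.features)
        spans_b = sorted((f.span.start, f.span.end) for f in fixture_store.features)
        assert spans_a == spans_b
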