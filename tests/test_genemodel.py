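"""Gene-model construction, GTF I/O, flattening, typing, junction catalog."""

import numpy as np
import pytest

from spliceforge.genemodel import (
    FlatBin,
    GenomicInterval,
    GtfValidationError,
    assign_functional_type,
    catalog_junctions,
    flatten_exons,
    read_gtf,
    write_gtf,
)

from conftest import (
    flatten_oracle,
    functional_type_oracle,
    make_transcript,
    random_gene,
)
from spliceforge.genemodel import GeneModel


GTF_ONE_GENE = """\
chr1\tsrc\tgene\t101\t900\t.\t+\t.\tgene_id "g1"; gene_biotype "protein_coding";
chr1\tsrc\ttranscript\t101\t900\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\tsrc\texon\t301\t500\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\tsrc\texon\t701\t900\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\tsrc\tCDS\t151\t200\t.\t+\t0\tgene_id "g1"; transcript_id "t1";
chr1\tsrc\tCDS\t301\t400\t.\t+\t0\tgene_id "g1"; transcript_id "t1";
"""


def test_read_gtf_one_gene_converts_coordinates(tmp_path):
    path = tmp_path / "one.gtf"
    path.write_text(GTF_ONE_GENE)
    genes = read_gtf(str(path))
    assert len(genes) == 1
    (g,) = genes
    t = g.transcripts[0]
    assert len(t.exons) == 3
    # 1-based [101,200] becomes half-open [100,200)
    assert (t.exons[0].start, t.exons[0].end) == (100, 200)
    assert t.cds.start == 150 and t.cds.end == 400
    assert g.biotype == "protein_coding"
    assert t.tss == 100


def test_read_gtf_shared_exon(tmp_path):
    rows = [
        'chr1\ts\tgene\t101\t800\t.\t+\t.\tgene_id "g";',
        'chr1\ts\ttranscript\t101\t800\t.\t+\t.\tgene_id "g"; transcript_id "a";',
        'chr1\ts\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "a";',
        'chr1\ts\texon\t601\t800\t.\t+\t.\tgene_id "g"; transcript_id "a";',
        'chr1\ts\ttranscript\t101\t500\t.\t+\t.\tgene_id "g"; transcript_id "b";',
        'chr1\ts\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "b";',
        'chr1\ts\texon\t401\t500\t.\t+\t.\tgene_id "g"; transcript_id "b";',
    ]
    path = tmp_path / "two.gtf"
    path.write_text("\n".join(rows) + "\n")
    (g,) = read_gtf(str(path))
    assert len(g.transcripts) == 2
    a, b = g.transcripts
    assert a.exons[0] == b.exons[0]


def test_read_gtf_exon_outside_gene_span_raises(tmp_path):
    rows = [
        'chr1\ts\tgene\t101\t200\t.\t+\t.\tgene_id "g";',
        'chr1\ts\ttranscript\t101\t300\t.\t+\t.\tgene_id "g"; transcript_id "a";',
        'chr1\ts\texon\t101\t300\t.\t+\t.\tgene_id "g"; transcript_id "a";',
    ]
    path = tmp_path / "bad.gtf"
    path.write_text("\n".join(rows) + "\n")
    with pytest.raises(GtfValidationError):
        read_gtf(str(path))


def test_gtf_round_trip_preserves_models(tmp_path, rng):
    genes = [random_gene(rng, f"G{i}") for i in range(20)]
    path = tmp_path / "rt.gtf"
    write_gtf(genes, str(path))
    back = read_gtf(str(path))
    assert len(back) == len(genes)
    by_id = {g.gene_id: g for g in back}
    for g in genes:
        h = by_id[g.gene_id]
        assert h.strand == g.strand and h.chrom == g.chrom
        ts_g = {t.transcript_id: t for t in g.transcripts}
        ts_h = {t.transcript_id: t for t in h.transcripts}
        assert ts_g.keys() == ts_h.keys()
        for tid in ts_g:
            assert ts_g[tid].exons == ts_h[tid].exons
            if ts_g[tid].cds is None:
                assert ts_h[tid].cds is None


class TestFlatten:
    def test_no_overlap_bins_equal_exons(self):
        t = make_transcript("t", "g", "c", "+", [(0, 100), (200, 300)])
        g = GeneModel("g", [t], "noncoding")
        bins = flatten_exons(g)
        assert [(b.interval.start, b.interval.end) for b in bins] == [
            (0, 100),
            (200, 300),
        ]

    def test_nested_overlap_splits_at_cover_change(self):
        t1 = make_transcript("t1", "g", "c", "+", [(0, 100)])
        t2 = make_transcript("t2", "g", "c", "+", [(0, 150)])
        g = GeneModel("g", [t1, t2], "noncoding")
        bins = flatten_exons(g)
        assert [(b.interval.start, b.interval.end) for b in bins] == [
            (0, 100),
            (100, 150),
        ]

    def test_internal_overlap_three_bins(self):
        t1 = make_transcript("t1", "g", "c", "+", [(0, 100)])
        t2 = make_transcript("t2", "g", "c", "+", [(50, 80)])
        g = GeneModel("g", [t1, t2], "noncoding")
        bins = flatten_exons(g)
        assert [(b.interval.start, b.interval.end) for b in bins] == [
            (0, 50),
            (50, 80),
            (80, 100),
        ]

    def test_matches_per_base_oracle_on_random_genes(self, rng):
        for i in range(200):
            g = random_gene(rng, f"G{i}", max_transcripts=6, max_exons=10)
            got = [(b.interval.start, b.interval.end) for b in flatten_exons(g)]
            assert sorted(got) == flatten_oracle(g)
            # disjoint and tiling the exon union
            union = {
                p for t in g.transcripts for e in t.exons
                for p in range(e.start, e.end)
            }
            covered = [p for s, e in got for p in range(s, e)]
            assert len(covered) == len(set(covered)) == len(union)

    def test_bin_numbering_follows_strand(self):
        t = make_transcript("t", "g", "c", "-", [(0, 100), (200, 300)])
        g = GeneModel("g", [t], "noncoding")
        bins = flatten_exons(g)
        # bin 001 is the 5'-most on the minus strand, i.e. rightmost
        assert bins[0].bin_id.endswith("001")
        assert bins[0].interval.start == 200

    def test_three_prime_terminal_flag(self):
        t = make_transcript("t", "g", "c", "+", [(0, 100), (200, 300)])
        g = GeneModel("g", [t], "noncoding")
        bins = flatten_exons(g)
        assert not bins[0].is_three_prime_terminal
        assert bins[1].is_three_prime_terminal


class TestFunctionalType:
    def _coding_gene(self):
        t = make_transcript(
            "t", "g", "c", "+", [(0, 100), (200, 300), (400, 500)],
            cds=(50, 450),
        )
        return GeneModel("g", [t], "protein_coding")

    def test_bin_upstream_of_cds_is_five_prime_utr(self):
        g = self._coding_gene()
        b = FlatBin("g:1", "g", GenomicInterval("c", 0, 50, "+"))
        assert assign_functional_type(b, g) == "five_prime_utr"

    def test_bin_spanning_cds_start_is_multi_type(self):
        g = self._coding_gene()
        b = FlatBin("g:1", "g", GenomicInterval("c", 0, 100, "+"))
        assert assign_functional_type(b, g) == "multi_type"

    def test_noncoding_gene_forces_noncoding(self):
        t = make_transcript("t", "g", "c", "+", [(0, 100)])
        g = GeneModel("g", [t], "noncoding")
        b = FlatBin("g:1", "g", GenomicInterval("c", 0, 100, "+"))
        assert assign_functional_type(b, g) == "noncoding"

    def test_bin_outside_exon_union_raises(self):
        g = self._coding_gene()
        b = FlatBin("g:1", "g", GenomicInterval("c", 150, 160, "+"))
        with pytest.raises(GtfValidationError):
            assign_functional_type(b, g)

    def test_matches_per_base_oracle_on_random_coding_genes(self, rng):
        for i in range(100):
            g = random_gene(rng, f"G{i}", coding=True)
            for b in flatten_exons(g):
                assert b.functional_type == functional_type_oracle(
                    g, b.interval.start, b.interval.end
                )


class TestCatalogJunctions:
    def test_three_exon_transcript_two_junctions(self):
        t = make_transcript(
            "t", "g", "c", "+", [(0, 100), (200, 300), (400, 500)]
        )
        g = GeneModel("g", [t], "noncoding")
        js = catalog_junctions(g)
        assert len(js) == 2
        assert {(j.donor, j.acceptor) for j in js} == {(99, 200), (299, 400)}
        assert all(j.canonical for j in js)

    def test_shared_junction_deduplicated(self):
        t1 = make_transcript("t1", "g", "c", "+", [(0, 100), (200, 300)])
        t2 = make_transcript(
            "t2", "g", "c", "+", [(0, 100), (200, 300), (400, 500)]
        )
        g = GeneModel("g", [t1, t2], "noncoding")
        js = catalog_junctions(g)
        assert len(js) == 2

    def test_short_intron_excluded(self):
        # 40-bp intron between exons
        t = make_transcript("t", "g", "c", "+", [(0, 100), (140, 240)])
        g = GeneModel("g", [t], "noncoding")
        assert catalog_junctions(g) == []
        assert len(catalog_junctions(g, min_intron=30)) == 1

    def test_short_exon_excluded(self):
        t = make_transcript("t", "g", "c", "+", [(0, 20), (200, 300)])
        g = GeneModel("g", [t], "noncoding")
        assert catalog_junctions(g) == []

    def test_minus_strand_donor_acceptor_orientation(self):
        t = make_transcript("t", "g", "c", "-", [(0, 100), (200, 300)])
        g = GeneModel("g", [t], "noncoding")
        (j,) = catalog_junctions(g)
        # transcription right-to-left: donor is the left edge of the right
        # exon, acceptor the right edge of the left exon
        assert j.donor == 200
        assert j.acceptor == 99
        assert (j.left, j.right) == (99, 200)
        assert j.intron_length == 100

    def test_count_matches_naive_enumeration(self, rng):
        for i in range(100):
            g = random_gene(rng, f"G{i}", max_transcripts=6, max_exons=10)
            naive = set()
            for t in g.transcripts:
                for up, down in zip(t.exons, t.exons[1:]):
                    if len(up) < 25 or len(down) < 25:
                        continue
                    if g.strand == "+":
                        d, a = up.end - 1, down.start
                    else:
                        d, a = up.start, down.end - 1
                    if abs(a - d) - 1 < 50:
                        continue
                    naive.add((d, a))
            assert {(j.donor, j.acceptor) for j in catalog_junctions(g)} == naive
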